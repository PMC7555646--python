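"""Tandem-duplication clustering and collinear (segmental) block detection.

Tandem duplication follows the 200-kb rule: family genes on one
chromosome chain into a cluster while consecutive genes are within
``max_gap`` bp; clusters of two or more genes are reported. Collinear
blocks are chains of homologous gene pairs (anchors) monotonic in gene
rank on both chromosomes, found by dynamic programming in rank space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .models import Annotation, SequenceRecord

log = logging.getLogger(__name__)

# rough Karlin-Altschul parameters for gapped BLOSUM62 (-11/-1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class AnchorPair:
    """A homologous gene pair with a local-alignment score."""

    gene_a: str
    gene_b: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("anchor pair must be in canonical order (gene_a < gene_b)")
        if self.score <= 0:
            raise ValueError("anchor score must be positive")


@dataclass
class TandemCluster:
    chrom: str
    members: list[str]  # ordered by position
    span: int  # bp, first start to last end

    @property
    def n_pairs(self) -> int:
        return len(self.members) - 1


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    chain_score: float = 0.0


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def find_anchor_pairs(
    proteins: list[SequenceRecord],
    min_score: float = 100.0,
    e_max: float = 1e-6,
) -> list[AnchorPair]:
    """All-vs-all local protein alignment; keep high-scoring pairs.

    Smith-Waterman with BLOSM62/affine gaps stands in for the all-vs-all
    BLAST step; the E-value is a Karlin-Altschul estimate from the raw
    score and the two sequence lengths.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    aligner = make_aligner()
    out: list[AnchorPair] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            score = float(aligner.score(a.seq, b.seq))
            if score < min_score:
                continue
            evalue = _KA_K * len(a.seq) * len(b.seq) * math.exp(-_KA_LAMBDA * score)
            if evalue > e_max:
                continue
            ga, gb = sorted((a.id, b.id))
            out.append(AnchorPair(ga, gb, score, evalue))
    return out


# ---------------------------------------------------------------------------
# Tandem clustering


def detect_tandem_clusters(
    family_genes: list[str],
    annotation: Annotation,
    max_gap: int = 200_000,
    distance_mode: str = "end_to_start",
    unplaced_prefix: str = "scaffold",
) -> list[TandemCluster]:
    """Single-linkage chaining of family genes along each chromosome.

    Consecutive (position-sorted) family genes join one cluster while
    their separation is <= ``max_gap`` bp; distance is measured
    end-to-start by default (start-to-start as an alternative). Genes on
    unplaced scaffolds are skipped with a log line. Any number of
    intervening non-family genes is allowed.
    """
    if distance_mode not in ("end_to_start", "start_to_start"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    placed: dict[str, list] = {}
    for gid in family_genes:
        gene = annotation[gid]
        if gene.chrom.startswith(unplaced_prefix):
            log.info("skipping unplaced gene %s (%s)", gid, gene.chrom)
            continue
        placed.setdefault(gene.chrom, []).append(gene)

    clusters: list[TandemCluster] = []
    for chrom in sorted(placed):
        genes = sorted(placed[chrom], key=lambda g: (g.start, g.gene_id))
        run = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            if distance_mode == "end_to_start":
                gap = cur.start - prev.end
            else:
                gap = cur.start - prev.start
            if gap <= max_gap:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run))
                run = [cur]
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, genes: list) -> TandemCluster:
    return TandemCluster(
        chrom=chrom,
        members=[g.gene_id for g in genes],
        span=max(g.end for g in genes) - min(g.start for g in genes),
    )


def tandem_pair_count(clusters: list[TandemCluster], mode: str = "consecutive") -> int:
    """Total duplicated-pair count: consecutive pairs (default) or all pairs."""
    if mode == "consecutive":
        return sum(c.n_pairs for c in clusters)
    if mode == "all_pairs":
        return sum(len(c.members) * (len(c.members) - 1) // 2 for c in clusters)
    raise ValueError(f"unknown pair-count mode {mode!r}")


# ---------------------------------------------------------------------------
# Collinear blocks


def _anchor_points(
    anchors: list[AnchorPair],
    annot_a: Annotation,
    annot_b: Annotation,
) -> dict[tuple[str, str], list[tuple[int, int, AnchorPair]]]:
    """Map anchors to (rank_a, rank_b) points grouped by chromosome pair."""
    ranks_a = {c: annot_a.ranks(c) for c in annot_a.chromosomes()}
    ranks_b = {c: annot_b.ranks(c) for c in annot_b.chromosomes()}
    grouped: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    same = annot_a is annot_b
    for anc in anchors:
        if anc.gene_a not in annot_a or anc.gene_b not in annot_b:
            missing = anc.gene_a if anc.gene_a not in annot_a else anc.gene_b
            raise ValueError(f"anchor gene {missing!r} absent from annotation")
        ca, cb = annot_a[anc.gene_a].chrom, annot_b[anc.gene_b].chrom
        ra = ranks_a[ca][anc.gene_a]
        rb = ranks_b[cb][anc.gene_b]
        if same and (cb, rb) < (ca, ra):
            ca, cb, ra, rb = cb, ca, rb, ra
        grouped.setdefault((ca, cb), []).append((ra, rb, anc))
    return grouped


def _best_chain(
    points: list[tuple[int, int, AnchorPair]],
    max_rank_gap: int,
    sign: int,
) -> tuple[float, list[int]]:
    """Highest-scoring chain strictly increasing in x and in sign*y."""
    pts = sorted(range(len(points)), key=lambda k: (points[k][0], sign * points[k][1]))
    best_score = [0.0] * len(pts)
    back: list[int | None] = [None] * len(pts)
    for bi, k in enumerate(pts):
        x, y, anc = points[k]
        best_score[bi] = anc.score
        for bj in range(bi):
            px, py, _ = points[pts[bj]]
            dx = x - px
            dy = sign * (y - py)
            if 1 <= dx <= max_rank_gap and 1 <= dy <= max_rank_gap:
                cand = best_score[bj] + anc.score
                if cand > best_score[bi]:
                    best_score[bi] = cand
                    back[bi] = bj
    if not pts:
        return 0.0, []
    end = max(range(len(pts)), key=lambda b: best_score[b])
    chain: list[int] = []
    b: int | None = end
    while b is not None:
        chain.append(pts[b])
        b = back[b]
    chain.reverse()
    return best_score[end], chain


def detect_collinear_blocks(
    anchors: list[AnchorPair],
    annotation: Annotation,
    min_anchors: int = 3,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Collinear blocks within one genome (self-comparison)."""
    return cross_species_synteny(annotation, annotation, anchors, min_anchors, max_rank_gap)


def cross_species_synteny(
    annot_a: Annotation,
    annot_b: Annotation,
    anchors: list[AnchorPair],
    min_anchors: int = 3,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain anchors into monotonic blocks, greedily best-chain-first.

    Per chromosome pair, the best-scoring strictly monotonic chain (rank
    gap <= ``max_rank_gap`` per step on both sides) is extracted, its
    anchors removed, and the search repeated; chains shorter than
    ``min_anchors`` are discarded. Each anchor lands in at most one block.
    """
    grouped = _anchor_points(anchors, annot_a, annot_b)
    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(grouped):
        points = grouped[(ca, cb)]
        while True:
            fwd_score, fwd = _best_chain(points, max_rank_gap, sign=+1)
            rev_score, rev = _best_chain(points, max_rank_gap, sign=-1)
            if fwd_score >= rev_score:
                score, chain, orientation = fwd_score, fwd, "same"
            else:
                score, chain, orientation = rev_score, rev, "inverted"
            if len(chain) < min_anchors:
                break
            chosen = [points[k] for k in chain]
            blocks.append(
                SyntenyBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=[p[2] for p in chosen],
                    orientation=orientation,
                    chain_score=score,
                )
            )
            used = {id(p[2]) for p in chosen}
            points = [p for p in points if id(p[2]) not in used]
    return blocks


# ---------------------------------------------------------------------------
# Chromosome map


def chromosome_map(
    annotation: Annotation,
    family_genes: list[str],
    clusters: list[TandemCluster] | None = None,
    unplaced_prefix: str = "scaffold",
) -> dict:
    """Per-chromosome family counts, gene midpoints, and cluster spans."""
    counts: dict[str, int] = {}
    midpoints: dict[str, list[tuple[str, float]]] = {}
    unplaced: list[str] = []
    for gid in family_genes:
        gene = annotation[gid]
        if gene.chrom.startswith(unplaced_prefix):
            unplaced.append(gid)
            continue
        counts[gene.chrom] = counts.get(gene.chrom, 0) + 1
        midpoints.setdefault(gene.chrom, []).append(
            (gid, (gene.start + gene.end) / 2.0)
        )
    cluster_spans = [
        {
            "chrom": c.chrom,
            "first": c.members[0],
            "last": c.members[-1],
            "span_bp": c.span,
            "n_members": len(c.members),
        }
        for c in (clusters or [])
    ]
    return {
        "counts": counts,
        "midpoints": midpoints,
        "unplaced": unplaced,
        "clusters": cluster_spans,
    }


def write_links(
    blocks: list[SyntenyBlock],
    annot_a: Annotation,
    annot_b: Annotation,
    path,
) -> None:
    """Circos-style link table: one line per anchor pair."""
    with open(path, "w") as fh:
        for blk in blocks:
            for anc in blk.anchors:
                ga, gb = annot_a[anc.gene_a], annot_b[anc.gene_b]
                fh.write(
                    f"{ga.chrom}\t{ga.start}\t{ga.end}\t"
                    f"{gb.chrom}\t{gb.start}\t{gb.end}\n"
                )


def write_family_bed(annotation: Annotation, family_genes: list[str], path) -> None:
    rows = []
    for gid in family_genes:
        g = annotation[gid]
        rows.append((g.chrom, g.start - 1, g.end, gid, 0, g.strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
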
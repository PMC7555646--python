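"""Synthetic genome, annotation, domain-hit, promoter and expression
generator with machine-readable planted truth.

The generator emulates the data a receptor-kinase family survey consumes:
a multi-chromosome genome carrying background genes and a planted family
whose members have LRR + kinase domain hits; tandem clusters inside the
200-kb rule; collinear (segmental) duplicate runs across chromosomes with
duplicate pairs evolved to target Ks and Ka/Ks; promoters seeded with
library cis-elements; a tissue expression atlas and a rhizobial-infection
genotype x time course with planted specific/peaking gene sets.

All randomness flows from the single config seed. Family proteins share
one alignment length (indel-free), so the multiple-alignment step reduces
to reading the emitted alignment FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .kaks import codon_sites, translate_codon
from .models import ExpressionMatrix, SequenceRecord
from .promoter import IUPAC_DNA, MotifDef, load_motif_library

_BASES = "ACGT"
_AAS = "ACDEFGHIKLMNPQRSTVWY"

LRR_ACCS = ("PF00560", "PF13306", "PF13516", "PF13855", "PF08263")
KINASE_ACC = "PF00069"


# ---------------------------------------------------------------------------
# Config and truth


@dataclass
class SimConfig:
    """Generator settings; the defaults are the packaged study conditions."""

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 3_000_000
    n_background_genes: int = 160
    n_family_genes: int = 40
    n_scaffold_genes: int = 2
    n_outliers: int = 0
    aa_len: int = 350
    # within-subgroup divergence (Ks of a member from its subgroup ancestor)
    member_ks: float = 0.4
    member_omega: float = 0.25
    ref_ks: float = 0.5
    # duplication plans
    tandem_sizes: tuple[int, ...] = (2, 3, 5)
    tandem_ks: float = 0.15
    seg_blocks: tuple[tuple[int, str], ...] = ((4, "same"), (3, "inverted"))
    seg_ks: float = 0.6
    dup_omega: float = 0.2
    tandem_gap: tuple[int, int] = (20_000, 60_000)  # intra-cluster, bp
    island_gap: int = 200_001  # minimum separation between family islands
    # promoters
    elements_per_gene: tuple[int, int] = (2, 4)
    promoter_len: int = 2000
    # expression
    tissues: tuple[str, ...] = (
        "flower", "leaf", "petiole", "pod", "root", "root_tip", "seedling",
        "stem", "veg_bud", "nodule_4d", "nodule_10d", "nodule_28d",
    )
    specific_conditions: tuple[str, ...] = ("root", "nodule_10d")
    genotypes: tuple[str, ...] = ("A17", "nfp", "lyk3", "skl")
    timepoints: tuple[float, ...] = (0, 0.5, 1, 3, 6, 12, 24, 36, 48)
    n_expr_genes: int = 150
    n_specific: int = 52
    n_skl12: int = 36
    n_skl48: int = 21
    n_double_positive: int = 6
    n_replicates: int = 3
    noise_sd: float = 0.5
    planted_fold: float = 8.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        used = (
            self.n_scaffold_genes
            + sum(self.tandem_sizes)
            + 2 * sum(n for n, _ in self.seg_blocks)
            + self.n_outliers
        )
        if used > self.n_family_genes + self.n_outliers:
            raise ValueError("duplication plans exceed n_family_genes")
        if self.n_skl12 + self.n_skl48 + self.n_specific > 3 * self.n_expr_genes:
            raise ValueError("expression plans exceed n_expr_genes")


@dataclass
class TruthTables:
    """Planted ground truth, internally consistent with the emitted files."""

    family: pd.DataFrame = field(default_factory=pd.DataFrame)
    reference_labels: dict[str, str] = field(default_factory=dict)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    seg_blocks: list[dict] = field(default_factory=list)
    kaks_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoter_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    rescue_ids: list[str] = field(default_factory=list)
    background_ids: list[str] = field(default_factory=list)
    outlier_ids: list[str] = field(default_factory=list)
    expression: dict = field(default_factory=dict)
    n_genes_total: int = 0
    n_domain_hits: int = 0

    def write(self, truth_dir: Path) -> None:
        truth_dir.mkdir(parents=True, exist_ok=True)
        self.family.to_csv(truth_dir / "family.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.reference_labels.items()), columns=["leaf", "subgroup"]
        ).to_csv(truth_dir / "reference_labels.tsv", sep="\t", index=False)
        with open(truth_dir / "tandem_clusters.tsv", "w") as fh:
            for members in self.tandem_clusters:
                fh.write("\t".join(members) + "\n")
        with open(truth_dir / "seg_blocks.json", "w") as fh:
            json.dump(self.seg_blocks, fh, indent=1)
        self.kaks_pairs.to_csv(truth_dir / "kaks_pairs.tsv", sep="\t", index=False)
        self.promoter_counts.to_csv(truth_dir / "promoter_counts.tsv", sep="\t")
        with open(truth_dir / "expression.json", "w") as fh:
            json.dump(
                {
                    k: sorted(v) if isinstance(v, (set, list)) else v
                    for k, v in self.expression.items()
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Sequence evolution


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AAS), size=n))


_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _c = _b1 + _b2 + _b3
            _aa = translate_codon(_c)
            if _aa is not None:
                _CODONS_BY_AA.setdefault(_aa, []).append(_c)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """A random stop-free CDS encoding the given protein."""
    out = []
    for aa in protein:
        choices = _CODONS_BY_AA[aa]
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def evolve_cds(
    ancestor: str,
    target_ks: float,
    omega: float,
    seed: int | np.random.Generator,
) -> tuple[str, dict]:
    """Mutate a CDS by seeded point substitutions to a target divergence.

    Plants round(target_ks * S) synonymous and round(omega * target_ks * N)
    nonsynonymous events, where S and N are the ancestor's NG86 site
    counts; sites can be hit repeatedly (so downstream estimates need the
    usual multiple-hit correction). Substitutions creating stop codons are
    rejected and resampled. Returns the mutated CDS and a realized-event
    record.
    """
    if len(ancestor) % 3 != 0 or not ancestor:
        raise ValueError("ancestor length must be a positive multiple of 3")
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = [ancestor[k : k + 3] for k in range(0, len(ancestor), 3)]
    if any(translate_codon(c) is None for c in codons):
        raise ValueError("ancestor contains an internal stop codon")
    s_sites = sum(codon_sites(c)[0] for c in codons)
    n_sites = 3 * len(codons) - s_sites
    n_syn = round(target_ks * s_sites)
    n_non = round(omega * target_ks * n_sites)

    seq = list(ancestor)
    remaining_syn, remaining_non = n_syn, n_non
    max_iter = 2000 * (n_syn + n_non + 1)
    it = 0
    while remaining_syn > 0 or remaining_non > 0:
        it += 1
        if it > max_iter:
            raise ValueError("substitution target unreachable on this sequence")
        pos = int(rng.integers(len(seq)))
        alt = _BASES[int(rng.integers(4))]
        if alt == seq[pos]:
            continue
        ci = pos // 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        off = pos - 3 * ci
        new_codon = old_codon[:off] + alt + old_codon[off + 1 :]
        if translate_codon(new_codon) is None:
            continue
        synonymous = translate_codon(new_codon) == translate_codon(old_codon)
        if synonymous and remaining_syn > 0:
            seq[pos] = alt
            remaining_syn -= 1
        elif not synonymous and remaining_non > 0:
            seq[pos] = alt
            remaining_non -= 1
    record = {
        "target_ks": target_ks,
        "omega": omega,
        "n_syn_events": n_syn,
        "n_nonsyn_events": n_non,
        "s_sites": s_sites,
        "n_sites": n_sites,
    }
    return "".join(seq), record


# ---------------------------------------------------------------------------
# Naive promoter scan (independent truth oracle for planted elements)


def _matches_iupac(window: str, pattern: str) -> bool:
    return all(w in IUPAC_DNA[p] for w, p in zip(window, pattern))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def naive_scan_counts(
    promoters: dict[str, str], motifs: list[MotifDef]
) -> pd.DataFrame:
    """Position-by-position motif counting (both strands, one count per
    locus for palindromes); intentionally simple and regex-free."""
    names = [m.name for m in motifs]
    rows = {}
    for gid, seq in promoters.items():
        seq = seq.upper()
        counts = dict.fromkeys(names, 0)
        for motif in motifs:
            w = len(motif.pattern)
            for o in range(len(seq) - w + 1):
                win = seq[o : o + w]
                if _matches_iupac(win, motif.pattern):
                    counts[motif.name] += 1
                elif motif.both_strands and _matches_iupac(_revcomp(win), motif.pattern):
                    counts[motif.name] += 1
        rows[gid] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=names).astype(int)


# ---------------------------------------------------------------------------
# Genome simulation


@dataclass
class _GenePlan:
    key: str
    subgroup: str | None
    role: str  # isolated | tandem | segmental | scaffold | outlier | background
    cds: str
    protein: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    gene_id: str = ""
    exon_count: int = 0
    in_rescue: bool = False
    cluster_idx: int = -1
    block_idx: int = -1


def _split_exons(
    cds_len: int, k: int, rng: np.random.Generator
) -> list[int]:
    """Split a CDS into k exon lengths, each a positive multiple of 3."""
    n_codons = cds_len // 3
    if k > n_codons:
        k = n_codons
    cuts = sorted(rng.choice(np.arange(1, n_codons), size=k - 1, replace=False)) if k > 1 else []
    bounds = [0, *cuts, n_codons]
    return [3 * (b - a) for a, b in zip(bounds, bounds[1:])]


def simulate_genome(cfg: SimConfig, outdir: str | Path):
    """Emit the full synthetic bundle and its truth tables.

    Files: genome.fa, genes.gff3, proteins.fa, cds.fa, alignment.fa,
    domains.tsv, rescue_ids.txt, reference_labels.tsv, tissues.tsv,
    infection.tsv, ct.tsv and truth/*.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    from .phylo import subgroup_labels  # local import to avoid cycle at module load

    labels = subgroup_labels()
    motifs = load_motif_library()

    # ---- subgroup / role plan ------------------------------------------------
    plans: list[_GenePlan] = []
    kaks_rows: list[dict] = []
    clusters_truth: list[list[str]] = []
    seg_truth: list[dict] = []

    label_iter = iter(labels)
    ancestors: dict[str, str] = {}
    key_counter = iter(range(10**6))

    def ancestor_cds(label: str) -> str:
        if label not in ancestors:
            ancestors[label] = reverse_translate(random_protein(rng, cfg.aa_len), rng)
        return ancestors[label]

    def make_member(label: str, role: str, ks: float, omega: float, base: str | None = None):
        src = base if base is not None else ancestor_cds(label)
        cds, _ = evolve_cds(src, ks, omega, rng)
        protein = str(Seq(cds).translate())
        return _GenePlan(
            key=f"k{next(key_counter):03d}", subgroup=label, role=role,
            cds=cds, protein=protein,
        )

    # tandem clusters: members chained at tandem_ks from one subgroup founder
    cluster_plans: list[list[_GenePlan]] = []
    for ci, size in enumerate(cfg.tandem_sizes):
        label = next(label_iter)
        members: list[_GenePlan] = []
        founder = make_member(label, "tandem", cfg.member_ks, cfg.member_omega)
        founder.cluster_idx = ci
        plans.append(founder)
        members.append(founder)
        for _ in range(size - 1):
            prev = members[-1]
            child = make_member(label, "tandem", cfg.tandem_ks, cfg.dup_omega, base=prev.cds)
            child.cluster_idx = ci
            plans.append(child)
            members.append(child)
            kaks_rows.append(
                {"a_key": prev.key, "b_key": child.key, "target_ks": cfg.tandem_ks,
                 "omega": cfg.dup_omega, "kind": "tandem"}
            )
        cluster_plans.append(members)

    # segmental blocks: per anchor pair, a fresh subgroup and a duplicate at seg_ks
    block_plans: list[tuple[list[_GenePlan], list[_GenePlan], str]] = []
    for bi, (n_pairs, orientation) in enumerate(cfg.seg_blocks):
        a_side: list[_GenePlan] = []
        b_side: list[_GenePlan] = []
        for _ in range(n_pairs):
            label = next(label_iter)
            a = make_member(label, "segmental", cfg.member_ks, cfg.member_omega)
            b = make_member(label, "segmental", cfg.seg_ks, cfg.dup_omega, base=a.cds)
            a.block_idx = b.block_idx = bi
            plans.extend([a, b])
            a_side.append(a)
            b_side.append(b)
            kaks_rows.append(
                {"a_key": a.key, "b_key": b.key, "target_ks": cfg.seg_ks,
                 "omega": cfg.dup_omega, "kind": "segmental"}
            )
        block_plans.append((a_side, b_side, orientation))

    # scaffold + isolated members spread over the remaining subgroups
    remaining_labels = list(label_iter)
    n_rest = cfg.n_family_genes - sum(len(c) for c in cluster_plans) - 2 * sum(
        n for n, _ in cfg.seg_blocks
    )
    rest_plans: list[_GenePlan] = []
    for i in range(n_rest):
        label = remaining_labels[i % len(remaining_labels)] if remaining_labels else labels[i % len(labels)]
        role = "scaffold" if i < cfg.n_scaffold_genes else "isolated"
        p = make_member(label, role, cfg.member_ks, cfg.member_omega)
        plans.append(p)
        rest_plans.append(p)

    outlier_plans: list[_GenePlan] = []
    for i in range(cfg.n_outliers):
        cds = reverse_translate(random_protein(rng, cfg.aa_len), rng)
        p = _GenePlan(
            key=f"k{next(key_counter):03d}", subgroup=None, role="outlier",
            cds=cds, protein=str(Seq(cds).translate()),
        )
        plans.append(p)
        outlier_plans.append(p)

    # reference (anchor) proteins, one per subgroup
    reference_labels: dict[str, str] = {}
    reference_seqs: dict[str, str] = {}
    for label in labels:
        ref_cds, _ = evolve_cds(ancestor_cds(label), cfg.ref_ks, cfg.member_omega, rng)
        leaf = f"REF_{label}"
        reference_labels[leaf] = label
        reference_seqs[leaf] = str(Seq(ref_cds).translate())

    # ---- layout --------------------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    islands: dict[str, list[list[_GenePlan]]] = {c: [] for c in chroms}
    for ci, members in enumerate(cluster_plans):
        islands[chroms[ci % len(chroms)]].append(members)
    for bi, (a_side, b_side, orientation) in enumerate(block_plans):
        ca = chroms[bi % len(chroms)]
        cb = chroms[(bi + 1) % len(chroms)]
        for g in a_side:
            islands[ca].append([g])
        b_order = list(b_side) if orientation == "same" else list(reversed(b_side))
        for g in b_order:
            islands[cb].append([g])
    non_scaffold_rest = [p for p in rest_plans if p.role != "scaffold"] + outlier_plans
    for i, p in enumerate(non_scaffold_rest):
        islands[chroms[i % len(chroms)]].append([p])

    # interleave islands deterministically along each chromosome
    exon_plan_of_subgroup = {
        label: int(rng.integers(1, 16)) for label in labels
    }

    def build_gene(p: _GenePlan, chrom: str, start: int) -> int:
        base = exon_plan_of_subgroup.get(p.subgroup, 3)
        k = int(np.clip(base + rng.integers(-1, 2), 1, 15))
        lens = _split_exons(len(p.cds), k, rng)
        p.exon_count = len(lens)
        p.strand = "+" if rng.random() < 0.5 else "-"
        pos = start
        exons = []
        for li, L in enumerate(lens):
            exons.append((pos, pos + L - 1))
            pos += L
            if li < len(lens) - 1:
                pos += int(rng.integers(100, 400))  # intron
        p.chrom, p.start, p.end, p.exons = chrom, start, exons[-1][1], exons
        return p.end

    for chrom in chroms:
        pos = 60_000
        for island in islands[chrom]:
            for gi, p in enumerate(island):
                end = build_gene(p, chrom, pos)
                if gi < len(island) - 1:
                    pos = end + int(rng.integers(*cfg.tandem_gap))
                else:
                    pos = end + cfg.island_gap + int(rng.integers(0, 20_000))
            if pos > cfg.chrom_length - 20_000:
                raise ValueError(f"plans exceed capacity of {chrom}")

    # scaffold genes
    scaffold_plans = [p for p in rest_plans if p.role == "scaffold"]
    scaffold_lengths: dict[str, int] = {}
    for i, p in enumerate(scaffold_plans):
        chrom = f"scaffold{i + 1:04d}"
        build_gene(p, chrom, 5_000)
        scaffold_lengths[chrom] = p.end + 5_000

    # background genes fill the gaps between family islands
    family_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for p in plans:
        if p.chrom in family_windows:
            # reserve the gene body plus its 2-kb promoter side
            lo = p.start - (cfg.promoter_len + 500) if p.strand == "+" else p.start - 500
            hi = p.end + (cfg.promoter_len + 500) if p.strand == "-" else p.end + 500
            family_windows[p.chrom].append((max(1, lo), hi))

    bg_plans: list[_GenePlan] = []
    n_bg_left = cfg.n_background_genes
    chrom_cycle = 0
    positions = {c: 15_000 for c in chroms}
    while n_bg_left > 0:
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        pos = positions[chrom] + int(rng.integers(25_000, 45_000))
        if pos > cfg.chrom_length - 15_000:
            if all(positions[c] > cfg.chrom_length - 60_000 for c in chroms):
                raise ValueError("cannot place requested background genes")
            positions[chrom] = cfg.chrom_length
            continue
        positions[chrom] = pos
        n_codons = int(rng.integers(150, 400))
        cds = reverse_translate(random_protein(rng, n_codons), rng)
        p = _GenePlan(
            key=f"bg{len(bg_plans):03d}", subgroup=None, role="background",
            cds=cds, protein=str(Seq(cds).translate()),
        )
        end_guess = pos + len(cds) + 3 * 400
        if any(lo <= end_guess and pos <= hi for lo, hi in family_windows[chrom]):
            continue
        build_gene(p, chrom, pos)
        if any(lo <= p.end and p.start <= hi for lo, hi in family_windows[chrom]):
            continue
        positions[chrom] = p.end
        bg_plans.append(p)
        n_bg_left -= 1

    # ---- gene ids (by position) ---------------------------------------------
    all_plans = plans + bg_plans
    by_chrom: dict[str, list[_GenePlan]] = {}
    for p in all_plans:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        for i, p in enumerate(ps):
            p.gene_id = f"{chrom}_g{i + 1:03d}"

    family_plans = [p for p in plans if p.role != "outlier"]
    for members in cluster_plans:
        clusters_truth.append([m.gene_id for m in members])
    for bi, (a_side, b_side, orientation) in enumerate(block_plans):
        seg_truth.append(
            {
                "chrom_a": a_side[0].chrom,
                "chrom_b": b_side[0].chrom,
                "orientation": orientation,
                "pairs": [[a.gene_id, b.gene_id] for a, b in zip(a_side, b_side)],
            }
        )

    # ---- genome sequences, promoters ----------------------------------------
    chrom_seqs: dict[str, np.ndarray] = {}
    base_arr = np.array(list(_BASES))
    for chrom in chroms:
        chrom_seqs[chrom] = rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
    for chrom, length in scaffold_lengths.items():
        chrom_seqs[chrom] = rng.integers(0, 4, size=length).astype(np.uint8)
    base_code = {b: i for i, b in enumerate(_BASES)}

    def write_seq(chrom: str, start: int, seq: str) -> None:
        codes = np.fromiter((base_code[c] for c in seq), dtype=np.uint8, count=len(seq))
        chrom_seqs[chrom][start - 1 : start - 1 + len(seq)] = codes

    for p in all_plans:
        spliced = p.cds if p.strand == "+" else _revcomp(p.cds)
        off = 0
        for (s, e) in p.exons:
            write_seq(p.chrom, s, spliced[off : off + (e - s + 1)])
            off += e - s + 1

    # plant promoter elements (family genes only)
    promoter_strings: dict[str, str] = {}
    for p in family_plans:
        chrom_arr = chrom_seqs[p.chrom]
        if p.strand == "+":
            lo = max(1, p.start - cfg.promoter_len)
            window = "".join(base_arr[chrom_arr[lo - 1 : p.start - 1]])
        else:
            hi = min(len(chrom_arr), p.end + cfg.promoter_len)
            window = _revcomp("".join(base_arr[chrom_arr[p.end : hi]]))
        n_elem = int(rng.integers(cfg.elements_per_gene[0], cfg.elements_per_gene[1] + 1))
        prom = list(window)
        taken: list[tuple[int, int]] = []
        for _ in range(n_elem):
            motif = motifs[int(rng.integers(len(motifs)))]
            w = len(motif.pattern)
            for _attempt in range(50):
                o = int(rng.integers(0, len(prom) - w + 1))
                if all(o + w <= s or o >= e for s, e in taken):
                    concrete = "".join(
                        IUPAC_DNA[ch][int(rng.integers(len(IUPAC_DNA[ch])))]
                        for ch in motif.pattern
                    )
                    prom[o : o + w] = list(concrete)
                    taken.append((o, o + w))
                    break
        prom_str = "".join(prom)
        promoter_strings[p.gene_id] = prom_str
        # write the (possibly modified) promoter back, strand-correctly
        if p.strand == "+":
            lo = max(1, p.start - cfg.promoter_len)
            write_seq(p.chrom, lo, prom_str)
        else:
            hi = min(len(chrom_arr), p.end + cfg.promoter_len)
            write_seq(p.chrom, p.end + 1, _revcomp(prom_str))

    promoter_counts = naive_scan_counts(promoter_strings, motifs)

    # ---- domain hits ---------------------------------------------------------
    hit_lines: list[str] = []

    def lrr_hits_for(p: _GenePlan) -> None:
        n_regions = int(rng.integers(1, 4))
        region_starts = sorted(
            rng.choice(np.arange(25, max(26, cfg.aa_len - 130), 30), size=n_regions, replace=False)
        )
        for ri, s in enumerate(region_starts):
            acc = LRR_ACCS[int(rng.integers(len(LRR_ACCS)))]
            e = s + int(rng.integers(20, 28))
            ev = 10.0 ** float(rng.uniform(-30, -5))
            hit_lines.append(f"{p.gene_id}\t{acc}.12\t{ev:.3g}\t{s}\t{e}")
            if ri == 0 and rng.random() < 0.25:
                # a second clan profile over the same residues: counts once
                acc2 = LRR_ACCS[int(rng.integers(len(LRR_ACCS)))]
                ev2 = 10.0 ** float(rng.uniform(-20, -5))
                hit_lines.append(f"{p.gene_id}\t{acc2}.9\t{ev2:.3g}\t{s + 3}\t{e - 2}")
        p.__dict__["n_lrr_truth"] = n_regions

    family_and_outliers = [p for p in plans]
    two_kinase = set(
        rng.choice([p.key for p in family_plans], size=min(2, len(family_plans)), replace=False)
    )
    for p in family_and_outliers:
        lrr_hits_for(p)
        n_kin = 2 if p.key in two_kinase else 1
        kstart = cfg.aa_len - 110
        for ki in range(n_kin):
            ev = 10.0 ** float(rng.uniform(-60, -20))
            s = max(5, kstart - 120 * ki)
            hit_lines.append(f"{p.gene_id}\t{KINASE_ACC}.25\t{ev:.3g}\t{s}\t{s + 95}")
        p.__dict__["n_kinase_truth"] = n_kin

    # decoy hits on background genes
    bg_ids = [p.gene_id for p in bg_plans]
    decoy_lrr = bg_ids[0:8]
    decoy_kin = bg_ids[8:14]
    decoy_highe = bg_ids[14:18]
    boundary = bg_ids[18:19]
    for gid in decoy_lrr:
        ev = 10.0 ** float(rng.uniform(-15, -4))
        hit_lines.append(f"{gid}\t{LRR_ACCS[0]}.12\t{ev:.3g}\t10\t35")
    for gid in decoy_kin:
        ev = 10.0 ** float(rng.uniform(-30, -10))
        hit_lines.append(f"{gid}\t{KINASE_ACC}.25\t{ev:.3g}\t20\t115")
    for gid in decoy_highe:  # LRR+kinase but above the E-value ceiling
        hit_lines.append(f"{gid}\t{LRR_ACCS[1]}.12\t0.01\t10\t35")
        hit_lines.append(f"{gid}\t{KINASE_ACC}.25\t0.02\t60\t155")
    for gid in boundary:  # exactly at the ceiling: strict less-than removes it
        hit_lines.append(f"{gid}\t{LRR_ACCS[2]}.12\t0.001\t10\t35")
        hit_lines.append(f"{gid}\t{KINASE_ACC}.25\t0.001\t60\t155")

    # similarity-rescue candidate list: some family genes plus decoys
    rescue_pool = [p.gene_id for p in family_plans]
    n_rescue_family = min(5, len(rescue_pool))
    rescue_ids = sorted(
        list(rng.choice(rescue_pool, size=n_rescue_family, replace=False))
        + decoy_kin[:3]
    )
    for p in plans:
        p.in_rescue = p.gene_id in rescue_ids

    # ---- write files ---------------------------------------------------------
    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in [*chroms, *sorted(scaffold_lengths)]:
            seq = "".join(base_arr[chrom_seqs[chrom]])
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")

    gff_path = outdir / "genes.gff3"
    secondary_tx = set(
        rng.choice(
            [p.gene_id for p in family_plans if p.exon_count >= 3],
            size=min(4, sum(1 for p in family_plans if p.exon_count >= 3)),
            replace=False,
        )
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chroms:
            fh.write(f"##sequence-region {chrom} 1 {cfg.chrom_length}\n")
        for chrom in sorted(scaffold_lengths):
            fh.write(f"##sequence-region {chrom} 1 {scaffold_lengths[chrom]}\n")
        for chrom in [*chroms, *sorted(scaffold_lengths)]:
            for p in sorted(by_chrom.get(chrom, []), key=lambda q: q.start):
                gid = p.gene_id
                fh.write(
                    f"{p.chrom}\tsim\tgene\t{p.start}\t{p.end}\t.\t{p.strand}\t.\tID={gid}\n"
                )
                tx_sets = [(f"{gid}.1", p.exons)]
                if gid in secondary_tx:
                    tx_sets.append((f"{gid}.2", p.exons[:-1]))
                for tx_id, exons in tx_sets:
                    fh.write(
                        f"{p.chrom}\tsim\tmRNA\t{exons[0][0]}\t{exons[-1][1]}\t.\t"
                        f"{p.strand}\t.\tID={tx_id};Parent={gid}\n"
                    )
                    for ei, (s, e) in enumerate(exons, start=1):
                        fh.write(
                            f"{p.chrom}\tsim\texon\t{s}\t{e}\t.\t{p.strand}\t.\t"
                            f"ID={tx_id}.e{ei};Parent={tx_id}\n"
                        )
                        fh.write(
                            f"{p.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{p.strand}\t0\t"
                            f"ID={tx_id}.c{ei};Parent={tx_id}\n"
                        )

    def write_fa(path: Path, entries: list[tuple[str, str]]) -> None:
        with open(path, "w") as fh:
            for name, seq in entries:
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")

    all_sorted = sorted(all_plans, key=lambda p: p.gene_id)
    write_fa(outdir / "proteins.fa", [(p.gene_id, p.protein) for p in all_sorted])
    write_fa(outdir / "cds.fa", [(p.gene_id, p.cds) for p in all_sorted])
    aln_entries = [(p.gene_id, p.protein) for p in sorted(plans, key=lambda p: p.gene_id)]
    aln_entries += sorted(reference_seqs.items())
    write_fa(outdir / "alignment.fa", aln_entries)

    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("# gene_id accession evalue env_start env_end\n")
        fh.write("\n".join(hit_lines) + "\n")

    with open(outdir / "rescue_ids.txt", "w") as fh:
        fh.write("\n".join(rescue_ids) + "\n")

    pd.DataFrame(
        sorted(reference_labels.items()), columns=["leaf", "subgroup"]
    ).to_csv(outdir / "reference_labels.tsv", sep="\t", index=False)

    # ---- expression ----------------------------------------------------------
    family_ids = sorted(p.gene_id for p in family_plans)
    tissues_m, infection_m, ct_df, expr_truth = simulate_expression(
        cfg, gene_ids=family_ids + bg_ids, family_ids=family_ids
    )
    from .io import write_expression_tsv

    write_expression_tsv(tissues_m, outdir / "tissues.tsv")
    write_expression_tsv(infection_m, outdir / "infection.tsv")
    ct_df.to_csv(outdir / "ct.tsv", sep="\t", index=False)

    # ---- truth ---------------------------------------------------------------
    fam_rows = []
    for p in sorted(family_plans, key=lambda q: q.gene_id):
        fam_rows.append(
            {
                "gene_id": p.gene_id,
                "subgroup": p.subgroup or "",
                "role": p.role,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "exon_count": p.exon_count,
                "n_lrr": p.__dict__.get("n_lrr_truth", 0),
                "n_kinase": p.__dict__.get("n_kinase_truth", 0),
                "in_rescue": p.in_rescue,
                "protein_length": len(p.protein),
            }
        )
    key_to_id = {p.key: p.gene_id for p in plans}
    kaks_df = pd.DataFrame(
        [
            {
                "gene_a": key_to_id[r["a_key"]],
                "gene_b": key_to_id[r["b_key"]],
                "target_ks": r["target_ks"],
                "omega": r["omega"],
                "kind": r["kind"],
            }
            for r in kaks_rows
        ]
    )

    truth = TruthTables(
        family=pd.DataFrame(fam_rows),
        reference_labels=reference_labels,
        tandem_clusters=clusters_truth,
        seg_blocks=seg_truth,
        kaks_pairs=kaks_df,
        promoter_counts=promoter_counts,
        rescue_ids=rescue_ids,
        background_ids=bg_ids,
        outlier_ids=[p.gene_id for p in outlier_plans],
        expression=expr_truth,
        n_genes_total=len(all_plans),
        n_domain_hits=len(hit_lines),
    )
    truth.write(outdir / "truth")

    paths = {
        "genome": genome_path,
        "gff3": gff_path,
        "proteins": outdir / "proteins.fa",
        "cds": outdir / "cds.fa",
        "alignment": outdir / "alignment.fa",
        "domains": outdir / "domains.tsv",
        "rescue": outdir / "rescue_ids.txt",
        "reference_labels": outdir / "reference_labels.tsv",
        "tissues": outdir / "tissues.tsv",
        "infection": outdir / "infection.tsv",
        "ct": outdir / "ct.tsv",
    }
    _self_check(paths, truth, cfg)
    return paths, truth


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(
    cfg: SimConfig,
    gene_ids: list[str] | None = None,
    family_ids: list[str] | None = None,
):
    """Tissue atlas + infection time-course matrices with planted calls.

    Baseline abundances are log-normal; planted tissue-specific genes are
    elevated ``planted_fold`` x in the target conditions with the other
    tissues near zero; planted responders peak at (skl, 12 h) or
    (skl, 48 h); three replicates per condition carry Gaussian noise
    truncated at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000003]))
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_expr_genes)]
    genes = sorted(gene_ids)[: cfg.n_expr_genes]
    family_ids = [g for g in (family_ids or genes) if g in set(genes)]

    # planted sets
    dp = list(rng.choice(family_ids, size=min(cfg.n_double_positive, len(family_ids)), replace=False))
    others = [g for g in genes if g not in set(dp)]
    perm = list(rng.permutation(others))
    n12_extra = cfg.n_skl12 - len(dp)
    skl12 = set(dp) | set(perm[:n12_extra])
    skl48 = set(perm[n12_extra : n12_extra + cfg.n_skl48])
    n_spec_extra = cfg.n_specific - len(dp)
    spec_pool = perm[n12_extra + cfg.n_skl48 :]
    specific = set(dp) | set(spec_pool[:n_spec_extra])

    baselines = {g: float(rng.lognormal(3.0, 0.4)) for g in genes}

    def noisy(mean: float) -> float:
        return max(0.0, mean + float(rng.normal(0.0, cfg.noise_sd)))

    # tissue atlas
    t_conds = list(cfg.tissues)
    t_cols: dict[str, list[float]] = {}
    t_meta_rows = []
    tissue_means: dict[str, dict[str, float]] = {g: {} for g in genes}
    for g in genes:
        b = baselines[g]
        for cond in t_conds:
            if g in specific:
                mean = b * cfg.planted_fold if cond in cfg.specific_conditions else b * 0.02
            else:
                mean = b * float(rng.uniform(0.85, 1.18))
            tissue_means[g][cond] = mean
    for cond in t_conds:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{cond}.r{r}"
            t_cols[sid] = [noisy(tissue_means[g][cond]) for g in genes]
            t_meta_rows.append({"condition": cond, "replicate": r})
    tissues_m = ExpressionMatrix(
        pd.DataFrame(t_cols, index=genes),
        pd.DataFrame(t_meta_rows, index=list(t_cols)),
    )

    # infection course
    def fmt(t: float) -> str:
        return f"{t:g}"

    i_conds = [f"{g}:{fmt(t)}" for g in cfg.genotypes for t in cfg.timepoints]
    infect_means: dict[str, dict[str, float]] = {g: {} for g in genes}
    for g in genes:
        b = baselines[g]
        for cond in i_conds:
            geno, _, t = cond.partition(":")
            mean = b
            if g in skl12:
                if (geno, t) == ("skl", "12"):
                    mean = b * cfg.planted_fold
                elif (geno, t) == ("A17", "12"):
                    mean = b * 3.0
                elif (geno, t) == ("lyk3", "12"):
                    mean = b * 2.0
            elif g in skl48:
                if (geno, t) == ("skl", "48"):
                    mean = b * cfg.planted_fold
                elif (geno, t) == ("skl", "24"):
                    mean = b * 2.0
            infect_means[g][cond] = mean
    i_cols: dict[str, list[float]] = {}
    i_meta_rows = []
    for cond in i_conds:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{cond}.r{r}"
            i_cols[sid] = [noisy(infect_means[g][cond]) for g in genes]
            i_meta_rows.append({"condition": cond, "replicate": r})
    infection_m = ExpressionMatrix(
        pd.DataFrame(i_cols, index=genes),
        pd.DataFrame(i_meta_rows, index=list(i_cols)),
    )

    # qPCR Ct table for one double-positive gene against a reference gene
    target = dp[0] if dp else genes[0]
    rel_truth = {"A17_0h": 1.0, "skl_0h": 1.2, "skl_12h": 9.0, "skl_48h": 4.0}
    ct_rows = []
    ref_ct = 20.0
    dct_cal = 8.0
    for sample, rel in rel_truth.items():
        for _ in range(cfg.n_replicates):
            ct_rows.append(
                {"gene": "reference", "sample": sample,
                 "ct": ref_ct + float(rng.normal(0, 0.05))}
            )
            ct_rows.append(
                {"gene": target, "sample": sample,
                 "ct": ref_ct + dct_cal - np.log2(rel) + float(rng.normal(0, 0.05))}
            )
    ct_df = pd.DataFrame(ct_rows)

    expr_truth = {
        "specific": sorted(specific),
        "specific_conditions": list(cfg.specific_conditions),
        "skl12_peak": sorted(skl12),
        "skl48_peak": sorted(skl48),
        "double_positive": sorted(dp),
        "ct_target": target,
        "ct_reference": "reference",
        "ct_calibrator": "A17_0h",
        "ct_rel_truth": rel_truth,
        "baseline_condition": f"{cfg.genotypes[0]}:{fmt(cfg.timepoints[0])}",
    }
    return tissues_m, infection_m, ct_df, expr_truth


# ---------------------------------------------------------------------------
# Self-check


def _self_check(paths: dict, truth: TruthTables, cfg: SimConfig) -> None:
    """Verify the truth tables against the emitted files before returning."""
    from .io import read_fasta, read_gff3

    annotation = read_gff3(paths["gff3"])
    assert len(annotation) == truth.n_genes_total, "gene count mismatch"
    proteins = {r.id: r for r in read_fasta(paths["proteins"], alphabet="protein")}
    cds = {r.id: r for r in read_fasta(paths["cds"], alphabet="dna")}
    for row in truth.family.itertuples():
        assert row.gene_id in annotation, f"{row.gene_id} missing from GFF"
        assert row.gene_id in proteins, f"{row.gene_id} missing from proteins"
        translated = str(Seq(cds[row.gene_id].seq).translate())
        assert translated == proteins[row.gene_id].seq, f"CDS/protein mismatch {row.gene_id}"
        gene = annotation[row.gene_id]
        primary = max(gene.transcripts, key=lambda t: t.cds_length())
        assert len(primary.exons) == row.exon_count, f"exon count mismatch {row.gene_id}"
    aln = read_fasta(paths["alignment"], alphabet="protein")
    assert len({len(r.seq) for r in aln}) == 1, "alignment rows differ in length"
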
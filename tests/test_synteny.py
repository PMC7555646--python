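"""Tandem clustering (200-kb rule), anchor detection, collinear chaining."""

import random

import pytest

from lrrkit import synteny
from lrrkit.models import Annotation, GeneModel, SequenceRecord
from lrrkit.synteny import AnchorPair

from .oracles import best_monotonic_chain_oracle, tandem_components_oracle


def _annotation(genes):
    """genes: list of (gid, chrom, start, end)."""
    ann = Annotation()
    for gid, chrom, start, end in genes:
        ann.add(GeneModel(gid, chrom, "+", start, end))
    return ann


# ---------------------------------------------------------------------------
# Tandem clusters


def test_two_genes_within_200kb_form_one_cluster():
    ann = _annotation([("a", "chr1", 100_000, 105_000), ("b", "chr1", 155_000, 160_000)])
    clusters = synteny.detect_tandem_clusters(["a", "b"], ann)
    assert len(clusters) == 1
    assert clusters[0].members == ["a", "b"]
    assert clusters[0].n_pairs == 1


def test_two_genes_beyond_200kb_do_not_cluster():
    ann = _annotation([("a", "chr1", 100_000, 105_000), ("b", "chr1", 355_001, 360_000)])
    assert synteny.detect_tandem_clusters(["a", "b"], ann) == []


def test_exact_200kb_boundary_is_inside_the_rule():
    ann = _annotation([("a", "chr1", 100_000, 105_000), ("b", "chr1", 305_000, 310_000)])
    assert len(synteny.detect_tandem_clusters(["a", "b"], ann)) == 1


def _random_layout(rng, n):
    genes, pos = [], 0
    for i in range(n):
        pos += rng.randint(1_000, 400_000)
        length = rng.randint(1_000, 8_000)
        genes.append((f"g{i:03d}", pos, pos + length))
        pos += length
    return genes


def test_clustering_matches_brute_force_on_random_layouts():
    """200 random layouts, including near-boundary gaps, against an
    all-pairs single-linkage connected-components oracle."""
    rng = random.Random(1234)
    for trial in range(200):
        n = rng.randint(2, 12)
        genes = _random_layout(rng, n)
        if trial % 3 == 0:  # force boundary-exact gaps sometimes
            gid, s, e = genes[-1]
            genes[-1] = (gid, genes[-2][2] + 200_000, genes[-2][2] + 205_000)
        ann = _annotation([(g, "chr1", s, e) for g, s, e in genes])
        ids = [g for g, _, _ in genes]
        rng.shuffle(ids)  # input order must not matter
        ours = sorted(c.members for c in synteny.detect_tandem_clusters(ids, ann))
        oracle = tandem_components_oracle(genes, 200_000)
        assert ours == oracle, f"trial {trial}"


def test_raising_max_gap_never_unclusters_genes():
    rng = random.Random(5)
    genes = _random_layout(rng, 10)
    ann = _annotation([(g, "chr1", s, e) for g, s, e in genes])
    ids = [g for g, _, _ in genes]
    prev = -1
    for gap in (50_000, 150_000, 250_000, 450_000):
        clustered = sum(
            len(c.members) for c in synteny.detect_tandem_clusters(ids, ann, gap)
        )
        assert clustered >= prev
        prev = clustered


def test_unplaced_scaffold_genes_are_skipped():
    ann = _annotation(
        [("a", "scaffold0001", 1_000, 2_000), ("b", "scaffold0001", 3_000, 4_000)]
    )
    assert synteny.detect_tandem_clusters(["a", "b"], ann) == []


def test_generator_tandem_clusters_recovered(bundle_annotation, bundle_family, bundle_truth):
    clusters = synteny.detect_tandem_clusters(bundle_family.members, bundle_annotation)
    assert sorted(c.members for c in clusters) == sorted(bundle_truth.tandem_clusters)


# ---------------------------------------------------------------------------
# Anchor pairs


def test_identical_proteins_are_a_maximal_anchor():
    rng = random.Random(0)
    seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
    pair = synteny.find_anchor_pairs(
        [SequenceRecord("a", seq, "protein"), SequenceRecord("b", seq, "protein")]
    )
    assert len(pair) == 1 and pair[0].gene_a == "a"
    aligner = synteny.make_aligner()
    assert pair[0].score == aligner.score(seq, seq)


def test_unrelated_random_proteins_score_below_threshold():
    """100 random 200-aa pairs: none reaches the default anchor score."""
    rng = random.Random(99)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    for i in range(2):
        records.append("".join(rng.choice(aas) for _ in range(200)))
    hits = 0
    for trial in range(100):
        a = "".join(rng.choice(aas) for _ in range(200))
        b = "".join(rng.choice(aas) for _ in range(200))
        found = synteny.find_anchor_pairs(
            [SequenceRecord("a", a, "protein"), SequenceRecord("b", b, "protein")]
        )
        hits += len(found)
    assert hits == 0


def test_anchor_canonical_order_enforced():
    with pytest.raises(ValueError, match="canonical"):
        AnchorPair("z", "a", 100.0, 1e-10)


# ---------------------------------------------------------------------------
# Collinear chaining


def _rank_annotation(n_per_chrom, chroms=("chrA", "chrB")):
    genes = []
    for chrom in chroms:
        for i in range(n_per_chrom):
            start = 1_000 + 10_000 * i
            genes.append((f"{chrom}_{i:02d}", chrom, start, start + 2_000))
    return _annotation(genes)


def _anchor(i, j, score=100.0):
    return AnchorPair(f"chrA_{i:02d}", f"chrB_{j:02d}", score, 1e-20)


def test_perfect_rank_order_yields_one_same_orientation_block():
    ann = _rank_annotation(6)
    anchors = [_anchor(i, i) for i in range(5)]
    blocks = synteny.detect_collinear_blocks(anchors, ann, min_anchors=3, max_rank_gap=5)
    assert len(blocks) == 1
    assert blocks[0].orientation == "same"
    assert len(blocks[0].anchors) == 5


def test_reversed_rank_order_yields_inverted_block():
    ann = _rank_annotation(6)
    anchors = [_anchor(i, 4 - i) for i in range(5)]
    blocks = synteny.detect_collinear_blocks(anchors, ann, min_anchors=3, max_rank_gap=5)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_chain_scores_match_exhaustive_enumeration():
    """Random <=8-anchor instances with decoys: the DP chain equals the
    best chain found by enumerating every monotonic subsequence."""
    rng = random.Random(2024)
    for trial in range(40):
        n = rng.randint(2, 8)
        pts = []
        used = set()
        while len(pts) < n:
            x, y = rng.randint(0, 14), rng.randint(0, 14)
            if (x, y) in used:
                continue
            used.add((x, y))
            pts.append((x, y, round(rng.uniform(50, 150), 3)))
        gap = rng.randint(2, 6)
        ann = _rank_annotation(15)
        anchors = [_anchor(x, y, s) for x, y, s in pts]
        blocks = synteny.detect_collinear_blocks(anchors, ann, min_anchors=1, max_rank_gap=gap)
        best_ours = max((b.chain_score for b in blocks), default=0.0)
        best_oracle, _ = best_monotonic_chain_oracle(pts, gap)
        assert best_ours == pytest.approx(best_oracle), f"trial {trial}"


def test_emitted_blocks_are_strictly_monotonic_in_both_ranks():
    rng = random.Random(77)
    pts = {(rng.randint(0, 14), rng.randint(0, 14)) for _ in range(12)}
    ann = _rank_annotation(15)
    anchors = [_anchor(x, y, rng.uniform(50, 150)) for x, y in pts]
    blocks = synteny.detect_collinear_blocks(anchors, ann, min_anchors=2, max_rank_gap=6)
    ranks_a = ann.ranks("chrA")
    ranks_b = ann.ranks("chrB")
    for b in blocks:
        xs = [ranks_a[a.gene_a] for a in b.anchors]
        ys = [ranks_b[a.gene_b] for a in b.anchors]
        assert xs == sorted(xs) and len(set(xs)) == len(xs)
        assert ys == sorted(ys) or ys == sorted(ys, reverse=True)
        assert len(set(ys)) == len(ys)


def test_identical_genomes_give_full_length_blocks_per_chromosome():
    ann_a = _rank_annotation(6, chroms=("c1", "c2"))
    ann_b = _rank_annotation(6, chroms=("c1", "c2"))
    # rename B-side ids to avoid collisions while keeping identical layout
    ann_b2 = Annotation()
    for g in ann_b.genes.values():
        ann_b2.add(GeneModel("x" + g.gene_id, g.chrom, g.strand, g.start, g.end))
    anchors = [
        AnchorPair(f"{c}_{i:02d}", f"x{c}_{i:02d}", 100.0, 1e-20)
        for c in ("c1", "c2")
        for i in range(6)
    ]
    blocks = synteny.cross_species_synteny(ann_a, ann_b2, anchors, min_anchors=3)
    assert sorted((b.chrom_a, len(b.anchors)) for b in blocks) == [("c1", 6), ("c2", 6)]


def test_shuffled_gene_order_gives_no_blocks():
    """A fixed-seed permutation control: this shuffle contains no chance
    monotonic run satisfying the chain constraints."""
    rng = random.Random(10)
    ann = _rank_annotation(30)
    ys = list(range(30))
    rng.shuffle(ys)
    anchors = [_anchor(i, ys[i]) for i in range(30)]
    blocks = synteny.detect_collinear_blocks(anchors, ann, min_anchors=3, max_rank_gap=3)
    assert blocks == []


def test_generator_planted_blocks_have_full_anchor_recall(
    bundle_paths, bundle_annotation, bundle_family, bundle_truth
):
    """Every planted segmental anchor pair lands in a detected block."""
    from lrrkit import io as lio

    proteins = lio.fasta_dict(lio.read_fasta(bundle_paths["proteins"], alphabet="protein"))
    fam_prot = [proteins[g] for g in bundle_family.members]
    anchors = synteny.find_anchor_pairs(fam_prot)
    in_cluster = set()
    for c in bundle_truth.tandem_clusters:
        for i, a in enumerate(c):
            for b in c[i + 1 :]:
                in_cluster.add((min(a, b), max(a, b)))
    seg_anchors = [a for a in anchors if (a.gene_a, a.gene_b) not in in_cluster]
    blocks = synteny.detect_collinear_blocks(seg_anchors, bundle_annotation)
    found = {
        (min(a.gene_a, a.gene_b), max(a.gene_a, a.gene_b))
        for b in blocks
        for a in b.anchors
    }
    for blk in bundle_truth.seg_blocks:
        for a, b in blk["pairs"]:
            assert (min(a, b), max(a, b)) in found


# ---------------------------------------------------------------------------
# Chromosome map


def test_chromosome_map_counts_and_unplaced():
    ann = _annotation(
        [("a", "chr1", 1_000, 2_000), ("b", "chr1", 400_000, 402_000),
         ("c", "chr1", 900_000, 902_000), ("d", "scaffold0009", 100, 900)]
    )
    cmap = synteny.chromosome_map(ann, ["a", "b", "c", "d"])
    assert cmap["counts"] == {"chr1": 3}
    assert cmap["unplaced"] == ["d"]


def test_chromosome_map_empty_family():
    ann = _annotation([("a", "chr1", 1_000, 2_000)])
    cmap = synteny.chromosome_map(ann, [])
    assert cmap["counts"] == {} and cmap["unplaced"] == []


def test_chromosome_map_matches_generator_truth(bundle_annotation, bundle_family, bundle_truth):
    cmap = synteny.chromosome_map(bundle_annotation, bundle_family.members)
    truth = bundle_truth.family
    placed = truth[~truth.chrom.str.startswith("scaffold")]
    assert cmap["counts"] == placed.groupby("chrom").size().to_dict()
    assert sorted(cmap["unplaced"]) == sorted(
        truth[truth.chrom.str.startswith("scaffold")].gene_id
    )
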
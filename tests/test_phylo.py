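"""p-distances, neighbor-joining, bootstrap supports, subgroup assignment."""

import random

import numpy as np
import pytest

from lrrkit import phylo
from lrrkit.models import SequenceRecord

from .oracles import (
    dendropy_splits,
    enumerate_unrooted_topologies,
    ols_fit_residual,
    random_additive_matrix,
    tree_splits,
)


def prot(i, seq):
    return SequenceRecord(f"t{i}", seq, "protein")


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_identical_rows_is_zero():
    d = phylo.p_distance_matrix([prot(0, "ACDE"), prot(1, "ACDE")])
    assert d.get("t0", "t1") == 0.0


def test_p_distance_counts_mismatches_per_site():
    d = phylo.p_distance_matrix([prot(0, "AAAA"), prot(1, "TTTA")])
    assert d.get("t0", "t1") == pytest.approx(0.75)


def test_p_distance_pairwise_deletion_excludes_gapped_sites():
    d = phylo.p_distance_matrix(
        [prot(0, "A-CD"), prot(1, "ABCD")], gap_mode="pairwise_deletion"
    )
    assert d.get("t0", "t1") == 0.0


def test_p_distance_complete_deletion_drops_columns_with_any_gap():
    rows = [prot(0, "A-CD"), prot(1, "ABCD"), prot(2, "ABCE")]
    d = phylo.p_distance_matrix(rows, gap_mode="complete_deletion")
    # column 2 removed everywhere: compare ACD vs ACE etc on 3 cols
    assert d.get("t1", "t2") == pytest.approx(1 / 3)


def test_p_distance_no_comparable_sites_is_an_error():
    with pytest.raises(ValueError, match="t0.*t1"):
        phylo.p_distance_matrix([prot(0, "A--"), prot(1, "-AA")])


# ---------------------------------------------------------------------------
# Neighbor-joining


def test_nj_two_taxa_single_edge():
    d = phylo.DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
    tree = phylo.nj_tree(d)
    pdm = tree.phylogenetic_distance_matrix()
    ta, tb = tree.taxon_namespace.get_taxon("a"), tree.taxon_namespace.get_taxon("b")
    assert pdm.patristic_distance(ta, tb) == pytest.approx(0.4)


def test_nj_three_taxa_closed_form_pendants():
    m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = phylo.nj_tree(phylo.DistanceMatrix(["a", "b", "c"], m))
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError, match="symmetric"):
        phylo.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [0.5, 0]]))


def _patristic_matrix(tree, taxa):
    pdm = tree.phylogenetic_distance_matrix()
    tl = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(tl[taxa[i]], tl[taxa[j]])
    return out


def test_nj_recovers_random_additive_trees_exactly():
    """On additive matrices NJ returns the generating topology and branch
    lengths (checked via the patristic matrix) to within 1e-9."""
    rng = random.Random(42)
    for _ in range(50):
        n = rng.randint(4, 12)
        taxa, d, g = random_additive_matrix(rng, n)
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa, d))
        assert dendropy_splits(tree, taxa) == tree_splits(g, taxa)
        assert np.abs(_patristic_matrix(tree, taxa) - d).max() < 1e-9


def test_nj_cherry_pendant_lengths_sum_to_pair_distance():
    rng = random.Random(3)
    taxa, d, g = random_additive_matrix(rng, 8)
    tree = phylo.nj_tree(phylo.DistanceMatrix(taxa, d))
    dm = {taxa[i]: i for i in range(len(taxa))}
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            a, b = (k.taxon.label for k in kids)
            assert kids[0].edge.length + kids[1].edge.length == pytest.approx(
                d[dm[a], dm[b]], abs=1e-9
            )


def test_nj_topology_agrees_with_independent_library_implementation():
    """Cross-check against scikit-bio's neighbor joining on noisy (non-
    additive) matrices: same unrooted topology."""
    import skbio

    rng = random.Random(17)
    nprng = np.random.default_rng(17)
    for _ in range(10):
        n = rng.randint(4, 9)
        taxa, d, _ = random_additive_matrix(rng, n)
        noise = nprng.uniform(0, 0.01, size=d.shape)
        d = d + (noise + noise.T)  # keep bitwise symmetry
        np.fill_diagonal(d, 0.0)
        ours = phylo.nj_tree(phylo.DistanceMatrix(taxa, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        import io as _io

        theirs_dendropy = __import__("dendropy").Tree.get(
            data=theirs.write(_io.StringIO()).getvalue(),
            schema="newick",
            preserve_underscores=True,
        )
        assert dendropy_splits(ours, taxa) == dendropy_splits(theirs_dendropy, taxa)


def test_nj_topology_is_ols_optimal_on_additive_input():
    """Against exhaustive enumeration of all 5-taxon unrooted topologies
    scored by OLS, the NJ topology attains the minimum residual (zero)."""
    rng = random.Random(9)
    taxa, d, g = random_additive_matrix(rng, 5)
    tree = phylo.nj_tree(phylo.DistanceMatrix(taxa, d))
    nj_splits = dendropy_splits(tree, taxa)
    residuals = {}
    for topo in enumerate_unrooted_topologies(taxa):
        residuals[frozenset(tree_splits(topo, taxa))] = ols_fit_residual(topo, taxa, d)
    best = min(residuals.values())
    assert residuals[frozenset(nj_splits)] == pytest.approx(best, abs=1e-9)
    assert best < 1e-12


# ---------------------------------------------------------------------------
# Bootstrap


def _two_clade_alignment():
    """Twenty diagnostic columns, no homoplasy: clade {t0,t1} vs {t2,t3,t4}."""
    a, b = "A" * 20, "C" * 20
    rows = [a, a, b, b, b]
    suffix = ["DEFGHIKLMN", "DEFGHIKLMI", "DEFGHIKLMV", "DEFGHIKLMW", "DEFGHIKLMY"]
    return [prot(i, rows[i] + suffix[i]) for i in range(5)]


def test_bootstrap_deterministic_given_seed():
    aln = _two_clade_alignment()
    t1 = phylo.bootstrap_supports(aln, n_reps=25, seed=123)
    t2 = phylo.bootstrap_supports(aln, n_reps=25, seed=123)
    s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
    s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
    assert s1 == s2


def test_bootstrap_clean_split_gets_full_support():
    aln = _two_clade_alignment()
    tree = phylo.bootstrap_supports(aln, n_reps=50, seed=0)
    taxa = [r.id for r in aln]
    target = frozenset({"t2", "t3", "t4"})  # side not containing anchor t0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if "t0" not in clade else frozenset(set(taxa) - clade)
        if side == target:
            assert node.support == 100.0
            return
    pytest.fail("separating edge not found")


def test_bootstrap_single_replicate_supports_are_zero_or_hundred():
    aln = _two_clade_alignment()
    tree = phylo.bootstrap_supports(aln, n_reps=1, seed=7)
    sup = [n.support for n in tree.preorder_node_iter() if hasattr(n, "support")]
    assert sup and set(sup) <= {0.0, 100.0}


# ---------------------------------------------------------------------------
# Subgroup assignment


def _labeled_tree(newick):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def test_assign_query_sister_to_single_reference():
    tree = _labeled_tree("((q1:0.1,REF_A:0.1):0.5,(REF_B:0.1,x:0.8):0.5,REF_C:0.9);")
    labels = {
        "REF_A": "RLK-Pelle_LRR-I",
        "REF_B": "RLK-Pelle_LRR-IV",
        "REF_C": "RLK-Pelle_LRR-XV",
    }
    out = {a.gene_id: a for a in phylo.assign_subgroups(tree, labels)}
    assert out["q1"].subgroup == "RLK-Pelle_LRR-I"
    assert out["q1"].status == "assigned"


def test_assign_mixed_label_clade_is_unclassified():
    tree = _labeled_tree(
        "((q1:0.1,(REF_A:0.1,REF_B:0.1):0.1):0.5,(REF_C:0.1,REF_D:0.1):0.5);"
    )
    labels = {
        "REF_A": "RLK-Pelle_LRR-II-1",
        "REF_B": "RLK-Pelle_LRR-IV",
        "REF_C": "RLK-Pelle_LRR-II-1",
        "REF_D": "RLK-Pelle_LRR-IV",
    }
    out = {a.gene_id: a for a in phylo.assign_subgroups(tree, labels)}
    assert out["q1"].status == "unclassified"


def test_assign_requires_reference_leaves():
    tree = _labeled_tree("((a:1,b:1):1,c:1,d:1);")
    with pytest.raises(ValueError, match="no labeled reference"):
        phylo.assign_subgroups(tree, {})


def test_assignments_only_use_packaged_labels(bundle_paths, bundle_truth):
    from lrrkit import io as lio

    aln = lio.read_fasta(bundle_paths["alignment"], alphabet="protein")
    tree = phylo.nj_tree_from_alignment(aln)
    out = phylo.assign_subgroups(tree, bundle_truth.reference_labels)
    allowed = set(phylo.subgroup_labels())
    assert all(a.subgroup in allowed for a in out if a.status == "assigned")


def test_generator_subgroups_assigned_perfectly(bundle_paths, bundle_truth):
    """Every planted family member lands in its planted subgroup."""
    from lrrkit import io as lio

    aln = lio.read_fasta(bundle_paths["alignment"], alphabet="protein")
    tree = phylo.bootstrap_supports(aln, n_reps=50, seed=1)
    out = {a.gene_id: a for a in phylo.assign_subgroups(tree, bundle_truth.reference_labels)}
    truth = bundle_truth.family.set_index("gene_id")["subgroup"]
    for gid, expected in truth.items():
        assert out[gid].status == "assigned", gid
        assert out[gid].subgroup == expected, gid


def test_three_queries_per_subgroup_all_assigned(tmp_path):
    """A 24-subgroup plan with 3 queries each classifies 100% correctly."""
    from lrrkit import io as lio
    from lrrkit.simulate import SimConfig, simulate_genome

    cfg = SimConfig(
        seed=13, n_family_genes=72, n_scaffold_genes=0,
        tandem_sizes=(), seg_blocks=(), n_background_genes=60,
        chrom_length=6_000_000,
    )
    paths, truth = simulate_genome(cfg, tmp_path / "b")
    aln = lio.read_fasta(paths["alignment"], alphabet="protein")
    tree = phylo.bootstrap_supports(aln, n_reps=50, seed=2)
    out = {a.gene_id: a for a in phylo.assign_subgroups(tree, truth.reference_labels)}
    fam = truth.family.set_index("gene_id")["subgroup"]
    assert len(fam) == 72
    assert all(out[g].subgroup == s for g, s in fam.items())
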
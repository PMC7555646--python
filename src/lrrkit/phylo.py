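"""Distance-based phylogenetics: p-distances, neighbor-joining, bootstrap
supports, and reference-anchored subgroup classification.

The family is classified into the 24 canonical LRR-RLK subgroups
(RLK-Pelle_LRR-I ... RLK-Pelle_LRR-XV) by clade membership with labeled
reference leaves, the way plant LRR-RLK surveys anchor their trees with
Arabidopsis sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ilres

import dendropy
import numpy as np
import pandas as pd

from .models import SequenceRecord

GAP_CHARS = frozenset("-.")


def load_subgroup_census() -> pd.DataFrame:
    """Packaged per-subgroup member counts for the three reference species."""
    with _ilres.files("lrrkit.data").joinpath("subgroup_census.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def subgroup_labels() -> list[str]:
    return list(load_subgroup_census()["subgroup"])


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])


def _char_matrix(records: list[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    return np.array([list(r.seq.upper()) for r in records])


def p_distance_matrix(
    records: list[SequenceRecord],
    gap_mode: str = "pairwise_deletion",
) -> DistanceMatrix:
    """Proportion of differing residues per compared site.

    ``pairwise_deletion`` excludes, per pair, positions gapped in either
    row; ``complete_deletion`` first drops columns gapped in any row.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 taxa")
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    chars = _char_matrix(records)
    is_gap = np.isin(chars, list(GAP_CHARS))
    if gap_mode == "complete_deletion":
        keep = ~is_gap.any(axis=0)
        chars = chars[:, keep]
        is_gap = is_gap[:, keep]
    n = len(records)
    if not is_gap.any():
        # indel-free fast path (bootstrap replicates hit this constantly)
        codes = chars.view(np.uint32).reshape(chars.shape)
        diff = codes[:, None, :] != codes[None, :, :]
        d = diff.mean(axis=2)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix([r.id for r in records], d)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(is_gap[i] | is_gap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {records[i].id!r} and {records[j].id!r}"
                )
            mism = int((chars[i, ok] != chars[j, ok]).sum())
            d[i, j] = d[j, i] = mism / compared
    return DistanceMatrix([r.id for r in records], d)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining on a distance matrix.

    Joins minimize Q(i,j) = (n-2) d(i,j) - R_i - R_j with ties broken by
    the smallest (i,j) index pair in current taxon order. Pendant lengths
    use the standard two-point formulas; negative lengths are clamped to
    zero. The result is unrooted (trifurcating seed node for >=3 taxa).
    """
    taxa = dist.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    tns = dendropy.TaxonNamespace(taxa)
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(label)) for label in taxa
    ]

    if len(taxa) == 2:
        root = dendropy.Node()
        half = float(dist.d[0, 1]) / 2.0
        for node in nodes:
            node.edge.length = half
            root.add_child(node)
        tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
        tree.is_rooted = False
        return tree

    n0 = len(taxa)
    # pre-allocated matrix with room for every join node
    big = np.zeros((2 * n0, 2 * n0))
    big[:n0, :n0] = dist.d
    active = list(range(n0))  # indices into big, in current taxon order
    node_of = {i: nodes[i] for i in active}
    next_idx = n0

    while len(active) > 3:
        m = len(active)
        act = np.array(active)
        sub = big[np.ix_(act, act)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin: ties resolve to the smallest (i, j) index pair
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = float(sub[ai, aj])
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        node_of[i].edge.length = max(float(li), 0.0)
        node_of[j].edge.length = max(float(lj), 0.0)
        parent = dendropy.Node()
        parent.add_child(node_of[i])
        parent.add_child(node_of[j])
        u = next_idx
        next_idx += 1
        rest = np.array([k for k in active if k not in (i, j)])
        if rest.size:
            du = 0.5 * (big[i, rest] + big[j, rest] - dij)
            big[u, rest] = du
            big[rest, u] = du
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = parent

    # final trifurcation
    a, b, c = active
    dab, dac, dbc = float(big[a, b]), float(big[a, c]), float(big[b, c])
    root = dendropy.Node()
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        node_of[idx].edge.length = max(length, 0.0)
        root.add_child(node_of[idx])
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False
    return tree


def nj_tree_from_alignment(
    records: list[SequenceRecord], gap_mode: str = "pairwise_deletion"
) -> dendropy.Tree:
    return nj_tree(p_distance_matrix(records, gap_mode=gap_mode))


# ---------------------------------------------------------------------------
# Bootstrap


def _bipartitions(tree: dendropy.Tree, anchor: str) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions keyed by the leaf side not holding ``anchor``."""
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if anchor not in clade else frozenset(all_leaves - clade)
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap_supports(
    records: list[SequenceRecord],
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise_deletion",
) -> dendropy.Tree:
    """NJ tree on the full alignment with column-resampled bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree, and every internal edge of the full-data tree is scored by
    the percentage of replicates containing the same bipartition.
    Deterministic for a given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    chars = _char_matrix(records)
    if chars.shape[1] < 1:
        raise ValueError("alignment has no columns")
    tree = nj_tree_from_alignment(records, gap_mode=gap_mode)
    anchor = records[0].id
    main_bips = _bipartitions(tree, anchor)
    counts = {bip: 0 for bip in main_bips}

    rng = np.random.default_rng(seed)
    ncol = chars.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [
            SequenceRecord(r.id, "".join(chars[i, cols]), r.alphabet)
            for i, r in enumerate(records)
        ]
        rep_tree = nj_tree_from_alignment(resampled, gap_mode=gap_mode)
        rep_bips = set(_bipartitions(rep_tree, anchor))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1

    for bip, node in main_bips.items():
        support = 100.0 * counts[bip] / n_reps
        node.support = support
        node.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# Subgroup assignment


@dataclass
class SubgroupAssignment:
    gene_id: str
    subgroup: str | None
    support: float
    status: str  # "assigned" | "unclassified"


def assign_subgroups(
    tree: dendropy.Tree,
    reference_labels: dict[str, str],
    min_support: float = 50.0,
) -> list[SubgroupAssignment]:
    """Label each query leaf by its smallest well-supported reference clade.

    A query gets the label of the smallest bipartition side (support >=
    ``min_support``; edges without a recorded support count as fully
    supported) that contains the query plus at least one reference, all of
    whose references agree on one label. Conflicting or absent anchors
    leave the query unclassified.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    refs = {l: reference_labels[l] for l in leaves if l in reference_labels}
    if not refs:
        raise ValueError("tree contains no labeled reference leaves")
    queries = sorted(leaves - set(refs))
    allowed = set(subgroup_labels())
    for label in refs.values():
        if label not in allowed:
            raise ValueError(f"unknown subgroup label {label!r}")

    # candidate clades: both sides of every internal edge
    anchor = next(iter(leaves))
    sides: list[tuple[frozenset, float]] = []
    for side, node in _bipartitions(tree, anchor).items():
        support = getattr(node, "support", None)
        support = 100.0 if support is None else float(support)
        sides.append((side, support))
        sides.append((frozenset(leaves - side), support))

    out: list[SubgroupAssignment] = []
    for q in queries:
        candidates = []
        for side, support in sides:
            if q not in side or support < min_support:
                continue
            side_refs = {refs[l] for l in side if l in refs}
            if len(side_refs) == 1:
                candidates.append((len(side), -support, sorted(side), side_refs.pop(), support))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            _, _, _, label, support = candidates[0]
            out.append(SubgroupAssignment(q, label, support, "assigned"))
        else:
            out.append(SubgroupAssignment(q, None, 0.0, "unclassified"))
    return out


def assignment_table(assignments: list[SubgroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "subgroup": a.subgroup or "",
                "support": a.support,
                "status": a.status,
            }
            for a in assignments
        ]
    )
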
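"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, quadratic scans,
hand-rolled arithmetic) and shares no code path with lrrkit itself.
"""

from __future__ import annotations

import itertools
import random

import numpy as np

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def ng86_oracle(seq_a: str, seq_b: str) -> dict:
    """Brute-force NG86: explicit per-codon site fractions and pathway
    enumeration, Jukes-Cantor corrected. Stops count as nonsynonymous in
    site fractions; pathways through stops are skipped when avoidable."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    bases = "ACGT"

    def sites(codon):
        aa = GENETIC_CODE[codon]
        syn = 0.0
        for i in range(3):
            for b in bases:
                if b != codon[i]:
                    alt = codon[:i] + b + codon[i + 1 :]
                    if GENETIC_CODE[alt] == aa:
                        syn += 1 / 3
        return syn, 3 - syn

    def path_counts(ca, cb):
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(diff):
            cur, s, n, ok = ca, 0, 0, True
            for i in order:
                nxt = cur[:i] + cb[i] + cur[i + 1 :]
                if GENETIC_CODE[nxt] == "*":
                    ok = False
                    break
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                results.append((s, n))
        if not results:  # every pathway crosses a stop: count them all anyway
            for order in itertools.permutations(diff):
                cur, s, n = ca, 0, 0
                for i in order:
                    nxt = cur[:i] + cb[i] + cur[i + 1 :]
                    if (
                        GENETIC_CODE[cur] != "*"
                        and GENETIC_CODE[nxt] != "*"
                        and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
                    ):
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                results.append((s, n))
        s = sum(r[0] for r in results) / len(results)
        n = sum(r[1] for r in results) / len(results)
        return s, n

    S = N = sd = nd = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        sa, na = sites(ca)
        sb, nb = sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = path_counts(ca, cb)
        sd += s
        nd += n
    ps, pn = sd / S, nd / N

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * np.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "sd": sd, "nd": nd, "ps": ps, "pn": pn,
            "ks": jc(ps), "ka": jc(pn)}


def random_coding_pair(rng: random.Random, n_codons: int, p_sub: float = 0.1):
    """Two stop-free random CDSs: the second mutated per-base from the first."""
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases) for _ in range(3))
        if GENETIC_CODE[c] != "*":
            codons.append(c)
    a = "".join(codons)
    while True:
        b_codons = []
        for k in range(0, len(a), 3):
            while True:
                cb = "".join(
                    ch if rng.random() > p_sub else rng.choice(bases)
                    for ch in a[k : k + 3]
                )
                if GENETIC_CODE[cb] != "*":
                    break
            b_codons.append(cb)
        b = "".join(b_codons)
        if b != a:
            return a, b


# ---------------------------------------------------------------------------
# Trees


def random_additive_matrix(rng: random.Random, n_taxa: int):
    """A random binary unrooted tree and its exact leaf-to-leaf distances.

    Built by sequential leaf attachment on an edge list; distances by
    graph shortest paths (unique on a tree).
    """
    import networkx as nx

    g = nx.Graph()
    taxa = [f"t{i}" for i in range(n_taxa)]
    g.add_edge(taxa[0], taxa[1], weight=round(rng.uniform(0.05, 1.0), 6))
    internal = 0
    for leaf in taxa[2:]:
        u, v = rng.choice(list(g.edges()))
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        node = f"x{internal}"
        internal += 1
        split = rng.uniform(0.2, 0.8) * w
        g.add_edge(u, node, weight=round(split, 6))
        g.add_edge(node, v, weight=round(w - split, 6))
        g.add_edge(node, leaf, weight=round(rng.uniform(0.05, 1.0), 6))
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            d[i, j] = dist[a][b]
    d = (d + d.T) / 2
    return taxa, d, g


def tree_splits(g, taxa) -> set[frozenset]:
    """Non-trivial bipartitions of a networkx tree, canonicalized."""
    import networkx as nx

    splits = set()
    anchor = taxa[0]
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in taxa if t in comp)
        if anchor in side:
            side = frozenset(set(taxa) - side)
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def dendropy_splits(tree, taxa) -> set[frozenset]:
    anchor = taxa[0]
    all_set = set(taxa)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        side = clade if anchor not in clade else frozenset(all_set - clade)
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def enumerate_unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies on <=6 taxa, as networkx graphs,
    generated by recursive leaf attachment and deduplicated by split set."""
    import networkx as nx  # noqa: F401

    def graphs(n):
        if n == 3:
            g = nx.Graph()
            g.add_edges_from([("x0", taxa[0]), ("x0", taxa[1]), ("x0", taxa[2])])
            yield g, 1
            return
        for g, ni in graphs(n - 1):
            for u, v in list(g.edges()):
                h = g.copy()
                h.remove_edge(u, v)
                node = f"x{ni}"
                h.add_edge(u, node)
                h.add_edge(node, v)
                h.add_edge(node, taxa[n - 1])
                yield h, ni + 1

    seen = set()
    for g, _ in graphs(len(taxa)):
        splits = frozenset(tree_splits(g, taxa))
        if splits not in seen:
            seen.add(splits)
            yield g


def ols_fit_residual(g, taxa, d: np.ndarray) -> float:
    """Least-squares branch-length fit of a topology to a distance matrix;
    returns the residual sum of squares (lengths unconstrained)."""
    import networkx as nx

    edges = list(g.edges())
    rows = []
    y = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            path = nx.shortest_path(g, taxa[i], taxa[j])
            on_path = {frozenset(e) for e in zip(path, path[1:])}
            rows.append([1.0 if frozenset(e) in on_path else 0.0 for e in edges])
            y.append(d[i, j])
    A = np.array(rows)
    y = np.array(y)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


# ---------------------------------------------------------------------------
# Clustering / chaining


def tandem_components_oracle(genes, max_gap):
    """All-pairs single-linkage: connected components of the <=max_gap graph.

    ``genes``: list of (gene_id, start, end) on one chromosome.
    Returns sorted clusters (>=2 members) as position-ordered id lists.
    """
    n = len(genes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            gi, gj = genes[i], genes[j]
            first, second = (gi, gj) if gi[1] <= gj[1] else (gj, gi)
            if second[1] - first[2] <= max_gap:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(genes[i])
    out = []
    for members in comps.values():
        if len(members) >= 2:
            members.sort(key=lambda g: (g[1], g[0]))
            out.append([g[0] for g in members])
    out.sort()
    return out


def best_monotonic_chain_oracle(points, max_rank_gap):
    """Exhaustive search over all subsequences: the maximum-score chain
    strictly monotonic in x and (up or down) in y with per-step gaps
    <= max_rank_gap. ``points``: list of (x, y, score). Returns
    (best_score, n_anchors)."""
    n = len(points)
    order = sorted(range(n), key=lambda k: points[k][0])
    best = (0.0, 0)
    for mask in range(1, 1 << n):
        chosen = [order[i] for i in range(n) if mask & (1 << i)]
        xs = [points[k][0] for k in chosen]
        ys = [points[k][1] for k in chosen]
        ok_x = all(1 <= b - a <= max_rank_gap for a, b in zip(xs, xs[1:]))
        up = all(1 <= b - a <= max_rank_gap for a, b in zip(ys, ys[1:]))
        down = all(1 <= a - b <= max_rank_gap for a, b in zip(ys, ys[1:]))
        if ok_x and (up or down or len(chosen) == 1):
            score = sum(points[k][2] for k in chosen)
            if score > best[0]:
                best = (score, len(chosen))
    return best


# ---------------------------------------------------------------------------
# Motif scanning


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def naive_motif_hits(seq: str, pattern: str, both_strands: bool):
    """Window-by-window scan; one hit per locus; '+' wins for palindromes."""
    w = len(pattern)
    seq = seq.upper()
    hits = []
    for o in range(len(seq) - w + 1):
        win = seq[o : o + w]
        if all(c in IUPAC[p] for c, p in zip(win, pattern)):
            hits.append((o + 1, "+"))
        elif both_strands:
            rc = win.translate(_COMP)[::-1]
            if all(c in IUPAC[p] for c, p in zip(rc, pattern)):
                hits.append((o + 1, "-"))
    return hits
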
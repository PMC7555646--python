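"""Gene-family identification from domain architecture.

The cascade: filter domain hits at a strict E-value ceiling, require at
least one LRR-class and one kinase-class domain per protein, merge the
HMM-derived candidate set with a similarity-rescue set, and optionally
prune long-branch members against labeled references on a phylogeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .models import DomainHit, SequenceRecord

log = logging.getLogger(__name__)


@dataclass
class ArchitectureCall:
    """Per-protein domain architecture summary and family verdict."""

    gene_id: str
    n_lrr: int
    n_kinase: int
    is_family: bool
    protein_length: int


@dataclass
class FamilySet:
    """Confirmed family members with provenance and pruning log."""

    members: list[str] = field(default_factory=list)
    calls: dict[str, ArchitectureCall] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # hmm_search|rescue|both
    removed: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, reason)


def filter_domain_hits(hits: list[DomainHit], e_max: float = 1e-3) -> list[DomainHit]:
    """Keep hits with E-value strictly below ``e_max``; order preserved."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.evalue < e_max]


def _merged_interval_count(intervals: list[tuple[int, int]]) -> int:
    """Number of maximal runs after merging overlapping/touching intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    count = 1
    _, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            count += 1
            cur_end = end
        else:
            cur_end = max(cur_end, end)
    return count


def call_architecture(
    gene_id: str,
    hits: list[DomainHit],
    protein: SequenceRecord,
) -> ArchitectureCall:
    """Classify one protein by its domain content.

    LRR hits from different repeat profiles often tile the same residues;
    overlapping LRR envelopes are merged before counting so one repeat
    region is not counted once per profile. Kinase hits are counted as-is
    (tandem kinase domains are a real, reported architecture).
    """
    if protein is None:
        raise ValueError(f"protein sequence missing for {gene_id}")
    foreign = [h.gene_id for h in hits if h.gene_id != gene_id]
    if foreign:
        raise ValueError(f"hits for {foreign[0]!r} passed to call for {gene_id!r}")
    lrr_ivals = [(h.env_start, h.env_end) for h in hits if h.domain_class == "LRR"]
    n_lrr = _merged_interval_count(lrr_ivals)
    n_kinase = sum(1 for h in hits if h.domain_class == "kinase")
    return ArchitectureCall(
        gene_id=gene_id,
        n_lrr=n_lrr,
        n_kinase=n_kinase,
        is_family=(n_lrr >= 1 and n_kinase >= 1),
        protein_length=len(protein),
    )


def call_architectures(
    hits: list[DomainHit], proteins: dict[str, SequenceRecord]
) -> dict[str, ArchitectureCall]:
    """Architecture calls for every protein, hit-bearing or not."""
    by_gene: dict[str, list[DomainHit]] = {gid: [] for gid in proteins}
    for h in hits:
        if h.gene_id in by_gene:
            by_gene[h.gene_id].append(h)
    return {
        gid: call_architecture(gid, gh, proteins[gid])
        for gid, gh in by_gene.items()
    }


def merge_candidates(
    hmm_set: set[str],
    rescue_set: set[str],
    calls: dict[str, ArchitectureCall],
) -> FamilySet:
    """Union the HMM and similarity-rescue candidate sets, keep true members.

    Candidates failing the architecture rule are logged under ``removed``
    with reason "architecture". Member order is deterministic (sorted id).
    """
    missing = (hmm_set | rescue_set) - set(calls)
    if missing:
        raise ValueError(f"no architecture call for {sorted(missing)[0]!r}")
    family = FamilySet()
    for gid in sorted(hmm_set | rescue_set):
        call = calls[gid]
        if not call.is_family:
            family.removed.append((gid, "architecture"))
            continue
        family.members.append(gid)
        family.calls[gid] = call
        if gid in hmm_set and gid in rescue_set:
            family.provenance[gid] = "both"
        elif gid in hmm_set:
            family.provenance[gid] = "hmm_search"
        else:
            family.provenance[gid] = "rescue"
    return family


def prune_by_tree(
    family: FamilySet,
    tree: dendropy.Tree,
    reference_leaves: set[str],
    max_distance: float = 1.0,
) -> FamilySet:
    """Drop members whose nearest reference leaf is too far on the tree.

    Distance is patristic (sum of branch lengths). Removals are logged with
    the measured distance so the pruning decision is auditable.
    """
    if not reference_leaves:
        raise ValueError("no reference leaves given")
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [m for m in family.members if m not in labels]
    if missing:
        raise ValueError(f"family member {missing[0]!r} absent from tree")
    refs_in_tree = reference_leaves & labels
    if not refs_in_tree:
        raise ValueError("no reference leaf present in tree")

    pdm = tree.phylogenetic_distance_matrix()
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    pruned = FamilySet(provenance=dict(family.provenance), removed=list(family.removed))
    for gid in family.members:
        d_min = min(
            pdm.patristic_distance(taxon_by_label[gid], taxon_by_label[ref])
            for ref in refs_in_tree
        )
        if d_min > max_distance:
            pruned.removed.append((gid, f"tree_distance={d_min:.4f}"))
            pruned.provenance.pop(gid, None)
            log.info("pruned %s at patristic distance %.4f", gid, d_min)
        else:
            pruned.members.append(gid)
            pruned.calls[gid] = family.calls[gid]
    return pruned


def summarize_family(family: FamilySet) -> dict:
    """Member count, protein length range/mean, multi-kinase tally."""
    if not family.members:
        raise ValueError("empty family")
    lengths = [family.calls[g].protein_length for g in family.members]
    return {
        "n_members": len(family.members),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "mean_length": sum(lengths) / len(lengths),
        "n_multi_kinase": sum(
            1 for g in family.members if family.calls[g].n_kinase >= 2
        ),
    }


def family_table(family: FamilySet) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g,
            "n_lrr": family.calls[g].n_lrr,
            "n_kinase": family.calls[g].n_kinase,
            "protein_length": family.calls[g].protein_length,
            "provenance": family.provenance.get(g, ""),
        }
        for g in family.members
    ]
    return pd.DataFrame(rows)


def removed_table(family: FamilySet) -> pd.DataFrame:
    return pd.DataFrame(family.removed, columns=["gene_id", "reason"])
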
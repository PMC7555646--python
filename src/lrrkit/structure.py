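"""Exon/intron statistics per gene and per phylogenetic subgroup."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .identify import FamilySet
from .io import select_primary_transcript
from .models import Annotation
from .phylo import SubgroupAssignment

log = logging.getLogger(__name__)


@dataclass
class StructureStats:
    """One row of the per-subgroup exon summary."""

    subgroup: str
    n_genes: int
    max_exons: int
    min_exons: int
    mean_exons: float
    sd_exons: float  # sample SD (n-1); 0 for a single gene


def exon_counts(annotation: Annotation, family: FamilySet) -> dict[str, int]:
    """Exon count of the primary transcript for every family gene."""
    counts: dict[str, int] = {}
    for gid in family.members:
        if gid not in annotation:
            raise ValueError(f"family gene {gid!r} missing from annotation")
        tx = select_primary_transcript(annotation[gid])
        counts[gid] = tx.exon_count()
    return counts


def _sample_sd(values: list[int]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def subgroup_stats(
    counts: dict[str, int],
    assignments: list[SubgroupAssignment],
) -> list[StructureStats]:
    """Per-subgroup exon-count summaries plus a Total row.

    Unclassified genes are excluded (their number is logged). The SD is
    the sample standard deviation (n-1 denominator), zero for singleton
    subgroups.
    """
    by_subgroup: dict[str, list[int]] = {}
    n_excluded = 0
    assigned = {a.gene_id: a for a in assignments}
    for gid in counts:
        a = assigned.get(gid)
        if a is None or a.status != "assigned":
            n_excluded += 1
            continue
        by_subgroup.setdefault(a.subgroup, []).append(counts[gid])
    if n_excluded:
        log.info("excluded %d unclassified genes from structure stats", n_excluded)

    rows: list[StructureStats] = []
    total = 0
    for subgroup in sorted(by_subgroup):
        vals = by_subgroup[subgroup]
        total += len(vals)
        rows.append(
            StructureStats(
                subgroup=subgroup,
                n_genes=len(vals),
                max_exons=max(vals),
                min_exons=min(vals),
                mean_exons=sum(vals) / len(vals),
                sd_exons=_sample_sd(vals),
            )
        )
    rows.append(
        StructureStats(
            subgroup="Total",
            n_genes=total,
            max_exons=max((r.max_exons for r in rows), default=0),
            min_exons=min((r.min_exons for r in rows), default=0),
            mean_exons=(
                sum(r.mean_exons * r.n_genes for r in rows) / total if total else 0.0
            ),
            sd_exons=float("nan"),
        )
    )
    return rows


def stats_table(rows: list[StructureStats]) -> pd.DataFrame:
    """2-decimal display table in the conventional subgroup-summary layout."""
    return pd.DataFrame(
        [
            {
                "subgroup": r.subgroup,
                "n_genes": r.n_genes,
                "max_exons": r.max_exons,
                "min_exons": r.min_exons,
                "mean_exons": round(r.mean_exons, 2),
                "sd_exons": round(r.sd_exons, 2) if not math.isnan(r.sd_exons) else "",
            }
            for r in rows
        ]
    )
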
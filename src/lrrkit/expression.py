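"""Expression profiling: replicate condensation, tissue-specificity (tau),
infection time-course peak calling, heatmap ordering, and qPCR ddCt.

The specificity score is tau = sum_i (1 - x_i / x_max) / (N - 1), 0 for a
uniform profile and 1 for single-condition expression. "Specific" and
"high" calls are criterion-relative: the thresholds are package defaults,
not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .models import ExpressionMatrix


class CondensedMatrix:
    """Genes x conditions replicate means.

    ``values``: DataFrame indexed by gene with one column per condition
    label (a tissue, or a genotype x timepoint pair).
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if (values.to_numpy() < 0).any():
            raise ValueError("negative condensed values")
        self.values = values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def replicate_means(matrix: ExpressionMatrix) -> CondensedMatrix:
    """Arithmetic mean over each replicate group, per gene and condition."""
    groups = matrix.replicate_groups()
    empty = [c for c, samples in groups.items() if not samples]
    if empty:
        raise ValueError(f"condition {empty[0]!r} has no replicates")
    data = {
        cond: matrix.values[samples].mean(axis=1) for cond, samples in groups.items()
    }
    return CondensedMatrix(pd.DataFrame(data, index=matrix.values.index))


# ---------------------------------------------------------------------------
# Tissue specificity


@dataclass
class SpecificityCall:
    gene_id: str
    tau: float | None  # None for an all-zero profile
    called_conditions: list[str] = field(default_factory=list)
    mode: str = "none"  # "specific" | "high" | "none"


def tissue_tau(row: np.ndarray) -> float | None:
    """Yanai-style specificity index on a condition-mean profile."""
    x_max = row.max()
    if x_max <= 0:
        return None
    n = len(row)
    return float((1.0 - row / x_max).sum() / (n - 1))


def specificity_calls(
    matrix: CondensedMatrix,
    tau_min: float = 0.8,
    fold_min: float = 2.0,
) -> list[SpecificityCall]:
    """Call condition-specific and generally high-expressing genes.

    specific: tau >= tau_min and the conditions within fold_min of the
    maximum (the called set) form a proper subset of all conditions — the
    top condition then exceeds fold_min x the best condition outside the
    called set by construction. high: not specific, but the maximum
    exceeds fold_min x the row mean. Otherwise none.
    """
    if len(matrix.conditions) < 2:
        raise ValueError("need at least 2 conditions")
    conds = np.array(matrix.conditions)
    out: list[SpecificityCall] = []
    for gene_id, row in matrix.values.iterrows():
        x = row.to_numpy(dtype=float)
        tau = tissue_tau(x)
        if tau is None:
            out.append(SpecificityCall(gene_id, None, [], "none"))
            continue
        order = np.argsort(-x, kind="stable")
        top = x[order[0]]
        within = x * fold_min >= top
        if tau >= tau_min and not within.all():
            called = [str(c) for c in conds[within]]
            out.append(SpecificityCall(gene_id, tau, called, "specific"))
        elif top > fold_min * x.mean():
            out.append(SpecificityCall(gene_id, tau, [str(conds[order[0]])], "high"))
        else:
            out.append(SpecificityCall(gene_id, tau, [], "none"))
    return out


# ---------------------------------------------------------------------------
# Infection time-course peaks


@dataclass
class PeakCall:
    gene_id: str
    peak_condition: str  # "genotype:time" label
    fold_over_baseline: float
    called: bool


def _condition_key(label: str, genotype_order: list[str] | None):
    """Sort key (time, genotype-order) for tie-breaking argmax conditions."""
    geno, _, time = label.partition(":")
    try:
        t = float(time)
    except ValueError:
        t = math.inf
    g = genotype_order.index(geno) if genotype_order and geno in genotype_order else 0
    return (t, g)


def peak_time_calls(
    matrix: CondensedMatrix,
    baseline: str,
    fold_min: float = 2.0,
    genotype_order: list[str] | None = None,
) -> list[PeakCall]:
    """Argmax-with-fold peak calls over genotype x time condition means.

    Condition labels are "genotype:time". Ties at the maximum go to the
    earliest timepoint, then the configured genotype order. A gene is
    called when its peak mean >= fold_min x the baseline-condition mean
    (infinite fold when the baseline is zero but the peak is not).
    """
    if baseline not in matrix.conditions:
        raise ValueError(f"baseline condition {baseline!r} absent")
    out: list[PeakCall] = []
    conds = matrix.conditions
    for gene_id, row in matrix.values.iterrows():
        x = row.to_numpy(dtype=float)
        peak_val = x.max()
        tied = [c for c, v in zip(conds, x) if v == peak_val]
        tied.sort(key=lambda c: _condition_key(c, genotype_order))
        peak_cond = tied[0]
        base = float(row[baseline])
        if base > 0:
            fold = peak_val / base
        elif peak_val > 0:
            fold = math.inf
        else:
            fold = 0.0
        out.append(PeakCall(gene_id, peak_cond, fold, fold >= fold_min))
    return out


# ---------------------------------------------------------------------------
# Heatmap ordering


def heatmap_order(matrix: CondensedMatrix, transform: str = "log2p1") -> list[str]:
    """Deterministic leaf order from average-linkage Euclidean clustering.

    Rows are log2(x+1)-transformed (or row z-scored); a constant matrix
    returns the input order unchanged.
    """
    if len(matrix.genes) < 2:
        raise ValueError("need at least 2 genes")
    x = matrix.values.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform == "zscore_row":
        sd = x.std(axis=1, ddof=0, keepdims=True)
        mean = x.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            x = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if np.allclose(x, x[0]):
        return list(matrix.genes)
    d = pdist(x, metric="euclidean")
    link = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(link)
    return [matrix.genes[i] for i in order]


# ---------------------------------------------------------------------------
# qPCR ddCt


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per gene and sample.

    Replicate Ct values (duplicate gene/sample rows) are averaged first;
    dCt = Ct_target - Ct_reference per sample, ddCt is taken against the
    calibrator sample, and the returned table carries the per-replicate
    relative expressions' mean and SD where replicates exist.
    """
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    ref = ct[ct["gene"] == reference_gene].groupby("sample")["ct"].mean()
    samples = sorted(set(ct["sample"]))
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"reference gene not measured in sample {missing[0]!r}")
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")

    rows = []
    for gene, sub in ct[ct["gene"] != reference_gene].groupby("gene"):
        per_sample = sub.groupby("sample")["ct"].agg(["mean", "std", "count"])
        if calibrator_sample not in per_sample.index:
            continue
        dct = per_sample["mean"] - ref.loc[per_sample.index]
        ddct = dct - dct.loc[calibrator_sample]
        rel = 2.0 ** (-ddct)
        # per-replicate spread propagated on the log2 scale
        for sample in per_sample.index:
            reps = sub[sub["sample"] == sample]["ct"]
            ref_mean = ref.loc[sample]
            rel_reps = 2.0 ** (
                -((reps - ref_mean) - dct.loc[calibrator_sample])
            )
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "rel_expr": float(rel.loc[sample]),
                    "rel_mean": float(rel_reps.mean()),
                    "rel_sd": float(rel_reps.std(ddof=1)) if len(rel_reps) > 1 else 0.0,
                    "n_reps": int(per_sample.loc[sample, "count"]),
                }
            )
    return pd.DataFrame(rows)
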
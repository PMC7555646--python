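"""Replicate condensation, tissue specificity, time-course peaks, heatmap
ordering, and ddCt quantification."""

import numpy as np
import pandas as pd
import pytest

from lrrkit import expression as expr
from lrrkit.models import ExpressionMatrix


def _matrix(rows, conditions, n_reps=3, values=None):
    """rows: dict gene -> list of per-condition replicate triples."""
    cols = {}
    meta = []
    for cond in conditions:
        for r in range(1, n_reps + 1):
            sid = f"{cond}.r{r}"
            cols[sid] = []
            meta.append({"condition": cond, "replicate": r})
    for gene, reps in rows.items():
        for ci, cond in enumerate(conditions):
            for r in range(n_reps):
                cols[f"{cond}.r{r + 1}"].append(reps[ci][r])
    values = pd.DataFrame(cols, index=list(rows))
    sample_meta = pd.DataFrame(meta, index=list(cols))
    return ExpressionMatrix(values, sample_meta)


def _condensed(rows, conditions):
    return expr.CondensedMatrix(
        pd.DataFrame(rows, index=conditions).T.astype(float)
    )


# ---------------------------------------------------------------------------
# Replicate means


def test_replicate_means_arithmetic():
    m = _matrix({"g1": [(2, 4, 6)]}, ["root"])
    means = expr.replicate_means(m)
    assert means.values.loc["g1", "root"] == pytest.approx(4.0)


def test_replicate_means_single_replicate_is_identity():
    m = _matrix({"g1": [(5,)]}, ["root"], n_reps=1)
    assert expr.replicate_means(m).values.loc["g1", "root"] == 5.0


def test_replicate_means_match_generator_truth():
    from lrrkit.simulate import SimConfig, simulate_expression

    cfg = SimConfig(seed=3, noise_sd=0.0)
    tissues, infection, _, truth = simulate_expression(cfg)
    means = expr.replicate_means(tissues)
    # noiseless: replicate means equal planted means, so every specific
    # gene shows exactly fold x baseline in its target conditions
    for g in truth["specific"]:
        row = means.values.loc[g]
        on = [row[c] for c in truth["specific_conditions"]]
        off = row.drop(truth["specific_conditions"])
        assert min(on) > 10 * off.max()


# ---------------------------------------------------------------------------
# Specificity


def test_tau_extremes():
    assert expr.tissue_tau(np.array([0.0, 0.0, 0.0, 9.0])) == pytest.approx(1.0)
    assert expr.tissue_tau(np.array([5.0, 5.0, 5.0, 5.0])) == pytest.approx(0.0)
    assert expr.tissue_tau(np.zeros(4)) is None


def test_specificity_single_condition_gene_called():
    m = _condensed({"g1": [0, 0, 0, 9]}, ["a", "b", "c", "d"])
    call = expr.specificity_calls(m)[0]
    assert call.mode == "specific" and call.called_conditions == ["d"]
    assert call.tau == pytest.approx(1.0)


def test_specificity_uniform_profile_is_none():
    m = _condensed({"g1": [5, 5, 5, 5]}, ["a", "b", "c", "d"])
    call = expr.specificity_calls(m)[0]
    assert call.mode == "none" and call.tau == pytest.approx(0.0)


def test_specificity_invariant_to_row_scaling_and_column_order():
    conds = list("abcdefgh")
    row = [40, 1, 1, 38, 1, 1, 1, 1]
    c1 = expr.specificity_calls(_condensed({"g": row}, conds))[0]
    c2 = expr.specificity_calls(_condensed({"g": [x * 7 for x in row]}, conds))[0]
    assert c1.tau == pytest.approx(c2.tau)
    assert c1.mode == c2.mode == "specific"
    assert sorted(c1.called_conditions) == ["a", "d"]
    shuffled = _condensed(
        {"g": [1, 38, 40, 1, 1, 1, 1, 1]}, ["c", "d", "a", "b", "e", "f", "g", "h"]
    )
    c3 = expr.specificity_calls(shuffled)[0]
    assert sorted(c3.called_conditions) == ["a", "d"]


def test_generator_specific_genes_fully_recovered():
    from lrrkit.simulate import SimConfig, simulate_expression

    cfg = SimConfig(seed=17)
    tissues, _, _, truth = simulate_expression(cfg)
    calls = expr.specificity_calls(expr.replicate_means(tissues))
    called = {c.gene_id for c in calls if c.mode == "specific"}
    assert called == set(truth["specific"])


# ---------------------------------------------------------------------------
# Peak calls


def test_peak_argmax_and_fold():
    conds = ["A17:0", "A17:12", "skl:12"]
    m = _condensed({"g1": [2, 4, 16]}, conds)
    call = expr.peak_time_calls(m, "A17:0")[0]
    assert call.peak_condition == "skl:12"
    assert call.fold_over_baseline == pytest.approx(8.0)
    assert call.called


def test_peak_flat_row_not_called():
    m = _condensed({"g1": [3, 3, 3]}, ["A17:0", "A17:12", "skl:12"])
    assert not expr.peak_time_calls(m, "A17:0")[0].called


def test_peak_tie_breaks_to_earliest_time():
    conds = ["A17:0", "skl:48", "skl:12"]
    m = _condensed({"g1": [1, 8, 8]}, conds)
    call = expr.peak_time_calls(m, "A17:0")[0]
    assert call.peak_condition == "skl:12"


def test_peak_zero_baseline_gives_infinite_fold():
    m = _condensed({"g1": [0, 8]}, ["A17:0", "skl:12"])
    call = expr.peak_time_calls(m, "A17:0")[0]
    assert call.fold_over_baseline == np.inf and call.called


def test_generator_peak_sets_recovered_exactly():
    from lrrkit.simulate import SimConfig, simulate_expression

    cfg = SimConfig(seed=23)
    _, infection, _, truth = simulate_expression(cfg)
    peaks = expr.peak_time_calls(
        expr.replicate_means(infection), truth["baseline_condition"]
    )
    skl12 = {p.gene_id for p in peaks if p.called and p.peak_condition == "skl:12"}
    skl48 = {p.gene_id for p in peaks if p.called and p.peak_condition == "skl:48"}
    assert skl12 == set(truth["skl12_peak"])
    assert skl48 == set(truth["skl48_peak"])


def test_double_positive_intersection_matches_planted_set():
    """Root/nodule-specific AND peaking at (skl, 12 h) recovers exactly
    the planted double-positive genes."""
    from lrrkit.simulate import SimConfig, simulate_expression

    cfg = SimConfig(seed=29)
    tissues, infection, _, truth = simulate_expression(cfg)
    spec = {
        c.gene_id
        for c in expr.specificity_calls(expr.replicate_means(tissues))
        if c.mode == "specific"
    }
    peaks = expr.peak_time_calls(
        expr.replicate_means(infection), truth["baseline_condition"]
    )
    skl12 = {p.gene_id for p in peaks if p.called and p.peak_condition == "skl:12"}
    assert spec & skl12 == set(truth["double_positive"])


# ---------------------------------------------------------------------------
# Heatmap ordering


def test_identical_rows_end_up_adjacent():
    m = _condensed(
        {"a": [1, 1, 1], "far": [90, 2, 50], "b": [1, 1, 1]}, ["x", "y", "z"]
    )
    order = expr.heatmap_order(m)
    ia, ib = order.index("a"), order.index("b")
    assert abs(ia - ib) == 1


def test_order_is_permutation_invariant_up_to_relabeling():
    rows = {"a": [1, 2, 3], "b": [1.1, 2, 3], "c": [9, 1, 0], "d": [8.5, 1, 0.2]}
    m1 = _condensed(rows, ["x", "y", "z"])
    m2 = _condensed({k: rows[k] for k in ["d", "b", "a", "c"]}, ["x", "y", "z"])
    o1 = expr.heatmap_order(m1)
    o2 = expr.heatmap_order(m2)
    pairs1 = {frozenset(o1[i : i + 2]) for i in range(len(o1) - 1)}
    pairs2 = {frozenset(o2[i : i + 2]) for i in range(len(o2) - 1)}
    assert {frozenset({"a", "b"}), frozenset({"c", "d"})} <= pairs1
    assert {frozenset({"a", "b"}), frozenset({"c", "d"})} <= pairs2


def test_constant_matrix_returns_input_order():
    m = _condensed({"a": [1, 1], "b": [1, 1], "c": [1, 1]}, ["x", "y"])
    assert expr.heatmap_order(m) == ["a", "b", "c"]


# ---------------------------------------------------------------------------
# ddCt


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "ct"])


def test_ddct_calibrator_is_one_and_doubling_rule():
    ct = _ct_table(
        [
            ("ref", "cal", 20.0), ("ref", "s1", 20.0),
            ("tgt", "cal", 25.0), ("tgt", "s1", 24.0),
        ]
    )
    out = expr.delta_delta_ct(ct, "ref", "cal").set_index("sample")
    assert out.loc["cal", "rel_expr"] == pytest.approx(1.0)
    assert out.loc["s1", "rel_expr"] == pytest.approx(2.0)


def test_ddct_matches_spreadsheet_oracle():
    rows = []
    ct_ref = {"cal": 18.2, "s1": 19.1, "s2": 17.6}
    ct_tgt = {"cal": 26.0, "s1": 24.3, "s2": 27.9}
    for s in ct_ref:
        rows += [("ref", s, ct_ref[s]), ("tgt", s, ct_tgt[s])]
    out = expr.delta_delta_ct(_ct_table(rows), "ref", "cal").set_index("sample")
    dct_cal = ct_tgt["cal"] - ct_ref["cal"]
    for s in ct_ref:
        expected = 2 ** (-((ct_tgt[s] - ct_ref[s]) - dct_cal))
        assert out.loc[s, "rel_expr"] == pytest.approx(expected)


def test_ddct_missing_reference_sample_is_an_error():
    ct = _ct_table([("ref", "cal", 20.0), ("tgt", "cal", 25.0), ("tgt", "s1", 24.0)])
    with pytest.raises(ValueError, match="s1"):
        expr.delta_delta_ct(ct, "ref", "cal")


def test_ddct_recovers_generator_planted_levels():
    from lrrkit.simulate import SimConfig, simulate_expression

    cfg = SimConfig(seed=31)
    _, _, ct, truth = simulate_expression(cfg)
    out = expr.delta_delta_ct(
        ct, truth["ct_reference"], truth["ct_calibrator"]
    ).set_index("sample")
    for sample, rel in truth["ct_rel_truth"].items():
        assert out.loc[sample, "rel_expr"] == pytest.approx(rel, rel=0.15)
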
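"""QC filtering and rupture-calling tests."""

import numpy as np
import pandas as pd
import pytest

from rupturekit.calling import (FilterConfig, RuptureThresholds,
                                apply_qc_filters, call_cells,
                                compute_thresholds, summarize_conditions)
from rupturekit.phantoms import simulate_cell_records

from conftest import make_plate


def _records(**cols):
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__"))
    base = {
        "well": "W1", "condition": "CTRL", "replicate": 1,
        "label": np.arange(1, n + 1),
        "hoechst_nuc_mean": 500.0, "rfp_cyto_mean": 200.0,
        "rfp_nuc_cyto": 0.35, "gfp_cyto_nuc": 0.3,
        "nucleus_area_um2": 180.0, "nucleus_solidity": 0.97,
    }
    base.update(cols)
    return pd.DataFrame(base)


# --- thresholds ------------------------------------------------------------


def test_constant_controls_give_constant_threshold():
    rec = _records(rfp_nuc_cyto=np.full(50, 0.4), gfp_cyto_nuc=np.full(50, 0.3))
    thr = compute_thresholds(rec)
    assert thr.rfp[1] == pytest.approx(0.4)
    assert thr.gfp[1] == pytest.approx(0.3)


def test_threshold_formula_exact():
    # values 1,2,3: median 2, sample SD 1 -> threshold 3
    rec = _records(rfp_nuc_cyto=np.array([1.0, 2.0, 3.0]))
    thr = compute_thresholds(rec)
    assert thr.rfp[1] == pytest.approx(3.0)


def test_threshold_scale_equivariance():
    vals = np.random.default_rng(0).lognormal(0.0, 0.3, 200)
    t1 = compute_thresholds(_records(rfp_nuc_cyto=vals)).rfp[1]
    t2 = compute_thresholds(_records(rfp_nuc_cyto=vals * 3.0)).rfp[1]
    assert t2 == pytest.approx(3.0 * t1)


def test_threshold_errors():
    with pytest.raises(ValueError, match="no control records"):
        compute_thresholds(_records(rfp_nuc_cyto=np.array([0.3])).iloc[:0])
    with pytest.raises(ValueError, match=">= 2"):
        compute_thresholds(_records(rfp_nuc_cyto=np.array([0.3])))


# --- calling ---------------------------------------------------------------


def test_strict_boundary():
    thr = RuptureThresholds(rfp={1: 0.5}, gfp={1: 0.5})
    rec = _records(rfp_nuc_cyto=np.array([0.5, 0.5 + 1e-9, 0.49]))
    calls = call_cells(rec, thr)
    assert calls["rfp_positive"].tolist() == [False, True, False]


def test_gfp_only_among_rfp_positive():
    thr = RuptureThresholds(rfp={1: 0.5}, gfp={1: 0.4})
    rec = _records(rfp_nuc_cyto=np.array([0.6, 0.3]),
                   gfp_cyto_nuc=np.array([0.9, 0.9]))
    calls = call_cells(rec, thr)
    assert calls["gfp_positive"].tolist() == [True, False]


def test_missing_replicate_threshold_raises():
    thr = RuptureThresholds(rfp={1: 0.5}, gfp={1: 0.5})
    rec = _records(rfp_nuc_cyto=np.array([0.6]), replicate=2)
    with pytest.raises(KeyError, match="replicate"):
        call_cells(rec, thr)


def test_nan_ratios_are_negative_calls():
    thr = RuptureThresholds(rfp={1: 0.5}, gfp={1: 0.5})
    rec = _records(rfp_nuc_cyto=np.array([np.nan, 0.6]))
    calls = call_cells(rec, thr)
    assert calls["rfp_positive"].tolist() == [False, True]


def test_calling_sensitivity_and_specificity():
    spec = make_plate(seed=5, n_cells=4000, conditions=[("CTRL", 0.10)],
                      replicates=(1,))
    rec = simulate_cell_records(spec)
    thr = compute_thresholds(rec)
    calls = call_cells(rec, thr).join(rec["true_state"])
    ruptured = rec["true_state"].isin(["ruptured", "rupturing"])
    sens = calls.loc[ruptured, "rfp_positive"].mean()
    spec_ = 1.0 - calls.loc[~ruptured, "rfp_positive"].mean()
    assert sens >= 0.9
    assert spec_ >= 0.85


# --- QC filters ------------------------------------------------------------


def test_filter_cascade_order_and_conservation():
    rec = _records(
        rfp_cyto_mean=np.array([10.0, 10.0, 200.0, 200.0, 200.0, 200.0]),
        hoechst_nuc_mean=np.array([500.0, 100.0, 100.0, 2000.0, 500.0, 500.0]),
        nucleus_solidity=np.array([0.97, 0.97, 0.97, 0.999, 0.6, 0.97]),
        nucleus_area_um2=np.array([180.0, 180, 180, 180, 50.0, 180]),
    )
    cfg = FilterConfig(rfp_expression_min=40.0, hoechst_min=250.0,
                       hoechst_max=1200.0, mitotic_solidity_max=0.99,
                       nucleus_area_min={"CTRL": 100.0},
                       solidity_min={"CTRL": 0.9}, solidity_max={"CTRL": 1.0})
    retained, ledger = apply_qc_filters(rec, cfg)
    assert len(retained) + len(ledger) == len(rec)
    reasons = dict(zip(ledger["label"], ledger["reason"]))
    # cell 1 fails only expression; cell 2 fails expression AND focus ->
    # first filter in the cascade wins
    assert reasons[1] == "low_expression"
    assert reasons[2] == "low_expression"
    assert reasons[3] == "out_of_focus"
    assert reasons[4] == "mitotic"
    assert reasons[5] == "dead"
    assert retained["label"].tolist() == [6]


def test_filters_idempotent_with_explicit_thresholds():
    rng = np.random.default_rng(1)
    rec = _records(rfp_cyto_mean=rng.lognormal(5.0, 0.5, 300),
                   nucleus_solidity=rng.uniform(0.8, 1.0, 300))
    cfg = FilterConfig(rfp_expression_min=100.0,
                       nucleus_area_min={"CTRL": 100.0},
                       solidity_min={"CTRL": 0.85}, solidity_max={"CTRL": 1.0})
    once, ledger1 = apply_qc_filters(rec, cfg)
    twice, ledger2 = apply_qc_filters(once, cfg)
    assert len(ledger2) == 0
    pd.testing.assert_frame_equal(once, twice)


def test_missing_condition_in_explicit_config_raises():
    rec = _records(rfp_nuc_cyto=np.full(5, 0.4))
    cfg = FilterConfig(nucleus_area_min={"OTHER": 10.0})
    with pytest.raises(KeyError, match="CTRL"):
        apply_qc_filters(rec, cfg)


def test_quantile_defaults_remove_extremes_per_condition():
    rng = np.random.default_rng(2)
    a = _records(nucleus_area_um2=np.r_[rng.normal(180, 10, 499), 1.0])
    b = _records(nucleus_area_um2=np.r_[rng.normal(90, 5, 499), 1.0],
                 condition="TREAT")
    rec = pd.concat([a, b], ignore_index=True)
    retained, ledger = apply_qc_filters(rec, FilterConfig())
    # the planted outlier is removed in each condition, with per-condition
    # thresholds (a 90 µm² nucleus is normal for TREAT, not an outlier)
    assert (ledger["reason"] == "dead").sum() >= 2
    assert retained[retained["condition"] == "TREAT"]["nucleus_area_um2"].min() > 50


# --- summaries and gating --------------------------------------------------


def _calls(n_rfp_by_rep, n_per_rep=1000, cond="A"):
    rows = []
    for rep, n_rfp in n_rfp_by_rep.items():
        for i in range(n_per_rep):
            rfp = i < n_rfp
            rows.append({"well": f"{cond}_r{rep}", "condition": cond,
                         "replicate": rep, "label": i + 1,
                         "rfp_positive": rfp,
                         "gfp_positive": rfp and (i % 4 == 0)})
    return pd.DataFrame(rows)


def test_gating_at_exactly_175():
    ok = summarize_conditions(_calls({1: 175, 2: 180, 3: 200}))
    assert ok["gfp_eligible"].iloc[0]
    assert not np.isnan(ok["prop_gfp_of_rfp"].iloc[0])

    under = summarize_conditions(_calls({1: 174, 2: 180, 3: 200}))
    assert not under["gfp_eligible"].iloc[0]
    assert np.isnan(under["prop_gfp_of_rfp"].iloc[0])
    # RFP columns are unaffected by the gate
    assert under["n_rfp_positive"].iloc[0] == 174 + 180 + 200


def test_summary_counts_and_proportions():
    s = summarize_conditions(_calls({1: 250, 2: 250, 3: 250}))
    assert s["n"].iloc[0] == 3000
    assert s["prop_rfp_positive"].iloc[0] == pytest.approx(0.25)
    assert s["n_gfp_positive"].iloc[0] == 3 * len(range(0, 250, 4))
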
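"""QC filtering and control-derived rupture calling.

Cells pass a fixed-order filter cascade (low expression → out-of-focus →
mitotic → dead); the first failing filter is recorded as the removal reason.
Intensity filters are global; morphology filters are per condition, to
accommodate condition-specific changes in nucleus shape and size.

A cell is called ruptured (RFP+) when its RFP nuc:cyto ratio strictly exceeds
median + k·SD of the pooled control cells of its replicate (k = 1), and
rupturing (GFP+) when, additionally, its GFP cyto:nuc ratio exceeds the
analogous control threshold. GFP analysis of a condition requires at least
``min_rfp_events`` RFP+ nuclei in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "RuptureThresholds",
    "apply_qc_filters",
    "compute_thresholds",
    "call_cells",
    "summarize_conditions",
]

DEFAULT_MIN_RFP_EVENTS = 175


@dataclass
class FilterConfig:
    """QC thresholds. Global intensity filters; per-condition morphology.

    Per-condition entries map condition -> value; conditions absent from an
    explicit per-condition dict raise. When a per-condition dict is None the
    thresholds are derived from each condition's own quantiles
    (area floor: 1st percentile; solidity window: 0.5th-99.5th percentiles).
    """

    rfp_expression_min: float | None = None   # global: drop low expressers
    hoechst_min: float | None = None          # global: out-of-focus
    hoechst_max: float | None = None          # global: mitotic (with solidity)
    mitotic_solidity_max: float | None = None  # solidity ceiling coupled to hoechst_max
    nucleus_area_min: dict | None = None      # per condition
    solidity_min: dict | None = None          # per condition
    solidity_max: dict | None = None          # per condition
    area_quantile: float = 0.01
    solidity_quantiles: tuple[float, float] = (0.005, 0.995)

    def resolve_morphology(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-condition morphology thresholds as a frame indexed by condition."""
        conds = records["condition"].unique()
        rows = []
        for cond in conds:
            sub = records[records["condition"] == cond]
            rows.append({
                "condition": cond,
                "area_min": self._lookup(self.nucleus_area_min, cond,
                                         sub["nucleus_area_um2"].quantile(self.area_quantile)),
                "sol_min": self._lookup(self.solidity_min, cond,
                                        sub["nucleus_solidity"].quantile(self.solidity_quantiles[0])),
                "sol_max": self._lookup(self.solidity_max, cond,
                                        sub["nucleus_solidity"].quantile(self.solidity_quantiles[1])),
            })
        return pd.DataFrame(rows).set_index("condition")

    @staticmethod
    def _lookup(table, cond, default):
        if table is None:
            return float(default)
        if cond not in table:
            raise KeyError(f"condition {cond!r} missing from per-condition filter config")
        return float(table[cond])


@dataclass
class RuptureThresholds:
    """Per-replicate calling thresholds: median + k·SD of control ratios."""

    rfp: dict  # replicate -> threshold on rfp_nuc_cyto
    gfp: dict  # replicate -> threshold on gfp_cyto_nuc
    k: float = 1.0
    control_condition: str = "CTRL"


# fixed cascade order; first failure is the recorded reason
_FILTER_ORDER = ("low_expression", "out_of_focus", "mitotic", "dead")


def apply_qc_filters(records: pd.DataFrame, config: FilterConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC cascade; returns (retained records, removal ledger).

    The ledger has one row per removed cell (identifiers + reason); counts by
    reason sum to the number removed, and retained + removed = input.
    """
    morph = config.resolve_morphology(records)
    reason = pd.Series(pd.NA, index=records.index, dtype="object")

    def flag(mask: pd.Series, name: str) -> None:
        mask = mask & reason.isna()
        reason[mask] = name

    if config.rfp_expression_min is not None:
        flag(records["rfp_cyto_mean"] < config.rfp_expression_min, "low_expression")
    if config.hoechst_min is not None:
        flag(records["hoechst_nuc_mean"] < config.hoechst_min, "out_of_focus")
    if config.hoechst_max is not None:
        mito = records["hoechst_nuc_mean"] > config.hoechst_max
        if config.mitotic_solidity_max is not None:
            mito &= records["nucleus_solidity"] > config.mitotic_solidity_max
        flag(mito, "mitotic")
    area_min = records["condition"].map(morph["area_min"])
    sol_min = records["condition"].map(morph["sol_min"])
    sol_max = records["condition"].map(morph["sol_max"])
    flag((records["nucleus_area_um2"] < area_min)
         | (records["nucleus_solidity"] < sol_min)
         | (records["nucleus_solidity"] > sol_max), "dead")

    removed = ~reason.isna()
    ledger = records.loc[removed, ["well", "condition", "replicate", "label"]].copy()
    ledger["reason"] = reason[removed]
    return records.loc[~removed].copy(), ledger


def compute_thresholds(control_records: pd.DataFrame, k: float = 1.0,
                       control_condition: str = "CTRL") -> RuptureThresholds:
    """Thresholds per replicate: median + k·SD over pooled control cells.

    SD is the sample standard deviation (n−1). Requires at least two control
    cells per replicate.
    """
    if len(control_records) == 0:
        raise ValueError("no control records to derive thresholds from")
    rfp, gfp = {}, {}
    for rep, sub in control_records.groupby("replicate"):
        if len(sub) < 2:
            raise ValueError(f"replicate {rep}: need >= 2 control cells")
        r = sub["rfp_nuc_cyto"].dropna()
        g = sub["gfp_cyto_nuc"].dropna()
        rfp[rep] = float(r.median() + k * r.std(ddof=1))
        gfp[rep] = float(g.median() + k * g.std(ddof=1))
    return RuptureThresholds(rfp=rfp, gfp=gfp, k=k,
                             control_condition=control_condition)


def call_cells(records: pd.DataFrame, thresholds: RuptureThresholds
               ) -> pd.DataFrame:
    """Call RFP+ (ruptured) and, among RFP+, GFP+ (rupturing) cells.

    Positivity is strict (> threshold). GFP positivity is only evaluated for
    RFP+ cells; it is False elsewhere.
    """
    reps = set(records["replicate"].unique())
    missing = reps - set(thresholds.rfp)
    if missing:
        raise KeyError(f"no thresholds for replicate(s) {sorted(missing)}")
    rfp_thr = records["replicate"].map(thresholds.rfp)
    gfp_thr = records["replicate"].map(thresholds.gfp)
    out = records[["well", "condition", "replicate", "label"]].copy()
    out["rfp_positive"] = (records["rfp_nuc_cyto"] > rfp_thr).fillna(False)
    out["gfp_positive"] = out["rfp_positive"] & \
        (records["gfp_cyto_nuc"] > gfp_thr).fillna(False)
    return out


def summarize_conditions(calls: pd.DataFrame,
                         min_rfp_events: int = DEFAULT_MIN_RFP_EVENTS
                         ) -> pd.DataFrame:
    """Per-condition counts and proportions.

    GFP (rupturing) proportions are only reported for conditions where every
    replicate has at least ``min_rfp_events`` RFP+ nuclei; others are flagged
    ``gfp_eligible=False`` with NaN GFP columns.
    """
    rows = []
    for cond, sub in calls.groupby("condition"):
        n = len(sub)
        n_rfp = int(sub["rfp_positive"].sum())
        per_rep = sub.groupby("replicate")["rfp_positive"].sum()
        eligible = bool((per_rep >= min_rfp_events).all()) and len(per_rep) > 0
        row = {
            "condition": cond,
            "n": n,
            "n_rfp_positive": n_rfp,
            "prop_rfp_positive": n_rfp / n if n else 0.0,
            "gfp_eligible": eligible,
            "n_gfp_positive": np.nan,
            "prop_gfp_of_rfp": np.nan,
        }
        if eligible:
            rfp_sub = sub[sub["rfp_positive"]]
            n_gfp = int(rfp_sub["gfp_positive"].sum())
            row["n_gfp_positive"] = n_gfp
            row["prop_gfp_of_rfp"] = n_gfp / len(rfp_sub)
        rows.append(row)
    return pd.DataFrame(rows)
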
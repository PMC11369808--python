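"""Bench quantifications: ΔΔCT qPCR fold changes, western-blot densitometry
normalization, and two-tailed t-tests.

ΔΔCT assumes an amplification efficiency of 2.0 per cycle:
ΔCT = CT_target − CT_reference per replicate, ΔΔCT = ΔCT − mean control
ΔCT, fold change = 2^(−ΔΔCT). Densitometry lanes are normalized as
signal / loading-control, then scaled by the mean baseline-stage ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "condition", "gene", "ct", "replicate"]
BLOT_COLUMNS = ["stage", "condition", "signal", "control_signal", "replicate"]


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return ct


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_gene: str = "odc",
    control_condition: str = "wild_type",
) -> pd.DataFrame:
    """Per-gene, per-condition fold change by the ΔΔCT method.

    Each biological replicate contributes one ΔCT per (condition, gene);
    ΔΔCT subtracts the control-condition mean ΔCT of that gene; the reported
    mean and sd are over per-replicate fold changes 2^(−ΔΔCT).
    """
    ct = validate_ct_table(ct)
    if control_condition not in set(ct["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from table")
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "replicate"])["ct"]
    targets = ct[ct["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("no target genes in CT table")

    rows = []
    for (gene, condition), grp in targets.groupby(["gene", "condition"]):
        key_missing = [
            (c, r)
            for c, r in zip(grp["condition"], grp["replicate"])
            if (c, r) not in ref.index
        ]
        if key_missing:
            raise ValueError(
                f"missing reference gene {reference_gene!r} wells for "
                f"(condition, replicate) {key_missing[:3]}"
            )
        dct = grp["ct"].to_numpy() - ref.loc[
            list(zip(grp["condition"], grp["replicate"]))
        ].to_numpy()
        rows.append(dict(gene=gene, condition=condition, dct=dct, replicates=grp["replicate"].tolist()))

    per = pd.DataFrame(rows)
    out = []
    for gene, grp in per.groupby("gene"):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control-condition wells")
        ctrl_mean = float(np.concatenate(ctrl["dct"].to_list()).mean())
        for row in grp.itertuples(index=False):
            folds = 2.0 ** (-(row.dct - ctrl_mean))
            out.append(
                dict(gene=gene, condition=row.condition, n=len(folds),
                     fold_change=float(folds.mean()),
                     fold_sd=float(folds.std(ddof=1)) if len(folds) > 1 else np.nan)
            )
    return pd.DataFrame(out)


def normalize_blot(blot: pd.DataFrame, baseline_stage, condition: str | None = None) -> pd.DataFrame:
    """Loading-control normalization of densitometry lanes.

    Per lane: ratio = signal / control_signal; normalized = ratio divided by
    the mean ratio of ``baseline_stage`` lanes (same condition). Per stage the
    summary reports the normalized mean, its sd, the signed percent change
    100*(normalized − 1), and the decrease form 100*(1 − normalized).
    """
    missing = set(BLOT_COLUMNS) - set(blot.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    if condition is not None:
        blot = blot[blot["condition"] == condition]
    if (blot["control_signal"] <= 0).any():
        raise ValueError("loading control signal must be positive")
    blot = blot.copy()
    blot["ratio"] = blot["signal"] / blot["control_signal"]
    base = blot.loc[blot["stage"] == baseline_stage, "ratio"]
    if base.empty:
        raise ValueError(f"baseline stage {baseline_stage!r} absent from table")
    blot["normalized"] = blot["ratio"] / base.mean()

    rows = []
    for stage, grp in blot.groupby("stage", sort=False):
        m = float(grp["normalized"].mean())
        rows.append(
            dict(stage=stage, n=len(grp), normalized_mean=m,
                 normalized_sd=float(grp["normalized"].std(ddof=1)) if len(grp) > 1 else np.nan,
                 percent_change=100.0 * (m - 1.0),
                 percent_decrease=100.0 * (1.0 - m))
        )
    return pd.DataFrame(rows)


def two_tailed_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Student by default, Welch via flag)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means; p -> 0", stacklevel=2)
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
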
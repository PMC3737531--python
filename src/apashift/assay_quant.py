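"""Quantification formulas for bench validation assays.

Covers ChIP-PCR efficiency ``(V_ChIP - V_control)/V_input``, northern/RPA
distal:proximal band ratios with percent-of-control conversion, and the
shared two-sample Student t-test used for significance calls.  Band and PCR
signals enter as plain numeric tables; densitometry is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def chip_efficiency(v_chip: float, v_control: float, v_input: float) -> float:
    """Background-subtracted, input-normalized ChIP-PCR signal.

    ``(v_chip - v_control) / v_input`` where v_chip and v_control are PCR
    product amounts from specific- and control-antibody precipitates and
    v_input from input DNA.  May be negative when the control antibody
    recovers more product than the specific one.
    """
    if v_input <= 0:
        raise ValueError("v_input must be positive")
    if v_chip < 0 or v_control < 0:
        raise ValueError("signals must be nonnegative")
    return (v_chip - v_control) / v_input


def chip_efficiency_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply ``chip_efficiency`` row-wise to a (region, v_chip, v_control,
    v_input) table."""
    out = df.copy()
    out["efficiency"] = [
        chip_efficiency(r.v_chip, r.v_control, r.v_input) for r in df.itertuples()
    ]
    return out


def band_dp_ratio(df: pd.DataFrame, control_condition: str = "control") -> pd.DataFrame:
    """Distal/proximal band-intensity ratios, as percent of control.

    ``df`` holds one row per (assay, condition, replicate) with ``distal``
    and ``proximal`` band intensities.  Per replicate,
    ``dp_ratio = distal / proximal``; ``percent_of_control`` rescales each
    replicate by the control condition's mean dp_ratio within the same
    assay, so the control group averages 100 by construction.
    """
    if (df["proximal"] <= 0).any():
        raise ValueError("proximal band intensity must be positive")
    out = df.copy()
    out["dp_ratio"] = out["distal"] / out["proximal"]
    ctrl = out[out["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"no {control_condition!r} replicates present")
    if "assay" in out.columns:
        ctrl_mean = out["assay"].map(ctrl.groupby("assay")["dp_ratio"].mean())
        if ctrl_mean.isna().any():
            missing = out.loc[ctrl_mean.isna(), "assay"].iloc[0]
            raise ValueError(f"no {control_condition!r} replicates for assay {missing!r}")
    else:
        ctrl_mean = ctrl["dp_ratio"].mean()
    out["percent_of_control"] = 100.0 * out["dp_ratio"] / ctrl_mean
    return out


def band_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of percent_of_control per condition (and
    assay, if present)."""
    keys = [k for k in ("assay", "condition") if k in df.columns]
    return (
        df.groupby(keys)["percent_of_control"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def two_sample_ttest(a, b, sides: str = "two") -> TTestResult:
    """Equal-variance Student t-test with df = n_a + n_b - 2.

    With zero pooled variance the test degenerates: equal means give p = 1,
    unequal means p = 0 (flagged).  ``sides='one'`` halves the two-sided
    p-value toward mean(a) > mean(b).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, 1.0, df)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0, df, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if sides == "one":
        p = p / 2 if t > 0 else 1 - p / 2
    return TTestResult(float(t), float(p), df)
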
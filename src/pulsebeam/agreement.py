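"""Radar-vs-reference agreement statistics over an evaluation table.

Works on a pandas DataFrame with per-evaluation paired columns
``radar_<index>`` / ``ref_<index>`` (see
:func:`pulsebeam.synthetic_scene.generate_study` for the layout).
Provides the validity screen (RMSSD cap, SDNN inside the reference
range), Pearson correlation, Bland-Altman bias and limits of agreement,
and the intraclass correlation ICC(2,1): two-way random effects, single
measure, absolute agreement, with its F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HRV_INDEX_COLUMNS = ("mean_rr_ms", "sdnn_ms", "rmssd_ms", "lf_hf")


@dataclass(frozen=True)
class IndexAgreement:
    """Agreement statistics of one HRV index across the valid evaluations."""

    pearson_r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    n: int


def apply_outlier_rules(
    records: pd.DataFrame,
    rmssd_cap: float = 100.0,
    sdnn_bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Screen evaluations for radar-measurement validity.

    A record is invalid iff its radar RMSSD exceeds ``rmssd_cap`` (ms) or
    its radar SDNN falls outside ``sdnn_bounds``.  By default the bounds
    are the [min, max] of the *reference* SDNN over the input table — the
    reference method defines the plausible SDNN range for the session —
    but fixed bounds may be supplied.  Returns a copy with ``valid``
    (bool) and ``exclusion_reason`` (';'-joined) columns; idempotent.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    out = records.copy()
    if sdnn_bounds is None:
        sdnn_bounds = (float(out["ref_sdnn_ms"].min()), float(out["ref_sdnn_ms"].max()))
    reasons = []
    for _, row in out.iterrows():
        why = []
        if row["radar_rmssd_ms"] > rmssd_cap:
            why.append("rmssd")
        if not (sdnn_bounds[0] <= row["radar_sdnn_ms"] <= sdnn_bounds[1]):
            why.append("sdnn")
        reasons.append(";".join(why))
    out["exclusion_reason"] = reasons
    out["valid"] = [r == "" for r in reasons]
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman bias and 1.96-SD limits of agreement of d = y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_2_1(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    With n subjects and k = 2 raters (the two measurement methods),

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC and MSE are the rows (subjects), columns (methods) and
    error mean squares of the two-way layout.  The confidence interval is
    the Shrout-Fleiss/McGraw-Wong F-based interval with a Satterthwaite
    degrees-of-freedom approximation.
    """
    data = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    n, k = data.shape
    if n < 5:
        raise ValueError("need n >= 5 paired observations")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("degenerate mean squares; ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    # Satterthwaite df for the composite denominator
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), 1.0, 1.0
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num_v / den_v if den_v > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), float(lower), float(upper)


def agreement_report(
    records: pd.DataFrame,
    indices: tuple[str, ...] = HRV_INDEX_COLUMNS,
    valid_only: bool = True,
) -> dict[str, IndexAgreement]:
    """Per-index agreement statistics over the (valid) evaluations."""
    df = records
    if valid_only and "valid" in df.columns:
        df = df[df["valid"]]
    report = {}
    for name in indices:
        x = df[f"ref_{name}"].to_numpy(float)
        y = df[f"radar_{name}"].to_numpy(float)
        r, p = pearson(x, y)
        bias, lo, hi = bland_altman(x, y)
        icc, ci_lo, ci_hi = icc_2_1(x, y)
        report[name] = IndexAgreement(
            pearson_r=r, p_value=p, bias=bias, loa_low=lo, loa_high=hi,
            icc=icc, icc_ci_low=ci_lo, icc_ci_high=ci_hi, n=len(df),
        )
    return report
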
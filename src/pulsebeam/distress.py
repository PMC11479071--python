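"""VAS-based distress grouping, group comparison, and ROC analysis.

Evaluations are binned by their visual-analog-scale (VAS, 0-10) mental
distress score: three control bins below 7.5 and a "high" distress group
at and above the third quartile 7.5.  Inference contrasts the pooled
controls against the high group: a one-way ANOVA per HRV index, and an
ROC curve whose thresholds sit at midpoints between sorted unique values
(plus the two infinite ends).  Orientation is fixed per index — lower
mean RR / SDNN / RMSSD indicate distress, higher LF/HF does — rather than
auto-selected, which would inflate AUC under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSpec:
    """VAS bin edges and labels; half-open bins, last bin closed at 10."""

    edges: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0)
    labels: tuple[str, ...] = ("control1", "control2", "control3", "high")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need one label per bin")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    def label(self, vas: float) -> str:
        if not (self.edges[0] <= vas <= self.edges[-1]):
            raise ValueError(f"VAS score {vas} outside [{self.edges[0]}, {self.edges[-1]}]")
        for lo, hi, lab in zip(self.edges[:-1], self.edges[1:], self.labels):
            if lo <= vas < hi:
                return lab
        return self.labels[-1]  # closed last bin


#: per-index ROC orientation: True when low values indicate distress
POSITIVE_LOW = {"mean_rr_ms": True, "sdnn_ms": True, "rmssd_ms": True, "lf_hf": False}


@dataclass(frozen=True)
class ROCResult:
    """An ROC curve with its AUC and per-threshold operating points."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_low: bool


def assign_groups(records: pd.DataFrame, spec: GroupSpec | None = None) -> pd.DataFrame:
    """Label each record by its VAS bin; adds a ``group`` column."""
    spec = spec or GroupSpec()
    out = records.copy()
    out["group"] = [spec.label(v) for v in out["vas"]]
    return out


def group_counts(records: pd.DataFrame, spec: GroupSpec | None = None) -> dict[str, int]:
    spec = spec or GroupSpec()
    counts = records["group"].value_counts().to_dict()
    return {lab: int(counts.get(lab, 0)) for lab in spec.labels}


def anova_two_group(values_high: np.ndarray, values_control: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for the high-distress vs pooled-control contrast.

    For two groups F equals the square of the pooled-variance t statistic.
    """
    h = np.asarray(values_high, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if len(h) < 2 or len(c) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(h, ddof=1) == 0 and np.var(c, ddof=1) == 0:
        if h.mean() == c.mean():
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means: F undefined")
    f, p = stats.f_oneway(h, c)
    return float(f), float(p)


def anova_groups(*groups: np.ndarray) -> tuple[float, float]:
    """One-way omnibus ANOVA across any number of groups (e.g. the four
    VAS bins); the two-group contrast above is the primary inference."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def roc(values: np.ndarray, labels: np.ndarray, positive_low: bool = True) -> ROCResult:
    """ROC curve of a scalar index against binary distress labels.

    Thresholds are the midpoints between sorted unique values plus the
    two infinite ends.  With ``positive_low`` a record is called positive
    when its value is <= the threshold; otherwise when >= .  AUC is the
    trapezoid area of the (1-specificity, sensitivity) curve, identical
    to the normalised Mann-Whitney U statistic.

    Raises
    ------
    ValueError
        Unless both classes are present.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        called = v <= thr if positive_low else v >= thr
        sens[i] = np.count_nonzero(called & y) / n_pos
        spec[i] = np.count_nonzero(~called & ~y) / n_neg
    fpr = 1.0 - spec
    # traverse the staircase: within an FPR tie the top point must come last
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(auc=auc, thresholds=thresholds, sensitivity=sens, specificity=spec,
                     positive_low=positive_low)


def topleft_threshold(result: ROCResult) -> tuple[float, float, float]:
    """Operating point closest to the top-left corner of the ROC plane.

    Minimises (1-sens)^2 + (1-spec)^2; ties break toward higher
    sensitivity.  Returns (threshold, sensitivity, specificity).
    """
    if len(result.thresholds) == 0:
        raise ValueError("empty ROC result")
    d2 = (1.0 - result.sensitivity) ** 2 + (1.0 - result.specificity) ** 2
    # lexsort: among minimal distances prefer the highest sensitivity
    best = min(range(len(d2)), key=lambda i: (d2[i], -result.sensitivity[i]))
    return (
        float(result.thresholds[best]),
        float(result.sensitivity[best]),
        float(result.specificity[best]),
    )
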
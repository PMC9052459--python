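"""ROC curves, optimal cut points, AUC with DeLong and bootstrap intervals.

Shared machinery for threshold estimation against a dichotomous anchor.
Candidate thresholds are placed at the midpoints between adjacent distinct
observed scores (plus one degenerate endpoint on each side), which is what
produces half-unit thresholds such as 2.5 on an integer 0-10 pain scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateIntervalWarning, EstimationError

__all__ = [
    "RocCurve",
    "CutpointResult",
    "AucResult",
    "roc_curve",
    "optimal_cutpoint",
    "auc",
    "auc_ci_delong",
    "BootstrapInterval",
    "bootstrap_ci",
]

_ORIENTATIONS = ("higher_score_positive", "lower_score_positive")


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    return scores if orientation == "higher_score_positive" else -scores


def _classes(labels, scores):
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-d and the same length")
    if y.all() or not y.any():
        raise EstimationError("ROC undefined: both classes must be present")
    return y, x


@dataclass
class RocCurve:
    """Operating points of an empirical ROC curve.

    Thresholds are in original score units, strictly increasing.  A pair is
    called positive when its score is strictly beyond the threshold in the
    positive direction (above for ``higher_score_positive``, below for
    ``lower_score_positive``); with midpoint thresholds the strict/weak
    distinction never matters.
    """

    orientation: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_positive: int
    n_negative: int
    positive_label_meaning: str = "positive"

    def trapezoidal_auc(self) -> float:
        """Area under the (FPR, TPR) polygon by the trapezoidal rule."""
        fpr = 1.0 - self.specificity
        order = np.lexsort((self.sensitivity, fpr))
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


@dataclass
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    distance_to_corner: float


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    method: str = "delong"
    degenerate: bool = False

    @property
    def discrimination_label(self) -> str:
        """poor (<0.7), acceptable (0.7-0.8 inclusive), excellent (>0.8)."""
        if self.auc > 0.8:
            return "excellent"
        if self.auc >= 0.7:
            return "acceptable"
        return "poor"


def roc_curve(
    labels: Sequence,
    scores: Sequence,
    orientation: str = "higher_score_positive",
    positive_label_meaning: str = "positive",
) -> RocCurve:
    """Build the empirical ROC curve over midpoint candidate thresholds.

    One operating point per gap between distinct observed scores plus the
    two degenerate endpoints (sens=1/spec=0 and sens=0/spec=1).
    """
    y, x = _classes(labels, scores)
    s = _oriented(x, orientation)
    distinct = np.unique(s)
    if distinct.size > 1:
        half_gap = np.min(np.diff(distinct)) / 2.0
        mids = (distinct[:-1] + distinct[1:]) / 2.0
    else:
        half_gap = 0.5
        mids = np.empty(0)
    thr = np.concatenate(([distinct[0] - half_gap], mids, [distinct[-1] + half_gap]))

    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    # positive call: oriented score > threshold
    sens = (pos.size - np.searchsorted(pos, thr, side="right")) / pos.size
    spec = np.searchsorted(neg, thr, side="right") / neg.size

    if orientation == "lower_score_positive":
        thr, sens, spec = -thr[::-1], sens[::-1], spec[::-1]
    return RocCurve(
        orientation=orientation,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        positive_label_meaning=positive_label_meaning,
    )


def optimal_cutpoint(curve: RocCurve) -> CutpointResult:
    """Cut point closest to the top-left (0, 1) corner of ROC space.

    Minimizes sqrt((1-sens)^2 + (1-spec)^2); ties (within 1e-12) are broken
    toward higher sensitivity, then toward the smaller absolute threshold.
    """
    d = np.hypot(1.0 - curve.sensitivity, 1.0 - curve.specificity)
    near = d <= d.min() + 1e-12
    idx = np.flatnonzero(near)
    best_sens = curve.sensitivity[idx].max()
    idx = idx[curve.sensitivity[idx] >= best_sens - 1e-12]
    idx = idx[np.argmin(np.abs(curve.thresholds[idx]))]
    return CutpointResult(
        threshold=float(curve.thresholds[idx]),
        sensitivity=float(curve.sensitivity[idx]),
        specificity=float(curve.specificity[idx]),
        distance_to_corner=float(d[idx]),
    )


def auc(labels, scores, orientation: str = "higher_score_positive") -> float:
    """Mann-Whitney AUC: P(positive outranks negative), ties counted half."""
    y, x = _classes(labels, scores)
    s = _oriented(x, orientation)
    r = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components (placement values) for each observation."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()


def auc_ci_delong(
    labels,
    scores,
    alpha: float = 0.05,
    orientation: str = "higher_score_positive",
) -> AucResult:
    """AUC with a Wald confidence interval from DeLong's variance estimator.

    The variance is S10/m + S01/n where S10, S01 are the sample variances of
    the positive- and negative-class placement values.  The interval is
    truncated to [0, 1]; perfect separation gives zero variance and a
    degenerate interval, reported with a warning rather than an error.
    """
    y, x = _classes(labels, scores)
    s = _oriented(x, orientation)
    pos, neg = s[y], s[~y]
    if pos.size < 2 or neg.size < 2:
        raise EstimationError("DeLong CI requires at least 2 observations per class")
    v10, v01, a = _placements(pos, neg)
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    se = float(np.sqrt(var))
    degenerate = se == 0.0
    if degenerate:
        warnings.warn(
            "zero DeLong variance (perfect separation): interval collapses to a point",
            DegenerateIntervalWarning,
            stacklevel=2,
        )
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AucResult(
        auc=float(a),
        ci_low=float(max(0.0, a - z * se)),
        ci_high=float(min(1.0, a + z * se)),
        se=se,
        method="delong",
        degenerate=degenerate,
    )


@dataclass
class BootstrapInterval:
    low: float
    high: float
    n_undefined: int = 0
    degenerate: bool = False

    def __iter__(self):
        return iter((self.low, self.high))


def _take(data, idx):
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    if isinstance(data, tuple):
        return tuple(np.asarray(a)[idx] for a in data)
    return np.asarray(data)[idx]


def _length(data) -> int:
    if isinstance(data, tuple):
        return len(data[0])
    return len(data)


def bootstrap_ci(
    statistic: Callable,
    data,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed=None,
    units=None,
    max_undefined_frac: float = 0.2,
) -> BootstrapInterval:
    """Percentile bootstrap interval for ``statistic`` over resampled rows.

    ``data`` may be a DataFrame, an ndarray, or a tuple of equal-length
    arrays resampled jointly.  Resampling is with replacement at the row
    (pair) level, or at the cluster level when ``units`` gives a per-row
    cluster label (patient-level bootstrap).  Resamples on which the
    statistic is undefined (raises :class:`EstimationError`/ValueError or
    returns a non-finite value) are redrawn up to a cap; if more than
    ``max_undefined_frac`` of ``n_reps`` are undefined the interval is an
    error, with the failure rate reported.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = _length(data)
    if n == 0:
        raise EstimationError("cannot bootstrap an empty sample")

    if units is not None:
        units = np.asarray(units)
        uniq = pd.unique(units)
        members = {u: np.flatnonzero(units == u) for u in uniq}

    values = np.empty(n_reps)
    got = 0
    undefined = 0
    cap = int(np.ceil(n_reps * (1.0 + max_undefined_frac))) + 1
    attempts = 0
    while got < n_reps and attempts < cap:
        attempts += 1
        if units is None:
            idx = rng.integers(0, n, n)
        else:
            chosen = rng.choice(len(uniq), len(uniq), replace=True)
            idx = np.concatenate([members[uniq[c]] for c in chosen])
        try:
            v = float(statistic(_take(data, idx)))
        except (EstimationError, ValueError, ArithmeticError, np.linalg.LinAlgError):
            undefined += 1
            continue
        if not np.isfinite(v):
            undefined += 1
            continue
        values[got] = v
        got += 1
    if undefined > max_undefined_frac * n_reps or got < n_reps:
        raise EstimationError(
            f"bootstrap failed: {undefined}/{attempts} resamples yielded an "
            "undefined statistic"
        )
    low, high = np.percentile(values, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    degenerate = low == high
    if degenerate:
        warnings.warn(
            "bootstrap distribution is a point mass: degenerate interval",
            DegenerateIntervalWarning,
            stacklevel=2,
        )
    return BootstrapInterval(float(low), float(high), undefined, degenerate)
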
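"""Anchor-based minimal important difference (MID) estimators.

Four estimators against a five-level global rating of change (GRC):

* mean change (MC): mean change score of the "somewhat better" group;
* mean difference of change (MDC): mean("somewhat better") - mean("unchanged");
* ROC: the cut point on the change score closest to the top-left corner,
  discriminating improved from unchanged pairs;
* predictive modelling: logistic regression of the dichotomized anchor on
  the change score; the MID is the change value at which the likelihood
  ratio for improvement equals 1, adjusted for the pre-test odds of
  improvement: MID = (ln(pre_odds) - C) / B for fitted intercept C and
  slope B.  The unadjusted variant -C/B (the 50% predicted-probability
  point) is reported alongside.

All confidence intervals are percentile bootstrap intervals over
anchor-outcome pairs (patient-level cluster bootstrap available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, GlobalRatingOfChange, INSTRUMENTS, PairSet, build_pairs
from .exceptions import DegenerateIntervalWarning, EstimationError, ValidationError
from .roc import (
    AucResult,
    auc_ci_delong,
    bootstrap_ci,
    optimal_cutpoint,
    roc_curve,
)

__all__ = [
    "GrcDichotomization",
    "MidResult",
    "mid_mc",
    "mid_mdc",
    "mid_roc",
    "mid_predictive",
    "mid_all",
    "predictive_threshold",
]

_ALL_LEVELS = frozenset(int(g) for g in GlobalRatingOfChange)


@dataclass(frozen=True)
class GrcDichotomization:
    """Partition of the five GRC levels for ROC / predictive estimation.

    The default cut lies between "unchanged" and "somewhat better": improved
    = {much_better, somewhat_better}, reference = {unchanged}, and the
    deteriorated levels are excluded from the analysis.
    """

    improved: frozenset = frozenset({1, 2})
    reference: frozenset = frozenset({3})
    excluded: frozenset = frozenset({4, 5})

    def __post_init__(self):
        parts = [frozenset(self.improved), frozenset(self.reference), frozenset(self.excluded)]
        object.__setattr__(self, "improved", parts[0])
        object.__setattr__(self, "reference", parts[1])
        object.__setattr__(self, "excluded", parts[2])
        union = parts[0] | parts[1] | parts[2]
        if union != _ALL_LEVELS or sum(len(p) for p in parts) != 5:
            raise ValidationError("dichotomization sets must partition the 5 GRC levels")
        if not parts[1]:
            raise ValidationError("reference set must be non-empty")


@dataclass
class MidResult:
    instrument: str
    method: str  # mc | mdc | roc | predictive
    mid: float
    ci_low: float
    ci_high: float
    n_improved: int
    n_reference: int
    sensitivity: float | None = None
    specificity: float | None = None
    auc: AucResult | None = None
    logistic_intercept: float | None = None
    logistic_slope: float | None = None
    pre_odds: float | None = None
    mid_unadjusted: float | None = None
    notes: list = field(default_factory=list)


def _changes(pairs: PairSet, levels) -> np.ndarray:
    df = pairs.df
    mask = df["grc"].isin(list(levels))
    return df.loc[mask, "change"].to_numpy(float)


def mid_mc(pairs: PairSet, n_boot: int = 1000, seed=None) -> MidResult:
    """Mean change among pairs rated "somewhat better" (level 2 only)."""
    ch = _changes(pairs, {int(GlobalRatingOfChange.somewhat_better)})
    if ch.size == 0:
        raise EstimationError("mean change method: no 'somewhat better' pairs")
    mid = float(ch.mean())
    lo = hi = np.nan
    notes = []
    if ch.size == 1:
        lo = hi = mid
        notes.append("single pair: degenerate interval")
        warnings.warn("mean change on a single pair: degenerate CI",
                      DegenerateIntervalWarning, stacklevel=2)
    elif n_boot > 0:
        ci = bootstrap_ci(lambda d: float(np.mean(d)), ch, n_reps=n_boot, seed=seed)
        lo, hi = ci.low, ci.high
    return MidResult(pairs.instrument, "mc", mid, lo, hi,
                     n_improved=int(ch.size), n_reference=0, notes=notes)


def mid_mdc(pairs: PairSet, n_boot: int = 1000, seed=None) -> MidResult:
    """Mean difference of change: mean("somewhat better") - mean("unchanged")."""
    sb = _changes(pairs, {2})
    un = _changes(pairs, {3})
    if sb.size == 0:
        raise EstimationError("mean difference of change: empty 'somewhat better' group")
    if un.size == 0:
        raise EstimationError("mean difference of change: empty 'unchanged' group")
    mid = float(sb.mean() - un.mean())
    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = (
            sb[rng.integers(0, sb.size, (n_boot, sb.size))].mean(axis=1)
            - un[rng.integers(0, un.size, (n_boot, un.size))].mean(axis=1)
        )
        lo, hi = (float(v) for v in np.percentile(reps, [2.5, 97.5]))
    return MidResult(pairs.instrument, "mdc", mid, lo, hi,
                     n_improved=int(sb.size), n_reference=int(un.size))


def _dichotomize(pairs: PairSet, dicho: GrcDichotomization):
    df = pairs.df[pairs.df["grc"].notna()]
    keep = df["grc"].isin(list(dicho.improved | dicho.reference))
    df = df[keep]
    labels = df["grc"].isin(list(dicho.improved)).to_numpy(bool)
    change = df["change"].to_numpy(float)
    units = df["patient_id"].to_numpy()
    return labels, change, units


def mid_roc(
    pairs: PairSet,
    dichotomization: GrcDichotomization | None = None,
    n_boot: int = 1000,
    seed=None,
    bootstrap_unit: str = "pair",
) -> MidResult:
    """ROC-based MID: change-score cut point closest to the top-left corner.

    Improved versus reference pairs (deteriorated excluded), higher change =
    positive.  The MID interval re-runs cut-point selection on each
    bootstrap resample; the AUC interval uses DeLong's method.
    """
    dicho = dichotomization or GrcDichotomization()
    labels, change, units = _dichotomize(pairs, dicho)
    n_imp, n_ref = int(labels.sum()), int((~labels).sum())
    if n_imp < 2 or n_ref < 2:
        raise EstimationError(
            f"ROC MID requires >=2 pairs per class (improved={n_imp}, reference={n_ref})"
        )
    curve = roc_curve(labels, change, "higher_score_positive", "improved")
    cp = optimal_cutpoint(curve)
    aucres = auc_ci_delong(labels, change, orientation="higher_score_positive")

    lo = hi = np.nan
    if n_boot > 0:
        def stat(d):
            y, x = d
            return optimal_cutpoint(roc_curve(y, x, "higher_score_positive")).threshold

        ci = bootstrap_ci(
            stat, (labels, change), n_reps=n_boot, seed=seed,
            units=units if bootstrap_unit == "patient" else None,
        )
        lo, hi = ci.low, ci.high
    return MidResult(
        pairs.instrument, "roc", cp.threshold, lo, hi,
        n_improved=n_imp, n_reference=n_ref,
        sensitivity=cp.sensitivity, specificity=cp.specificity, auc=aucres,
    )


def predictive_threshold(intercept: float, slope: float, pre_odds: float = 1.0) -> float:
    """Change value where the likelihood ratio for improvement equals 1.

    From posterior odds = pre_odds * exp(C + B*x) at the fitted logit, the
    LR = 1 point is x = (ln(pre_odds) - C) / B; with balanced classes
    (pre_odds = 1) this reduces to -C/B.
    """
    if slope <= 0:
        raise EstimationError("anchor and change inversely related (slope <= 0)")
    return float((np.log(pre_odds) - intercept) / slope)


def _fit_logit(labels: np.ndarray, change: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(labels.astype(float), sm.add_constant(change)).fit(disp=0)
        except Exception as exc:  # statsmodels raises several fit errors
            raise EstimationError(
                f"logistic fit failed ({exc}); consider the ROC method"
            ) from exc
    params = np.asarray(res.params, float)
    if not (np.all(np.isfinite(params)) and res.mle_retvals.get("converged", False)):
        raise EstimationError(
            "logistic fit did not converge (possible complete separation); "
            "consider the ROC method"
        )
    return float(params[0]), float(params[1])


def mid_predictive(
    pairs: PairSet,
    dichotomization: GrcDichotomization | None = None,
    n_boot: int = 1000,
    seed=None,
    adjusted: bool = True,
    bootstrap_unit: str = "pair",
) -> MidResult:
    """Predictive-modelling MID from a logistic model of the anchor.

    Fits logit P(improved) = C + B * change on improved-vs-reference pairs
    and returns the prevalence-adjusted threshold (ln(pre_odds) - C)/B by
    default (``adjusted=False`` returns -C/B).  Bootstrap intervals re-fit
    the model on each resample.
    """
    dicho = dichotomization or GrcDichotomization()
    labels, change, units = _dichotomize(pairs, dicho)
    n_imp, n_ref = int(labels.sum()), int((~labels).sum())
    if n_imp < 2 or n_ref < 2:
        raise EstimationError(
            f"predictive MID requires >=2 pairs per class (improved={n_imp}, reference={n_ref})"
        )
    intercept, slope = _fit_logit(labels, change)
    pre_odds = n_imp / n_ref
    mid_adj = predictive_threshold(intercept, slope, pre_odds)
    mid_unadj = predictive_threshold(intercept, slope, 1.0)
    mid = mid_adj if adjusted else mid_unadj
    aucres = auc_ci_delong(labels, change, orientation="higher_score_positive")

    lo = hi = np.nan
    if n_boot > 0:
        def stat(d):
            y, x = d
            ni, nr = int(y.sum()), int((~y).sum())
            if ni < 2 or nr < 2:
                raise EstimationError("resample lost a class")
            c, b = _fit_logit(y, x)
            return predictive_threshold(c, b, ni / nr if adjusted else 1.0)

        ci = bootstrap_ci(
            stat, (labels, change), n_reps=n_boot, seed=seed,
            units=units if bootstrap_unit == "patient" else None,
        )
        lo, hi = ci.low, ci.high
    return MidResult(
        pairs.instrument, "predictive", mid, lo, hi,
        n_improved=n_imp, n_reference=n_ref, auc=aucres,
        logistic_intercept=intercept, logistic_slope=slope,
        pre_odds=pre_odds, mid_unadjusted=mid_unadj,
        notes=["prevalence-adjusted" if adjusted else "unadjusted (-C/B)"],
    )


_MID_METHODS = {
    "mc": lambda p, d, nb, sd, bu: mid_mc(p, n_boot=nb, seed=sd),
    "mdc": lambda p, d, nb, sd, bu: mid_mdc(p, n_boot=nb, seed=sd),
    "roc": lambda p, d, nb, sd, bu: mid_roc(p, d, n_boot=nb, seed=sd, bootstrap_unit=bu),
    "predictive": lambda p, d, nb, sd, bu: mid_predictive(
        p, d, n_boot=nb, seed=sd, bootstrap_unit=bu
    ),
}


def mid_all(
    cohort: CohortTable,
    instruments=("nrs", "prwhe_total", "prwhe_pain", "prwhe_function"),
    dichotomization: GrcDichotomization | None = None,
    n_boot: int = 1000,
    seed=None,
    bootstrap_unit: str = "pair",
) -> pd.DataFrame:
    """All four MID methods for every registered instrument.

    Returns a tidy frame (instrument x method); per-cell estimation errors
    are captured in the ``error`` column instead of aborting the table.
    """
    for inst in instruments:
        if inst not in INSTRUMENTS:
            raise ValidationError(f"unknown instrument {inst!r}")
    dicho = dichotomization or GrcDichotomization()
    children = np.random.SeedSequence(seed).spawn(len(instruments) * len(_MID_METHODS))
    rows = []
    k = 0
    for inst in instruments:
        pairs = build_pairs(cohort, inst, require_anchor="grc")
        for method, fn in _MID_METHODS.items():
            child = int(children[k].generate_state(1)[0])
            k += 1
            row = {"instrument": inst, "method": method, "n_pairs": len(pairs)}
            try:
                r = fn(pairs, dicho, n_boot, child, bootstrap_unit)
                row.update(
                    mid=r.mid, ci_low=r.ci_low, ci_high=r.ci_high,
                    n_improved=r.n_improved, n_reference=r.n_reference,
                    sensitivity=r.sensitivity, specificity=r.specificity,
                    auc=r.auc.auc if r.auc else np.nan,
                    auc_ci_low=r.auc.ci_low if r.auc else np.nan,
                    auc_ci_high=r.auc.ci_high if r.auc else np.nan,
                    error="",
                )
            except EstimationError as exc:
                row.update(
                    mid=np.nan, ci_low=np.nan, ci_high=np.nan,
                    n_improved=np.nan, n_reference=np.nan,
                    sensitivity=np.nan, specificity=np.nan,
                    auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
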
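"""Patient acceptable symptom state (PASS) estimation.

PASS is a *state* concept: the score level below which (all instruments
here score lower = better) patients consider their symptoms acceptable.
It is estimated from follow-up state scores and the binary
acceptable-symptom-state anchor by two methods:

* 75th percentile of the state-score distribution among satisfied pairs,
  with the linear-interpolation quantile (index h = (n-1)p + 1);
* ROC cut point discriminating satisfied from unsatisfied pairs, with
  lower score = positive (acceptable) orientation: sensitivity is the
  proportion of satisfied pairs at or below the threshold, specificity the
  proportion of unsatisfied pairs above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, INSTRUMENTS, PairSet, build_pairs
from .exceptions import EstimationError, LowSampleWarning, ValidationError
from .roc import AucResult, auc_ci_delong, bootstrap_ci, optimal_cutpoint, roc_curve

__all__ = ["PassResult", "pass_percentile", "pass_roc", "pass_all"]


@dataclass
class PassResult:
    instrument: str
    method: str  # percentile75 | roc
    pass_threshold: float  # state units; scores <= threshold are acceptable
    n_satisfied: int
    n_unsatisfied: int
    sensitivity: float | None = None
    specificity: float | None = None
    auc: AucResult | None = None
    ci_low: float = np.nan
    ci_high: float = np.nan
    notes: list = field(default_factory=list)


def _states(pairs: PairSet):
    df = pairs.df[pairs.df["pass_satisfied"].notna()]
    sat = df["pass_satisfied"].astype(bool).to_numpy()
    state = df["state"].to_numpy(float)
    units = df["patient_id"].to_numpy()
    return sat, state, units


def pass_percentile(pairs: PairSet, percentile: float = 75.0) -> PassResult:
    """PASS as the 75th percentile of state scores among satisfied pairs.

    Uses the linear-interpolation quantile definition (order-statistic
    index h = (n-1)p + 1).
    """
    sat, state, _ = _states(pairs)
    satisfied = state[sat]
    if satisfied.size == 0:
        raise EstimationError("percentile PASS: no satisfied pairs")
    if satisfied.size < 4:
        warnings.warn(
            f"only {satisfied.size} satisfied pairs: the percentile is unstable",
            LowSampleWarning,
            stacklevel=2,
        )
    thr = float(np.percentile(satisfied, percentile, method="linear"))
    return PassResult(
        pairs.instrument, "percentile75", thr,
        n_satisfied=int(satisfied.size), n_unsatisfied=int((~sat).sum()),
    )


def pass_roc(
    pairs: PairSet,
    n_boot: int = 1000,
    seed=None,
    bootstrap_unit: str = "pair",
) -> PassResult:
    """PASS as the ROC cut point separating satisfied from unsatisfied pairs.

    Lower state score = positive (acceptable).  The threshold interval
    re-runs cut-point selection per bootstrap resample; AUC uses DeLong.
    """
    sat, state, units = _states(pairs)
    n_sat, n_unsat = int(sat.sum()), int((~sat).sum())
    if n_sat < 2 or n_unsat < 2:
        raise EstimationError(
            f"ROC PASS requires >=2 pairs per class (satisfied={n_sat}, unsatisfied={n_unsat})"
        )
    curve = roc_curve(sat, state, "lower_score_positive", "acceptable state")
    cp = optimal_cutpoint(curve)
    aucres = auc_ci_delong(sat, state, orientation="lower_score_positive")

    lo = hi = np.nan
    if n_boot > 0:
        def stat(d):
            y, x = d
            return optimal_cutpoint(roc_curve(y, x, "lower_score_positive")).threshold

        ci = bootstrap_ci(
            stat, (sat, state), n_reps=n_boot, seed=seed,
            units=units if bootstrap_unit == "patient" else None,
        )
        lo, hi = ci.low, ci.high
    return PassResult(
        pairs.instrument, "roc", cp.threshold,
        n_satisfied=n_sat, n_unsatisfied=n_unsat,
        sensitivity=cp.sensitivity, specificity=cp.specificity,
        auc=aucres, ci_low=lo, ci_high=hi,
    )


def pass_all(
    cohort: CohortTable,
    instruments=("nrs", "prwhe_total", "prwhe_pain", "prwhe_function"),
    n_boot: int = 1000,
    seed=None,
    scope: str = "pooled",
    bootstrap_unit: str = "pair",
) -> pd.DataFrame:
    """Both PASS methods for every instrument; tidy frame with error cells.

    ``scope="final"`` restricts to the last follow-up (12 months) instead
    of pooling all follow-up timepoints.
    """
    if scope not in ("pooled", "final"):
        raise ValidationError("scope must be 'pooled' or 'final'")
    children = np.random.SeedSequence(seed).spawn(len(instruments))
    rows = []
    for inst, child in zip(instruments, children):
        pairs = build_pairs(cohort, inst, require_anchor="pass")
        if scope == "final":
            pairs = pairs.at_timepoint("m12")
        for method in ("percentile75", "roc"):
            row = {"instrument": inst, "method": method, "n_pairs": len(pairs)}
            try:
                if method == "percentile75":
                    r = pass_percentile(pairs)
                else:
                    r = pass_roc(
                        pairs, n_boot=n_boot,
                        seed=int(child.generate_state(1)[0]),
                        bootstrap_unit=bootstrap_unit,
                    )
                row.update(
                    pass_threshold=r.pass_threshold,
                    n_satisfied=r.n_satisfied, n_unsatisfied=r.n_unsatisfied,
                    sensitivity=r.sensitivity, specificity=r.specificity,
                    auc=r.auc.auc if r.auc else np.nan,
                    auc_ci_low=r.auc.ci_low if r.auc else np.nan,
                    auc_ci_high=r.auc.ci_high if r.auc else np.nan,
                    ci_low=r.ci_low, ci_high=r.ci_high, error="",
                )
            except EstimationError as exc:
                row.update(
                    pass_threshold=np.nan, n_satisfied=np.nan, n_unsatisfied=np.nan,
                    sensitivity=np.nan, specificity=np.nan,
                    auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan,
                    ci_low=np.nan, ci_high=np.nan, error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
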
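"""Anchor credibility checks for the global rating of change (GRC).

Before a transition anchor is trusted for threshold estimation, its
Spearman correlation with the change score should exceed 0.5 in absolute
value.  Because the GRC codes 1 = much better ... 5 = much worse while a
positive change score means improvement, a credible anchor shows a
*negative* change-score correlation; credibility is judged on |rho|.
Correlations with the baseline and follow-up scores are reported for
context without a pass/fail judgement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, FOLLOWUP_LABELS, PairSet, build_pairs
from .exceptions import EstimationError, LowSampleWarning
from .roc import BootstrapInterval, bootstrap_ci

__all__ = ["spearman_rho", "validate_anchor", "AnchorValidationReport", "anchor_table"]

CREDIBILITY_THRESHOLD = 0.5


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d and the same length")
    if x.size < 3:
        raise EstimationError("Spearman correlation requires at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise EstimationError("correlation undefined: constant input vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class AnchorValidationReport:
    instrument: str
    scope: str  # "pooled" or a follow-up timepoint label
    n_pairs: int
    rho_baseline: float
    rho_baseline_ci: BootstrapInterval | None
    rho_followup: float
    rho_followup_ci: BootstrapInterval | None
    rho_change: float
    rho_change_ci: BootstrapInterval | None

    @property
    def credible(self) -> bool:
        """|rho(GRC, change)| > 0.5 - the anchor tracks perceived change."""
        return abs(self.rho_change) > CREDIBILITY_THRESHOLD


def validate_anchor(
    pairs: PairSet,
    scope: str = "pooled",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed=None,
    low_n_floor: int = 10,
) -> AnchorValidationReport:
    """Correlate the GRC anchor with baseline, follow-up and change scores.

    Percentile bootstrap intervals with ``n_boot`` resamples (``n_boot=0``
    skips them).  ``scope`` is ``"pooled"`` or one follow-up label; small
    scopes (fewer than ``low_n_floor`` pairs) trigger a warning but still
    report.
    """
    df = pairs.df if scope == "pooled" else pairs.at_timepoint(scope).df
    df = df[df["grc"].notna()]
    if len(df) == 0:
        raise EstimationError(f"no pairs with a GRC anchor in scope {scope!r}")
    if len(df) < low_n_floor:
        warnings.warn(
            f"scope {scope!r} has only {len(df)} pairs (floor {low_n_floor})",
            LowSampleWarning,
            stacklevel=2,
        )
    grc = df["grc"].to_numpy(float)

    out = {}
    children = np.random.SeedSequence(seed).spawn(3)
    for component, child in zip(("baseline", "state", "change"), children):
        y = df[component].to_numpy(float)
        rho = spearman_rho(grc, y)
        ci = None
        if n_boot > 0:
            ci = bootstrap_ci(
                lambda d: spearman_rho(d[0], d[1]),
                (grc, y),
                n_reps=n_boot,
                alpha=alpha,
                seed=np.random.default_rng(child),
            )
        out[component] = (rho, ci)

    return AnchorValidationReport(
        instrument=pairs.instrument,
        scope=scope,
        n_pairs=len(df),
        rho_baseline=out["baseline"][0],
        rho_baseline_ci=out["baseline"][1],
        rho_followup=out["state"][0],
        rho_followup_ci=out["state"][1],
        rho_change=out["change"][0],
        rho_change_ci=out["change"][1],
    )


def anchor_table(
    cohort: CohortTable,
    instruments=("nrs", "prwhe_total", "prwhe_pain", "prwhe_function"),
    scopes=("pooled",) + FOLLOWUP_LABELS,
    n_boot: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Anchor-validation summary: rows = instrument x scope, tidy columns.

    The pooled rows are the headline credibility check; the per-timepoint
    rows mirror the supplementary correlation tables.
    """
    children = np.random.SeedSequence(seed).spawn(len(instruments))
    rows = []
    for inst, child in zip(instruments, children):
        pairs = build_pairs(cohort, inst, require_anchor="grc")
        for scope in scopes:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", LowSampleWarning)
                    rep = validate_anchor(
                        pairs, scope=scope, n_boot=n_boot,
                        seed=int(child.generate_state(1)[0]),
                    )
            except EstimationError:
                continue
            rows.append(
                {
                    "instrument": inst,
                    "scope": scope,
                    "n_pairs": rep.n_pairs,
                    "rho_baseline": rep.rho_baseline,
                    "rho_baseline_low": getattr(rep.rho_baseline_ci, "low", np.nan),
                    "rho_baseline_high": getattr(rep.rho_baseline_ci, "high", np.nan),
                    "rho_followup": rep.rho_followup,
                    "rho_followup_low": getattr(rep.rho_followup_ci, "low", np.nan),
                    "rho_followup_high": getattr(rep.rho_followup_ci, "high", np.nan),
                    "rho_change": rep.rho_change,
                    "rho_change_low": getattr(rep.rho_change_ci, "low", np.nan),
                    "rho_change_high": getattr(rep.rho_change_ci, "high", np.nan),
                    "credible": rep.credible,
                }
            )
    return pd.DataFrame(rows)
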
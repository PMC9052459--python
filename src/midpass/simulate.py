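"""Reproducible synthetic cohorts with known MID / PASS ground truth.

The generator emulates a single-arm longitudinal cohort (baseline plus
five follow-ups) of patients recovering after treatment for base-of-thumb
osteoarthritis, scored on NRS pain and the PRWHE:

* a latent recovery fraction s[i, t] = recovery_curve[t] + u_i, where u_i
  is a patient random effect, drives all instruments;
* observed follow-up score = clip(baseline - s * gain + noise), rounded to
  the instrument's granularity;
* the GRC anchor is the latent recovery plus anchor noise, discretized at
  four thresholds - so the anchor reflects *true* improvement, not the
  observed change, giving the realistic imperfect-anchor regime (AUC < 1);
* the binary acceptable-state anchor is a logistic draw on the
  range-normalized deficit of the observed state scores relative to the
  per-instrument acceptability locations.

Ground truth: the implied MID of instrument k is grc_thresholds[2] *
gain[k] (the change-scale position of the unchanged / somewhat-better
boundary); the implied PASS is pass_location[k].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, FOLLOWUP_LABELS, INSTRUMENTS
from .exceptions import ValidationError

__all__ = ["SyntheticConfig", "generate_cohort", "true_parameters", "study_regime_config"]

# change-scale position (fraction of the NRS gain) of the
# unchanged/somewhat-better boundary: 2.5 NRS points out of a 6.5-point gain
_DEFAULT_MID_FRACTION = 2.5 / 6.5


def _default_baselines():
    # mean, sd of the truncated-normal baseline severity per instrument
    return {"nrs": (6.5, 1.7), "prwhe_pain": (34.2, 6.8), "prwhe_function": (30.0, 7.9)}


def _default_recovery():
    # mean recovered fraction of the instrument gain at each follow-up
    return {
        "post_splint_6wk": 0.10,
        "m3": 0.45,
        "m6": 0.55,
        "m9": 0.60,
        "m12": 0.65,
    }


def _default_gain():
    # full-recovery change (instrument units) when the latent fraction is 1
    return {"nrs": 6.5, "prwhe_pain": 29.0, "prwhe_function": 27.0}


def _default_noise():
    return {"nrs": 0.9, "prwhe_pain": 3.0, "prwhe_function": 3.5}


def _default_pass_location():
    # state score at which satisfaction probability is 50%
    return {"nrs": 2.5, "prwhe_pain": 15.0, "prwhe_function": 11.0}


@dataclass
class SyntheticConfig:
    """Full parameterization of the latent-improvement generative model.

    Defaults reproduce the study regime this package targets: 50 patients,
    five follow-ups each (250 anchor-outcome pairs), NRS baseline 6.5 (1.7),
    PRWHE total baseline ~64 (12), an implied NRS MID of 2.5 change points
    and an implied NRS PASS of 2.5 state points, a GRC anchor whose change
    correlation is strong (|rho| well above 0.5) yet imperfect.
    """

    n_patients: int = 50
    baseline: dict = field(default_factory=_default_baselines)
    recovery_curve: dict = field(default_factory=_default_recovery)
    improvement_gain: dict = field(default_factory=_default_gain)
    noise_sd: dict = field(default_factory=_default_noise)
    patient_sd: float = 0.25
    baseline_correlation: float = 0.5
    grc_thresholds: tuple = (-0.35, -0.05, _DEFAULT_MID_FRACTION, 0.55)
    anchor_noise_sd: float = 0.12
    pass_location: dict = field(default_factory=_default_pass_location)
    pass_scale: float = 0.10
    missing_rate: float = 0.0
    include_items: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if len(self.grc_thresholds) != 4 or not np.all(np.diff(self.grc_thresholds) > 0):
            raise ValidationError("grc_thresholds must be 4 strictly increasing values")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        for name in ("nrs", "prwhe_pain", "prwhe_function"):
            for d, what in (
                (self.baseline, "baseline"),
                (self.improvement_gain, "improvement_gain"),
                (self.noise_sd, "noise_sd"),
                (self.pass_location, "pass_location"),
            ):
                if name not in d:
                    raise ValidationError(f"{what} missing entry for {name!r}")
        if set(self.recovery_curve) != set(FOLLOWUP_LABELS):
            raise ValidationError("recovery_curve must cover the five follow-up labels")
        if self.pass_scale <= 0 or self.patient_sd < 0 or self.anchor_noise_sd < 0:
            raise ValidationError("scale/sd parameters must be positive")

    # flat key-value (JSON) round-trip ---------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "grc_thresholds" in raw:
            raw["grc_thresholds"] = tuple(raw["grc_thresholds"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def study_regime_config(seed: int = 0, n_patients: int = 50) -> SyntheticConfig:
    """The bundled study-regime configuration (defaults) with a chosen seed."""
    return SyntheticConfig(seed=seed, n_patients=n_patients)


def bundled_config_path():
    """Path to the packaged study-regime generator config (JSON)."""
    from importlib.resources import files

    return files("midpass") / "data" / "study_regime.json"


def _truncnorm(rng, mean, sd, low, high, z=None, size=None):
    """Truncated normal by redraw; z supplies pre-correlated standard draws."""
    if z is None:
        z = rng.standard_normal(size)
    x = mean + sd * z
    bad = (x < low) | (x > high)
    while bad.any():
        x[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        bad = (x < low) | (x > high)
    return x


def _round_step(x, step):
    return np.round(np.asarray(x) / step) * step


def _composition(total: int, k: int, cap: int, rng) -> np.ndarray:
    """Random composition of ``total`` into k integer parts each <= cap."""
    parts = np.zeros(k, dtype=int)
    for _ in range(total):
        open_idx = np.flatnonzero(parts < cap)
        parts[open_idx[rng.integers(0, open_idx.size)]] += 1
    return parts


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a cohort from the latent-improvement model; seed-deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    insts = ("nrs", "prwhe_pain", "prwhe_function")

    # correlated baseline severity across instruments via a shared factor
    h = rng.standard_normal(n)
    rho = config.baseline_correlation
    baselines = {}
    for name in insts:
        mean, sd = config.baseline[name]
        z = rho * h + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        lo, hi = INSTRUMENTS[name].low, INSTRUMENTS[name].high
        b = _truncnorm(rng, mean, sd, lo, hi, z=z)
        baselines[name] = _round_step(b, INSTRUMENTS[name].step)

    u = rng.normal(0.0, config.patient_sd, n)  # patient random effect

    rows = []
    pids = [f"P{i + 1:03d}" for i in range(n)]
    for i, pid in enumerate(pids):
        rec = {"patient_id": pid, "timepoint": "baseline",
               "grc": np.nan, "pass_satisfied": None}
        for name in insts:
            rec[name] = float(baselines[name][i])
        rec["prwhe_total"] = rec["prwhe_pain"] + rec["prwhe_function"]
        rows.append(rec)

        for tp in FOLLOWUP_LABELS:
            s = config.recovery_curve[tp] + u[i]
            states = {}
            for name in insts:
                inst = INSTRUMENTS[name]
                raw = (
                    baselines[name][i]
                    - s * config.improvement_gain[name]
                    + rng.normal(0.0, config.noise_sd[name])
                )
                states[name] = float(
                    np.clip(_round_step(raw, inst.step), inst.low, inst.high)
                )
            perceived = s + rng.normal(0.0, config.anchor_noise_sd)
            grc = 5 - int(np.searchsorted(config.grc_thresholds, perceived, side="right"))

            deficit = sum(
                (states[name] - config.pass_location[name]) / INSTRUMENTS[name].span
                for name in insts
            )
            p_sat = 1.0 / (1.0 + np.exp(deficit / config.pass_scale))
            satisfied = bool(rng.random() < p_sat)

            rec = {
                "patient_id": pid, "timepoint": tp,
                "nrs": states["nrs"],
                "prwhe_pain": states["prwhe_pain"],
                "prwhe_function": states["prwhe_function"],
                "prwhe_total": states["prwhe_pain"] + states["prwhe_function"],
                "grc": grc, "pass_satisfied": satisfied,
            }
            rows.append(rec)

    df = pd.DataFrame(rows)

    if config.include_items:
        items = np.full((len(df), 15), np.nan)
        for r in range(len(df)):
            pain = int(round(df.loc[r, "prwhe_pain"]))
            func2 = int(round(2 * df.loc[r, "prwhe_function"]))
            items[r, :5] = _composition(pain, 5, 10, rng)
            items[r, 5:] = _composition(func2, 10, 10, rng)
            # keep stored subscales exactly consistent with the items
            df.loc[r, "prwhe_pain"] = float(items[r, :5].sum())
            df.loc[r, "prwhe_function"] = items[r, 5:].sum() / 2.0
            df.loc[r, "prwhe_total"] = (
                df.loc[r, "prwhe_pain"] + df.loc[r, "prwhe_function"]
            )
        for j in range(15):
            df[f"prwhe_item_{j + 1:02d}"] = items[:, j]

    if config.missing_rate > 0:
        fu = df["timepoint"] != "baseline"
        for block in (["nrs"], ["prwhe_pain", "prwhe_function", "prwhe_total"],
                      ["grc"], ["pass_satisfied"]):
            drop = fu & (rng.random(len(df)) < config.missing_rate)
            df.loc[drop, block] = np.nan if block != ["pass_satisfied"] else None

    return CohortTable(df)


def true_parameters(config: SyntheticConfig) -> dict:
    """Ground-truth MID and PASS targets implied by a generator config.

    MID[k] = grc_thresholds[2] * gain[k] (change units at the
    unchanged/somewhat-better boundary); PASS[k] = pass_location[k].
    Totals are the sum of the pain and function components.
    """
    config.validate()
    c3 = config.grc_thresholds[2]
    mid = {k: c3 * g for k, g in config.improvement_gain.items()}
    mid["prwhe_total"] = mid["prwhe_pain"] + mid["prwhe_function"]
    pas = dict(config.pass_location)
    pas["prwhe_total"] = pas["prwhe_pain"] + pas["prwhe_function"]
    return {"mid": mid, "pass": pas}
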
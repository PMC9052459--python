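"""Cohort data model for longitudinal patient-reported outcomes.

Holds one row per patient x timepoint with NRS pain (0-10), the PRWHE
instrument (15 items, pain and function subscales, total), a five-level
global rating of change (GRC) anchor and a binary acceptable-symptom-state
anchor at follow-ups.  All four registered instruments are scored so that
lower is better; a positive change score (baseline minus follow-up)
therefore means improvement.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Timepoint",
    "GlobalRatingOfChange",
    "Instrument",
    "INSTRUMENTS",
    "FOLLOWUP_LABELS",
    "score_prwhe",
    "compute_change",
    "CohortTable",
    "PairSet",
    "ExclusionLog",
    "build_pairs",
    "read_cohort",
    "write_cohort",
    "parse_grc",
    "parse_bool",
]


class Timepoint(enum.IntEnum):
    """The six assessment occasions; the value is the ordinal index."""

    baseline = 0
    post_splint_6wk = 1
    m3 = 2
    m6 = 3
    m9 = 4
    m12 = 5

    @property
    def is_followup(self) -> bool:
        return self > 0


TIMEPOINT_LABELS = tuple(t.name for t in Timepoint)
FOLLOWUP_LABELS = tuple(t.name for t in Timepoint if t.is_followup)


class GlobalRatingOfChange(enum.IntEnum):
    """Five-level global rating of change; 1 is the best outcome."""

    much_better = 1
    somewhat_better = 2
    unchanged = 3
    somewhat_worse = 4
    much_worse = 5


#: accepted spellings for GRC levels beyond the canonical enum names
_GRC_SYNONYMS = {
    "much better": 1,
    "somewhat better": 2,
    "unchanged": 3,
    "no change": 3,
    "no_change": 3,
    "somewhat worse": 4,
    "much worse": 5,
}

_TRUE_STRINGS = {"yes", "true", "1", "y"}
_FALSE_STRINGS = {"no", "false", "0", "n"}


def parse_grc(value) -> int | None:
    """Parse a GRC cell: integer 1-5 or a text label ('no change' == 'unchanged')."""
    if value is None or (not isinstance(value, str) and pd.isna(value)):
        return None
    if isinstance(value, str):
        text = value.strip().lower().replace("-", " ")
        if text == "":
            return None
        text_us = text.replace(" ", "_")
        if text_us in GlobalRatingOfChange.__members__:
            return int(GlobalRatingOfChange[text_us])
        if text in _GRC_SYNONYMS:
            return _GRC_SYNONYMS[text]
        try:
            value = int(text)
        except ValueError:
            raise ValidationError(f"unrecognized GRC value {value!r}") from None
    code = int(value)
    if float(code) != float(value) or not 1 <= code <= 5:
        raise ValidationError(f"GRC must be an integer 1-5, got {value!r}")
    return code


def parse_bool(value) -> bool | None:
    """Parse an acceptable-symptom-state cell: yes/no, true/false, 1/0."""
    if value is None or (not isinstance(value, str) and pd.isna(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValidationError(f"unrecognized yes/no value {value!r}")


@dataclass(frozen=True)
class Instrument:
    """A registered patient-reported outcome scale.

    ``step`` is the score granularity (the PRWHE function subscale moves in
    half points because it is the sum of ten items divided by two).
    """

    name: str
    low: float
    high: float
    step: float
    direction: str = "lower_is_better"

    @property
    def span(self) -> float:
        return self.high - self.low

    def check(self, value: float, context: str = "") -> None:
        if not (self.low <= value <= self.high):
            raise ValidationError(
                f"{context}{self.name} score {value} outside [{self.low}, {self.high}]"
            )


INSTRUMENTS: dict[str, Instrument] = {
    "nrs": Instrument("nrs", 0, 10, 1),
    "prwhe_pain": Instrument("prwhe_pain", 0, 50, 1),
    "prwhe_function": Instrument("prwhe_function", 0, 50, 0.5),
    "prwhe_total": Instrument("prwhe_total", 0, 100, 0.5),
}

SCORE_COLUMNS = ("nrs", "prwhe_pain", "prwhe_function", "prwhe_total")
ITEM_COLUMNS = tuple(f"prwhe_item_{i:02d}" for i in range(1, 16))
MANDATORY_COLUMNS = ("patient_id", "timepoint", *SCORE_COLUMNS, "grc", "pass_satisfied")


def score_prwhe(items) -> tuple[float, float, float]:
    """Score the 15-item PRWHE questionnaire.

    Items 1-5 form the pain subscale (their sum, 0-50); items 6-15 form the
    function subscale (their sum divided by two, 0-50, half points possible);
    the total is the sum of both subscales (0-100).

    Parameters
    ----------
    items : sequence of 15 integers, each in [0, 10]

    Returns
    -------
    (pain, function, total)
    """
    items = list(items)
    if len(items) != 15:
        raise ValidationError(f"PRWHE requires exactly 15 items, got {len(items)}")
    for i, item in enumerate(items, start=1):
        if item is None or (isinstance(item, float) and np.isnan(item)):
            raise ValidationError(f"PRWHE item {i} is missing")
        if float(item) != int(item) or not 0 <= int(item) <= 10:
            raise ValidationError(
                f"PRWHE item {i} must be an integer in [0, 10], got {item!r}"
            )
    vals = [int(v) for v in items]
    pain = float(sum(vals[:5]))
    function = sum(vals[5:]) / 2.0
    return pain, function, pain + function


def compute_change(baseline: float, followup: float, instrument: str | None = None) -> float:
    """Change score: baseline minus follow-up, so positive change = improvement."""
    if baseline is None or (isinstance(baseline, float) and np.isnan(baseline)):
        raise ValidationError("baseline score is missing")
    if followup is None or (isinstance(followup, float) and np.isnan(followup)):
        raise ValidationError("follow-up score is missing")
    if instrument is not None:
        inst = INSTRUMENTS[instrument]
        inst.check(float(baseline), "baseline ")
        inst.check(float(followup), "follow-up ")
    return float(baseline) - float(followup)


class CohortTable:
    """Validated long-format cohort: one row per (patient, timepoint).

    Wraps a :class:`pandas.DataFrame` whose columns are the mandatory score
    and anchor fields plus optional PRWHE item columns and arbitrary
    covariate columns (carried through untouched).  Soft problems (a patient
    with follow-ups but no baseline row, item/subscale disagreement) are
    recorded in :attr:`flags` and emitted as warnings; hard violations raise
    :class:`ValidationError`.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.flags: list[str] = []
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: list[dict]) -> "CohortTable":
        df = pd.DataFrame.from_records(records)
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        return cls(df)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"missing mandatory column {col!r}")

        bad_tp = ~df["timepoint"].isin(TIMEPOINT_LABELS)
        if bad_tp.any():
            row = int(df.index[bad_tp][0])
            raise ValidationError(
                f"row {row}: unknown timepoint {df.loc[row, 'timepoint']!r}"
            )

        dup = df.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            row = int(df.index[dup][0])
            raise ValidationError(
                f"row {row}: duplicate record for patient "
                f"{df.loc[row, 'patient_id']!r} at {df.loc[row, 'timepoint']!r}"
            )

        for col in SCORE_COLUMNS:
            inst = INSTRUMENTS[col]
            vals = pd.to_numeric(df[col], errors="coerce")
            present = df[col].notna()
            nonnumeric = present & vals.isna()
            if nonnumeric.any():
                row = int(df.index[nonnumeric][0])
                raise ValidationError(f"row {row}: non-numeric {col} value")
            out = present & ((vals < inst.low) | (vals > inst.high))
            if out.any():
                row = int(df.index[out][0])
                raise ValidationError(
                    f"row {row}: {col} = {vals[row]} outside [{inst.low}, {inst.high}]"
                )
            self.df[col] = vals

        nrs = self.df["nrs"]
        frac = nrs.notna() & (nrs != np.round(nrs))
        if frac.any():
            row = int(df.index[frac][0])
            raise ValidationError(f"row {row}: nrs must be an integer, got {nrs[row]}")

        both = self.df["prwhe_pain"].notna() & self.df["prwhe_function"].notna()
        tot = self.df["prwhe_total"]
        mismatch = both & tot.notna() & (
            np.abs(tot - (self.df["prwhe_pain"] + self.df["prwhe_function"])) > 1e-9
        )
        if mismatch.any():
            row = int(df.index[mismatch][0])
            raise ValidationError(
                f"row {row}: prwhe_total != prwhe_pain + prwhe_function"
            )

        # anchors only at follow-ups
        at_baseline = df["timepoint"] == "baseline"
        for col in ("grc", "pass_satisfied"):
            bad = at_baseline & df[col].notna()
            if bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(f"row {row}: {col} present at baseline")

        # parse anchors into canonical types
        self.df["grc"] = [parse_grc(v) for v in df["grc"]]
        self.df["grc"] = pd.to_numeric(self.df["grc"], errors="coerce")
        self.df["pass_satisfied"] = pd.array(
            [parse_bool(v) for v in df["pass_satisfied"]], dtype="boolean"
        )

        # every patient with a follow-up should also have a baseline
        has_base = set(df.loc[at_baseline, "patient_id"])
        for pid in df.loc[~at_baseline, "patient_id"].unique():
            if pid not in has_base:
                self.flags.append(f"patient {pid!r} has follow-ups but no baseline record")

        # recompute subscales from items where all 15 are present
        if all(c in df.columns for c in ITEM_COLUMNS):
            items = df.loc[:, list(ITEM_COLUMNS)].apply(pd.to_numeric, errors="coerce")
            self.df[list(ITEM_COLUMNS)] = items
            complete = items.notna().all(axis=1)
            for row in df.index[complete]:
                pain, function, total = score_prwhe(items.loc[row].tolist())
                stored = (
                    self.df.loc[row, "prwhe_pain"],
                    self.df.loc[row, "prwhe_function"],
                    self.df.loc[row, "prwhe_total"],
                )
                if any(
                    pd.notna(s) and abs(s - v) > 1e-9
                    for s, v in zip(stored, (pain, function, total))
                ):
                    self.flags.append(
                        f"row {row}: stored PRWHE subscales disagree with the "
                        f"15 item responses (recomputed {pain}/{function}/{total})"
                    )

        for msg in self.flags:
            warnings.warn(msg, UserWarning, stacklevel=3)

    # -- accessors -----------------------------------------------------

    @property
    def patients(self) -> list:
        return list(pd.unique(self.df["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def baseline(self) -> pd.DataFrame:
        return self.df[self.df["timepoint"] == "baseline"]

    def followups(self) -> pd.DataFrame:
        return self.df[self.df["timepoint"] != "baseline"]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class ExclusionLog:
    """Counts of candidate (patient, follow-up) rows dropped and why."""

    no_baseline_record: int = 0
    missing_baseline_score: int = 0
    missing_followup_score: int = 0
    missing_grc: int = 0
    missing_pass: int = 0

    @property
    def total(self) -> int:
        return (
            self.no_baseline_record
            + self.missing_baseline_score
            + self.missing_followup_score
            + self.missing_grc
            + self.missing_pass
        )

    def as_dict(self) -> dict:
        return {
            "no_baseline_record": self.no_baseline_record,
            "missing_baseline_score": self.missing_baseline_score,
            "missing_followup_score": self.missing_followup_score,
            "missing_grc": self.missing_grc,
            "missing_pass": self.missing_pass,
        }


@dataclass
class PairSet:
    """Anchor-outcome pairs for one instrument, pooled across follow-ups.

    ``df`` columns: patient_id, timepoint, baseline, state (follow-up
    score), change (baseline - state), grc, pass_satisfied.
    """

    instrument: str
    df: pd.DataFrame
    exclusions: ExclusionLog = field(default_factory=ExclusionLog)

    def __len__(self) -> int:
        return len(self.df)

    def at_timepoint(self, label: str) -> "PairSet":
        if label not in FOLLOWUP_LABELS:
            raise ValidationError(f"unknown follow-up timepoint {label!r}")
        return PairSet(self.instrument, self.df[self.df["timepoint"] == label], self.exclusions)


def build_pairs(
    cohort: CohortTable,
    instrument: str,
    require_anchor: str = "grc",
    timepoint: str | None = None,
) -> PairSet:
    """Pool anchor-outcome pairs across follow-up timepoints.

    One pair per (patient, follow-up) with a baseline score, a follow-up
    score and the required anchor; everything else is excluded and counted
    in the returned :class:`ExclusionLog` (pairwise deletion).

    ``require_anchor`` is ``"grc"`` (change analyses), ``"pass"`` (state
    analyses) or ``"none"`` (keep any scored pair).
    """
    if instrument not in INSTRUMENTS:
        raise ValidationError(f"unknown instrument {instrument!r}")
    if require_anchor not in ("grc", "pass", "none"):
        raise ValidationError(f"require_anchor must be grc/pass/none, got {require_anchor!r}")

    log = ExclusionLog()
    base = cohort.baseline().set_index("patient_id")[instrument]
    rows = []
    fu = cohort.followups()
    if timepoint is not None:
        fu = fu[fu["timepoint"] == timepoint]
    if len(cohort) == 0:
        warnings.warn("empty cohort: no anchor-outcome pairs", UserWarning, stacklevel=2)
    for _, rec in fu.iterrows():
        pid = rec["patient_id"]
        if pid not in base.index:
            log.no_baseline_record += 1
            continue
        b = base.loc[pid]
        if pd.isna(b):
            log.missing_baseline_score += 1
            continue
        s = rec[instrument]
        if pd.isna(s):
            log.missing_followup_score += 1
            continue
        if require_anchor == "grc" and pd.isna(rec["grc"]):
            log.missing_grc += 1
            continue
        if require_anchor == "pass" and pd.isna(rec["pass_satisfied"]):
            log.missing_pass += 1
            continue
        rows.append(
            {
                "patient_id": pid,
                "timepoint": rec["timepoint"],
                "baseline": float(b),
                "state": float(s),
                "change": float(b) - float(s),
                "grc": rec["grc"] if pd.notna(rec["grc"]) else np.nan,
                "pass_satisfied": rec["pass_satisfied"]
                if pd.notna(rec["pass_satisfied"])
                else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "timepoint",
            "baseline",
            "state",
            "change",
            "grc",
            "pass_satisfied",
        ],
    )
    return PairSet(instrument, df, log)


# -- CSV I/O ------------------------------------------------------------


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (see the package README for the column contract).

    Validation errors report the offending data row (0-based, header
    excluded).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan})
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    return CohortTable(raw)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips losslessly."""
    df = cohort.df.copy()
    df["grc"] = [("" if pd.isna(v) else str(int(v))) for v in df["grc"]]
    df["pass_satisfied"] = [
        "" if pd.isna(v) else ("yes" if v else "no") for v in df["pass_satisfied"]
    ]
    def _fmt(v):
        if pd.isna(v):
            return ""
        f = float(v)
        return str(int(f)) if f == int(f) else repr(f)

    for col in SCORE_COLUMNS + tuple(c for c in ITEM_COLUMNS if c in df.columns):
        df[col] = [_fmt(v) for v in df[col]]
    df.to_csv(path, index=False)
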
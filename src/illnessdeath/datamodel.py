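"""Cohort data model and delimited-text I/O for illness-death trajectories.

A cohort is a collection of subjects followed from a common time origin
(here: hospital discharge after an index fracture). Each subject may pass
through an intermediate transient state (refracture) before reaching the
absorbing state (death) or being administratively censored. All times are
durations from the origin, in years.

The on-disk format is a plain CSV with columns
``id,sex,age,t_refracture,refracture,t_terminal,death`` where ``sex`` is
``F``/``M`` (configurable), ``t_refracture`` is empty for subjects without
an intermediate event, and the indicator columns are 0/1. A leading comment
line ``# age_center=<value>`` records the age-centering constant so that a
cohort round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

SEX_WOMAN = "woman"
SEX_MAN = "man"

#: default mapping from file sex codes to internal labels
DEFAULT_SEX_MAP: Mapping[str, str] = {"F": SEX_WOMAN, "M": SEX_MAN}

#: columns of the canonical cohort CSV, in order
COHORT_COLUMNS = ("id", "sex", "age", "t_refracture", "refracture", "t_terminal", "death")

DAYS_PER_YEAR = 365.25


class CohortValidationError(ValueError):
    """Raised when one or more cohort rows violate trajectory invariants.

    Attributes
    ----------
    errors : list of (row_label, message)
        One entry per offending row.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid cohort row(s): {lines}{more}")


@dataclass(frozen=True)
class CovariateProfile:
    """Covariates entering the proportional-hazards linear predictor.

    Parameters
    ----------
    sex : {"woman", "man"}
        Women enter the linear predictor through the indicator I_Wo = 1;
        men are the reference group.
    age : float
        Age in years at the time origin (discharge).
    age_bounds : tuple of float, optional
        Sanity range for ``age``; widen for unusual populations.
    """

    sex: str
    age: float
    age_bounds: tuple[float, float] = field(default=(50.0, 110.0), compare=False)

    def __post_init__(self):
        if self.sex not in (SEX_WOMAN, SEX_MAN):
            raise ValueError(f"sex must be {SEX_WOMAN!r} or {SEX_MAN!r}, got {self.sex!r}")
        lo, hi = self.age_bounds
        if not (lo <= self.age <= hi):
            raise ValueError(f"age {self.age} outside sane range [{lo}, {hi}]")

    @property
    def is_woman(self) -> int:
        return 1 if self.sex == SEX_WOMAN else 0


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observed trajectory through the illness-death model.

    Times are years since the common origin. ``t_refracture`` is present iff
    the subject entered the intermediate state; ``t_terminal`` is the time of
    death or censoring, whichever observation ended follow-up.
    """

    id: str
    sex: str
    age: float
    t_terminal: float
    died: bool
    t_refracture: float | None = None

    def __post_init__(self):
        problems = self.problems()
        if problems:
            raise ValueError(f"invalid record {self.id!r}: " + "; ".join(problems))

    def problems(self) -> list[str]:
        out = []
        if self.sex not in (SEX_WOMAN, SEX_MAN):
            out.append(f"unknown sex {self.sex!r}")
        if not math.isfinite(self.age):
            out.append("age not finite")
        if not (self.t_terminal > 0):
            out.append(f"t_terminal must be > 0, got {self.t_terminal}")
        if self.t_refracture is not None:
            if not (self.t_refracture > 0):
                out.append(f"t_refracture must be > 0, got {self.t_refracture}")
            elif not (self.t_refracture < self.t_terminal):
                out.append(
                    f"t_refracture ({self.t_refracture}) must precede t_terminal ({self.t_terminal})"
                )
        return out

    @property
    def refractured(self) -> bool:
        return self.t_refracture is not None

    @property
    def is_woman(self) -> int:
        return 1 if self.sex == SEX_WOMAN else 0

    def profile(self, **kwargs) -> CovariateProfile:
        return CovariateProfile(self.sex, self.age, **kwargs)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of :class:`SubjectRecord` plus the age-centering
    constant used by every model fitted to it.

    ``age_center`` is stored with the data (and with every fitted model):
    predictions must always use the training centering constant.
    """

    records: tuple[SubjectRecord, ...]
    age_center: float

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise ValueError(f"duplicate subject ids: {sorted(dup)[:5]}")
        if not math.isfinite(self.age_center):
            raise ValueError("age_center must be finite")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord], age_center: float | None = None) -> "Cohort":
        records = tuple(records)
        if age_center is None:
            if not records:
                raise ValueError("age_center must be given for an empty cohort")
            age_center = float(np.mean([r.age for r in records]))
        return cls(records, float(age_center))

    def to_frame(self, sex_map: Mapping[str, str] = DEFAULT_SEX_MAP) -> pd.DataFrame:
        inv = {v: k for k, v in sex_map.items()}
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sex": [inv[r.sex] for r in self.records],
                "age": [r.age for r in self.records],
                "t_refracture": [r.t_refracture for r in self.records],
                "refracture": [int(r.refractured) for r in self.records],
                "t_terminal": [r.t_terminal for r in self.records],
                "death": [int(r.died) for r in self.records],
            },
            columns=list(COHORT_COLUMNS),
        )


def cohort_from_frame(
    df: pd.DataFrame,
    *,
    sex_map: Mapping[str, str] = DEFAULT_SEX_MAP,
    time_unit: str = "years",
    day_divisor: float = DAYS_PER_YEAR,
    tie_offset: float | None = None,
    age_center: float | None = None,
) -> Cohort:
    """Build a validated :class:`Cohort` from a DataFrame in the canonical layout.

    Rows violating the trajectory invariants are collected and reported
    together in a :class:`CohortValidationError` carrying the row labels.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"cohort table missing required column(s): {missing}")
    if time_unit not in ("years", "days"):
        raise ValueError(f"time_unit must be 'years' or 'days', got {time_unit!r}")
    scale = 1.0 / day_divisor if time_unit == "days" else 1.0

    records, errors = [], []
    for label, row in df.iterrows():
        sex_code = str(row["sex"])
        if sex_code not in sex_map:
            errors.append((label, f"unknown sex code {sex_code!r}"))
            continue
        t_ref = row["t_refracture"]
        has_ref = not (pd.isna(t_ref)) and bool(int(row["refracture"]))
        if bool(int(row["refracture"])) != (not pd.isna(t_ref)):
            errors.append((label, "refracture indicator inconsistent with t_refracture"))
            continue
        t_term = float(row["t_terminal"]) * scale
        t_ref_v = float(t_ref) * scale if has_ref else None
        if tie_offset is not None and t_ref_v is not None and t_ref_v >= t_term:
            if t_ref_v == t_term:
                t_term = t_term + tie_offset
        try:
            rec = SubjectRecord(
                id=str(row["id"]),
                sex=sex_map[sex_code],
                age=float(row["age"]),
                t_terminal=t_term,
                died=bool(int(row["death"])),
                t_refracture=t_ref_v,
            )
        except ValueError as exc:
            errors.append((label, str(exc)))
            continue
        records.append(rec)
    if errors:
        raise CohortValidationError(errors)
    return Cohort.from_records(records, age_center=age_center)


def read_cohort(
    path,
    *,
    sex_map: Mapping[str, str] = DEFAULT_SEX_MAP,
    time_unit: str = "years",
    day_divisor: float = DAYS_PER_YEAR,
    tie_offset: float | None = None,
    age_center: float | None = None,
    dialect: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path : path-like
    sex_map : mapping, optional
        File sex code -> {"woman", "man"}.
    time_unit : {"years", "days"}
        With "days", times are divided by ``day_divisor`` (365.25).
    tie_offset : float, optional
        If given, a tied refracture/terminal time is broken by adding this
        offset (years) to the terminal time instead of rejecting the row.
        A common choice is half a day, ``0.5/365.25``.
    age_center : float, optional
        Overrides the stored/default centering constant (cohort mean age).
    dialect : mapping, optional
        Canonical column name -> file column name, for files with other headers.
    """
    path = Path(path)
    stored_center = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# age_center="):
        stored_center = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    if age_center is None:
        age_center = stored_center
    return cohort_from_frame(
        df,
        sex_map=sex_map,
        time_unit=time_unit,
        day_divisor=day_divisor,
        tie_offset=tie_offset,
        age_center=age_center,
    )


def write_cohort(cohort: Cohort, path, *, sex_map: Mapping[str, str] = DEFAULT_SEX_MAP) -> None:
    """Write a cohort to CSV so that :func:`read_cohort` recovers it exactly."""
    path = Path(path)
    df = cohort.to_frame(sex_map=sex_map)
    with open(path, "w") as fh:
        fh.write(f"# age_center={cohort.age_center!r}\n")
        # %.17g guarantees binary round-trip of the stored times and ages
        df.to_csv(fh, index=False, float_format="%.17g")


def cohort_summary(cohort: Cohort) -> pd.Series:
    """Descriptive statistics of a cohort.

    Returns counts and percentages of women, intermediate events and deaths,
    mean age at origin and the median follow-up time estimated by the
    reverse Kaplan-Meier method (the median of the censoring distribution,
    treating deaths as censored observations of the potential follow-up).
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    women = sum(r.is_woman for r in cohort)
    refr = sum(r.refractured for r in cohort)
    died = sum(r.died for r in cohort)
    ages = np.array([r.age for r in cohort])
    t_term = np.array([r.t_terminal for r in cohort])
    censored = np.array([not r.died for r in cohort])
    return pd.Series(
        {
            "n": n,
            "n_women": women,
            "pct_women": 100.0 * women / n,
            "mean_age": float(ages.mean()),
            "n_refractured": refr,
            "pct_refractured": 100.0 * refr / n,
            "n_died": died,
            "pct_died": 100.0 * died / n,
            "median_followup": _reverse_km_median(t_term, censored),
            "age_center": cohort.age_center,
        }
    )


def _reverse_km_median(t_term: np.ndarray, censored: np.ndarray) -> float:
    """Median of the censoring (potential follow-up) distribution by the
    reverse Kaplan-Meier estimator: administrative censorings are the
    "events", deaths the censored observations."""
    order = np.argsort(t_term, kind="stable")
    t = t_term[order]
    ev = censored[order].astype(int)
    event_times = np.unique(t[ev == 1])
    if event_times.size == 0:
        return float("nan")
    n = t.size
    surv = 1.0
    for et in event_times:
        at_risk = n - np.searchsorted(t, et, side="left")
        d = int(np.sum((t == et) & (ev == 1)))
        surv *= 1.0 - d / at_risk
        if surv <= 0.5:
            return float(et)
    return float("nan")
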
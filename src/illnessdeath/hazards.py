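"""Weibull proportional-hazards transition intensities.

Each of the three transitions (F→R fracture-to-refracture, F→D
fracture-to-death, R→D refracture-to-death) carries a Weibull baseline
hazard ``h0(t) = alpha * lam * t**(alpha-1)`` multiplied by
``exp(beta_wo * I_Wo + beta_age * (age - age_center))``.

Note the parameterization: ``lam`` is a *rate-like* scale, so the baseline
cumulative hazard is ``H0(t) = lam * t**alpha``. It is not the textbook
Weibull scale sigma = (1/lam)**(1/alpha).

The R→D transition runs on a clock that resets at the refracture time
(semi-Markov): its ``t`` argument is the elapsed time since refracture.
Optionally the refracture time itself enters the R→D linear predictor via
``beta_t12`` (a homogeneity check for the clock-reset assumption).

All functions accept numpy arrays for the parameter fields and/or times and
broadcast, which is how posterior draws are propagated efficiently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .datamodel import CovariateProfile

TRANSITIONS = ("FR", "FD", "RD")


@dataclass(frozen=True)
class WeibullPHParams:
    """Parameters of one transition's Weibull PH intensity.

    ``beta_t12`` (log-hazard-ratio per year of fracture-to-refracture time)
    is only meaningful for the RD transition and is absent by default.
    """

    transition: str
    alpha: float
    lam: float
    beta_wo: float
    beta_age: float
    beta_t12: float | None = None

    def __post_init__(self):
        if self.transition not in TRANSITIONS:
            raise ValueError(f"transition must be one of {TRANSITIONS}, got {self.transition!r}")
        if not np.all(np.asarray(self.alpha) > 0):
            raise ValueError("alpha must be > 0")
        if not np.all(np.asarray(self.lam) > 0):
            raise ValueError("lam must be > 0")
        if self.beta_t12 is not None and self.transition != "RD":
            raise ValueError("beta_t12 is only allowed on the RD transition")


@dataclass(frozen=True)
class IllnessDeathParams:
    """The full parameter set of the three-transition model plus the
    age-centering constant it was estimated under."""

    fr: WeibullPHParams
    fd: WeibullPHParams
    rd: WeibullPHParams
    age_center: float

    def __post_init__(self):
        for p, tr in ((self.fr, "FR"), (self.fd, "FD"), (self.rd, "RD")):
            if p.transition != tr:
                raise ValueError(f"expected transition {tr}, got {p.transition}")

    def __getitem__(self, transition: str) -> WeibullPHParams:
        return {"FR": self.fr, "FD": self.fd, "RD": self.rd}[transition]


def linear_predictor(
    params: WeibullPHParams,
    profile: CovariateProfile,
    age_center: float,
    t12: float | None = None,
):
    """beta_wo * I_Wo + beta_age * (age - age_center) [+ beta_t12 * t12]."""
    lp = params.beta_wo * profile.is_woman + params.beta_age * (profile.age - age_center)
    if params.beta_t12 is not None:
        if t12 is None:
            raise ValueError("beta_t12 present: the refracture time t12 is required")
        lp = lp + params.beta_t12 * t12
    return lp


def hazard(params: WeibullPHParams, t, lp):
    """Transition intensity alpha*lam*t**(alpha-1)*exp(lp) at elapsed time t.

    For ``alpha < 1`` the intensity diverges as ``t -> 0+``; that is a
    feature of the Weibull family, not an error, but ``t`` must be > 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    return params.alpha * params.lam * t ** (params.alpha - 1.0) * np.exp(lp)


def cumulative_hazard(params: WeibullPHParams, t, lp):
    """Integrated intensity lam*t**alpha*exp(lp) over (0, t]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative_hazard requires t >= 0")
    return params.lam * t**params.alpha * np.exp(lp)


def survival(params: WeibullPHParams, t, lp):
    """exp(-H(t)): probability of not yet having made this transition
    (in the absence of competition)."""
    return np.exp(-cumulative_hazard(params, t, lp))


# -- flat key-value serialization (transition,param,value) ------------------

_FIELDS = ("alpha", "lam", "beta_wo", "beta_age", "beta_t12")


def save_params(params: IllnessDeathParams, path) -> None:
    """Serialize a parameter set to a flat CSV ``transition,param,value``.

    The age-centering constant is stored under the pseudo-transition ``ALL``.
    """
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["transition", "param", "value"])
        w.writerow(["ALL", "age_center", repr(params.age_center)])
        for tr in TRANSITIONS:
            p = params[tr]
            for f in _FIELDS:
                v = getattr(p, f)
                if v is None:
                    continue
                w.writerow([tr, f, repr(float(v))])


def load_params(path) -> IllnessDeathParams:
    """Inverse of :func:`save_params`."""
    values: dict[str, dict[str, float]] = {tr: {} for tr in TRANSITIONS}
    age_center = None
    with open(Path(path)) as fh:
        for row in csv.DictReader(fh):
            tr, name, val = row["transition"], row["param"], float(row["value"])
            if tr == "ALL" and name == "age_center":
                age_center = val
            else:
                values[tr][name] = val
    if age_center is None:
        raise ValueError("parameter file lacks the ALL,age_center row")
    made = {tr: WeibullPHParams(transition=tr, **values[tr]) for tr in TRANSITIONS}
    return IllnessDeathParams(fr=made["FR"], fd=made["FD"], rd=made["RD"], age_center=age_center)


def with_arrays(params: WeibullPHParams, **arrays) -> WeibullPHParams:
    """Replace parameter fields with (broadcastable) numpy arrays, e.g. a
    column of posterior draws. Validation is broadcast-aware."""
    return replace(params, **arrays)
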
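"""Cause-specific decomposition of cohort trajectories and exact
log-likelihood of the three-transition Weibull PH model.

The full likelihood factorizes over transitions: each subject contributes a
right-censored observation to the F->R and F->D datasets (death without
refracture censors the refracture time; administrative censoring censors
both), and refractured subjects additionally contribute to the R->D dataset
on the clock that starts at refracture. The three transitions can therefore
be fitted independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Cohort
from .hazards import IllnessDeathParams, WeibullPHParams


@dataclass
class TransitionDataset:
    """A right-censored dataset for one transition.

    ``time`` is on the transition's own clock (years); ``event`` is 1 if the
    transition was observed, 0 if censored. ``t12`` (time of entry into the
    intermediate state, measured from the origin) is present iff the
    transition is RD.
    """

    transition: str
    time: np.ndarray
    event: np.ndarray
    is_woman: np.ndarray
    age: np.ndarray
    t12: np.ndarray | None = None
    # cached sufficient pieces (filled lazily)
    _logt: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.is_woman = np.asarray(self.is_woman, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        if self.t12 is not None:
            self.t12 = np.asarray(self.t12, dtype=float)
        if (self.t12 is not None) != (self.transition == "RD"):
            raise ValueError("t12 must be present iff transition == 'RD'")
        if self.n and self.time.min() <= 0:
            raise ValueError("all transition times must be > 0")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def logt(self) -> np.ndarray:
        if self._logt is None:
            self._logt = np.log(self.time)
        return self._logt

    def design_matrix(self, age_center: float, include_t12: bool = False) -> np.ndarray:
        """Columns: I_Wo, age - age_center [, t12]."""
        cols = [self.is_woman, self.age - age_center]
        if include_t12:
            if self.t12 is None:
                raise ValueError("dataset has no t12 column")
            cols.append(self.t12)
        return np.column_stack(cols)


def decompose(cohort: Cohort) -> dict[str, TransitionDataset]:
    """Split a cohort into the three cause-specific datasets.

    |FR| = |FD| = n; |RD| = number of refractured subjects.
    """
    t_exit1, ev_fr, ev_fd, woman, age = [], [], [], [], []
    rd_time, rd_ev, rd_w, rd_age, rd_t12 = [], [], [], [], []
    for r in cohort:
        exit1 = r.t_refracture if r.refractured else r.t_terminal
        t_exit1.append(exit1)
        ev_fr.append(1 if r.refractured else 0)
        ev_fd.append(1 if (r.died and not r.refractured) else 0)
        woman.append(r.is_woman)
        age.append(r.age)
        if r.refractured:
            rd_time.append(r.t_terminal - r.t_refracture)
            rd_ev.append(1 if r.died else 0)
            rd_w.append(r.is_woman)
            rd_age.append(r.age)
            rd_t12.append(r.t_refracture)
    return {
        "FR": TransitionDataset("FR", t_exit1, ev_fr, woman, age),
        "FD": TransitionDataset("FD", t_exit1, ev_fd, woman, age),
        "RD": TransitionDataset("RD", rd_time, rd_ev, rd_w, rd_age, t12=rd_t12),
    }


def loglik_transition(params: WeibullPHParams, data: TransitionDataset, age_center: float) -> float:
    """Sum_i [ delta_i * log h(t_i) - H(t_i) ] for one transition."""
    if params.transition != data.transition:
        raise ValueError(
            f"parameter transition {params.transition!r} does not match dataset {data.transition!r}"
        )
    if data.n == 0:
        return 0.0
    lp = params.beta_wo * data.is_woman + params.beta_age * (data.age - age_center)
    if params.beta_t12 is not None:
        lp = lp + params.beta_t12 * data.t12
    ev = data.event.astype(bool)
    H = params.lam * np.exp(params.alpha * data.logt + lp)
    ll = (
        data.n_events * (np.log(params.alpha) + np.log(params.lam))
        + (params.alpha - 1.0) * data.logt[ev].sum()
        + lp[ev].sum()
        - H.sum()
    )
    return float(ll)


def loglik_model(params: IllnessDeathParams, cohort: Cohort) -> float:
    """Total log-likelihood: the sum of the three per-transition terms,
    evaluated at the cohort's own age-centering constant."""
    if len(cohort) == 0:
        return 0.0
    data = decompose(cohort)
    return sum(loglik_transition(params[tr], data[tr], cohort.age_center) for tr in ("FR", "FD", "RD"))
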
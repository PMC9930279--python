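"""Frequentist nonparametric estimators for model checking.

Nelson-Aalen cumulative hazards per transition and the Aalen-Johansen
product-integral estimator of the illness-death transition probability
matrix. These are descriptive, covariate-free estimators: compute them on a
cohort (or a covariate-defined subset) and compare with the fitted
parametric curves. For the p_1j(0, t) state-occupation probabilities the
Aalen-Johansen estimator remains consistent under the semi-Markov model
because censoring here is purely administrative (independent of everything).

Ties are handled with the standard convention that events precede
censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Cohort
from .likelihood import TransitionDataset
from .hazards import IllnessDeathParams


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function starting at ``initial`` with jumps at
    ``times`` to ``values``; optional pointwise variance."""

    times: np.ndarray
    values: np.ndarray
    variance: np.ndarray | None = None
    initial: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[self.initial], np.asarray(self.values, dtype=float)])
        return vals[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "value": self.values})
        if self.variance is not None:
            df["variance"] = self.variance
        return df


def nelson_aalen(data: TransitionDataset) -> StepFunction:
    """Nelson-Aalen estimator of the cumulative cause-specific hazard:
    jumps d_i/n_i at each distinct event time (d_i events, n_i at risk),
    with the Poisson-type variance increment d_i/n_i^2."""
    if data.n == 0:
        raise ValueError("empty dataset")
    order = np.argsort(data.time, kind="stable")
    t_sorted = data.time[order]
    ev_sorted = data.event[order]
    event_times, first_idx = np.unique(t_sorted[ev_sorted == 1], return_index=True)
    if event_times.size == 0:
        return StepFunction(np.array([]), np.array([]), np.array([]))
    # at risk just before t: all with observed time >= t
    n_at_risk = data.n - np.searchsorted(t_sorted, event_times, side="left")
    d = np.array([np.sum((t_sorted == t) & (ev_sorted == 1)) for t in event_times], dtype=float)
    jumps = d / n_at_risk
    var = np.cumsum(d / n_at_risk**2)
    return StepFunction(event_times, np.cumsum(jumps), var)


@dataclass(frozen=True)
class AalenJohansen:
    """Aalen-Johansen estimate of the 3x3 matrix P(0, t) on the state space
    (1 = initial, 2 = intermediate, 3 = dead). ``matrices[k]`` is P(0, times[k])."""

    times: np.ndarray
    matrices: np.ndarray  # shape (k, 3, 3)

    def probability(self, i: int, j: int) -> StepFunction:
        """p_ij(0, .) as a step function (states are 1-based)."""
        return StepFunction(
            self.times, self.matrices[:, i - 1, j - 1], initial=1.0 if i == j else 0.0
        )

    def occupation(self, t) -> np.ndarray:
        """State-occupation probabilities (p11, p12, p13)(0, t) at times t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        mats = np.concatenate([np.eye(3)[None], self.matrices])
        return mats[idx][..., 0, :]


def aalen_johansen(cohort: Cohort) -> AalenJohansen:
    """Product-integral over the empirical transition intensity matrices.

    At each distinct observed transition time t the increment matrix has
    off-diagonal entries dN_ij(t) / Y_i(t) (observed i->j transitions over
    the number at risk in state i just before t); P is the ordered product
    of (I + dA). Rows sum to one by construction.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    t_ref = np.array([r.t_refracture if r.refractured else np.nan for r in cohort])
    t_term = np.array([r.t_terminal for r in cohort])
    refr = np.array([r.refractured for r in cohort])
    died = np.array([r.died for r in cohort])

    exit1 = np.where(refr, t_ref, t_term)  # leaves state 1 (event or censoring)
    sorted_exit1 = np.sort(exit1)
    sorted_entry2 = np.sort(t_ref[refr])
    sorted_exit2 = np.sort(t_term[refr])
    n = len(cohort)

    times_12 = t_ref[refr]
    times_13 = t_term[died & ~refr]
    times_23 = t_term[died & refr]
    all_times = np.unique(np.concatenate([times_12, times_13, times_23]))

    P = np.eye(3)
    mats = np.empty((all_times.size, 3, 3))
    for k, t in enumerate(all_times):
        y1 = n - np.searchsorted(sorted_exit1, t, side="left")
        y2 = np.searchsorted(sorted_entry2, t, side="left") - np.searchsorted(
            sorted_exit2, t, side="left"
        )
        d12 = np.sum(times_12 == t)
        d13 = np.sum(times_13 == t)
        d23 = np.sum(times_23 == t)
        A = np.zeros((3, 3))
        if y1 > 0:
            A[0, 1] = d12 / y1
            A[0, 2] = d13 / y1
            A[0, 0] = -(A[0, 1] + A[0, 2])
        if y2 > 0:
            A[1, 2] = d23 / y2
            A[1, 1] = -A[1, 2]
        P = P @ (np.eye(3) + A)
        mats[k] = P
    return AalenJohansen(all_times, mats)


# -- parametric vs nonparametric comparison ---------------------------------


def _marginal_parametric_occupation(params: IllnessDeathParams, cohort: Cohort, grid, n_nodes=64):
    """Covariate-averaged parametric (p11, p12, p13)(0, t) over the cohort:
    the model-implied marginal state occupation, comparable to the AJ
    estimate on the same cohort."""
    from .probabilities import _gl_nodes

    woman = np.array([r.is_woman for r in cohort], dtype=float)[:, None]
    age_c = (np.array([r.age for r in cohort], dtype=float) - params.age_center)[:, None]
    lp_fr = params.fr.beta_wo * woman + params.fr.beta_age * age_c
    lp_fd = params.fd.beta_wo * woman + params.fd.beta_age * age_c
    lp_rd0 = params.rd.beta_wo * woman + params.rd.beta_age * age_c
    fr, fd, rd = params.fr, params.fd, params.rd
    if rd.beta_t12 is not None:
        bt = rd.beta_t12
    else:
        bt = 0.0

    v, w = _gl_nodes(n_nodes)
    k = max(2.0, 3.0 / fr.alpha)
    out = np.empty((len(grid), 3))
    for i, t in enumerate(grid):
        if t == 0:
            out[i] = (1.0, 0.0, 0.0)
            continue
        H_fr_t = fr.lam * np.exp(lp_fr) * t**fr.alpha
        H_fd_t = fd.lam * np.exp(lp_fd) * t**fd.alpha
        p11_i = np.exp(-(H_fr_t + H_fd_t))[:, 0]
        u = t * v**k
        jac = t * k * v ** (k - 1.0)
        surv1 = np.exp(-fr.lam * np.exp(lp_fr) * u**fr.alpha - fd.lam * np.exp(lp_fd) * u**fd.alpha)
        h12 = fr.alpha * fr.lam * u ** (fr.alpha - 1.0) * np.exp(lp_fr)
        surv2 = np.exp(-rd.lam * np.exp(lp_rd0 + bt * u) * (t - u) ** rd.alpha)
        p12_i = np.sum(surv1 * h12 * surv2 * (w * jac), axis=-1)
        out[i] = (p11_i.mean(), p12_i.mean(), 1.0 - p11_i.mean() - p12_i.mean())
    return out


def model_check(
    post_or_params,
    cohort: Cohort,
    grid=None,
    n_nodes: int = 64,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Compare parametric and Aalen-Johansen state-occupation curves.

    Returns the per-grid-point comparison table (parametric vs AJ p11, p12,
    p13 averaged over the cohort's covariates) and the maximum absolute
    discrepancy per curve.
    """
    params = post_or_params if isinstance(post_or_params, IllnessDeathParams) else post_or_params.mean_params()
    if grid is None:
        grid = np.linspace(0.0, 5.0, 51)
    grid = np.asarray(grid, dtype=float)
    par = _marginal_parametric_occupation(params, cohort, grid, n_nodes=n_nodes)
    aj = aalen_johansen(cohort).occupation(grid)
    df = pd.DataFrame(
        {
            "time": grid,
            "p11_model": par[:, 0],
            "p12_model": par[:, 1],
            "p13_model": par[:, 2],
            "p11_aj": aj[:, 0],
            "p12_aj": aj[:, 1],
            "p13_aj": aj[:, 2],
        }
    )
    disc = {
        f"p1{j}": float(np.max(np.abs(par[:, j - 1] - aj[:, j - 1]))) for j in (1, 2, 3)
    }
    return df, disc
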
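"""Cumulative incidences and illness-death transition probabilities.

Given the three Weibull PH intensities h_FR, h_FD (time since origin) and
h_RD (time since refracture; semi-Markov clock reset), the functionals are

    p11(s,t)        = exp(-[H_FR(t)-H_FR(s)] - [H_FD(t)-H_FD(s)])
    p22(s,t | t12)  = exp(-[H_RD(t-t12) - H_RD(s-t12)])
    p12(s,t)        = int_s^t p11(s,u) h_FR(u) p22(u,t | u) du
    p13(s,t)        = 1 - p11(s,t) - p12(s,t)
    p23(s,t | t12)  = 1 - p22(s,t | t12)
    F_1j(t)         = int_0^t h_1j(u) p11(0,u) du          (j = R, D)

The integrals are computed by fixed-order Gauss-Legendre quadrature (64
nodes by default) after mapping to the integration interval; when the lower
limit is 0 and some Weibull shape is below 1 the integrand has an
integrable endpoint singularity u^(alpha-1), which is removed by the
substitution u = t * v^(1/alpha_min) before applying the rule.

Every function broadcasts over parameter fields given as arrays, which is
how posterior draws are propagated to credible bands (`posterior_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .datamodel import SEX_MAN, SEX_WOMAN, CovariateProfile
from .hazards import IllnessDeathParams, WeibullPHParams, linear_predictor

QUERY_KINDS = ("p11", "p12", "p13", "p22", "p23", "cif_FR", "cif_FD")


@dataclass(frozen=True)
class ProbabilityQuery:
    """A single probability functional to evaluate.

    For ``p22``/``p23``, ``clock`` selects the time scale of ``s`` and
    ``t``: on the ``"refracture"`` clock they are years since refracture
    (the common reporting scale); on the ``"fracture"`` clock they are years
    since the origin and ``t12`` (the refracture time) is required.
    """

    kind: str
    s: float
    t: float
    profile: CovariateProfile
    t12: float | None = None
    clock: str = "refracture"

    def __post_init__(self):
        if self.kind not in QUERY_KINDS:
            raise ValueError(f"kind must be one of {QUERY_KINDS}")
        if not (0 <= self.s <= self.t):
            raise ValueError(f"need 0 <= s <= t, got s={self.s}, t={self.t}")
        if self.kind in ("p22", "p23") and self.clock == "fracture":
            if self.t12 is None:
                raise ValueError("fracture-clock p22/p23 requires t12")
            if self.s < self.t12:
                raise ValueError("need s >= t12 on the fracture clock")
        if self.clock not in ("refracture", "fracture"):
            raise ValueError("clock must be 'refracture' or 'fracture'")


@dataclass(frozen=True)
class ProbabilityCurve:
    """Posterior mean and equal-tailed credible band of a functional over a
    time grid, for one covariate profile."""

    query: ProbabilityQuery
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    def __post_init__(self):
        eps = 1e-9
        ok = (
            (self.lower >= -eps)
            & (self.lower <= self.mean + eps)
            & (self.mean <= self.upper + eps)
            & (self.upper <= 1 + eps)
        )
        if not np.all(ok):
            raise ValueError("curve violates 0 <= lower <= mean <= upper <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.grid, "mean": self.mean, "lower": self.lower, "upper": self.upper}
        )


# -- quadrature --------------------------------------------------------------


@lru_cache(maxsize=8)
def _gl_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    # map to (0, 1)
    return 0.5 * (x + 1.0), 0.5 * w


def _integrate(f, s: float, t: float, n_nodes: int, singular_alpha: float | None):
    """Integrate ``f`` over (s, t); ``f`` maps a node vector (m,) to values
    whose last axis is the node axis. ``singular_alpha`` < 1 triggers the
    singularity-removing substitution (only valid for s == 0)."""
    if t <= s:
        return np.asarray(0.0)
    v, w = _gl_nodes(n_nodes)
    if s == 0.0 and singular_alpha is not None:
        # power substitution u = t*v**k regularizes both the integrable
        # singularity (alpha < 1) and the fractional-power derivative
        # singularity (non-integer alpha > 1) at the origin
        # k*alpha - 1 >= 2 makes the transformed integrand twice
        # differentiable at the origin for every shape in the set
        k = max(2.0, 3.0 / singular_alpha)
        u = t * v**k
        jac = t * k * v ** (k - 1.0)
        return np.sum(f(u) * (w * jac), axis=-1)
    u = s + (t - s) * v
    return (t - s) * np.sum(f(u) * w, axis=-1)


def _min_alpha(*params: WeibullPHParams) -> float:
    return float(min(np.min(np.asarray(p.alpha)) for p in params))


# -- core functionals --------------------------------------------------------


def _lp(params: IllnessDeathParams, tr: str, profile: CovariateProfile):
    return linear_predictor(params[tr], profile, params.age_center)


def _delta_H(p: WeibullPHParams, lp, s, t):
    return p.lam * np.exp(lp) * (np.maximum(t, 0.0) ** p.alpha - np.maximum(s, 0.0) ** p.alpha)


def _as_scalar(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else np.squeeze(x)


def p11(params: IllnessDeathParams, s: float, t: float, profile: CovariateProfile):
    """Event-free probability: still in the initial state at t given state 1 at s."""
    if not 0 <= s <= t:
        raise ValueError(f"need 0 <= s <= t, got s={s}, t={t}")
    out = np.exp(
        -_delta_H(params.fr, _lp(params, "FR", profile), s, t)
        - _delta_H(params.fd, _lp(params, "FD", profile), s, t)
    )
    return _as_scalar(out)


def p22(
    params: IllnessDeathParams,
    s: float,
    t: float,
    profile: CovariateProfile,
    t12: float | None = None,
    clock: str = "refracture",
):
    """Probability of remaining in the intermediate state at t given presence
    there at s. On the "refracture" clock s, t count from the refracture; on
    the "fracture" clock they count from the origin and ``t12`` is required.
    Without a ``beta_t12`` covariate the result depends on t12 only through
    the elapsed times (clock-reset semi-Markov property)."""
    if clock == "fracture":
        if t12 is None:
            raise ValueError("fracture-clock p22 requires t12")
        if s < t12:
            raise ValueError(f"need s >= t12, got s={s} < t12={t12}")
        s, t = s - t12, t - t12
    if not 0 <= s <= t:
        raise ValueError(f"need 0 <= s <= t, got s={s}, t={t}")
    lp = linear_predictor(params.rd, profile, params.age_center, t12=t12)
    return _as_scalar(np.exp(-_delta_H(params.rd, lp, s, t)))


def p12(
    params: IllnessDeathParams,
    s: float,
    t: float,
    profile: CovariateProfile,
    n_nodes: int = 64,
):
    """Probability of being alive in the intermediate state at t given the
    initial state at s: quadrature of p11(s,u) h_FR(u) p22(u,t|u)."""
    if not 0 <= s <= t:
        raise ValueError(f"need 0 <= s <= t, got s={s}, t={t}")
    if t == s:
        return 0.0
    lp_fr = _lp(params, "FR", profile)
    lp_fd = _lp(params, "FD", profile)
    fr, fd, rd = params.fr, params.fd, params.rd

    def integrand(u):
        # broadcast draws (d,1) against nodes (m,)
        lp_rd = linear_predictor(rd, profile, params.age_center, t12=u)
        surv1 = np.exp(-_delta_H(fr, lp_fr, s, u) - _delta_H(fd, lp_fd, s, u))
        h12 = fr.alpha * fr.lam * u ** (fr.alpha - 1.0) * np.exp(lp_fr)
        surv2 = np.exp(-rd.lam * np.exp(lp_rd) * (t - u) ** rd.alpha)
        return surv1 * h12 * surv2

    return _as_scalar(_integrate(integrand, s, t, n_nodes, _min_alpha(params.fr)))


def p13(
    params: IllnessDeathParams,
    s: float,
    t: float,
    profile: CovariateProfile,
    n_nodes: int = 64,
):
    """Total probability of death by t (with or without refracture) given
    the initial state at s: the complement 1 - p11 - p12."""
    return _as_scalar(
        1.0 - p11(params, s, t, profile) - p12(params, s, t, profile, n_nodes=n_nodes)
    )


def p23(
    params: IllnessDeathParams,
    s: float,
    t: float,
    profile: CovariateProfile,
    t12: float | None = None,
    clock: str = "refracture",
):
    """Probability of death after refracture by t given presence in the
    refracture state at s (complement of p22)."""
    return _as_scalar(1.0 - p22(params, s, t, profile, t12=t12, clock=clock))


def cif(
    params: IllnessDeathParams,
    t: float,
    profile: CovariateProfile,
    event: str = "FR",
    n_nodes: int = 64,
):
    """Cumulative incidence of refracture (event="FR") or death without
    refracture (event="FD") by time t: int_0^t h_1j(u) p11(0,u) du."""
    if event not in ("FR", "FD"):
        raise ValueError("event must be 'FR' or 'FD'")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    lp_fr = _lp(params, "FR", profile)
    lp_fd = _lp(params, "FD", profile)
    cause = params[event]
    lp_cause = lp_fr if event == "FR" else lp_fd
    fr, fd = params.fr, params.fd

    def integrand(u):
        h = cause.alpha * cause.lam * u ** (cause.alpha - 1.0) * np.exp(lp_cause)
        surv = np.exp(-_delta_H(fr, lp_fr, 0.0, u) - _delta_H(fd, lp_fd, 0.0, u))
        return h * surv

    return _as_scalar(_integrate(integrand, 0.0, t, n_nodes, _min_alpha(fr, fd)))


def evaluate(params: IllnessDeathParams, query: ProbabilityQuery, n_nodes: int = 64):
    """Dispatch a :class:`ProbabilityQuery` to the matching functional."""
    q = query
    if q.kind == "p11":
        return p11(params, q.s, q.t, q.profile)
    if q.kind == "p12":
        return p12(params, q.s, q.t, q.profile, n_nodes=n_nodes)
    if q.kind == "p13":
        return p13(params, q.s, q.t, q.profile, n_nodes=n_nodes)
    if q.kind == "p22":
        return p22(params, q.s, q.t, q.profile, t12=q.t12, clock=q.clock)
    if q.kind == "p23":
        return p23(params, q.s, q.t, q.profile, t12=q.t12, clock=q.clock)
    if q.kind == "cif_FR":
        return cif(params, q.t, q.profile, event="FR", n_nodes=n_nodes)
    return cif(params, q.t, q.profile, event="FD", n_nodes=n_nodes)


# -- posterior propagation ---------------------------------------------------


def _resolve_draw_params(post_or_params) -> tuple[IllnessDeathParams, bool]:
    """Accept either an IllnessDeathParams (plug-in) or a ModelPosterior."""
    if isinstance(post_or_params, IllnessDeathParams):
        return post_or_params, False
    return post_or_params.draw_params(), True


def posterior_curve(
    post,
    query: ProbabilityQuery,
    grid,
    level: float = 0.95,
    n_nodes: int = 64,
) -> ProbabilityCurve:
    """Evaluate a functional at every posterior draw over a time grid and
    summarize pointwise by mean and equal-tailed credible bounds.

    ``query.t`` is ignored; the grid supplies the end times (start fixed at
    ``query.s``). Accepts a plug-in parameter set as well, in which case the
    band is degenerate (width zero).
    """
    params, is_post = _resolve_draw_params(post)
    if is_post and post.n_draws < 100:
        raise ValueError("posterior_curve needs at least 100 draws")
    grid = np.asarray(grid, dtype=float)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    mean = np.empty_like(grid)
    lower = np.empty_like(grid)
    upper = np.empty_like(grid)
    for i, t in enumerate(grid):
        t_eff = max(float(t), query.s)
        vals = np.atleast_1d(evaluate(params, replace(query, t=t_eff), n_nodes=n_nodes))
        mean[i] = vals.mean()
        lower[i] = np.quantile(vals, lo_q)
        upper[i] = np.quantile(vals, hi_q)
    return ProbabilityCurve(query=query, grid=grid, mean=mean, lower=lower, upper=upper, level=level)


DEFAULT_AGES = (70.0, 80.0, 90.0)


def mortality_table(
    post_or_params,
    ages=DEFAULT_AGES,
    horizon: float = 1.0,
    conditioning=(0.0,),
    level: float = 0.95,
    n_nodes: int = 64,
) -> pd.DataFrame:
    """Incidence/probability table over sex x age profiles, in percent.

    Rows: cumulative incidence of refracture (F->R) and of death without
    refracture (F->D) over ``(0, horizon]``, and the probability of death
    after refracture (R->D, refracture clock) over ``(c, c + horizon]`` for
    each conditioning time ``c`` (c = 0 is the unconditioned case).

    With a posterior, point estimates are posterior means with equal-tailed
    credible bounds; with a plug-in parameter set only the estimate column
    is filled.
    """
    params, is_post = _resolve_draw_params(post_or_params)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for sex in (SEX_WOMAN, SEX_MAN):
        for age in ages:
            profile = CovariateProfile(sex, float(age))
            cells = [("F->R", 0.0, cif(params, horizon, profile, "FR", n_nodes=n_nodes)),
                     ("F->D", 0.0, cif(params, horizon, profile, "FD", n_nodes=n_nodes))]
            for c in conditioning:
                cells.append(
                    ("R->D", float(c), p23(params, float(c), float(c) + horizon, profile))
                )
            for quantity, c, val in cells:
                vals = np.atleast_1d(val)
                row = {
                    "quantity": quantity,
                    "sex": sex,
                    "age": float(age),
                    "conditioned_on": c,
                    "horizon": horizon,
                    "estimate_pct": 100.0 * float(np.mean(vals)),
                }
                if is_post:
                    row["lower_pct"] = 100.0 * float(np.quantile(vals, lo_q))
                    row["upper_pct"] = 100.0 * float(np.quantile(vals, hi_q))
                rows.append(row)
    return pd.DataFrame(rows)
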
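"""Scikit-learn-style estimator for the Bayesian Weibull illness-death model.

`BayesianIllnessDeathModel` wraps posterior sampling (fit) and probability
prediction (predict_*) behind the familiar estimator interface so it
composes with sklearn tooling (clone, get_params/set_params). The "X" it
fits is a cohort table -- a :class:`~illnessdeath.datamodel.Cohort` or a
DataFrame in the canonical cohort layout -- rather than a feature matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import Cohort, CovariateProfile, cohort_from_frame
from .inference import (
    MCMCSettings,
    PriorSpec,
    convergence_diagnostics,
    sample_posterior,
    summarize_posterior,
)
from .likelihood import loglik_model
from .probabilities import ProbabilityQuery, evaluate, mortality_table, posterior_curve


class BayesianIllnessDeathModel(BaseEstimator):
    """Three-state illness-death model with Weibull PH intensities, fitted
    by adaptive-Metropolis MCMC.

    Parameters
    ----------
    beta_mean, beta_sd : float
        Normal prior on regression coefficients.
    gamma_shape, gamma_rate : float
        Gamma prior (shape/rate) on Weibull shape and scale parameters.
    chains, iterations, burn_in, thin : int
        MCMC configuration (iterations counts retained, per chain, before
        thinning).
    seed : int
        Mandatory random seed.
    include_t12 : bool
        Add the refracture time as a covariate on the R->D transition
        (homogeneity check for the clock-reset assumption).

    Attributes
    ----------
    posterior_ : ModelPosterior
        Retained draws of all parameters.
    age_center_ : float
        Age-centering constant of the training cohort (used by every
        prediction).
    params_ : IllnessDeathParams
        Plug-in parameter set at the posterior means.
    summary_ : DataFrame
        Posterior mean/sd/quantiles per parameter.
    diagnostics_ : DataFrame
        Split-R-hat and effective sample size per parameter.
    """

    def __init__(
        self,
        beta_mean: float = 0.0,
        beta_sd: float = 100.0,
        gamma_shape: float = 0.01,
        gamma_rate: float = 0.01,
        chains: int = 3,
        iterations: int = 10000,
        burn_in: int = 5000,
        thin: int = 1,
        seed: int | None = None,
        include_t12: bool = False,
    ):
        self.beta_mean = beta_mean
        self.beta_sd = beta_sd
        self.gamma_shape = gamma_shape
        self.gamma_rate = gamma_rate
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.include_t12 = include_t12

    def _as_cohort(self, X) -> Cohort:
        if isinstance(X, Cohort):
            return X
        if isinstance(X, pd.DataFrame):
            return cohort_from_frame(X)
        raise TypeError("X must be a Cohort or a DataFrame in cohort layout")

    def fit(self, X, y=None):
        """Sample the posterior from a cohort. ``y`` is ignored (the outcome
        is part of the trajectory table)."""
        cohort = self._as_cohort(X)
        priors = PriorSpec(
            beta_mean=self.beta_mean,
            beta_sd=self.beta_sd,
            gamma_shape=self.gamma_shape,
            gamma_rate=self.gamma_rate,
        )
        settings = MCMCSettings(
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )
        self.posterior_ = sample_posterior(
            cohort, priors=priors, settings=settings, include_t12=self.include_t12
        )
        self.age_center_ = cohort.age_center
        self.params_ = self.posterior_.mean_params()
        self.summary_ = summarize_posterior(self.posterior_)
        if self.chains >= 2:
            self.diagnostics_ = convergence_diagnostics(self.posterior_)
        return self

    def predict_transition_probability(
        self,
        kind: str,
        s: float,
        t: float,
        profile: CovariateProfile,
        t12: float | None = None,
        clock: str = "refracture",
        level: float | None = None,
    ):
        """Posterior mean of a transition probability / cumulative incidence;
        with ``level`` given, returns (mean, lower, upper)."""
        check_is_fitted(self, "posterior_")
        q = ProbabilityQuery(kind=kind, s=s, t=t, profile=profile, t12=t12, clock=clock)
        vals = np.atleast_1d(evaluate(self.posterior_.draw_params(), q))
        if level is None:
            return float(vals.mean())
        lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(vals.mean()), float(lo), float(hi)

    def predict_curve(self, kind, s, grid, profile, t12=None, clock="refracture", level=0.95):
        """Posterior mean curve with credible band over a time grid."""
        check_is_fitted(self, "posterior_")
        q = ProbabilityQuery(
            kind=kind, s=s, t=max(float(np.max(grid)), s), profile=profile, t12=t12, clock=clock
        )
        return posterior_curve(self.posterior_, q, grid, level=level)

    def predict_table(self, ages=(70.0, 80.0, 90.0), horizon=1.0, conditioning=(0.0,), level=0.95):
        """Incidence/probability table over sex x age profiles (percent)."""
        check_is_fitted(self, "posterior_")
        return mortality_table(
            self.posterior_, ages=ages, horizon=horizon, conditioning=conditioning, level=level
        )

    def score(self, X, y=None) -> float:
        """Log-likelihood of a cohort at the posterior-mean parameters,
        evaluated with the training age-centering constant."""
        check_is_fitted(self, "params_")
        cohort = self._as_cohort(X)
        cohort = Cohort.from_records(cohort.records, age_center=self.age_center_)
        return loglik_model(self.params_, cohort)


def fit_illness_death(cohort, **kwargs) -> BayesianIllnessDeathModel:
    """Thin functional wrapper: fit a :class:`BayesianIllnessDeathModel`."""
    return BayesianIllnessDeathModel(**kwargs).fit(cohort)
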
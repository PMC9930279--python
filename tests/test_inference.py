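import math

import numpy as np
import pandas as pd
import pytest

from illnessdeath import (
    Cohort,
    MCMCSettings,
    ModelPosterior,
    PriorSpec,
    SubjectRecord,
    convergence_diagnostics,
    decompose,
    loglik_transition,
    sample_posterior,
    summarize_posterior,
)
from illnessdeath.hazards import WeibullPHParams
from illnessdeath.inference import log_prior_density, make_log_posterior, param_names
from illnessdeath.simulate import SimulationDesign, simulate_cohort


def make_posterior(draws_dict, chains=2):
    n = len(next(iter(draws_dict.values())))
    df = pd.DataFrame(draws_dict)
    df["chain"] = np.repeat(np.arange(chains), n // chains)
    return ModelPosterior(draws=df, age_center=83.4)


def iid_posterior(rng, n=4000, loc=0.0):
    cols = {}
    for name in param_names():
        if name.startswith(("alpha", "lam")):
            cols[name] = np.exp(rng.normal(loc, 0.1, n))
        else:
            cols[name] = rng.normal(loc, 1.0, n)
    return cols


class TestTargetDensity:
    def test_log_posterior_is_loglik_plus_log_prior(self, small_cohort):
        """The MCMC target must decompose exactly into the transition
        log-likelihood, the prior log-density and the log-Jacobian of the
        log transform (up to the prior's normalizing constant)."""
        priors = PriorSpec()
        data = decompose(small_cohort)["FD"]
        f = make_log_posterior(data, small_cohort.age_center, priors)
        for theta in ([0.1, -0.5, 0.2, 0.05], [-0.3, 0.4, -1.0, 0.01]):
            theta = np.asarray(theta)
            p = WeibullPHParams(
                "FD", alpha=math.exp(theta[0]), lam=math.exp(theta[1]),
                beta_wo=theta[2], beta_age=theta[3],
            )
            expected = (
                loglik_transition(p, data, small_cohort.age_center)
                + log_prior_density(p, priors)
                + theta[0] + theta[1]
            )
            # both sides drop/keep constants consistently: compare differences
            theta2 = theta + 0.05
            p2 = WeibullPHParams(
                "FD", alpha=math.exp(theta2[0]), lam=math.exp(theta2[1]),
                beta_wo=theta2[2], beta_age=theta2[3],
            )
            expected2 = (
                loglik_transition(p2, data, small_cohort.age_center)
                + log_prior_density(p2, priors)
                + theta2[0] + theta2[1]
            )
            assert f(theta) - f(theta2) == pytest.approx(expected - expected2, abs=1e-9)


class TestSampler:
    def test_seed_determinism(self):
        coh = simulate_cohort(SimulationDesign(n=400, seed=3))
        settings = MCMCSettings(chains=2, iterations=300, burn_in=200, seed=5)
        a = sample_posterior(coh, settings=settings)
        b = sample_posterior(coh, settings=settings)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_zero_event_transition_fails_with_named_transition(self):
        recs = [
            SubjectRecord(id=str(i), sex="man", age=80, t_terminal=1.0 + i / 10, died=i % 2 == 0)
            for i in range(20)
        ]
        coh = Cohort.from_records(recs)  # nobody refractures
        with pytest.raises(ValueError, match="RD"):
            sample_posterior(coh, settings=MCMCSettings(seed=1))

    def test_seed_mandatory(self):
        coh = simulate_cohort(SimulationDesign(n=50, seed=3))
        with pytest.raises(ValueError, match="seed"):
            sample_posterior(coh, settings=MCMCSettings())

    def test_exponential_rate_recovery(self):
        """Covariate-free data simulated from exponential hazards: the
        posterior mean of each lam should sit near events/exposure (the
        conjugate-style point estimate) under vague priors."""
        params = __import__("illnessdeath").IllnessDeathParams(
            fr=WeibullPHParams("FR", 1.0, 0.05, 0.0, 0.0),
            fd=WeibullPHParams("FD", 1.0, 0.25, 0.0, 0.0),
            rd=WeibullPHParams("RD", 1.0, 0.50, 0.0, 0.0),
            age_center=83.4,
        )
        design = SimulationDesign(
            n=3000, params=params, p_woman=0.0, age_normal=(83.4, 0.0), seed=21
        )
        coh = simulate_cohort(design)
        post = sample_posterior(
            coh, settings=MCMCSettings(chains=2, iterations=2000, burn_in=1500, seed=8)
        )
        data = decompose(coh)
        for tr, col in (("FR", "lam_FR"), ("FD", "lam_FD")):
            rate = data[tr].n_events / data[tr].time.sum()
            assert post.draws[col].mean() == pytest.approx(rate, rel=0.1)


class TestSummaries:
    def test_constant_draws(self):
        post = make_posterior({name: np.full(200, 2.0) for name in param_names()})
        s = summarize_posterior(post)
        assert (s["sd"] == 0).all() and (s["mean"] == 2.0).all()

    def test_standard_normal_moments(self):
        rng = np.random.default_rng(0)
        post = make_posterior(iid_posterior(rng, n=100_000))
        s = summarize_posterior(post)
        betas = [n for n in param_names() if n.startswith("beta")]
        assert np.allclose(s.loc[betas, "mean"], 0.0, atol=0.02)
        assert np.allclose(s.loc[betas, "sd"], 1.0, atol=0.02)

    def test_too_few_draws_rejected(self):
        post = make_posterior({name: np.ones(50) for name in param_names()})
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(post)

    def test_table_shape(self):
        post = make_posterior({name: np.random.default_rng(1).normal(1.5, 0.1, 500) + 1 for name in param_names()})
        s = summarize_posterior(post)
        assert s.shape[0] == 12 and {"mean", "sd"} <= set(s.columns)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(2)
        half = iid_posterior(rng, n=1000)
        post = make_posterior({k: np.concatenate([v, v]) for k, v in half.items()})
        d = convergence_diagnostics(post)
        assert np.allclose(d["rhat"], 1.0, atol=0.01)
        assert not d["flagged"].any()

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(3)
        a = iid_posterior(rng, n=1000)
        b = iid_posterior(rng, n=1000, loc=3.0)
        post = make_posterior({k: np.concatenate([a[k], b[k]]) for k in a})
        assert convergence_diagnostics(post)["flagged"].all()

    def test_ess_of_iid_draws_near_draw_count(self):
        rng = np.random.default_rng(4)
        post = make_posterior(iid_posterior(rng, n=4000))
        d = convergence_diagnostics(post)
        assert ((d["ess"] > 0.8 * 4000) & (d["ess"] < 1.25 * 4000)).all()

    def test_single_chain_rejected(self):
        post = make_posterior({name: np.ones(100) * 2 for name in param_names()}, chains=1)
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics(post)


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(beta_sd=0)
    with pytest.raises(ValueError):
        PriorSpec(gamma_rate=-1)
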
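import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from illnessdeath import (
    CovariateProfile,
    IllnessDeathParams,
    ProbabilityQuery,
    WeibullPHParams,
    cif,
    evaluate,
    mortality_table,
    p11,
    p12,
    p13,
    p22,
    p23,
    posterior_curve,
)

W70 = CovariateProfile("woman", 70)
W80 = CovariateProfile("woman", 80)
M70 = CovariateProfile("man", 70)
M80 = CovariateProfile("man", 80)
M90 = CovariateProfile("man", 90)


def exp_model(l_fr=0.1, l_fd=0.3, l_rd=0.6):
    """All-exponential special case with closed-form probabilities."""
    return IllnessDeathParams(
        fr=WeibullPHParams("FR", 1.0, l_fr, 0.0, 0.0),
        fd=WeibullPHParams("FD", 1.0, l_fd, 0.0, 0.0),
        rd=WeibullPHParams("RD", 1.0, l_rd, 0.0, 0.0),
        age_center=83.4,
    )


@st.composite
def random_weibull_model(draw):
    def tr(name):
        return WeibullPHParams(
            name,
            alpha=draw(st.floats(0.4, 2.5)),
            lam=draw(st.floats(0.02, 1.0)),
            beta_wo=draw(st.floats(-0.8, 0.8)),
            beta_age=draw(st.floats(-0.1, 0.1)),
        )

    return IllnessDeathParams(fr=tr("FR"), fd=tr("FD"), rd=tr("RD"), age_center=83.4)


class TestEventFree:
    def test_identity_at_s_equals_t(self, ref_params):
        assert p11(ref_params, 2.0, 2.0, W80) == 1.0

    def test_five_year_event_free_by_sex(self, ref_params):
        # published five-year event-free probabilities at age 80
        assert p11(ref_params, 0, 5, W80) == pytest.approx(0.5169, abs=0.002)
        assert p11(ref_params, 0, 5, M80) == pytest.approx(0.3612, abs=0.002)

    def test_s_after_t_rejected(self, ref_params):
        with pytest.raises(ValueError):
            p11(ref_params, 2.0, 1.0, W80)

    def test_monotone_nonincreasing_in_t(self, ref_params):
        grid = np.linspace(0, 10, 41)
        vals = [p11(ref_params, 0, t, M90) for t in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestRefractureState:
    def test_one_year_death_after_refracture(self, ref_params):
        assert p23(ref_params, 0, 1, W70) == pytest.approx(0.1481, abs=0.001)
        assert p22(ref_params, 0, 1, W70) == pytest.approx(1 - 0.1481, abs=0.001)

    def test_exponential_closed_form(self):
        m = exp_model()
        assert p22(m, 0.5, 2.0, W80) == pytest.approx(np.exp(-0.6 * 1.5), rel=1e-12)

    def test_semi_markov_depends_only_on_elapsed_time(self, ref_params):
        # without beta_t12, fracture-clock results depend on t12 only via t - t12
        a = p22(ref_params, 2.0, 3.0, W80, t12=2.0, clock="fracture")
        b = p22(ref_params, 5.0, 6.0, W80, t12=5.0, clock="fracture")
        assert a == pytest.approx(b, rel=1e-12)
        assert a == pytest.approx(p22(ref_params, 0.0, 1.0, W80), rel=1e-12)

    def test_conditioned_probability_one_year_survivors(self, ref_params):
        assert p23(ref_params, 1, 2, W70) == pytest.approx(0.0830, abs=0.001)

    def test_conditioning_reduces_risk(self, ref_params):
        """With a decreasing R->D baseline hazard (alpha < 1), the longer a
        patient survives after refracture the smaller the one-year risk."""
        risks = [p23(ref_params, k, k + 1.0, M80) for k in (0.0, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(risks, risks[1:]))

    def test_fracture_clock_requires_valid_s(self, ref_params):
        with pytest.raises(ValueError, match="t12"):
            p22(ref_params, 1.0, 2.0, W80, t12=1.5, clock="fracture")


class TestOccupancyAndDeath:
    def test_one_year_refracture_state_occupancy(self, ref_params):
        assert p12(ref_params, 0, 1, W80) == pytest.approx(0.0202, abs=0.001)
        assert p12(ref_params, 0, 1, M80) == pytest.approx(0.0162, abs=0.001)

    def test_vanishing_refracture_hazard(self):
        m = exp_model(l_fr=1e-12)
        assert p12(m, 0, 3, W80) == pytest.approx(0.0, abs=1e-10)

    def test_zero_width_interval(self, ref_params):
        assert p12(ref_params, 1.0, 1.0, W80) == 0.0

    def test_total_death_probability(self, ref_params):
        assert p13(ref_params, 0, 1, W70) == pytest.approx(0.0755, abs=0.001)
        assert p13(ref_params, 0, 1, M70) == pytest.approx(0.1227, abs=0.002)

    def test_exponential_closed_form_p12(self):
        l1, l2, l3 = 0.1, 0.3, 0.6
        m = exp_model(l1, l2, l3)
        a, t = l1 + l2, 2.0
        expected = l1 * np.exp(-l3 * t) * (np.exp((l3 - a) * t) - 1) / (l3 - a)
        assert p12(m, 0, t, M80) == pytest.approx(expected, rel=1e-9)


class TestCumulativeIncidence:
    def test_zero_at_origin(self, ref_params):
        assert cif(ref_params, 0.0, W70, "FR") == 0.0

    def test_published_one_year_values(self, ref_params):
        assert cif(ref_params, 1, W70, "FR") == pytest.approx(0.0196, abs=5e-4)
        assert cif(ref_params, 1, M90, "FD") == pytest.approx(0.4034, abs=1e-3)

    def test_exponential_closed_form(self):
        l1, l2 = 0.1, 0.3
        m = exp_model(l1, l2)
        t = 2.5
        expected = l1 / (l1 + l2) * (1 - np.exp(-(l1 + l2) * t))
        assert cif(m, t, W80, "FR") == pytest.approx(expected, rel=1e-9)

    def test_monotone_nondecreasing(self, ref_params):
        vals = [cif(ref_params, t, M80, "FD") for t in np.linspace(0, 8, 33)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    @given(model=random_weibull_model(), t=st.floats(0.2, 8.0))
    def test_accounting_identity(self, model, t):
        """cif_FR + cif_FD + p11 must exhaust probability at any horizon."""
        total = (
            cif(model, t, W80, "FR") + cif(model, t, W80, "FD") + p11(model, 0, t, W80)
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestConservation:
    @given(model=random_weibull_model(), t=st.floats(0.1, 9.0), s=st.floats(0.0, 2.0))
    def test_rows_sum_to_one(self, model, s, t):
        if s > t:
            s, t = t, s
        for prof in (W70, M90):
            total = p11(model, s, t, prof) + p12(model, s, t, prof) + p13(model, s, t, prof)
            assert total == pytest.approx(1.0, abs=1e-9)
            assert p22(model, s, t, prof) + p23(model, s, t, prof) == pytest.approx(1.0)

    def test_quadrature_self_consistency(self, ref_params):
        # 64-node result already converged: refining changes nothing material
        a = p12(ref_params, 0, 5, W80, n_nodes=64)
        b = p12(ref_params, 0, 5, W80, n_nodes=256)
        assert a == pytest.approx(b, abs=1e-6)


class TestPosteriorPropagation:
    def _degenerate_posterior(self, ref_params, n=200):
        from illnessdeath.inference import ModelPosterior, param_names

        row = {}
        for tr in ("FR", "FD", "RD"):
            p = ref_params[tr]
            row[f"alpha_{tr}"] = p.alpha
            row[f"lam_{tr}"] = p.lam
            row[f"beta_wo_{tr}"] = p.beta_wo
            row[f"beta_age_{tr}"] = p.beta_age
        df = pd.DataFrame({k: np.full(n, v) for k, v in row.items()})
        df["chain"] = np.repeat([0, 1], n // 2)
        return ModelPosterior(draws=df, age_center=ref_params.age_center)

    def test_degenerate_posterior_zero_width_band(self, ref_params):
        post = self._degenerate_posterior(ref_params)
        q = ProbabilityQuery("p11", 0.0, 5.0, W80)
        curve = posterior_curve(post, q, grid=np.linspace(0, 5, 11))
        assert np.allclose(curve.upper - curve.lower, 0.0)
        assert curve.mean[-1] == pytest.approx(p11(ref_params, 0, 5, W80), rel=1e-12)

    def test_conservation_per_draw(self, ref_params):
        post = self._degenerate_posterior(ref_params)
        dp = post.draw_params()
        tot = (
            np.atleast_1d(p11(dp, 0, 2, M80))
            + np.atleast_1d(p12(dp, 0, 2, M80))
            + np.atleast_1d(p13(dp, 0, 2, M80))
        )
        assert np.allclose(tot, 1.0, atol=1e-9)

    def test_curve_invariants(self, ref_params):
        rng = np.random.default_rng(6)
        from illnessdeath.inference import ModelPosterior

        base = self._degenerate_posterior(ref_params).draws
        jitter = base.copy()
        for c in jitter.columns:
            if c == "chain":
                continue
            jitter[c] = jitter[c] * np.exp(rng.normal(0, 0.02, len(jitter)))
        post = ModelPosterior(draws=jitter, age_center=ref_params.age_center)
        q = ProbabilityQuery("cif_FD", 0.0, 5.0, M90)
        curve = posterior_curve(post, q, grid=np.linspace(0, 5, 21))
        assert np.all(curve.lower <= curve.mean + 1e-12)
        assert np.all(curve.mean <= curve.upper + 1e-12)
        assert np.all((curve.lower >= 0) & (curve.upper <= 1))


class TestMortalityTable:
    def test_one_year_death_after_refracture_cells(self, ref_params):
        """Six sex-by-age cells of the published one-year table for the
        refracture-to-death transition (plug-in evaluation, percent)."""
        tbl = mortality_table(ref_params, horizon=1.0)
        rd = tbl[tbl["quantity"] == "R->D"].set_index(["sex", "age"])["estimate_pct"]
        published = {
            ("woman", 70.0): 14.81, ("woman", 80.0): 23.15, ("woman", 90.0): 35.16,
            ("man", 70.0): 25.50, ("man", 80.0): 38.49, ("man", 90.0): 55.04,
        }
        for key, val in published.items():
            assert rd[key] == pytest.approx(val, abs=0.15)

    def test_zero_horizon_all_zero(self, ref_params):
        tbl = mortality_table(ref_params, horizon=0.0)
        assert np.allclose(tbl["estimate_pct"], 0.0)

    def test_conditioned_cell(self, ref_params):
        tbl = mortality_table(ref_params, horizon=1.0, conditioning=(0.0, 1.0))
        cell = tbl[
            (tbl["quantity"] == "R->D")
            & (tbl["sex"] == "woman")
            & (tbl["age"] == 90.0)
            & (tbl["conditioned_on"] == 1.0)
        ]["estimate_pct"].iloc[0]
        assert cell == pytest.approx(20.88, abs=0.2)

    def test_layout(self, ref_params):
        tbl = mortality_table(ref_params, horizon=1.0)
        assert len(tbl) == 18  # 3 quantities x 2 sexes x 3 ages
        assert set(tbl["quantity"]) == {"F->R", "F->D", "R->D"}
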
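"""Latent-phase Poisson age model: likelihood, fitting, LRT, scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strdnm.age_model import (
    InvalidMeanError,
    fit_age_model,
    loglik,
    lrt_age_effect,
    predict_genomewide,
    scale_to_genomewide,
)
from strdnm.simulate import SimConfig, simulate_trio_counts


def make_data(y_p, y_m, y_u, father_age=None, mother_age=None, m_t=None):
    n = len(y_p)
    return pd.DataFrame(
        {
            "y_p": y_p,
            "y_m": y_m,
            "y_u": y_u,
            "father_age": father_age if father_age is not None else [30.0] * n,
            "mother_age": mother_age if mother_age is not None else [28.0] * n,
            **({"m_t": m_t} if m_t is not None else {}),
        }
    )


class TestLoglik:
    def test_two_term_latent_sum_hand_value(self):
        # one trio, y_P=1, y_M=0, y_U=1, both means 1:
        # log[f(1;1)f(1;1) + f(2;1)f(0;1)] = log(1.5 e^-2)
        d = make_data([1], [0], [1])
        assert loglik([1.0, 0.0, 1.0, 0.0], d) == pytest.approx(
            np.log(np.exp(-2) + 0.5 * np.exp(-2)), rel=1e-12
        )

    def test_brute_force_enumeration_of_latent_sum(self):
        # direct evaluation of the printed sum on small counts
        rng = np.random.default_rng(0)
        d = make_data([2], [1], [3], father_age=[35.0], mother_age=[31.0])
        params = [2.0, 0.05, 1.0, 0.02]
        mu_p = 2.0 + 0.05 * 35.0
        mu_m = 1.0 + 0.02 * 31.0
        y_t = 6
        total = sum(
            stats.poisson.pmf(k, mu_p) * stats.poisson.pmf(y_t - k, mu_m)
            for k in range(2, 2 + 3 + 1)
        )
        assert loglik(params, d) == pytest.approx(np.log(total), rel=1e-12)

    def test_zero_count_trio_contributes_zero_mass_term(self):
        base = make_data([3, 1], [1, 0], [0, 2])
        extra = make_data([3, 1, 0], [1, 0, 0], [0, 2, 0])
        params = [2.0, 0.0, 1.0, 0.0]
        assert loglik(params, extra) == pytest.approx(loglik(params, base) - 2.0 - 1.0)

    def test_fully_phased_reduces_to_independent_poissons(self):
        rng = np.random.default_rng(1)
        y_p = rng.poisson(8, size=50)
        y_m = rng.poisson(3, size=50)
        ages_f = rng.uniform(20, 45, size=50)
        ages_m = rng.uniform(20, 45, size=50)
        d = make_data(y_p, y_m, np.zeros(50, dtype=int), ages_f, ages_m)
        params = np.array([4.0, 0.15, 1.2, 0.05])
        mu_p = params[0] + params[1] * ages_f
        mu_m = params[2] + params[3] * ages_m
        direct = stats.poisson.logpmf(y_p, mu_p).sum() + stats.poisson.logpmf(y_m, mu_m).sum()
        assert loglik(params, d) == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_mean_is_signalled(self):
        d = make_data([1], [1], [0])
        with pytest.raises(InvalidMeanError):
            loglik([-100.0, 0.1, 1.0, 0.0], d)

    def test_equal_availability_makes_exposure_irrelevant(self):
        d = make_data([3, 2], [1, 1], [1, 0], [25.0, 40.0], [22.0, 38.0], m_t=[500, 500])
        params = [3.0, 0.1, 1.0, 0.03]
        assert loglik(params, d, use_exposure=True) == pytest.approx(
            loglik(params, d, use_exposure=False)
        )


class TestFit:
    def test_recovers_generating_parameters(self):
        cfg = SimConfig()
        rng = np.random.default_rng(5)
        data = simulate_trio_counts(cfg, 3000, rng)
        fit = fit_age_model(data)
        assert fit.params["beta_p"] == pytest.approx(cfg.beta_p, abs=0.035)
        assert fit.params["beta_m"] == pytest.approx(cfg.beta_m, abs=0.03)
        assert fit.params["alpha_p"] == pytest.approx(cfg.alpha_p, abs=1.2)

    def test_matches_identity_link_glm_when_fully_phased(self):
        import statsmodels.api as sm

        cfg = SimConfig()
        rng = np.random.default_rng(6)
        data = simulate_trio_counts(cfg, 2000, rng, phased_fraction=1.0)
        data["m_t"] = 100  # equal availability: exposure becomes unity
        fit = fit_age_model(data)
        ident = sm.families.Poisson(link=sm.families.links.Identity())
        Xf = sm.add_constant(data["father_age"])
        Xm = sm.add_constant(data["mother_age"])
        gp = sm.GLM(data["y_p"], Xf, family=ident).fit()
        gm = sm.GLM(data["y_m"], Xm, family=ident).fit()
        assert fit.params["beta_p"] == pytest.approx(gp.params["father_age"], abs=1e-3)
        assert fit.params["beta_m"] == pytest.approx(gm.params["mother_age"], abs=1e-3)
        assert fit.loglik == pytest.approx(gp.llf + gm.llf, rel=1e-8)

    def test_identifiability_guard(self):
        d = make_data([1, 2], [0, 1], [0, 0], [30.0, 30.0], [28.0, 28.0])
        with pytest.raises(ValueError):
            fit_age_model(d)

    def test_more_paternal_calls_shift_paternal_mean_up(self):
        cfg = SimConfig()
        rng = np.random.default_rng(7)
        data = simulate_trio_counts(cfg, 800, rng)
        bumped = data.copy()
        bumped["y_p"] = bumped["y_p"] + 2
        f0 = fit_age_model(data)
        f1 = fit_age_model(bumped)
        mean_age = data["father_age"].mean()
        m0 = f0.params["alpha_p"] + f0.params["beta_p"] * mean_age
        m1 = f1.params["alpha_p"] + f1.params["beta_p"] * mean_age
        assert m1 > m0

    def test_weighted_variant_differs_with_unphased_events(self):
        d = make_data([1, 2], [0, 1], [2, 1], [25.0, 40.0], [24.0, 36.0])
        params = [2.0, 0.05, 1.0, 0.02]
        assert loglik(params, d, weighted=True) > loglik(params, d, weighted=False)


class TestLrt:
    def test_strong_effect_detected(self):
        cfg = SimConfig()
        rng = np.random.default_rng(8)
        data = simulate_trio_counts(cfg, 1500, rng)
        stat, p = lrt_age_effect(data, "p")
        assert stat > 0
        assert p < 1e-6

    def test_zero_statistic_gives_p_one(self):
        # chi-square tail at 0 is exactly 1 (identical full and nested fits)
        assert stats.chi2.sf(0.0, df=1) == 1.0

    def test_invalid_parent_label(self):
        with pytest.raises(ValueError):
            lrt_age_effect(make_data([1], [1], [0]), "x")


class TestGenomewideScaling:
    def test_cohort_scale_factor(self):
        # 0.178 events/yr at 256,066 of 1,394,292 markers ~ 0.97 genome-wide
        assert scale_to_genomewide(0.178, 256_066) == pytest.approx(0.97, abs=0.005)
        assert scale_to_genomewide(0.058, 256_066) == pytest.approx(0.316, abs=0.005)

    def test_edge_cases(self):
        assert scale_to_genomewide(0.0, 1000.0) == 0.0
        assert scale_to_genomewide(0.5, 1_394_292) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            scale_to_genomewide(1.0, 0.0)

    def test_prediction_grows_by_genomewide_slope(self):
        params = {"alpha_p": 2.996, "beta_p": 0.178, "alpha_m": 1.69, "beta_m": 0.058}
        p20 = predict_genomewide(params, 20, 20, mbar=256_066)
        p40 = predict_genomewide(params, 40, 40, mbar=256_066)
        assert p20["paternal"] == pytest.approx(35.7, abs=0.3)
        assert p40["paternal"] == pytest.approx(55.1, abs=0.3)
        assert p40["paternal"] - p20["paternal"] == pytest.approx(20 * 0.97, abs=0.15)

    def test_flat_model_predicts_constant(self):
        params = {"alpha_p": 5.0, "beta_p": 0.0, "alpha_m": 2.0, "beta_m": 0.0}
        a = predict_genomewide(params, 20, 20, mbar=1_394_292)
        b = predict_genomewide(params, 45, 45, mbar=1_394_292)
        assert a["total"] == pytest.approx(b["total"])

    def test_prediction_at_mean_age_matches_mean_fitted_value(self):
        cfg = SimConfig()
        rng = np.random.default_rng(9)
        data = simulate_trio_counts(cfg, 1500, rng, phased_fraction=1.0)
        data["m_t"] = 1  # equal availability
        fit = fit_age_model(data)
        pred = predict_genomewide(fit, data["father_age"].mean(), data["mother_age"].mean())
        scale = 1_394_292 / fit.mbar
        fitted_mean = (
            fit.params["alpha_p"]
            + fit.params["beta_p"] * data["father_age"]
            + fit.params["alpha_m"]
            + fit.params["beta_m"] * data["mother_age"]
        ).mean() * scale
        assert pred["total"] == pytest.approx(fitted_mean, rel=1e-9)
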
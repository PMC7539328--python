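"""Drift-null S, population-wise S and H* selection tests."""

import numpy as np
import pandas as pd
import pytest

import driftgarden as dg
from driftgarden.divergence import (
    DivergenceResult, correlate_population_values, divergence_pca,
    fit_divergence_model, h_star_test, population_s_test, s_test,
    standardized_divergence,
)


def _synthetic_result(alpha_draws, mu=0.0, s2a=1.0, theta=None, pops=None):
    """Hand-built posterior for testing the statistics in isolation."""
    alpha_draws = np.asarray(alpha_draws, dtype=float)
    t, p = alpha_draws.shape
    theta = np.eye(p) * 0.5 if theta is None else theta
    return DivergenceResult(
        populations=pops or [f"pop{j}" for j in range(p)],
        mu=np.full((1, t), mu),
        alpha=alpha_draws[None, :, :],
        sigma2_A=np.full((1, t), s2a),
        sigma2_E=np.full((1, t), 1.0),
        theta_draws=theta[None, :, :],
        theta_idx=np.zeros(t, dtype=int),
        psrf={"mu": 1.0},
    )


class TestSTestLimits:
    def test_homogenizing_limit_is_zero(self):
        res = _synthetic_result(np.zeros((400, 6)))  # alpha identical to mu
        assert s_test(res, seed=1) == 0.0

    def test_diversifying_limit_is_one(self):
        alpha = np.tile([30.0, -30, 30, -30, 30, -30], (400, 1))
        res = _synthetic_result(alpha)
        assert s_test(res, seed=2) > 0.99

    def test_null_draws_give_half(self):
        rng = np.random.default_rng(3)
        p, t = 8, 4000
        alpha = rng.normal(size=(t, p)) * np.sqrt(2 * 1.0 * 0.5)
        res = _synthetic_result(alpha)
        assert s_test(res, seed=3) == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def planted_shift_fit():
    truth = dg.star_scenario(8, 0.05, seed=401, sigma2_A=0.4, sigma2_E=0.6)
    shift = np.zeros(8)
    shift[3] = 5 * np.sqrt(2 * 0.4 * 0.05)
    truth.pop_shifts = shift
    ped = dg.simulate_pedigree(truth, 15, 10)
    ph = dg.simulate_phenotypes(truth, ped)
    return fit_divergence_model(ph, ped, truth.theta_true, chains=2,
                                burn_in=1500, iters=1500, thin=5, seed=401)


class TestFittedModel:
    def test_planted_shift_detected_globally(self, planted_shift_fit):
        assert s_test(planted_shift_fit, seed=401) > 0.8

    def test_planted_shift_flagged_above(self, planted_shift_fit):
        flags = population_s_test(planted_shift_fit, seed=401)
        row = flags.set_index("population").loc["pop04"]
        assert row["unusual"] and row["direction"] == "above"
        assert flags["unusual"].sum() <= 2  # no mass false flagging

    def test_envelope_contains_null_predictive_median(self, planted_shift_fit):
        flags = population_s_test(planted_shift_fit, seed=401)
        mu_med = np.median(planted_shift_fit.pooled("mu"))
        assert ((flags["envelope_low"] < mu_med) & (mu_med < flags["envelope_high"])).all()

    def test_psrf_reported_for_all_monitored_scalars(self, planted_shift_fit):
        keys = set(planted_shift_fit.psrf)
        assert {"mu", "sigma2_A", "sigma2_E"} <= keys
        assert sum(k.startswith("alpha[") for k in keys) == 8

    def test_no_additive_variance_collapses_alpha(self):
        truth = dg.star_scenario(6, 0.05, seed=402, sigma2_A=0.0, sigma2_E=1.0)
        ped = dg.simulate_pedigree(truth, 12, 8)
        ph = dg.simulate_phenotypes(truth, ped)
        res = fit_divergence_model(ph, ped, truth.theta_true, chains=2,
                                   burn_in=1000, iters=1000, thin=5, seed=402)
        spread = res.pooled("alpha").std(axis=1).mean()
        assert spread < 0.15


class TestHStar:
    def test_neutral_exchangeability(self):
        rng = np.random.default_rng(5)
        p, t = 8, 2000
        theta = np.eye(p) * 0.5
        alpha = rng.normal(size=(t, p))  # matches null scale sqrt(2*1*0.5)
        res = _synthetic_result(alpha, theta=theta)
        driver = rng.normal(size=p)
        h = h_star_test(res, driver, seed=5)
        assert h["H_star"] == pytest.approx(0.5, abs=0.07)
        assert h["H"] == pytest.approx(0.5, abs=0.07)

    def test_driver_linked_selection_detected(self):
        truth = dg.study_scenario(seed=403, selection=True,
                                  driver_slope=3 * np.sqrt(2 * 0.4 * 0.05),
                                  sigma2_A=0.4, sigma2_E=0.6)
        ped = dg.simulate_pedigree(truth, 10, 8)
        ph = dg.simulate_phenotypes(truth, ped)
        res = fit_divergence_model(ph, ped, truth.theta_true, chains=2,
                                   burn_in=1200, iters=1200, thin=5, seed=403)
        h = h_star_test(res, truth.driver, seed=403)
        assert h["H_star"] > 0.9

    def test_confounded_selection_inflates_H_not_Hstar(self):
        rng = np.random.default_rng(6)
        driver = rng.normal(size=8)
        gaps = []
        for rep in range(3):
            rr = np.random.default_rng(600 + rep)
            shift = rr.choice([3.0, -3.0], size=8) * np.sqrt(2 * 0.4 * 0.05)
            truth = dg.star_scenario(8, 0.05, seed=600 + rep, sigma2_A=0.4,
                                     sigma2_E=0.6, pop_shifts=shift)
            ped = dg.simulate_pedigree(truth, 15, 10)
            ph = dg.simulate_phenotypes(truth, ped)
            res = fit_divergence_model(ph, ped, truth.theta_true, chains=2,
                                       burn_in=1000, iters=1000, thin=5,
                                       seed=600 + rep)
            h = h_star_test(res, driver, seed=600 + rep)
            gaps.append(abs(h["H"] - 0.5) - abs(h["H_star"] - 0.5))
        assert np.mean(gaps) > 0  # standardization reduces the false positive

    def test_constant_driver_rejected(self):
        res = _synthetic_result(np.zeros((10, 4)))
        with pytest.raises(ValueError, match="constant"):
            h_star_test(res, np.ones(4))


class TestDivergencePCA:
    def test_identical_trait_vectors_rank_one(self):
        z = np.random.default_rng(7).normal(size=8)
        table = pd.DataFrame({"t1": z, "t2": z})
        pca = divergence_pca(table)
        assert pca.variance_explained[0] == pytest.approx(1.0)

    def test_two_planted_complexes_separate(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        b -= (b @ a) / (a @ a) * a  # orthogonal patterns
        table = pd.DataFrame({
            "growth1": 3 * a + 0.1 * rng.normal(size=12),
            "growth2": 3 * a + 0.1 * rng.normal(size=12),
            "phen1": 3 * b + 0.1 * rng.normal(size=12),
            "phen2": 3 * b + 0.1 * rng.normal(size=12),
        })
        pca = divergence_pca(table)
        load = pca.loadings[["PC1", "PC2"]].to_numpy()
        # each complex loads together on one axis and not the other
        dominant = np.abs(load).argmax(axis=1)
        assert dominant[0] == dominant[1]
        assert dominant[2] == dominant[3]
        assert dominant[0] != dominant[2]

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError, match="2 traits"):
            divergence_pca(pd.DataFrame({"only": np.arange(5.0)}))

    def test_missing_divergence_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2, np.nan], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="missing"):
            divergence_pca(table)


class TestPopulationCorrelations:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        r, p = correlate_population_values(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_exact_anticorrelation(self):
        r, _ = correlate_population_values([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form_t_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=16)
        y = 0.5 * x + rng.normal(size=16)
        r, p = correlate_population_values(x, y)
        # independent oracle: direct formulas
        n = len(x)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        from scipy import stats as st
        tval = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
        p_direct = 2 * st.t.sf(abs(tval), df=n - 2)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, rel=1e-9)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=8), rng.normal(size=8)
        _, p_raw = correlate_population_values(x, y)
        _, p_adj = correlate_population_values(x, y, correction="bonferroni", m=31)
        assert p_adj == min(1.0, p_raw * 31)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_population_values([1, 1, 1], [1, 2, 3])


def test_standardized_divergence_shape_and_scale():
    rng = np.random.default_rng(11)
    alpha = rng.normal(size=(300, 5))
    res = _synthetic_result(alpha)
    z = standardized_divergence(res)
    assert z.shape == (300, 5)
    # alpha ~ N(0,1) with null sd sqrt(2*1*0.5)=1 -> z should be ~unit scale
    assert z.to_numpy().std() == pytest.approx(1.0, abs=0.05)
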
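"""Gibbs sampler machinery: summaries, diagnostics, model comparison, GEBVs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbreed import gblup
from microbreed.genomics import Grm
from tests.conftest import simulate_univariate_herd


class TestSummarize:
    def test_all_positive_samples_give_p0_one(self):
        s = gblup.summarize(np.abs(np.random.default_rng(0).standard_normal(500)) + 0.1)
        assert s.p0 == 1.0

    def test_symmetric_samples_give_p0_half(self):
        r = np.random.default_rng(1).standard_normal(20000)
        s = gblup.summarize(r)
        assert s.p0 == pytest.approx(0.5, abs=0.02)

    def test_normal_hpd_matches_closed_form(self):
        r = np.random.default_rng(2).standard_normal(100_000)
        s = gblup.summarize(r)
        assert s.hpd_low == pytest.approx(-1.96, abs=0.03)
        assert s.hpd_high == pytest.approx(1.96, abs=0.03)
        assert s.hpd_low < s.median < s.hpd_high

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            gblup.summarize(np.ones(50))


class TestGeweke:
    def test_iid_chain_calibration(self):
        r = np.random.default_rng(3)
        inside = sum(
            abs(gblup.geweke_z(r.standard_normal(2000))) < 2 for _ in range(1000)
        )
        assert inside >= 930

    def test_linear_trend_detected(self):
        r = np.random.default_rng(4)
        chain = r.standard_normal(2000) + np.linspace(0, 20, 2000)
        assert abs(gblup.geweke_z(chain)) > 5

    def test_identical_halves_give_zero(self):
        half = np.sin(np.arange(500)) + np.cos(np.arange(500) * 0.37)
        z = gblup.geweke_z(np.concatenate([half, half]), first=0.5, last=0.5)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_constant_chain_flagged_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(gblup.geweke_z(np.ones(500)))


class TestMcse:
    def test_iid_closed_form(self):
        r = np.random.default_rng(5)
        chain = r.standard_normal(40_000)
        mcse, ratio = gblup.mcse_timeseries(chain)
        assert mcse == pytest.approx(chain.std() / np.sqrt(len(chain)), rel=0.15)
        assert ratio == pytest.approx(np.sqrt(len(chain)), rel=0.15)

    def test_autocorrelation_inflates_mcse(self):
        r = np.random.default_rng(6)
        n = 40_000
        ar = np.empty(n)
        ar[0] = r.standard_normal()
        eps = r.standard_normal(n)
        for i in range(1, n):
            ar[i] = 0.9 * ar[i - 1] + eps[i]
        mcse, _ = gblup.mcse_timeseries(ar)
        assert mcse > 2 * ar.std() / np.sqrt(n)

    def test_thinning_scales_mcse_by_sqrt_factor(self):
        r = np.random.default_rng(7)
        chain = r.standard_normal(100_000)
        m_full, _ = gblup.mcse_timeseries(chain)
        m_thin, _ = gblup.mcse_timeseries(chain[::10])
        assert m_thin / m_full == pytest.approx(np.sqrt(10), rel=0.25)

    def test_constant_chain_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            mcse, ratio = gblup.mcse_timeseries(np.full(500, 3.0))
        assert mcse == 0.0 and np.isnan(ratio)


class TestHeritability:
    def test_per_draw_arithmetic(self):
        fit = _fake_univariate_fit(sg2=np.full(200, 1.0), se2=np.full(200, 3.0))
        h2 = gblup.h2_samples(fit)
        np.testing.assert_allclose(h2, 0.25)

    def test_zero_genomic_variance_gives_zero(self):
        fit = _fake_univariate_fit(sg2=np.zeros(200), se2=np.ones(200))
        np.testing.assert_allclose(gblup.h2_samples(fit), 0.0)

    @pytest.mark.parametrize("h2,label", [
        (0.10, "lowly heritable"),
        (0.30, "moderately heritable"),
        (0.45, "highly heritable"),
    ])
    def test_classification_bands(self, h2, label):
        assert gblup.classify_h2(h2) == label


def _fake_univariate_fit(sg2, se2, n=10):
    k = len(sg2)
    return gblup.McmcFit(
        trait_names=["y"], animal_ids=pd.Index(range(n)),
        samples={"sg2": np.asarray(sg2, float), "se2": np.asarray(se2, float),
                 "b": np.zeros((k, 1)), "g": np.zeros((k, n, 1))},
        gebv_mean=np.zeros((n, 1)), gebv_sd=np.full((n, 1), 0.1),
        deviance=np.zeros(k), deviance_at_mean=0.0,
        spec=gblup.ModelSpec(200, 0, 1), data_hash="x",
    )


class TestDeregression:
    def _grm(self, n):
        return Grm(pd.Index(range(n)), np.eye(n), 1.0)

    def test_full_reliability_is_identity(self):
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=4)
        fit.gebv_mean = np.array([[1.0], [2.0], [-1.0], [0.5]])
        fit.gebv_sd = np.zeros((4, 1))  # accuracy 1 -> reliability 1
        dg, excluded = gblup.deregress_gebv(fit, self._grm(4))
        np.testing.assert_allclose(dg.to_numpy(), [1.0, 2.0, -1.0, 0.5])
        assert excluded == []

    def test_half_reliability_doubles(self):
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=2)
        fit.gebv_mean = np.array([[2.0], [2.0]])
        # sd^2 = 0.5 -> accuracy^2 = 0.5 -> dGEBV = 2 / 0.5 = 4
        fit.gebv_sd = np.full((2, 1), np.sqrt(0.5))
        dg, _ = gblup.deregress_gebv(fit, self._grm(2))
        np.testing.assert_allclose(dg.to_numpy(), [4.0, 4.0])

    def test_deregression_never_shrinks_variance(self):
        r = np.random.default_rng(11)
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=30)
        fit.gebv_mean = r.standard_normal((30, 1))
        fit.gebv_sd = np.abs(r.uniform(0.1, 0.9, (30, 1)))
        dg, excluded = gblup.deregress_gebv(fit, self._grm(30))
        kept = fit.animal_ids.difference(pd.Index(excluded))
        base = pd.Series(fit.gebv_mean[:, 0], index=fit.animal_ids)[kept]
        assert dg.var() >= base.var()

    def test_low_reliability_excluded(self):
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=2)
        fit.gebv_sd = np.array([[0.9999], [0.1]])  # first ~ zero reliability
        dg, excluded = gblup.deregress_gebv(fit, self._grm(2), min_reliability=0.01)
        assert excluded == [0] and list(dg.index) == [1]


class TestGroupVariance:
    def test_constant_group_zero_variance(self):
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=6)
        fit.samples["g"] = np.tile(np.array([1., 1., 1., 0., 2., 4.]), (200, 1))[:, :, None]
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=fit.animal_ids)
        dists = gblup.group_genomic_variance(fit, groups)
        np.testing.assert_allclose(dists["a"], 0.0)
        np.testing.assert_allclose(dists["b"], 4.0)

    def test_scaling_group_by_two_quadruples_variance(self):
        r = np.random.default_rng(12)
        g = r.standard_normal((200, 8))
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=8)
        fit.samples["g"] = g[:, :, None]
        fit2 = _fake_univariate_fit(np.ones(200), np.ones(200), n=8)
        fit2.samples["g"] = (2 * g)[:, :, None]
        groups = pd.Series(["a"] * 8, index=fit.animal_ids)
        v1 = gblup.group_genomic_variance(fit, groups)["a"]
        v2 = gblup.group_genomic_variance(fit2, groups)["a"]
        np.testing.assert_allclose(v2, 4 * v1)

    def test_singleton_group_excluded_with_warning(self):
        fit = _fake_univariate_fit(np.ones(200), np.ones(200), n=3)
        groups = pd.Series(["a", "a", "b"], index=fit.animal_ids)
        with pytest.warns(UserWarning, match="'b'"):
            dists = gblup.group_genomic_variance(fit, groups)
        assert set(dists) == {"a"}

    def test_homogeneous_simulation_groups_overlap(self):
        y, factor, grm, truth = simulate_univariate_herd(seed=77, n=200, m=400,
                                                         h2=0.4)
        spec = gblup.ModelSpec(4000, 1000, 5, seed=1)
        fit = gblup.fit_univariate(y, spec, grm, fixed_factor=factor)
        labels = pd.Series(np.random.default_rng(0).integers(0, 4, len(y)),
                           index=y.index).astype(str)
        dists = gblup.group_genomic_variance(fit, labels)
        overlap = gblup.group_overlap_summary(dists)
        assert overlap["overlaps"].all()


class TestBayesFactorArithmetic:
    def test_prior_odds_correction(self):
        # bf_raw = 7419 and 2473 tests -> corrected 3.0 (pure arithmetic)
        assert 7419 / 2473 == pytest.approx(3.0, abs=1e-12)

    def test_model_against_itself_is_one(self):
        y, factor, grm, _ = simulate_univariate_herd(seed=5, n=150, m=300)
        fit1 = gblup.fit_univariate(y, gblup.ModelSpec(4000, 1000, 3, seed=1),
                                    grm, fixed_factor=factor)
        fit2 = gblup.fit_univariate(y, gblup.ModelSpec(4000, 1000, 3, seed=2),
                                    grm, fixed_factor=factor)
        bf, _ = gblup.bayes_factor(fit1, fit2, n_tests=1)
        assert 0.5 < bf < 2.0

    def test_conjugate_normal_mean_oracle(self):
        # y ~ N(mu, 1), flat prior on mu: marginal likelihood has closed form
        # m(y) = (2 pi)^(-(n-1)/2) n^(-1/2) exp(-0.5 * sum((y - ybar)^2))
        r = np.random.default_rng(13)
        y = r.standard_normal(40) + 0.3
        n = len(y)
        ybar = y.mean()
        log_m_true = (-0.5 * (n - 1) * np.log(2 * np.pi) - 0.5 * np.log(n)
                      - 0.5 * np.sum((y - ybar) ** 2))
        # Laplace-Metropolis with draws from the exact posterior mu | y
        k = 10_000
        mus = ybar + r.standard_normal(k) / np.sqrt(n)
        loglik = -0.5 * (n * np.log(2 * np.pi) + ((y[None, :] - mus[:, None]) ** 2).sum(axis=1))
        fit = _fake_univariate_fit(np.ones(k), np.ones(k))
        fit.theta_draws = mus[:, None]
        fit.loglik_integrated = loglik
        log_m_est = gblup._laplace_metropolis_logml(fit)
        assert log_m_est == pytest.approx(log_m_true, abs=0.1)


class TestOracleEquivalence:
    def test_fixed_variance_gibbs_matches_mme(self):
        """With variances fixed, Gibbs posterior-mean GEBVs equal the
        mixed-model-equation solution."""
        y, factor, grm, _ = simulate_univariate_herd(seed=21, n=50, m=200, h2=0.4)
        sg2, se2 = 0.4, 0.6
        spec = gblup.ModelSpec(250_000, 10_000, 25, seed=3)
        fit = gblup.fit_univariate(y, spec, grm, fixed_factor=factor,
                                   fixed_variances=(sg2, se2))
        # independent oracle: direct MME solve
        from microbreed.simulate import design_matrix_from_factor
        x = design_matrix_from_factor(factor.loc[y.index])
        gs = grm.stabilized(spec.blend)
        gi = np.linalg.inv(gs)
        lam = se2 / sg2
        n, p = len(y), x.shape[1]
        lhs = np.block([[x.T @ x, x.T], [x, np.eye(n) + gi * lam]])
        rhs = np.concatenate([x.T @ y.to_numpy(), y.to_numpy()])
        sol = np.linalg.solve(lhs, rhs)
        g_mme = sol[p:]
        assert np.abs(fit.gebv_mean[:, 0] - g_mme).max() < 1e-3

    def test_label_permutation_leaves_mme_solution_invariant(self):
        y, factor, grm, _ = simulate_univariate_herd(seed=22, n=60, m=150)
        spec = gblup.ModelSpec(120_000, 5_000, 20, seed=4)
        fit = gblup.fit_univariate(y, spec, grm, fixed_factor=factor,
                                   fixed_variances=(0.4, 0.6))
        perm = np.random.default_rng(0).permutation(len(y))
        y_p = y.iloc[perm]
        fit_p = gblup.fit_univariate(y_p, spec, grm, fixed_factor=factor.iloc[perm],
                                     fixed_variances=(0.4, 0.6))
        a = pd.Series(fit.gebv_mean[:, 0], index=fit.animal_ids)
        b = pd.Series(fit_p.gebv_mean[:, 0], index=fit_p.animal_ids)
        assert (a - b.loc[a.index]).abs().max() < 2e-3


class TestDicContracts:
    def test_mismatched_data_rejected(self):
        y, factor, grm, _ = simulate_univariate_herd(seed=30, n=120, m=200)
        spec = gblup.ModelSpec(2000, 500, 2, seed=1)
        fit1 = gblup.fit_univariate(y, spec, grm, fixed_factor=factor)
        fit2 = gblup.fit_univariate(y * 1.01, spec, grm, fixed_factor=factor)
        with pytest.raises(ValueError, match="identical data"):
            gblup.dic(fit1, fit2)

    def test_self_comparison_delta_small(self):
        y, factor, grm, _ = simulate_univariate_herd(seed=31, n=150, m=300, h2=0.4)
        spec1 = gblup.ModelSpec(30_000, 5_000, 5, seed=1)
        spec2 = gblup.ModelSpec(30_000, 5_000, 5, seed=2)
        f1 = gblup.fit_univariate(y, spec1, grm, fixed_factor=factor)
        f2 = gblup.fit_univariate(y, spec2, grm, fixed_factor=factor)
        _, _, delta = gblup.dic(f1, f2)
        assert abs(delta) < 10


class TestSpecValidation:
    def test_burn_in_must_precede_iterations(self):
        with pytest.raises(ValueError):
            gblup.ModelSpec(n_iter=100, burn_in=100)

    def test_production_settings_schedule(self):
        spec = gblup.ModelSpec.production_settings()
        assert (spec.n_iter, spec.burn_in, spec.thin) == (1_000_000, 200_000, 100)

    def test_rank_deficient_design_rejected(self):
        y, factor, grm, _ = simulate_univariate_herd(seed=33, n=50, m=100)
        x = np.ones((50, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            gblup.fit_univariate(y, gblup.ModelSpec(500, 100, 1, seed=1), grm, x=x)
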
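"""Selection theory: intensities, correlated response, bending, scenarios, panel."""

import numpy as np
import pandas as pd
import pytest

from microbreed import selection as sel


class TestSelectionIntensity:
    @pytest.mark.parametrize("p,expected", [
        (0.30, 1.1590), (0.20, 1.400), (0.10, 1.755), (0.05, 2.063), (0.01, 2.665),
    ])
    def test_printed_values(self, p, expected):
        assert sel.selection_intensity(p) == pytest.approx(expected, abs=5e-4)

    def test_selecting_everyone_gives_zero(self):
        assert sel.selection_intensity(1.0) == 0.0

    def test_out_of_range_rejected(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sel.selection_intensity(p)

    def test_monotone_decreasing_in_fraction(self):
        ps = np.linspace(0.01, 0.99, 25)
        vals = [sel.selection_intensity(p) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestCorrelatedResponse:
    def test_unit_inputs(self):
        out = sel.correlated_response(1.0, np.ones(200), np.ones(200), 1.0)
        assert out["median"] == pytest.approx(1.0)

    def test_zero_correlation_gives_zero_response(self):
        out = sel.correlated_response(1.5, np.full(200, 0.5), np.zeros(200), 2.0)
        np.testing.assert_allclose(out["samples"], 0.0)

    def test_arithmetic_oracle(self):
        out = sel.correlated_response(1.159, np.full(200, 0.5),
                                      np.full(200, -0.8), 2.0)
        assert out["median"] == pytest.approx(-0.9272, abs=1e-4)
        assert out["p0"] == 1.0

    def test_percent_of_mean_conversion(self):
        out = sel.correlated_response(1.0, np.ones(200), np.full(200, -0.5), 2.0,
                                      ch4_mean=20.0)
        assert out["percent_of_mean"] == pytest.approx(-5.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            sel.correlated_response(1.0, np.ones(100), np.ones(200), 1.0)


class TestBending:
    def test_psd_input_unchanged(self):
        m = np.array([[2.0, 0.5], [0.5, 1.0]])
        bent, log = sel.bend_matrix(m, tolerance=0.001)
        np.testing.assert_array_equal(bent, m)
        assert not log["bent"] and log["max_element_change"] == 0.0

    def test_indefinite_matrix_floored_at_tolerance(self):
        m = np.array([[1.0, 1.2], [1.2, 1.0]])  # eigenvalues -0.2, 2.2
        bent, log = sel.bend_matrix(m, tolerance=0.001)
        vals = np.linalg.eigvalsh(bent)
        assert vals.min() == pytest.approx(0.001, abs=1e-12)
        assert log["bent"]
        # flooring oracle: change is (0.001 - (-0.2)) spread over the eigenvector
        expected_change = 0.201 / 2  # rank-1 update with |v_i| = 1/sqrt(2)
        assert log["max_element_change"] == pytest.approx(expected_change, abs=1e-9)

    def test_output_symmetric_and_idempotent(self, rng):
        m = rng.standard_normal((6, 6))
        m = 0.5 * (m + m.T)
        bent, log = sel.bend_matrix(m, tolerance=0.001)
        np.testing.assert_allclose(bent, bent.T, atol=1e-12)
        again, log2 = sel.bend_matrix(bent, tolerance=0.001)
        np.testing.assert_allclose(again, bent, atol=1e-10)
        assert np.abs(bent - m).max() <= log["max_element_change"] + 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sel.bend_matrix(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestAccuracy:
    def test_zero_sd_gives_one(self):
        assert sel.accuracy(0.0, 1.0, 1.0)[0] == 1.0

    def test_sd_equal_to_prior_gives_zero(self):
        assert sel.accuracy(1.0, 1.0, 1.0)[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        assert sel.accuracy(np.sqrt(0.75), 1.0, 1.0)[0] == pytest.approx(0.5)

    def test_excess_sd_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            acc = sel.accuracy(2.0, 1.0, 1.0)
        assert acc[0] == 0.0

    def test_anti_monotone_in_sd(self, rng):
        sds = np.sort(rng.uniform(0, 1, 10))
        accs = sel.accuracy(sds, np.ones(10), 1.0)
        assert all(a >= b for a, b in zip(accs, accs[1:]))


class TestResponseToSelection:
    def _result(self, g):
        g = np.asarray(g, dtype=float)
        ids = pd.Index([f"a{i}" for i in range(g.shape[1])])
        return sel.SelectionResult(
            scenario=2, trait_names=["CH4"],
            gebv_mean=pd.Series(g.mean(axis=0), index=ids),
            gebv_sd=pd.Series(g.std(axis=0), index=ids),
            accuracies=pd.Series(np.ones(g.shape[1]), index=ids),
            gebv_samples=g,
        )

    def test_equal_gebvs_give_zero_response(self):
        res = self._result(np.ones((50, 10)))
        out = sel.response_to_selection(res, fractions=(0.2,))
        np.testing.assert_allclose(out[0.2], 0.0)

    def test_response_positive_for_nondegenerate_draws(self, rng):
        res = self._result(rng.standard_normal((100, 40)))
        out = sel.response_to_selection(res, fractions=(0.1, 0.5))
        assert (out[0.1] > 0).all() and (out[0.5] > 0).all()

    def test_fraction_selecting_none_rejected(self):
        res = self._result(np.ones((10, 5)))
        with pytest.raises(ValueError, match="selects no animals"):
            sel.response_to_selection(res, fractions=(0.01,))

    def test_breeders_equation_oracle(self, rng):
        """Truncation response on 10^5 true breeding values matches i(p)*sigma_g."""
        n = 100_000
        sigma_g = 1.7
        g = rng.standard_normal((1, n)) * sigma_g
        res = self._result(g)
        for p in (0.01, 0.10, 0.30):
            out = sel.response_to_selection(res, fractions=(p,))
            expected = sel.selection_intensity(p) * sigma_g
            assert out[p][0] == pytest.approx(expected, rel=0.05)


class TestAssembleCovariance:
    def _fake_bivariate(self, g0_med, r0_med, k=200, jitter=0.0, seed=0):
        from microbreed import gblup
        r = np.random.default_rng(seed)
        g0 = np.tile(np.asarray(g0_med, float), (k, 1, 1)) + \
            jitter * r.standard_normal((k, 2, 2))
        r0 = np.tile(np.asarray(r0_med, float), (k, 1, 1))
        return gblup.McmcFit(
            trait_names=["x", "y"], animal_ids=pd.Index(range(4)),
            samples={"G0": g0, "R0": r0, "b": np.zeros((k, 1, 2)),
                     "g": np.zeros((k, 4, 2))},
            gebv_mean=np.zeros((4, 2)), gebv_sd=np.ones((4, 2)),
            deviance=np.zeros(k), deviance_at_mean=0.0,
            spec=gblup.ModelSpec(200, 0, 1), data_hash="x",
        )

    def test_two_traits_equal_single_fit_medians(self):
        fit = self._fake_bivariate([[1.0, -0.4], [-0.4, 0.8]],
                                   [[2.0, 0.1], [0.1, 1.5]])
        cov = sel.assemble_covariance({("CH4", "geneA"): fit}, ["CH4", "geneA"])
        np.testing.assert_allclose(cov.G0, [[1.0, -0.4], [-0.4, 0.8]])
        np.testing.assert_allclose(cov.R0, [[2.0, 0.1], [0.1, 1.5]])

    def test_ch4_diagonal_is_mean_of_per_pair_medians(self):
        f1 = self._fake_bivariate([[1.0, -0.4], [-0.4, 0.8]],
                                  [[2.0, 0.0], [0.0, 1.0]])
        f2 = self._fake_bivariate([[1.4, -0.2], [-0.2, 0.9]],
                                  [[2.2, 0.0], [0.0, 1.0]])
        f3 = self._fake_bivariate([[0.8, 0.3], [0.3, 0.7]],
                                  [[1.0, 0.0], [0.0, 1.0]])
        cov = sel.assemble_covariance(
            {("CH4", "gA"): f1, ("CH4", "gB"): f2, ("gA", "gB"): f3},
            ["CH4", "gA", "gB"], ch4_trait="CH4")
        assert cov.G0[0, 0] == pytest.approx((1.0 + 1.4) / 2)
        assert cov.G0[0, 1] == pytest.approx(-0.4)
        assert cov.G0[1, 2] == pytest.approx(0.3)
        np.testing.assert_allclose(cov.G0, cov.G0.T)

    def test_missing_pair_reported(self):
        f1 = self._fake_bivariate([[1.0, 0.0], [0.0, 1.0]], np.eye(2))
        with pytest.raises(ValueError, match=r"\('gA', 'gB'\)"):
            sel.assemble_covariance({("CH4", "gA"): f1, ("CH4", "gB"): f1},
                                    ["CH4", "gA", "gB"])


class TestBreedingPanel:
    def _candidates(self):
        return pd.DataFrame({
            "occupancy_all": [True, True, True, False, True],
            "mean_ra": [0.01, 0.02, 5e-5, 0.02, 0.03],
            "h2_significant": [True, True, True, True, False],
            "p0": [0.99, 0.97, 0.99, 0.99, 0.99],
            "rg_median": [-0.8, 0.7, -0.9, -0.85, 0.9],
            "h2_median": [0.4, 0.3, 0.5, 0.45, 0.6],
        }, index=["g1", "g2", "g3", "g4", "g5"])

    def test_exactly_two_qualify(self):
        panel = sel.select_breeding_panel(self._candidates(), min_ra=1e-4)
        assert set(panel.index) == {"g1", "g2"}

    def test_no_qualifiers_gives_empty_panel(self):
        c = self._candidates()
        c["p0"] = 0.5
        panel = sel.select_breeding_panel(c)
        assert len(panel) == 0

    def test_cap_keeps_strongest_correlations(self):
        r = np.random.default_rng(0)
        c = pd.DataFrame({
            "occupancy_all": True, "mean_ra": 0.01, "h2_significant": True,
            "p0": 0.99, "rg_median": r.uniform(-0.95, 0.95, 38),
            "h2_median": r.uniform(0.2, 0.6, 38),
        }, index=[f"g{i}" for i in range(38)])
        panel = sel.select_breeding_panel(c, cap=30)
        assert len(panel) == 30
        dropped = c.loc[c.index.difference(panel.index)]
        assert panel["rg_median"].abs().min() >= dropped["rg_median"].abs().max()
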
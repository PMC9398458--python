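"""Synthetic two-group study generator: shape contracts, determinism,
planted-DIF arithmetic and distributional correctness."""

import numpy as np
import pytest
from scipy import stats

import promirt as P
from promirt.simulate import InvalidDesignError


class TestSimulateItemBank:
    def test_shape_and_ordering(self):
        bank = P.simulate_item_bank(29, 5, seed=1)
        assert len(bank) == 29
        for item in bank:
            assert item.n_categories == 5
            assert len(item.thresholds) == 4
            assert all(b2 > b1 for b1, b2 in zip(item.thresholds, item.thresholds[1:]))
            assert 1.0 <= item.slope <= 4.5
            assert -1.5 <= item.thresholds[0] and item.thresholds[-1] <= 3.5

    def test_deterministic_from_seed(self):
        a = P.simulate_item_bank(12, 5, seed=9)
        b = P.simulate_item_bank(12, 5, seed=9)
        assert a == b
        assert a != P.simulate_item_bank(12, 5, seed=10)

    def test_invalid_counts(self):
        with pytest.raises(InvalidDesignError):
            P.simulate_item_bank(0, 5)
        with pytest.raises(InvalidDesignError):
            P.simulate_item_bank(5, 1)


class TestInjectDif:
    def test_uniform_shift_arithmetic(self):
        # published-scale base thresholds 0.59, 1.18, 1.95; shift -0.4
        base = P.ParameterSet(
            (P.ItemParameters("a", 3.74, (0.59, 1.18, 1.95)),
             P.ItemParameters("b", 2.0, (0.0, 1.0, 2.0))),
        )
        out = P.inject_dif(base, 0, "uniform", threshold_shift=-0.4)
        assert out["a"].thresholds == pytest.approx((0.19, 0.78, 1.55))
        assert out["a"].slope == base["a"].slope
        assert out["b"] == base["b"]

    def test_identity_when_no_change(self):
        base = P.simulate_item_bank(5, 5, seed=2)
        out = P.inject_dif(base, 1, "uniform", threshold_shift=0.0)
        assert out.items == base.items

    def test_nonuniform_slope_factor(self):
        base = P.ParameterSet((P.ItemParameters("w", 3.14, (-0.57, 0.24, 1.22, 2.12)),))
        out = P.inject_dif(base, "w", "nonuniform", slope_factor=0.69)
        assert out["w"].slope == pytest.approx(3.14 * 0.69)
        assert out["w"].slope == pytest.approx(2.17, abs=0.01)

    def test_invalid_combinations(self):
        base = P.simulate_item_bank(3, 5, seed=2)
        with pytest.raises(InvalidDesignError):
            P.inject_dif(base, 0, "uniform", slope_factor=0.5)
        with pytest.raises(InvalidDesignError):
            P.inject_dif(base, 0, "nonuniform", slope_factor=1.0)
        with pytest.raises(InvalidDesignError):
            P.inject_dif(base, 0, "uniform", threshold_shift=float("nan"))
        with pytest.raises(InvalidDesignError):
            P.inject_dif(base, 7, "uniform", threshold_shift=0.1)


class TestSimulateResponses:
    def test_extreme_theta_saturates(self):
        item = P.ParameterSet((P.ItemParameters("e", 4.0, (-3.0, -2.5, -2.0, -1.5)),))
        resp, _ = P.simulate_responses(item, theta=np.full(500, 2.0), seed=3)
        assert resp.mean() > 4.95

    def test_category_frequencies_match_grm(self):
        """Empirical frequencies at n = 1e4 match the boundary-model
        probabilities (chi-squared goodness of fit, p > 0.001)."""
        item = P.ItemParameters("d", 2.93, (0.29, 0.88, 1.61, 2.36))
        params = P.ParameterSet((item,))
        rng = np.random.default_rng(44)
        thetas = rng.normal(0, 1, size=10_000)
        resp, _ = P.simulate_responses(params, theta=thetas, seed=45)
        counts = np.bincount(resp[:, 0], minlength=6)[1:]
        expected = P.category_probabilities(item, thetas).sum(axis=0)
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=4) > 0.001

    def test_empty_and_deterministic(self, small_bank):
        resp, thetas = P.simulate_responses(small_bank, n=0, seed=1)
        assert resp.shape == (0, 10) and len(thetas) == 0
        a, _ = P.simulate_responses(small_bank, n=100, seed=5)
        b, _ = P.simulate_responses(small_bank, n=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_missing_rate(self, small_bank):
        resp, _ = P.simulate_responses(small_bank, n=2000, seed=6, missing_rate=0.2)
        frac = (resp == -1).mean()
        assert 0.17 < frac < 0.23


class TestTwoGroupStudy:
    def test_no_dif_means_identical_parameters(self):
        design = P.SimulationDesign(n_items=6, n_reference=50, n_focal=30, seed=1)
        _, truth = P.simulate_two_group_study(design)
        assert truth.params_reference.items == truth.params_focal.items
        assert truth.dif_items == []

    def test_truth_differs_only_at_dif_items(self, small_study):
        matrix, truth = small_study
        assert set(truth.dif_items) == {"item_03", "item_06"}
        for ref, foc in zip(truth.params_reference, truth.params_focal):
            if ref.item_id in truth.dif_items:
                assert ref != foc
            else:
                assert ref == foc

    def test_matrix_layout_and_codes(self, small_study):
        matrix, truth = small_study
        assert matrix.n_persons == 2800
        assert matrix.n_items == 10
        assert set(matrix.groups) == {0, 1}
        arr = matrix.responses()
        assert arr.min() >= 1 and arr.max() <= 5
        assert set(matrix.df["age_bin"]) <= set(P.AGE_BINS)
        assert len(truth.theta) == 2800

    def test_covariate_proportions_within_binomial_error(self):
        design = P.SimulationDesign(n_items=2, n_reference=4000, n_focal=10, seed=77)
        matrix, _ = P.simulate_two_group_study(design)
        p_female = (matrix.df["gender"] == "female").mean()
        se = np.sqrt(0.521 * 0.479 / matrix.n_persons)
        assert abs(p_female - 0.521) < 4 * se
        p_young = (matrix.df["age_bin"] == "18-34").mean()
        se = np.sqrt(0.25 * 0.75 / matrix.n_persons)
        assert abs(p_young - 0.25) < 4 * se

    def test_reproducible_and_roundtrips(self, tmp_path, small_study):
        matrix, truth = small_study
        m2, t2 = P.simulate_two_group_study(
            P.SimulationDesign(
                n_items=10, n_reference=2000, n_focal=800,
                dif_spec=(
                    P.DIFSpec(2, "uniform", threshold_shift=-0.8),
                    P.DIFSpec(5, "nonuniform", threshold_shift=-0.7, slope_factor=0.5),
                ),
                seed=202,
            )
        )
        assert matrix.df.equals(m2.df)
        truth.to_json(tmp_path / "truth.json")
        back = P.TruthRecord.from_json(tmp_path / "truth.json")
        assert back.params_reference == truth.params_reference
        np.testing.assert_allclose(back.theta, truth.theta)

    def test_invalid_designs_rejected(self):
        with pytest.raises(InvalidDesignError):
            P.SimulationDesign(n_items=5, dif_spec=(P.DIFSpec(9, "uniform", 0.5),))
        with pytest.raises(InvalidDesignError):
            P.SimulationDesign(theta_focal=(0.0, 0.0))
        with pytest.raises(InvalidDesignError):
            P.SimulationDesign(
                dif_spec=(P.DIFSpec(1, "uniform", 0.1), P.DIFSpec(1, "uniform", 0.2))
            )
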
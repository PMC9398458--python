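"""Graded-response-model probabilities, EAP scoring and characteristic curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import promirt as P
from promirt.grm import posterior_over_grid


class TestBoundaryProbability:
    def test_half_at_threshold(self):
        assert P.boundary_probability(1.0, 0.0, 0.0) == pytest.approx(0.5)
        # published-scale parameters: slope 3.44, threshold -0.64
        assert P.boundary_probability(3.44, -0.64, -0.64) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        assert P.boundary_probability(2.0, 0.0, 50.0) == pytest.approx(1.0)
        assert P.boundary_probability(2.0, 0.0, -50.0) == pytest.approx(0.0, abs=1e-12)
        theta = np.linspace(-6, 6, 201)
        p = P.boundary_probability(1.7, 0.3, theta)
        assert np.all(np.diff(p) > 0)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            P.boundary_probability(0.0, 0.0, 0.0)


class TestCategoryProbabilities:
    def test_sum_to_one_over_grid(self, small_bank):
        theta = np.linspace(-6, 6, 121)
        for item in small_bank:
            p = P.category_probabilities(item, theta)
            assert p.shape == (121, item.n_categories)
            assert np.all(p >= 0)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_closed_form_middle_category(self):
        item = P.ItemParameters("x", 2.0, (-1.0, 0.0, 1.0, 2.0))
        p = P.category_probabilities(item, 0.0)
        expected = 1.0 / (1.0 + np.exp(-2.0)) - 0.5  # P*(>=2) - P*(>=3) at theta 0
        assert p[1] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        slope=st.floats(0.3, 5.0),
        b1=st.floats(-2.0, 1.0),
        theta=st.floats(-6.0, 6.0),
    )
    def test_probability_vector_property(self, slope, b1, theta):
        item = P.ItemParameters("h", slope, (b1, b1 + 0.7, b1 + 1.5))
        p = P.category_probabilities(item, theta)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-12)


class TestEAPScores:
    def test_all_missing_person_gets_prior_mean(self, small_bank):
        arr = np.full((3, 10), -1, dtype=np.int64)
        arr[0] = 3  # one person answers everything
        scores = P.eap_scores(arr, small_bank)
        assert scores.t[1] == pytest.approx(50.0)
        assert scores.t[2] == pytest.approx(50.0)
        assert scores.df["all_missing"].tolist() == [False, True, True]

    def test_t_score_is_linear_in_eap(self, small_bank):
        resp, _ = P.simulate_responses(small_bank, n=200, seed=7)
        s = P.eap_scores(resp, small_bank)
        np.testing.assert_allclose(s.t, 50 + 10 * s.eap, atol=1e-12)
        assert np.all(s.posterior_sd > 0)

    def test_fine_grid_oracle(self, small_bank):
        """Default 49-node grid agrees with a 10x finer integration."""
        resp, _ = P.simulate_responses(small_bank, n=300, seed=8)
        coarse = P.eap_scores(resp, small_bank, P.QuadratureGrid.normal())
        fine = P.eap_scores(resp, small_bank, P.QuadratureGrid.normal_fine(10))
        assert np.max(np.abs(coarse.eap - fine.eap)) < 1e-3

    def test_monotone_in_single_response(self):
        """Raising one item's response never lowers the EAP (3-item bank)."""
        bank = P.simulate_item_bank(3, 4, seed=31)
        patterns = np.array(
            [[i, j, k] for i in range(1, 5) for j in range(1, 5) for k in range(1, 5)]
        )
        eap = P.eap_scores(patterns, bank).eap
        lookup = {tuple(p): e for p, e in zip(map(tuple, patterns), eap)}
        for p in map(tuple, patterns):
            for pos in range(3):
                if p[pos] < 4:
                    q = list(p)
                    q[pos] += 1
                    assert lookup[tuple(q)] >= lookup[p] - 1e-12

    def test_missing_handled_as_absent_information(self, small_bank):
        """Scoring with an item missing equals scoring without that item."""
        resp, _ = P.simulate_responses(small_bank, n=50, seed=9)
        with_missing = resp.copy()
        with_missing[:, 4] = -1
        s1 = P.eap_scores(with_missing, small_bank)
        reduced = np.delete(resp, 4, axis=1)
        ids = [i for k, i in enumerate(small_bank.item_ids) if k != 4]
        s2 = P.eap_scores(reduced, small_bank.subset(ids))
        np.testing.assert_allclose(s1.eap, s2.eap, atol=1e-12)


class TestCharacteristicCurves:
    def test_tcc_limits_and_range(self, small_bank):
        theta = np.array([-30.0, 30.0])
        tcc = P.test_characteristic_curve(small_bank, theta)
        assert tcc[0] == pytest.approx(10 * 1, abs=1e-6)
        assert tcc[1] == pytest.approx(10 * 5, abs=1e-6)
        grid = np.linspace(-6, 6, 101)
        assert np.all(np.diff(P.test_characteristic_curve(small_bank, grid)) > 0)

    def test_tcc_additivity(self, toy_item):
        two = P.ParameterSet(
            (toy_item, P.ItemParameters("copy", toy_item.slope, toy_item.thresholds)),
        )
        one = P.ParameterSet((toy_item,))
        grid = np.linspace(-4, 4, 41)
        np.testing.assert_allclose(
            P.test_characteristic_curve(two, grid),
            2 * P.test_characteristic_curve(one, grid),
            atol=1e-12,
        )

    def test_tcc_unknown_item_or_empty(self, small_bank):
        with pytest.raises(KeyError):
            P.test_characteristic_curve(small_bank, np.array([0.0]), items=["nope"])
        with pytest.raises(ValueError):
            P.test_characteristic_curve(small_bank, np.array([0.0]), items=[])

    def test_small_tcc_difference_with_two_dif_items(self):
        """With 2 of 29 items shifted, the two groups' TCCs stay close."""
        ref = P.simulate_item_bank(29, 5, seed=41)
        foc = P.inject_dif(ref, 0, "uniform", -0.4)
        foc = P.inject_dif(foc, 1, "uniform", 0.4)
        grid = np.linspace(-4, 4, 81)
        diff = np.abs(
            P.test_characteristic_curve(ref, grid) - P.test_characteristic_curve(foc, grid)
        )
        # max possible score is 145; two mildly shifted items move the TCC little
        assert diff.max() < 2.0

    def test_crc_table(self, toy_item):
        shifted = P.ItemParameters("toy", toy_item.slope, tuple(b - 0.5 for b in toy_item.thresholds))
        grid = np.linspace(-3, 3, 25)
        table = P.category_response_curves(toy_item, shifted, grid)
        assert len(table) == 25 * 5 * 2
        same = P.category_response_curves(toy_item, toy_item, grid)
        ref = same[same.group == "reference"]["probability"].to_numpy()
        foc = same[same.group == "focal"]["probability"].to_numpy()
        np.testing.assert_allclose(ref, foc, atol=1e-15)
        # lowering thresholds by 0.5 shifts every curve left: the focal
        # curve at theta equals the reference curve at theta + 0.5
        shifted_tab = table[table.group == "focal"]
        base_tab = P.category_response_curves(toy_item, toy_item, grid + 0.5)[
            lambda d: d.group == "reference"
        ]
        np.testing.assert_allclose(
            shifted_tab["probability"].to_numpy(), base_tab["probability"].to_numpy(), atol=1e-12
        )


def test_posterior_weights_normalised(small_bank, grid):
    resp, _ = P.simulate_responses(small_bank, n=40, seed=3)
    post, _ = posterior_over_grid(resp, small_bank, grid)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
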
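"""DIF detection: nested-model invariants, planted-truth recovery,
purification scan behaviour and Monte-Carlo null thresholds."""

import numpy as np
import pytest

import promirt as P


@pytest.fixture(scope="module")
def null_fits(small_bank):
    """Three-model fits for every item of a no-DIF two-group sample."""
    n_ref, n_foc = 1500, 600
    resp_ref, _ = P.simulate_responses(small_bank, n=n_ref, theta=(0, 1), seed=61)
    resp_foc, _ = P.simulate_responses(small_bank, n=n_foc, theta=(0, 1), seed=62)
    arr = np.vstack([resp_ref, resp_foc])
    group = np.r_[np.zeros(n_ref), np.ones(n_foc)]
    theta = P.eap_scores(arr, small_bank).eap
    return [
        P.dif_test_item(arr[:, j], theta, group, 5, item_id=small_bank.item_ids[j])
        for j in range(len(small_bank))
    ]


class TestDifTestItem:
    def test_nesting_invariant(self, null_fits):
        for f in null_fits:
            assert f.loglik_1 <= f.loglik_2 + 1e-9 <= f.loglik_3 + 2e-9

    def test_r2_change_additivity(self, null_fits):
        for f in null_fits:
            assert f.dr2_13 == pytest.approx(f.dr2_12 + f.dr2_23, abs=1e-10)
            assert f.dr2_12 >= -1e-10 and f.dr2_23 >= -1e-10

    def test_null_sample_not_flagged(self, null_fits):
        assert not any(f.flagged for f in null_fits)
        assert all(f.dif_type == "none" for f in null_fits)

    def test_planted_uniform_dif_flagged_with_type(self, small_bank):
        focal_params = P.inject_dif(small_bank, 4, "uniform", -0.75)
        n_ref, n_foc = 3000, 1002
        rr, _ = P.simulate_responses(small_bank, n=n_ref, theta=(0, 1), seed=71)
        rf, _ = P.simulate_responses(focal_params, n=n_foc, theta=(0, 1), seed=72)
        arr = np.vstack([rr, rf])
        group = np.r_[np.zeros(n_ref), np.ones(n_foc)]
        theta = P.eap_scores(arr, small_bank).eap
        fit = P.dif_test_item(arr[:, 4], theta, group, 5, item_id="item_05")
        assert fit.flagged and fit.dif_type == "uniform"
        assert fit.dr2_12 > fit.dr2_23

    def test_interaction_dominates_for_pure_slope_change(self):
        """Slope-change-only DIF on an item whose thresholds straddle zero
        shows a dominant trait-by-group interaction component (tested at a
        lowered magnitude threshold; interaction R2 changes are small)."""
        design = P.SimulationDesign(
            n_items=10, n_reference=2000, n_focal=800,
            dif_spec=(P.DIFSpec(0, "nonuniform", threshold_shift=0.0, slope_factor=0.25),),
            seed=202,
        )
        matrix, truth = P.simulate_two_group_study(design)
        arr = matrix.responses()
        theta = P.eap_scores(arr, truth.params_reference).eap
        fit = P.dif_test_item(
            arr[:, 0], theta, matrix.groups.astype(float), 5,
            r2_threshold=0.005, item_id="item_01",
        )
        assert fit.flagged and fit.dif_type == "nonuniform"
        assert fit.dr2_23 > fit.dr2_12

    def test_degenerate_item_rejected(self):
        theta = np.random.default_rng(0).normal(size=100)
        with pytest.raises(ValueError, match="degenerate"):
            P.dif_test_item(np.ones(100, dtype=int), theta, np.zeros(100))

    def test_group_must_be_binary(self):
        theta = np.zeros(10)
        y = np.tile([1, 2], 5)
        with pytest.raises(ValueError):
            P.dif_test_item(y, theta, np.arange(10))

    def test_parametric_p_matches_permutation_null(self, small_bank):
        """On null data the chi2 p-value agrees with a group-permutation
        reference distribution within Monte-Carlo error."""
        rng = np.random.default_rng(99)
        n = 600
        resp, _ = P.simulate_responses(small_bank, n=n, theta=(0, 1), seed=98)
        theta = P.eap_scores(resp, small_bank).eap
        group = (rng.random(n) < 0.4).astype(float)
        fit = P.dif_test_item(resp[:, 0], theta, group, 5)
        perm_stats = []
        for _ in range(200):
            g = rng.permutation(group)
            pf = P.dif_test_item(resp[:, 0], theta, g, 5)
            perm_stats.append(pf.chi2_13)
        perm_p = np.mean(np.asarray(perm_stats) >= fit.chi2_13)
        assert abs(perm_p - fit.p_13) < 3 * np.sqrt(0.25 / 200) + 0.02


class TestIterativeScan:
    def test_no_dif_study_empty_flags(self):
        design = P.SimulationDesign(n_items=8, n_reference=1500, n_focal=600, seed=88)
        matrix, truth = P.simulate_two_group_study(design)
        scan = P.iterative_dif_scan(
            matrix, P.DIFScanConfig(em_tol=5e-3, em_max_cycles=60),
            params_reference=truth.params_reference,
        )
        assert scan.flagged_items == set()
        assert 1 <= scan.iterations <= 2
        assert scan.converged

    def test_planted_items_recovered(self, small_study):
        matrix, truth = small_study
        scan = P.iterative_dif_scan(matrix, P.DIFScanConfig(em_tol=5e-3, em_max_cycles=60))
        assert scan.flagged_items == set(truth.dif_items)
        types = {f.item_id: f.dif_type for f in scan.fits if f.flagged}
        assert types["item_03"] == "uniform"
        # the second planted item pairs a slope change with a shift; the
        # magnitude decomposition labels its dominant (location) component
        assert types["item_06"] in ("uniform", "nonuniform")
        # flag set stable across the final two iterations
        assert scan.converged
        assert scan.flag_history[-1] == scan.flag_history[-2]

    def test_needs_two_groups(self, small_bank):
        resp, _ = P.simulate_responses(small_bank, n=50, seed=5)
        import pandas as pd

        df = pd.DataFrame(resp, columns=small_bank.item_ids).astype(float)
        df.insert(0, "group", 0)
        df.insert(0, "person_id", np.arange(50))
        matrix = P.ResponseMatrix(df, small_bank.item_ids, 5)
        with pytest.raises(ValueError):
            P.iterative_dif_scan(matrix, params_reference=small_bank)


class TestMonteCarloThresholds:
    def test_null_thresholds_deterministic_and_small(self, small_bank):
        mc = P.monte_carlo_thresholds(
            small_bank, group_sizes=(800, 400), n_replications=30, alpha=0.01, seed=5
        )
        mc2 = P.monte_carlo_thresholds(
            small_bank, group_sizes=(800, 400), n_replications=30, alpha=0.01, seed=5
        )
        assert mc.p_thresholds == mc2.p_thresholds
        assert mc.r2_quantiles == mc2.r2_quantiles
        for v in mc.r2_quantiles.values():
            assert 0 <= v < 0.05
        for v in mc.p_thresholds.values():
            assert 0 <= v < 0.2
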
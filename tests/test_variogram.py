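"""Variography: estimator, exponential fit, screening, culling, comparisons."""

import numpy as np
import pandas as pd
import pytest

from mycogeo import (
    EmpiricalVariogram,
    RangeEstimate,
    VariogramModel,
    compare_ranges,
    cull_and_flag,
    empirical_semivariogram,
    estimate_ranges,
    fit_exponential,
    mantel_screen,
)
from mycogeo.simulate import simulate_gaussian_random_field
from mycogeo.variogram import single_otu_bray_curtis
from .conftest import make_table


def _make_estimate(range_m, otu="O", transect="T1", habitat="soil", label="generalist"):
    model = VariogramModel(sill=1.0, range_param=range_m / 3, sse=0.0, converged=True)
    return RangeEstimate(otu, transect, habitat, label, range_m, model)


class TestSingleOtuBC:
    def test_pairwise_formula_and_zero_convention(self):
        D = single_otu_bray_curtis([0.0, 2.0, 0.0]).values
        assert D[0, 1] == 1.0  # |0-2|/(0+2)
        assert D[0, 2] == 0.0  # both zero: defined as 0
        assert D[1, 2] == 1.0


class TestEmpiricalSemivariogram:
    def test_constant_field_gives_zero(self):
        coords = [(i, 0) for i in range(10)]
        emp = empirical_semivariogram(np.ones(10), coords, n_bins=4, min_pairs=1)
        assert (emp.semivariances == 0).all()

    def test_two_point_hand_value(self):
        emp = empirical_semivariogram(
            [0.0, 2.0], [(0, 0), (1, 0)], n_bins=1, max_lag=2.0, min_pairs=1
        )
        assert emp.semivariances[0] == pytest.approx(2.0)  # (1/2) * 2^2 / 1
        assert emp.pair_counts[0] == 1

    def test_iid_noise_is_flat_at_sigma_squared(self, dense_grid_coords):
        rng = np.random.default_rng(0)
        sigma2 = 4.0
        gs = []
        for _ in range(20):
            z = rng.normal(0, np.sqrt(sigma2), len(dense_grid_coords))
            emp = empirical_semivariogram(z, dense_grid_coords, n_bins=8, max_lag=10.0)
            gs.append(emp.semivariances)
        mean_gamma = np.mean(gs, axis=0)
        np.testing.assert_allclose(mean_gamma, sigma2, rtol=0.10)

    def test_insufficient_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            empirical_semivariogram([0.0, 1.0], [(0, 0), (1, 0)], n_bins=3, min_pairs=5)

    def test_bins_ordered_and_counts_respected(self, dense_grid_coords):
        z = np.arange(len(dense_grid_coords), dtype=float)
        emp = empirical_semivariogram(z, dense_grid_coords, n_bins=10, min_pairs=10)
        assert (np.diff(emp.lag_centers) > 0).all()
        assert (emp.pair_counts >= 10).all()


class TestExponentialFit:
    @pytest.mark.parametrize("sill, a", [(2.0, 3.0), (0.5, 1.0), (5.0, 8.0)])
    def test_noiseless_exact_recovery(self, sill, a):
        h = np.arange(1.0, 11.0)
        gamma = sill * (1 - np.exp(-h / a))
        emp = EmpiricalVariogram(h, gamma, np.full(10, 50), max_lag=10.0)
        model = fit_exponential(emp)
        assert model.converged
        assert model.sill == pytest.approx(sill, rel=1e-5)
        assert model.range_param == pytest.approx(a, rel=1e-5)
        assert model.sse < 1e-10

    def test_model_closed_forms(self):
        model = VariogramModel(sill=2.0, range_param=3.0, sse=0.0, converged=True)
        assert model.gamma(3.0) == pytest.approx(2.0 * (1 - np.exp(-1)))
        assert model.effective_range == 9.0
        assert model.gamma(model.effective_range) == pytest.approx(0.95 * 2.0, rel=1e-3)

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([1.0, 1.5]),
                                 np.array([20, 20]), max_lag=2.0)
        with pytest.raises(ValueError):
            fit_exponential(emp)


class TestMantelScreen:
    def _habitat_table(self, values, coords, transect="T1", habitat="soil"):
        # a constant companion OTU keeps per-sample relative abundance informative
        meta = [
            (f"s{i}", transect, habitat, i, float(x), float(y))
            for i, (x, y) in enumerate(coords)
        ]
        return make_table([[v, 10] for v in values], meta, otu_ids=["O1", "O2"])

    def test_monotone_gradient_is_flagged(self):
        coords = [(i % 4 * 2, i // 4 * 2) for i in range(16)]
        values = [40 - (x + y) for x, y in coords]  # deterministic decay from corner
        t = self._habitat_table(values, coords)
        screen = mantel_screen(t, alpha=0.05, n_permutations=199, seed=0)
        assert screen[screen["otu_id"] == "O1"]["flagged"].iloc[0]

    def test_absent_otu_skipped(self):
        coords = [(float(i), 0.0) for i in range(8)]
        t = self._habitat_table([0] * 8, coords)
        screen = mantel_screen(t, seed=0)
        assert len(screen) == 0

    def test_false_positive_rate_near_alpha(self):
        """I.i.d. abundance has no spatial signal: flag rate ~ alpha."""
        rng = np.random.default_rng(1)
        coords = [(i % 6 * 2.0, i // 6 * 2.0) for i in range(36)]
        meta = [(f"s{i}", "T1", "soil", i, x, y) for i, (x, y) in enumerate(coords)]
        n_otus = 150
        counts = rng.integers(0, 30, size=(36, n_otus)).tolist()
        t = make_table(counts, meta)
        screen = mantel_screen(t, alpha=0.05, n_permutations=199, seed=2)
        rate = screen["flagged"].mean()
        assert 0.01 <= rate <= 0.10  # binomial band around 0.05 at n=150


class TestEstimateRanges:
    def _coupled_table(self, seed=4):
        from mycogeo import StudyDesign, SyntheticParams, simulate_study

        p = SyntheticParams(
            design=StudyDesign(n_transects=1),
            n_soil_specialists=0, n_phyllo_specialists=0, n_generalists=4,
            base_log_abundance=3.0, detection_offset=0.0, coupling_rho=0.9, seed=seed,
        )
        return simulate_study(p)

    def test_generalist_screened_in_both_habitats_gets_two_estimates(self):
        from mycogeo import classify_otus, remove_singletons

        table, _ = self._coupled_table()
        filtered = remove_singletons(table)
        cls_list = classify_otus(filtered)
        screen = pd.DataFrame(
            [
                {"otu_id": o, "transect": "T1", "habitat": h, "mantel_r": 0.5,
                 "p": 0.01, "flagged": True}
                for o in filtered.otu_ids[:1]
                for h in ("soil", "phylloplane")
            ]
        )
        est = estimate_ranges(
            filtered.log1p_normalized(), cls_list, screen, min_pairs=5
        )
        assert len(est) == 2
        assert {e.habitat for e in est} == {"soil", "phylloplane"}

    def test_unscreened_otu_gets_no_estimate(self):
        from mycogeo import classify_otus, remove_singletons

        table, _ = self._coupled_table()
        filtered = remove_singletons(table)
        screen = pd.DataFrame(
            columns=["otu_id", "transect", "habitat", "mantel_r", "p", "flagged"]
        )
        est = estimate_ranges(filtered.log1p_normalized(), classify_otus(filtered), screen)
        assert est == []

    def test_recovery_of_known_effective_range(self, dense_grid_coords):
        """Median recovered effective range within 30% on a dense grid."""
        true_eff = 6.0
        a = true_eff / 3
        recovered = []
        for seed in range(30):
            z = simulate_gaussian_random_field(dense_grid_coords, 1.0, a, seed=seed)
            emp = empirical_semivariogram(z, dense_grid_coords, n_bins=12, min_pairs=10)
            model = fit_exponential(emp)
            if model.converged:
                recovered.append(model.effective_range)
        med = np.median(recovered)
        assert abs(med - true_eff) / true_eff <= 0.30


class TestCulling:
    def test_audit_arithmetic_on_study_scale_inputs(self):
        rng = np.random.default_rng(0)
        estimates = (
            [_make_estimate(float(r)) for r in rng.uniform(0.05, 0.99, 515)]
            + [_make_estimate(float(r)) for r in rng.uniform(1.5, 30.0, 539)]
            + [_make_estimate(float(r)) for r in rng.uniform(500.0, 1000.0, 6)]
        )
        flagged, audit = cull_and_flag(estimates, min_range_m=1.0, max_range_m=41.231)
        assert audit.n_total == 1060
        assert audit.n_culled == 515
        assert audit.n_outliers == 6
        assert audit.n_remaining == 539

    def test_nothing_removed_when_all_plausible(self):
        estimates = [_make_estimate(r) for r in (1.5, 3.0, 10.0)]
        flagged, audit = cull_and_flag(estimates, min_range_m=1.0, max_range_m=41.231)
        assert audit.n_culled == 0 and audit.n_outliers == 0
        assert all(not e.culled and not e.outlier for e in flagged)

    def test_range_beyond_transect_diagonal_is_outlier(self):
        flagged, audit = cull_and_flag(
            [_make_estimate(50.0), _make_estimate(5.0)], min_range_m=1.0, max_range_m=41.231
        )
        assert audit.n_outliers == 1
        assert next(e for e in flagged if e.range_m == 50.0).outlier

    def test_tukey_fence_flags_extreme_survivor(self):
        estimates = [_make_estimate(r) for r in [2, 2.2, 2.4, 2.6, 3.0, 900.0]]
        flagged, audit = cull_and_flag(estimates, min_range_m=1.0, tukey_fence=True)
        assert next(e for e in flagged if e.range_m == 900.0).outlier


class TestCompareRanges:
    def test_distinct_true_ranges_detected(self):
        rng = np.random.default_rng(5)
        est = [
            _make_estimate(float(r), otu=f"a{i}", habitat="soil", label="soil_specialist")
            for i, r in enumerate(rng.lognormal(np.log(2.0), 0.25, 40))
        ] + [
            _make_estimate(float(r), otu=f"b{i}", habitat="soil", label="generalist")
            for i, r in enumerate(rng.lognormal(np.log(8.0), 0.25, 40))
        ]
        df = compare_ranges(est)
        assert len(df) == 1
        assert df["p_adjusted"].iloc[0] < 0.001
        medians = {df["group_a"].iloc[0]: df["median_a"].iloc[0],
                   df["group_b"].iloc[0]: df["median_b"].iloc[0]}
        assert medians["soil_specialist:soil"] < medians["generalist:soil"]

    def test_identical_distributions_rarely_reject(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            est = [
                _make_estimate(float(r), otu=f"a{i}", label="soil_specialist")
                for i, r in enumerate(rng.lognormal(1, 0.3, 20))
            ] + [
                _make_estimate(float(r), otu=f"b{i}", label="generalist")
                for i, r in enumerate(rng.lognormal(1, 0.3, 20))
            ]
            if (compare_ranges(est)["p_adjusted"] < 0.05).any():
                rejections += 1
        assert rejections / n_rep <= 0.12

    def test_single_group_empty_table(self):
        df = compare_ranges([_make_estimate(2.0), _make_estimate(3.0)])
        assert len(df) == 0

    def test_culled_and_outliers_excluded(self):
        est, _ = cull_and_flag(
            [_make_estimate(0.5), _make_estimate(2.0)], min_range_m=1.0
        )
        df = compare_ranges(est)
        assert len(df) == 0  # only one survivor -> no pairs
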
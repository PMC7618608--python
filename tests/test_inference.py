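"""KDE, stratified permutation, deviation profiles, peaks, subset tests."""

import collections
import math

import numpy as np
import pytest

from rhythm_ioi.errors import (ConfigError, EmptySubsetError,
                               UntestableDatasetError)
from rhythm_ioi.inference import (DeviationProfile, InferenceConfig,
                                  call_peaks, kde_density, omission_test,
                                  pair_subset_test, run_rhythm_test,
                                  stratified_permute)
from rhythm_ioi.sequence_model import build_dataset

from conftest import annotations_from_iois, make_annotations


def dense_kde(samples, grid, bandwidth):
    """Direct O(n * G) Gaussian KDE, the oracle for the banded evaluator."""
    z = (grid[:, None] - np.asarray(samples)[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).mean(axis=1) / (
        bandwidth * math.sqrt(2 * math.pi))


class TestConfig:
    def test_insufficient_permutations(self):
        with pytest.raises(ConfigError, match="n_permutations"):
            InferenceConfig(n_permutations=50, alpha=0.01)

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"grid_size": 1}, {"kde_bandwidth": 0.0},
        {"ci_quantiles": (0.9, 0.1)}, {"stratum_mode": "nope"},
    ])
    def test_invalid_values(self, kwargs):
        with pytest.raises(ConfigError):
            InferenceConfig(n_permutations=1000, **kwargs)


class TestKde:
    def test_single_point_closed_form(self):
        cfg = InferenceConfig()
        d = kde_density([0.5], cfg)
        peak = 1 / (cfg.kde_bandwidth * math.sqrt(2 * math.pi))
        # grid discretization: nearest point is within step/2 of the sample
        assert d.density.max() == pytest.approx(peak, rel=0.01)
        assert d.grid[np.argmax(d.density)] == pytest.approx(0.5, abs=1e-3)

    def test_matches_dense_oracle(self, rng):
        cfg = InferenceConfig()
        samples = rng.uniform(0.02, 0.98, 200)
        d = kde_density(samples, cfg)
        expected = dense_kde(samples, d.grid, cfg.kde_bandwidth)
        np.testing.assert_allclose(d.density, expected, rtol=1e-10,
                                   atol=1e-10)

    def test_symmetry(self):
        cfg = InferenceConfig()
        d = kde_density([0.3] * 5 + [0.7] * 5, cfg)
        np.testing.assert_allclose(d.density, d.density[::-1], atol=1e-9)

    def test_interior_sample_integrates_to_one(self, rng):
        cfg = InferenceConfig()
        d = kde_density(rng.uniform(0.06, 0.94, 500), cfg)
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0,
                                                                abs=0.01)

    def test_boundary_leakage_allowed(self):
        cfg = InferenceConfig()
        d = kde_density([0.002, 0.998], cfg)
        integral = np.trapezoid(d.density, d.grid)
        assert 0.5 < integral < 1.0  # roughly half the mass leaks out

    def test_empty_sample_rejected(self):
        with pytest.raises(UntestableDatasetError):
            kde_density([], InferenceConfig())


class TestStratifiedPermute:
    @pytest.fixture
    def dataset(self):
        a = annotations_from_iois(
            [0.1, 0.2, 0.3, 0.15, 0.25, 0.12, 0.22, 0.18],
            classes=["C", "C", "N", "C", "N", "N", "C", "C", "N"])
        return build_dataset(a, 1.0)

    def test_per_stratum_multiset_exactly_conserved(self, dataset, rng):
        keys = dataset.stratum_keys("pair")
        for _ in range(20):
            permuted = stratified_permute(dataset, rng)
            orig = collections.defaultdict(list)
            perm = collections.defaultdict(list)
            for k, vo, vp in zip(keys, dataset.ioi_values, permuted):
                orig[k].append(vo)
                perm[k].append(vp)
            for k in orig:
                assert sorted(orig[k]) == sorted(perm[k])  # exact equality

    def test_singleton_strata_are_fixed_points(self):
        # every IOI has a distinct flanking pair -> nothing can move
        a = annotations_from_iois([0.1, 0.2, 0.3],
                                  classes=["A", "B", "C", "D"])
        ds = build_dataset(a, 1.0)
        permuted = stratified_permute(ds, np.random.default_rng(0))
        np.testing.assert_array_equal(permuted, ds.ioi_values)

    def test_single_stratum_uniform_shuffle(self):
        a = annotations_from_iois([1.0, 2.0, 3.0])
        ds = build_dataset(a, 10.0)
        counts = collections.Counter()
        for seed in range(600):
            permuted = stratified_permute(ds, seed)
            counts[tuple(permuted)] += 1
        assert len(counts) == 6  # all 3! orderings occur
        assert min(counts.values()) > 60  # roughly uniform (exp. 100)

    def test_individual_only_mode_mixes_classes(self, dataset):
        # with class-blind strata all 8 IOIs share one stratum
        strata = dataset.stratum_indices("individual_only")
        assert len(strata) == 1
        assert next(iter(strata.values())).size == dataset.n_iois


class TestRunRhythmTest:
    def test_too_few_ratios(self):
        ds = build_dataset(make_annotations([0.0, 0.2], durations=0.05), 1.0)
        with pytest.raises(UntestableDatasetError):
            run_rhythm_test(ds, InferenceConfig(n_permutations=100,
                                                alpha=0.05))

    def test_degenerate_all_equal_iois(self):
        """All permutations identical -> deviation 0, not significant,
        and no NaN/Inf anywhere despite zero permutation SD."""
        a = annotations_from_iois([0.2] * 10)
        ds = build_dataset(a, 1.0)
        res = run_rhythm_test(ds, InferenceConfig(n_permutations=100,
                                                  alpha=0.05, rng_seed=1))
        assert np.all(np.isfinite(res.profile.deviation))
        np.testing.assert_array_equal(res.profile.deviation, 0.0)
        assert res.profile.sd_floor_mask.all()
        assert not res.significant
        assert res.peaks == []

    def test_deviation_finite_on_sparse_data(self):
        a = annotations_from_iois([0.1, 0.9, 0.15, 0.85, 0.2])
        ds = build_dataset(a, 2.0)
        res = run_rhythm_test(ds, InferenceConfig(n_permutations=200,
                                                  alpha=0.05, rng_seed=0))
        assert np.all(np.isfinite(res.profile.deviation))
        assert np.all(np.isfinite(res.profile.ci_low))
        assert np.all(np.isfinite(res.profile.ci_high))

    def test_significance_definition(self):
        a = annotations_from_iois(np.tile([0.1, 0.2], 15))
        ds = build_dataset(a, 1.0)
        res = run_rhythm_test(ds, InferenceConfig(n_permutations=300,
                                                  alpha=0.05, rng_seed=5))
        assert res.significant == (res.observed_max > res.test_statistic)
        q = math.ceil(0.95 * 300) - 1
        assert res.test_statistic == np.sort(res.perm_maxima)[q]

    def test_determinism_bit_identical(self):
        a = annotations_from_iois(np.tile([0.1, 0.25, 0.17], 6))
        ds = build_dataset(a, 1.0)
        cfg = InferenceConfig(n_permutations=200, alpha=0.05, rng_seed=77)
        r1 = run_rhythm_test(ds, cfg)
        r2 = run_rhythm_test(ds, cfg)
        np.testing.assert_array_equal(r1.perm_maxima, r2.perm_maxima)
        np.testing.assert_array_equal(r1.profile.deviation,
                                      r2.profile.deviation)
        assert r1.observed_max == r2.observed_max

    def test_different_seeds_differ(self):
        a = annotations_from_iois(np.tile([0.1, 0.25, 0.17], 6))
        ds = build_dataset(a, 1.0)
        r1 = run_rhythm_test(ds, InferenceConfig(n_permutations=200,
                                                 alpha=0.05, rng_seed=1))
        r2 = run_rhythm_test(ds, InferenceConfig(n_permutations=200,
                                                 alpha=0.05, rng_seed=2))
        assert not np.array_equal(r1.perm_maxima, r2.perm_maxima)


def flat_profile(deviation, ci=2.5):
    n = len(deviation)
    return DeviationProfile(
        grid=np.linspace(0, 1, n), observed_density=np.zeros(n),
        perm_mean=np.zeros(n), perm_sd=np.ones(n),
        deviation=np.asarray(deviation, dtype=float),
        ci_low=np.full(n, -ci), ci_high=np.full(n, ci),
        sd_floor_mask=np.zeros(n, dtype=bool))


class TestCallPeaks:
    def test_single_bump(self):
        x = np.linspace(0, 1, 101)
        dev = 6 * np.exp(-0.5 * ((x - 0.5) / 0.05) ** 2)
        peaks = call_peaks(flat_profile(dev))
        assert len(peaks) == 1
        assert peaks[0].sign == "excess"
        assert peaks[0].ratio_location == pytest.approx(0.5, abs=0.01)

    def test_everything_inside_bands(self, rng):
        dev = rng.uniform(-2, 2, 101)
        assert call_peaks(flat_profile(dev, ci=2.5)) == []

    def test_two_bumps_split_by_dip(self):
        x = np.linspace(0, 1, 201)
        dev = 6 * np.exp(-0.5 * ((x - 0.3) / 0.04) ** 2) + \
            6 * np.exp(-0.5 * ((x - 0.7) / 0.04) ** 2)
        peaks = call_peaks(flat_profile(dev))
        assert [p.sign for p in peaks] == ["excess", "excess"]
        assert [round(p.ratio_location, 1) for p in peaks] == [0.3, 0.7]

    def test_deficit_peaks(self):
        x = np.linspace(0, 1, 101)
        dev = -6 * np.exp(-0.5 * ((x - 0.4) / 0.05) ** 2)
        peaks = call_peaks(flat_profile(dev))
        assert len(peaks) == 1 and peaks[0].sign == "deficit"

    def test_plateau_resolves_leftmost(self):
        dev = np.r_[np.zeros(10), np.full(5, 6.0), np.zeros(10)]
        peaks = call_peaks(flat_profile(dev))
        assert len(peaks) == 1
        grid = np.linspace(0, 1, len(dev))
        assert peaks[0].ratio_location == pytest.approx(grid[10])

    def test_matches_brute_force_scan(self, rng):
        """Strict-extremum scan as an independent oracle."""
        dev = rng.normal(0, 3, 300)
        profile = flat_profile(dev, ci=2.5)
        got = {(p.ratio_location, p.sign) for p in call_peaks(profile)}
        expected = set()
        for i in range(1, len(dev) - 1):
            if dev[i] > dev[i - 1] and dev[i] > dev[i + 1] and \
                    dev[i] > 2.5:
                expected.add((profile.grid[i], "excess"))
            if dev[i] < dev[i - 1] and dev[i] < dev[i + 1] and \
                    dev[i] < -2.5:
                expected.add((profile.grid[i], "deficit"))
        assert got == expected


class TestPairSubset:
    @pytest.fixture
    def dataset(self):
        classes = ["C", "C", "C", "N", "C", "C", "C", "C", "N", "C", "C",
                   "C", "C"]
        iois = np.tile([0.1, 0.2, 0.15], 4)
        return build_dataset(annotations_from_iois(iois, classes=classes),
                             1.0)

    def test_all_same_class_every_ratio_qualifies(self):
        ds = build_dataset(annotations_from_iois(np.tile([0.1, 0.2], 10)),
                           1.0)
        res = pair_subset_test(ds, ("C", "C"),
                               InferenceConfig(n_permutations=100,
                                               alpha=0.05, rng_seed=0))
        assert res.n_ratios == ds.n_ratios

    def test_absent_pair_raises(self, dataset):
        with pytest.raises(EmptySubsetError):
            pair_subset_test(dataset, ("N", "N"),
                             InferenceConfig(n_permutations=100, alpha=0.05))

    def test_alternating_classes_have_no_same_class_ratio(self):
        a = annotations_from_iois([0.1, 0.2, 0.15, 0.25],
                                  classes=["C", "N", "C", "N", "C"])
        ds = build_dataset(a, 1.0)
        with pytest.raises(EmptySubsetError):
            pair_subset_test(ds, ("C", "C"),
                             InferenceConfig(n_permutations=100, alpha=0.05))

    def test_subset_smaller_than_full(self, dataset):
        cfg = InferenceConfig(n_permutations=100, alpha=0.05, rng_seed=0)
        res = pair_subset_test(dataset, ("C", "C"), cfg)
        assert 0 < res.n_ratios < dataset.n_ratios


class TestOmission:
    def test_omit_nothing_is_identity(self):
        a = annotations_from_iois(np.tile([0.1, 0.2], 10))
        ds = build_dataset(a, 1.0)
        cfg = InferenceConfig(n_permutations=150, alpha=0.05, rng_seed=3)
        full = run_rhythm_test(ds, cfg)
        omitted = omission_test(ds, set(), cfg)
        np.testing.assert_array_equal(full.perm_maxima, omitted.perm_maxima)
        assert full.observed_max == omitted.observed_max

    def test_omit_everything_untestable(self):
        a = annotations_from_iois(np.tile([0.1, 0.2], 5))
        ds = build_dataset(a, 1.0)
        with pytest.raises(UntestableDatasetError):
            omission_test(ds, {("C", "C")},
                          InferenceConfig(n_permutations=100, alpha=0.05))

    def test_omission_reduces_counts(self):
        classes = ["C"] * 9 + ["N", "C", "N"]
        a = annotations_from_iois(np.tile([0.1, 0.2], 6)[:11],
                                  classes=classes)
        ds = build_dataset(a, 1.0)
        res = omission_test(ds, {("C", "C")},
                            InferenceConfig(n_permutations=100, alpha=0.05,
                                            rng_seed=0))
        assert res.n_ratios < ds.n_ratios
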
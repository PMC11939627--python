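"""Histogram-shape metrics, KS matrix, classification and group testing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perimotion.config import AnalysisConfig
from perimotion.errors import EmptyHistogramError, InsufficientSamplesError
from perimotion.metrics import (
    build_histogram,
    classify,
    distribution_width_index,
    group_test,
    ks_matrix,
    ks_statistic_bruteforce,
    peak_ratio,
)
from perimotion.phantom import DistributionSpec, generate_disparity_samples


class TestHistogram:
    def test_edges_and_right_inclusive_last_bin(self):
        h = build_histogram([0.0, 0.5, 1.0], n_bins=2)
        np.testing.assert_array_equal(h.counts, [1, 2])
        np.testing.assert_allclose(h.edges, [0.0, 0.5, 1.0])

    def test_counts_conserve_samples(self):
        rng = np.random.default_rng(0)
        samples = rng.random(1234)
        h = build_histogram(samples, n_bins=100)
        assert h.n_samples == 1234

    def test_uniform_samples_fill_bins_binomially(self):
        rng = np.random.default_rng(1)
        h = build_histogram(rng.random(10_000), n_bins=100)
        sd = math.sqrt(10_000 * 0.01 * 0.99)
        assert np.all(np.abs(h.counts - 100) <= 5 * sd)

    def test_empty_rejected(self):
        with pytest.raises(EmptyHistogramError):
            build_histogram([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([0.2, 1.2])


class TestPeakRatio:
    def test_flat_distribution_gives_one(self):
        h = build_histogram(np.linspace(0.005, 0.995, 100), n_bins=10)
        assert peak_ratio(h) == 1.0

    def test_direct_evaluation_small_histogram(self):
        # counts (8, 4, 2, 1) over 4 bins; alpha = 25% -> bin index 1
        samples = np.concatenate([
            np.full(8, 0.1), np.full(4, 0.3), np.full(2, 0.6), np.full(1, 0.9),
        ])
        h = build_histogram(samples, n_bins=4, alpha_percent=25.0)
        assert h.alpha_bin_index == 1
        assert peak_ratio(h) == pytest.approx(2.0)

    def test_sharp_decay_exceeds_adhesion_regime(self):
        samples = generate_disparity_samples(
            DistributionSpec("adhesion", n_samples=5000, decay_rate=40.0, rng_seed=0)
        )
        h = build_histogram(samples, n_bins=100, alpha_percent=25.0)
        assert peak_ratio(h) >= 100.0

    def test_empty_alpha_bin_guarded(self):
        h = build_histogram(np.full(50, 0.005), n_bins=100)
        assert h.h_alpha == 0
        assert peak_ratio(h) == 50.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000), reps=st.integers(2, 9))
    def test_invariant_under_uniform_count_rescaling(self, seed, reps):
        rng = np.random.default_rng(seed)
        samples = rng.random(300)
        h1 = build_histogram(samples, n_bins=20)
        h2 = build_histogram(np.tile(samples, reps), n_bins=20)
        if h1.h_alpha > 0:  # the zero-count guard intentionally breaks scaling
            assert peak_ratio(h2) == pytest.approx(peak_ratio(h1))
        assert distribution_width_index(h2) == distribution_width_index(h1)


class TestDWI:
    def test_all_bins_occupied(self):
        h = build_histogram(np.linspace(0.05, 0.95, 200), n_bins=10)
        assert distribution_width_index(h) == 1.0

    def test_direct_small_case(self):
        samples = [0.1, 0.1, 0.1, 0.6]  # counts {3, 0, 1, 0} over 4 bins
        h = build_histogram(samples, n_bins=4)
        np.testing.assert_array_equal(h.counts, [3, 0, 1, 0])
        assert distribution_width_index(h) == pytest.approx(0.5)

    def test_single_occupied_bin_of_hundred(self):
        h = build_histogram(np.full(20, 0.505), n_bins=100)
        assert distribution_width_index(h) == pytest.approx(0.01)

    def test_nonincreasing_under_concentration(self):
        # nested family: shrinking the spread never occupies new bins
        rng = np.random.default_rng(3)
        base = rng.normal(0.5, 1.0, 4000)
        last = 1.0
        for scale in (0.3, 0.2, 0.1, 0.05, 0.01):
            samples = np.clip(0.5 + base * scale, 0.0, 1.0)
            dwi = distribution_width_index(build_histogram(samples, n_bins=100))
            assert dwi <= last + 1e-12
            last = dwi


class TestKSMatrix:
    def test_identical_samples_give_zero(self):
        s = np.random.default_rng(4).random(50)
        ks = ks_matrix([s] * 9)
        np.testing.assert_array_equal(ks.d, np.zeros((9, 9)))

    def test_disjoint_supports_give_one(self):
        ks = ks_matrix([np.array([0.1, 0.2]), np.array([0.8, 0.9])])
        assert ks.d[0, 1] == 1.0

    def test_interleaved_two_point_samples(self):
        ks = ks_matrix([np.array([0.1, 0.5]), np.array([0.3, 0.7])])
        assert ks.d[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        ks = ks_matrix([rng.random(30 + k) for k in range(9)])
        np.testing.assert_array_equal(ks.d, ks.d.T)
        np.testing.assert_array_equal(np.diag(ks.d), np.zeros(9))
        assert np.all((ks.d >= 0) & (ks.d <= 1))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n1=st.integers(1, 40), n2=st.integers(1, 40))
    def test_statistic_equals_bruteforce_sup(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        x = rng.random(n1)
        y = np.round(rng.random(n2), 1)  # coarse values provoke ties
        ks = ks_matrix([x, y])
        assert ks.d[0, 1] == pytest.approx(ks_statistic_bruteforce(x, y), abs=1e-12)

    def test_empty_phase_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            ks_matrix([np.array([0.1]), np.array([])])


class TestClassification:
    @pytest.mark.parametrize(
        "pr, dwi, expected",
        [
            (120.0, 0.25, "adhesion"),
            (30.0, 0.50, "non-adhesion"),
            (70.0, 0.35, "indeterminate"),
            (120.0, 0.50, "indeterminate"),  # high PR but broad distribution
            (30.0, 0.25, "indeterminate"),   # concentrated but low PR
        ],
    )
    def test_threshold_rule(self, pr, dwi, expected):
        assert classify(pr, dwi) == expected

    def test_custom_thresholds_respected(self):
        cfg = AnalysisConfig(pr_adhesion_threshold=10.0, dwi_adhesion_threshold=0.9)
        assert classify(20.0, 0.5, cfg) == "adhesion"


class TestGroupTest:
    def test_identical_groups_give_p_one(self):
        with pytest.warns(UserWarning, match="all-tied"):
            assert group_test([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_fully_separated_seven_vs_thirteen_exact(self):
        a = np.linspace(100, 150, 7)
        b = np.linspace(20, 50, 13)
        expected = 2.0 * math.factorial(7) * math.factorial(13) / math.factorial(20)
        assert group_test(a, b) == pytest.approx(expected, rel=1e-9)

    def test_synthetic_cohort_separates_below_percent(self):
        from perimotion.phantom import generate_cohort
        from perimotion.pipeline import metrics_for_samples

        cases = generate_cohort(7, 13)
        prs = {"adhesion": [], "non-adhesion": []}
        for case in cases:
            prs[case.label].append(metrics_for_samples(case.samples).pr)
        assert group_test(prs["adhesion"], prs["non-adhesion"]) < 0.01

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_test([1.0], [2.0, 3.0])
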
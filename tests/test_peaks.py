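import numpy as np
import pandas as pd
import pytest

from peptidiag.peaks import (
    FeatureBin,
    Peak,
    PeakList,
    align_peaks,
    build_feature_matrix,
    detect_peaks,
    differential_screen,
    estimate_noise,
    filter_matrix_clusters,
)
from peptidiag.preprocess import smooth_savitzky_golay
from peptidiag.simulate import generate_spectrum, zero_baseline
from peptidiag.spectra import Spectrum, default_grid

from .conftest import synthetic_matrix
from .oracles import bins_as_sets, exhaustive_align, random_alignment_instance


def pl(sample_id, *mz_area):
    return PeakList(
        sample_id=sample_id,
        peaks=[Peak(mz=m, area=a, snr=10.0, sample_id=sample_id) for m, a in mz_area],
    )


class TestNoiseEstimate:
    def test_constant_intensity_gives_zero(self):
        s = Spectrum(mz=1000 + np.arange(500.0), intensity=np.full(500, 7.0))
        assert np.all(estimate_noise(s, 100.0) == 0.0)

    def test_gaussian_noise_scale_recovered(self):
        rng = np.random.default_rng(1)
        sigma = 3.0
        s = Spectrum(mz=1000 + 0.5 * np.arange(10000.0),
                     intensity=100 + rng.normal(0, sigma, 10000))
        est = np.median(estimate_noise(s, 200.0))
        assert est == pytest.approx(sigma, rel=0.15)

    def test_clipped_noise_scale_recovered(self):
        """Zero-clipping (as after baseline subtraction) must not bias the
        estimate: quantiles above the median are unaffected."""
        rng = np.random.default_rng(2)
        sigma = 3.0
        s = Spectrum(mz=1000 + 0.5 * np.arange(10000.0),
                     intensity=np.clip(rng.normal(0, sigma, 10000), 0, None))
        est = np.median(estimate_noise(s, 200.0))
        assert est == pytest.approx(sigma, rel=0.2)

    def test_window_wider_than_spectrum_falls_back_to_global(self):
        s = Spectrum(mz=np.array([1000.0, 1500.0, 2000.0]),
                     intensity=np.array([1.0, 2.0, 3.0]))
        est = estimate_noise(s, 10000.0)
        assert len(np.unique(est)) == 1

    def test_window_below_grid_step_rejected(self):
        s = Spectrum(mz=1000 + np.arange(10.0), intensity=np.ones(10))
        with pytest.raises(ValueError):
            estimate_noise(s, 0.5)


class TestDetectPeaks:
    def test_three_clean_gaussians_found(self):
        grid = default_grid(1000, 5000, 0.5)
        truth = [(2000.0, 300.0, 1.5), (3000.0, 250.0, 1.5), (4000.0, 350.0, 1.5)]
        s = generate_spectrum(truth, zero_baseline(), noise_sd=0.5,
                              drift_ppm=0.0, tic_scale=1.0, grid=grid, seed=3)
        # detection operates on preprocessed (smoothed) spectra; a 5-sigma
        # threshold keeps the tail of ~2000 correlated noise maxima out
        found = detect_peaks(smooth_savitzky_golay(s), snr_min=5.0)
        assert len(found) == 3
        for (m, _, _), p in zip(truth, found.peaks):
            assert abs(p.mz - m) <= 0.5

    def test_all_zero_spectrum_yields_empty_list(self):
        s = Spectrum(mz=1000 + np.arange(1000.0), intensity=np.zeros(1000))
        assert len(detect_peaks(s)) == 0

    def test_pure_noise_false_positive_rate_is_small(self):
        rng = np.random.default_rng(4)
        grid = default_grid()
        s = Spectrum(mz=grid, intensity=np.clip(rng.normal(0, 2.0, grid.size), 0, None))
        found = detect_peaks(s, snr_min=3.0)
        assert len(found) < 0.05 * grid.size


class TestMatrixClusterFilter:
    def test_artifact_match_inside_region_removed(self):
        out = filter_matrix_clusters(pl("a", (1740.2, 5.0)), [1740.0], tol_ppm=2500)
        assert len(out) == 0

    def test_real_peak_inside_region_retained(self):
        out = filter_matrix_clusters(pl("a", (1515.83, 5.0)), [1740.0], tol_ppm=2500)
        assert len(out) == 1

    def test_artifact_value_outside_region_not_applied(self):
        out = filter_matrix_clusters(pl("a", (2500.0, 5.0)), [2500.0], tol_ppm=2500)
        assert len(out) == 1


class TestAlignment:
    def test_two_peaks_within_tolerance_share_a_bin(self):
        bins = align_peaks([pl("a", (3000.0, 10.0)), pl("b", (3003.0, 10.0))])
        assert len(bins) == 1
        assert bins[0].support == 1.0

    def test_two_peaks_beyond_tolerance_split(self):
        bins = align_peaks([pl("a", (3000.0, 10.0)), pl("b", (3040.0, 10.0))])
        assert len(bins) == 2

    def test_empty_input_gives_empty_output(self):
        assert align_peaks([pl("a"), pl("b")]) == []

    def test_members_within_tolerance_of_consensus(self, medium_features):
        _, fm, _ = medium_features
        # re-derive bins from a small slice to keep the check direct
        lists = [
            pl("a", (3000.0, 5.0), (5000.0, 3.0)),
            pl("b", (3004.0, 8.0), (5008.0, 2.0)),
            pl("c", (2996.0, 2.0)),
        ]
        for b in align_peaks(lists):
            for _, p in b.members:
                assert abs(p.mz - b.consensus_mz) / b.consensus_mz * 1e6 <= 2500

    def test_sample_order_invariance(self):
        lists = [random_alignment_instance(s) for s in (11,)][0]
        a = bins_as_sets(align_peaks(lists))
        b = bins_as_sets(align_peaks(lists[::-1]))
        assert a == b

    def test_global_intensity_scaling_invariance(self):
        lists = random_alignment_instance(21)
        scaled = [
            PeakList(
                sample_id=l.sample_id,
                peaks=[Peak(p.mz, p.area * 37.0, p.snr, p.sample_id) for p in l.peaks],
            )
            for l in lists
        ]
        assert bins_as_sets(align_peaks(lists)) == bins_as_sets(align_peaks(scaled))

    @pytest.mark.parametrize("seed", range(0, 20))
    def test_matches_exhaustive_partition_small_instances(self, seed):
        lists = random_alignment_instance(seed)
        got = bins_as_sets(align_peaks(lists))
        want = exhaustive_align(lists, 2500.0)
        assert got == want


class TestFeatureMatrix:
    def bins(self):
        return [
            FeatureBin(3000.0, [("a", Peak(3000.0, 10.0, 5.0, "a")),
                                ("b", Peak(3001.0, 20.0, 5.0, "b"))], 1.0),
            FeatureBin(4000.0, [("a", Peak(4000.0, 10.0, 5.0, "a"))], 0.5),
            FeatureBin(5000.0, [("a", Peak(5000.0, 20.0, 5.0, "a")),
                                ("b", Peak(5001.0, 30.0, 5.0, "b"))], 1.0),
        ]

    def test_zero_fill(self):
        fm = build_feature_matrix(self.bins(), ["a", "b"], fill="zero")
        assert fm.values.loc["b", 4000.0] == 0.0
        assert fm.fill_mask.loc["b", 4000.0]

    def test_interpolate_fill_uses_flanking_mean(self):
        fm = build_feature_matrix(self.bins(), ["a", "b"], fill="interpolate")
        assert fm.values.loc["b", 4000.0] == pytest.approx((20.0 + 30.0) / 2)

    def test_interpolate_fill_edge_falls_back_to_zero(self):
        bins = self.bins()[:2]
        bins[1] = FeatureBin(4000.0, [("b", Peak(4000.0, 5.0, 5.0, "b"))], 0.5)
        bins.insert(0, FeatureBin(2000.0, [("b", Peak(2000.0, 5.0, 5.0, "b"))], 0.5))
        fm = build_feature_matrix(bins, ["a", "b"], fill="interpolate")
        assert fm.values.loc["a", 2000.0] == 0.0

    def test_duplicate_sample_in_bin_rejected(self):
        bad = [FeatureBin(3000.0, [("a", Peak(3000.0, 1.0, 5.0, "a")),
                                   ("a", Peak(3001.0, 1.0, 5.0, "a"))], 1.0)]
        with pytest.raises(ValueError):
            build_feature_matrix(bad, ["a"])

    def test_zero_fill_row_sums_bounded_by_detected_area(self):
        fm = build_feature_matrix(self.bins(), ["a", "b"], fill="zero")
        assert fm.values.loc["a"].sum() <= 10.0 + 10.0 + 20.0 + 1e-9


class TestDifferentialScreen:
    def test_identical_class_means_give_zero_log2fc(self):
        m = synthetic_matrix(n_per_class=50, n_features=5, effect_features=(),
                             seed=1, cv=1e-9)
        t = differential_screen(m).table
        assert np.abs(t.log2fc).max() < 1e-3

    def test_planted_log2fc_recovered_at_study_scale(self, medium_features):
        """Planted |log2fc|=1 peaks estimated within 0.1 at n=200/200."""
        cfg, fm, truth = medium_features
        t = differential_screen(fm).table
        fcs = {p.mz: p.log2fc for p in cfg.peak_panel}
        for mz in truth.discriminative_mz:
            if abs(fcs[mz]) != 1.0:
                continue
            j = np.argmin(np.abs(t.mz.to_numpy() - mz))
            assert abs(t.mz[j] - mz) / mz * 1e6 < 2500
            assert t.log2fc[j] == pytest.approx(fcs[mz], abs=0.1)

    def test_top_k_selectors(self):
        m = synthetic_matrix(n_per_class=30, n_features=40, seed=2)
        dt = differential_screen(m)
        top = dt.top_k_by_p(20)
        assert len(top) == 20
        assert np.all(np.diff(top.p_value.to_numpy()) >= 0)
        assert len(dt.top_k_by_abs_log2fc(20)) == 20

    def test_bh_q_monotone_in_p_and_bounded(self):
        m = synthetic_matrix(n_per_class=40, n_features=60, seed=3)
        t = differential_screen(m).table.sort_values("p_value")
        assert np.all(np.diff(t.q_value.to_numpy()) >= -1e-12)
        assert t.q_value.max() <= 1.0

    def test_small_class_rejected(self):
        m = synthetic_matrix(n_per_class=30, n_features=5, seed=4)
        m.labels[:] = "TC"
        m.labels.iloc[0] = "HC"
        with pytest.raises(ValueError):
            differential_screen(m)

    def test_mannwhitney_variant_agrees_on_strong_effects(self):
        m = synthetic_matrix(n_per_class=60, n_features=10,
                             effect_features=(0,), log2fc=2.0, seed=5)
        w = differential_screen(m, test="welch").table
        u = differential_screen(m, test="mannwhitney").table
        assert w.p_value[0] < 1e-6 and u.p_value[0] < 1e-6
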
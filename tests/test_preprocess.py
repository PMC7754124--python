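import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesiml.model import (
    Acquisition,
    FragmentSpectrum,
    PeakList,
    SampleRecord,
    ValidationError,
)
from pesiml.preprocess import (
    align_peaks,
    centroid,
    preprocess_cohort,
    split_fragments,
    tic_normalize,
)

from conftest import random_feature_matrix, single_linkage_bins

SAMPLE = SampleRecord("S1", "P1", "HCC", "HCC_cohort")


def _acq(times, intensities, axis=None):
    intensities = np.asarray(intensities, dtype=float)
    axis = axis if axis is not None else 100.0 + 0.1 * np.arange(intensities.shape[1])
    return Acquisition(sample=SAMPLE, mz_axis=axis, times=times, intensities=intensities)


class TestSplitFragments:
    def test_default_split_keeps_10_of_12_windows(self):
        rng = np.random.default_rng(0)
        acq = _acq(np.arange(120.0), rng.uniform(0, 10, size=(120, 4)))
        frags = split_fragments(acq)
        assert len(frags) == 10
        assert all(f.n_scans_averaged == 10 for f in frags)
        assert [f.fragment_index for f in frags] == list(range(10))

    def test_constant_scans_average_to_constant(self):
        v = np.array([1.0, 2.0, 3.0])
        acq = _acq(np.arange(120.0), np.tile(v, (120, 1)))
        for f in split_fragments(acq):
            np.testing.assert_allclose(f.intensities, v)

    def test_fragment_is_bruteforce_window_mean(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0, 100, size=(120, 6))
        acq = _acq(np.arange(120.0), y)
        frag3 = split_fragments(acq)[3]
        expected = y[(np.arange(120) >= 30) & (np.arange(120) < 40)].mean(axis=0)
        np.testing.assert_allclose(frag3.intensities, expected)

    def test_scans_partition_across_fragments(self):
        # counting scans over all kept windows covers each scan at most once
        times = np.sort(np.random.default_rng(1).uniform(0, 119.9, 57))
        acq = _acq(times, np.ones((57, 3)))
        frags = split_fragments(acq)
        total = sum(f.n_scans_averaged for f in frags)
        assert total == np.sum(times < 100.0)

    def test_empty_kept_window_names_window(self):
        acq = _acq(np.array([0.0, 1.0, 25.0]), np.ones((3, 3)))
        with pytest.raises(ValidationError, match="window 1"):
            split_fragments(acq)


def _gaussian_fragment(centres, heights, sigma=0.15, axis_lo=490.0, axis_hi=510.0):
    axis = np.arange(axis_lo, axis_hi, 0.1)
    y = np.zeros_like(axis)
    for c, h in zip(centres, heights):
        y += h * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
    return FragmentSpectrum(
        sample_id="S1", fragment_index=0, mz_axis=axis, intensities=y, n_scans_averaged=10
    )


class TestCentroid:
    def test_single_symmetric_bump_centroid(self):
        frag = _gaussian_fragment([500.0], [1000.0])
        peaks = centroid(frag)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 500.0) <= 0.05

    def test_flat_spectrum_yields_empty_list(self):
        axis = np.arange(100.0, 101.0, 0.1)
        frag = FragmentSpectrum(
            sample_id="S1", fragment_index=0, mz_axis=axis,
            intensities=np.full(axis.size, 7.0), n_scans_averaged=1,
        )
        assert len(centroid(frag)) == 0

    def test_all_zero_fragment_yields_empty_list(self):
        axis = np.arange(100.0, 101.0, 0.1)
        frag = FragmentSpectrum(
            sample_id="S1", fragment_index=0, mz_axis=axis,
            intensities=np.zeros(axis.size), n_scans_averaged=1,
        )
        assert len(centroid(frag)) == 0

    def test_min_rel_intensity_suppresses_small_bump(self):
        frag = _gaussian_fragment([497.0, 502.0], [1000.0, 100.0])
        peaks = centroid(frag, noise_k=0.0, min_rel_intensity=0.2)
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 497.0) <= 0.05
        # lowering the relative threshold recovers the second bump
        both = centroid(frag, noise_k=0.0, min_rel_intensity=0.05)
        assert len(both) == 2


def _peaklist(mzs, intens=None):
    mzs = np.asarray(mzs, dtype=float)
    intens = np.asarray(intens if intens is not None else np.ones_like(mzs), dtype=float)
    order = np.argsort(mzs)
    return PeakList(mz=mzs[order], intensity=intens[order])


class TestAlignPeaks:
    def test_peaks_within_tolerance_share_bin(self):
        fm = align_peaks([_peaklist([150.10]), _peaklist([150.40])], tol_da=0.5)
        assert fm.n_bins == 1
        assert fm.X.shape == (2, 1)

    def test_gap_beyond_tolerance_splits_bins(self):
        fm = align_peaks([_peaklist([100.0, 101.0])], tol_da=0.5)
        assert fm.n_bins == 2

    def test_within_fragment_peaks_summed_and_centroid_weighted(self):
        fm = align_peaks([_peaklist([100.0, 100.3], [1.0, 3.0])], tol_da=0.5)
        assert fm.n_bins == 1
        assert fm.X[0, 0] == 4.0
        assert np.isclose(fm.bin_mz[0], (100.0 * 1 + 100.3 * 3) / 4)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_single_linkage_oracle(self, trial):
        rng = np.random.default_rng(trial)
        for rep in range(30):
            n_lists = rng.integers(2, 8)
            lists = [
                _peaklist(rng.uniform(100, 120, rng.integers(1, 12)))
                for _ in range(n_lists)
            ]
            tol = float(rng.uniform(0.1, 2.0))
            fm = align_peaks(lists, tol)
            pooled = np.sort(np.concatenate([pl.mz for pl in lists]))
            oracle = single_linkage_bins(pooled, tol)
            assert fm.n_bins == len(oracle)
            # bin occupancy: each oracle cluster's total intensity equals column sum
            col_sums = fm.X.sum(axis=0)
            for k, members in enumerate(oracle):
                assert np.isclose(col_sums[k], len(members))

    def test_consecutive_member_gaps_within_tol(self):
        rng = np.random.default_rng(9)
        lists = [_peaklist(rng.uniform(100, 105, 20)) for _ in range(5)]
        tol = 0.3
        pooled = np.sort(np.concatenate([pl.mz for pl in lists]))
        new_bin = np.concatenate([[True], np.diff(pooled) > tol])
        bin_id = np.cumsum(new_bin) - 1
        for b in range(bin_id[-1] + 1):
            member_mz = pooled[bin_id == b]
            if member_mz.size > 1:
                assert np.all(np.diff(member_mz) <= tol)
        # and the implementation produces exactly these bins
        assert align_peaks(lists, tol).n_bins == bin_id[-1] + 1


class TestTicNormalize:
    def test_simple_row(self):
        fm = random_feature_matrix(np.random.default_rng(0), 1, 3)
        fm.X[0] = [2.0, 2.0, 4.0]
        out = tic_normalize(fm)
        np.testing.assert_allclose(out.X[0], [0.25, 0.25, 0.5])
        assert out.normalized

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-6, 1e6))
    def test_idempotent_and_scale_invariant(self, seed, scale):
        fm = random_feature_matrix(np.random.default_rng(seed), 5, 4)
        once = tic_normalize(fm)
        np.testing.assert_allclose(once.X.sum(axis=1), 1.0, atol=1e-9)
        twice = tic_normalize(once)
        np.testing.assert_allclose(twice.X, once.X, atol=1e-9)
        scaled = random_feature_matrix(np.random.default_rng(seed), 5, 4)
        scaled.X = scaled.X * scale
        np.testing.assert_allclose(tic_normalize(scaled).X, once.X, atol=1e-7)

    def test_zero_sum_row_names_fragment(self):
        fm = random_feature_matrix(np.random.default_rng(0), 2, 3)
        fm.X[1] = 0.0
        with pytest.raises(ValidationError, match="fragment 1"):
            tic_normalize(fm)


class TestPreprocessCohort:
    def test_single_sample_gives_10_rows(self, fast_sim):
        from pesiml.simulate import iter_cohort

        acq = next(iter_cohort(fast_sim))
        fm = preprocess_cohort([acq])
        assert fm.n_rows == 10
        assert sorted(fm.row_meta["fragment_index"]) == list(range(10))
        np.testing.assert_allclose(fm.X.sum(axis=1), 1.0, atol=1e-9)

    def test_ten_rows_per_sample(self, fast_cohort):
        manifest, fm = fast_cohort
        counts = fm.row_meta.groupby("sample_id").size()
        assert (counts == 10).all()
        assert fm.n_rows == 10 * len(manifest)

    def test_sample_order_permutation_invariant(self, fast_sim):
        from pesiml.simulate import simulate_cohort

        _, acqs = simulate_cohort(fast_sim)
        fm_fwd = preprocess_cohort(acqs)
        fm_rev = preprocess_cohort(list(reversed(acqs)))
        np.testing.assert_allclose(fm_fwd.bin_mz, fm_rev.bin_mz, atol=1e-12)
        key = ["sample_id", "fragment_index"]
        a = fm_fwd.row_meta.assign(i=range(fm_fwd.n_rows)).sort_values(key)["i"].to_numpy()
        b = fm_rev.row_meta.assign(i=range(fm_rev.n_rows)).sort_values(key)["i"].to_numpy()
        np.testing.assert_allclose(fm_fwd.X[a], fm_rev.X[b], atol=1e-12)
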
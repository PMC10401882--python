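"""Spectral-amplitude (ALFF) and rank-concordance (ReHo) measure correctness."""

import numpy as np
import pytest
from scipy import stats

from harmodp import (
    BandSpec,
    compute_alff,
    compute_reho,
    feature_pipeline,
    generate_timeseries_cohort,
    kendalls_w,
    smooth_gaussian,
    stack_feature_maps,
)

TR = 2.0
T = 256


def centered_cosine(freq_bin: int, amplitude: float = 1.0, t: int = T) -> np.ndarray:
    """Cosine at an exact DFT bin, even about the series midpoint.

    Midpoint symmetry makes the linear-detrend fit exactly zero, so the
    one-sided amplitude at the bin equals ``amplitude`` to rounding error.
    """
    n = np.arange(t)
    return amplitude * np.cos(2 * np.pi * freq_bin * (n - (t - 1) / 2) / t)


def as_volume(series: np.ndarray, shape=(3, 3, 3)) -> np.ndarray:
    return np.broadcast_to(series, shape + series.shape).copy()


class TestAlff:
    def test_constant_series_is_zero(self):
        """DC is excluded, so a constant series has zero ALFF."""
        out = compute_alff(as_volume(np.full(T, 7.0)), TR)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_in_band_exact_bin_amplitude(self):
        """Unit cosine on bin 26 (f≈0.0508 Hz, in band) gives ALFF = 1."""
        a = 1.0
        out = compute_alff(as_volume(centered_cosine(26, a)), TR)
        np.testing.assert_allclose(out, a, atol=1e-9)

    def test_out_of_band_rejected(self):
        """A ~0.2 Hz exact-bin cosine contributes nothing to the 0.01-0.1 band."""
        # bin 102 -> f = 102/(256*2) = 0.19922 Hz, outside the band, no leakage
        out = compute_alff(as_volume(centered_cosine(102)), TR)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_absolute_homogeneity(self):
        rng = np.random.default_rng(0)
        ts = as_volume(rng.normal(size=T))
        base = compute_alff(ts, TR)
        np.testing.assert_allclose(compute_alff(3.7 * ts, TR), 3.7 * base, atol=1e-9)
        np.testing.assert_allclose(compute_alff(-3.7 * ts, TR), 3.7 * base, atol=1e-9)

    def test_band_additivity_disjoint(self):
        """ALFF(0.01-0.05) + ALFF((0.05-0.1]) equals ALFF(0.01-0.1)."""
        rng = np.random.default_rng(1)
        ts = as_volume(rng.normal(size=T))
        whole = compute_alff(ts, TR, BandSpec(0.01, 0.1))
        low = compute_alff(ts, TR, BandSpec(0.01, 0.05), closed="both")
        high = compute_alff(ts, TR, BandSpec(0.05, 0.1), closed="right")
        np.testing.assert_allclose(low + high, whole, rtol=1e-12)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_alff(as_volume(np.zeros(T)), TR, BandSpec(0.01, 0.3))

    def test_dc_excluded_even_when_low_zero(self):
        ts = as_volume(np.full(T, 5.0))
        out = compute_alff(ts, TR, BandSpec(0.0, 0.1), detrend=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_mean_amplitude_and_power_stats(self):
        ts = as_volume(centered_cosine(26))
        band = BandSpec(0.01, 0.1)
        freqs = np.fft.rfftfreq(T, TR)
        nbins = int(np.sum((freqs >= 0.01) & (freqs <= 0.1)))
        mean_amp = compute_alff(ts, TR, band, stat="mean_amplitude")
        np.testing.assert_allclose(mean_amp, 1.0 / nbins, atol=1e-9)
        power = compute_alff(ts, TR, band, stat="sum_power")
        np.testing.assert_allclose(power, 1.0, atol=1e-9)


class TestKendallsW:
    def brute_force_w(self, rank_rows):
        """Direct evaluation of the W formula from printed ranks (no ties)."""
        R = np.sum(rank_rows, axis=0)
        K, t = np.shape(rank_rows)
        S = np.sum((R - R.mean()) ** 2)
        return 12.0 * S / (K**2 * (t**3 - t))

    def test_printed_three_series_example(self):
        """Ranks (1,2,3),(1,2,3),(3,2,1): rank sums (5,6,7), W = 1/9."""
        ranks = [(1, 2, 3), (1, 2, 3), (3, 2, 1)]
        expected = self.brute_force_w(ranks)
        assert expected == pytest.approx(1.0 / 9.0)
        assert kendalls_w(np.asarray(ranks, float)) == pytest.approx(expected)

    def test_identical_series_give_one(self):
        series = np.tile(np.random.default_rng(0).normal(size=40), (5, 1))
        assert kendalls_w(series) == pytest.approx(1.0)

    def test_tie_correction_matches_bruteforce(self):
        """Mid-ranks + tie-corrected denominator on series with repeats."""
        x = np.array([[1.0, 1.0, 2.0, 3.0], [2.0, 2.0, 2.0, 1.0], [1.0, 3.0, 3.0, 2.0]])
        ranks = stats.rankdata(x, axis=1)
        R = ranks.sum(axis=0)
        K, t = x.shape
        S = ((R - R.mean()) ** 2).sum()
        sum_T = 0.0
        for row in x:
            _, counts = np.unique(row, return_counts=True)
            sum_T += float(np.sum(counts**3 - counts))
        expected = 12.0 * S / (K**2 * (t**3 - t) - K * sum_T)
        assert kendalls_w(x) == pytest.approx(expected, abs=1e-12)


class TestReho:
    def test_identical_series_full_concordance(self):
        """Every voxel shares one series: W = 1 everywhere in the mask."""
        series = np.random.default_rng(0).normal(size=64)
        vol = as_volume(series, (4, 4, 4))
        out = compute_reho(vol, neighborhood=27)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    @pytest.mark.parametrize("nb", [7, 19, 27])
    def test_matches_kendalls_w_per_voxel(self, nb):
        """Grid ReHo equals kendalls_w applied to each voxel's neighbor stack."""
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(4, 3, 5, 64))
        mask = rng.random((4, 3, 5)) > 0.2
        out = compute_reho(vol, mask=mask, neighborhood=nb)
        offs = [
            (i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if abs(i) + abs(j) + abs(k) <= {7: 1, 19: 2, 27: 3}[nb]
        ]
        for x in range(4):
            for y in range(3):
                for z in range(5):
                    if not mask[x, y, z]:
                        assert out[x, y, z] == 0.0
                        continue
                    stackv = [
                        vol[x + i, y + j, z + k]
                        for i, j, k in offs
                        if 0 <= x + i < 4 and 0 <= y + j < 3 and 0 <= z + k < 5
                        and mask[x + i, y + j, z + k]
                    ]
                    if len(stackv) < 2:
                        assert out[x, y, z] == 0.0
                    else:
                        assert out[x, y, z] == pytest.approx(
                            kendalls_w(np.array(stackv)), abs=1e-10
                        )

    def test_monotone_transform_invariance(self):
        """W depends on ranks only: exp() per series leaves the map unchanged."""
        rng = np.random.default_rng(5)
        vol = rng.normal(size=(3, 3, 3, 64))
        np.testing.assert_allclose(
            compute_reho(vol), compute_reho(np.exp(vol)), atol=1e-12
        )

    def test_w_in_unit_interval(self):
        rng = np.random.default_rng(6)
        out = compute_reho(rng.normal(size=(4, 4, 4, 70)))
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_null_mean_matches_permutation_oracle(self):
        """Mean W of independent noise matches a Monte-Carlo estimate of E[W]."""
        rng = np.random.default_rng(7)
        t, K, reps = 200, 27, 300
        w_mc = np.array([kendalls_w(rng.normal(size=(K, t))) for _ in range(reps)])
        vol = rng.normal(size=(8, 8, 8, t))
        out = compute_reho(vol, neighborhood=27)
        interior = out[1:-1, 1:-1, 1:-1]  # voxels with the full 27 neighbors
        se = w_mc.std() / np.sqrt(interior.size) + w_mc.std() / np.sqrt(reps)
        assert abs(interior.mean() - w_mc.mean()) < 4 * se

    def test_isolated_voxel_emits_zero(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        mask[2, 2, 2] = True
        vol = np.random.default_rng(1).normal(size=(3, 3, 3, 64))
        out = compute_reho(vol, mask=mask, neighborhood=7)
        assert out[0, 0, 0] == 0.0 and out[2, 2, 2] == 0.0


class TestSmoothing:
    def test_delta_matches_closed_form_kernel(self):
        fwhm, vs = 4.0, 1.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        sm = smooth_gaussian(vol, fwhm, vs)
        x = np.arange(41) - 20.0
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        np.testing.assert_allclose(sm, expected, atol=1e-6)

    def test_constant_map_preserved(self):
        vol = np.full((8, 8, 8), 3.3)
        np.testing.assert_allclose(smooth_gaussian(vol, 6.0, 3.0), vol, atol=1e-10)

    def test_constant_map_preserved_with_mask(self):
        """Mask-aware renormalization: no edge dilution of a constant map."""
        vol = np.full((8, 8, 8), 2.0)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        sm = smooth_gaussian(vol, 6.0, 3.0, mask=mask)
        np.testing.assert_allclose(sm[mask], 2.0, atol=1e-10)
        np.testing.assert_allclose(sm[~mask], 0.0)

    def test_zero_fwhm_identity(self):
        vol = np.random.default_rng(0).normal(size=(5, 5, 5))
        np.testing.assert_array_equal(smooth_gaussian(vol, 0.0, 3.0), vol)

    def test_bad_voxel_size_rejected(self):
        with pytest.raises(ValueError, match="voxel size"):
            smooth_gaussian(np.zeros((3, 3, 3)), 6.0, 0.0)


class TestPipeline:
    def test_alff_zero_fwhm_reduces_to_compute_alff(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(3, 3, 3, T))
        out = feature_pipeline(vol, TR, "alff", fwhm_mm=0.0)
        np.testing.assert_array_equal(out, compute_alff(vol, TR))

    def test_reho_smoothing_order_matters(self):
        """Smooth-after (the convention) differs from smooth-before on two blobs."""
        rng = np.random.default_rng(1)
        vol = np.zeros((5, 5, 5, 64))
        vol[:2] = rng.normal(size=(2, 5, 5, 64))
        vol[2:] = rng.normal(scale=5.0, size=(3, 5, 5, 64))
        convention = feature_pipeline(vol, TR, "reho", fwhm_mm=6.0, voxel_size_mm=3.0)
        sm = np.stack(
            [smooth_gaussian(vol[..., j], 6.0, 3.0) for j in range(64)], axis=-1
        )
        other_order = compute_reho(sm)
        assert not np.allclose(convention, other_order, atol=1e-3)

    def test_site_amplitude_ordering_recovered(self):
        """Per-site mean ALFF follows the injected in-band amplitude ordering."""
        vols, cov = generate_timeseries_cohort(
            (3, 3, 3), 128, TR, {"A": 0.5, "B": 1.0, "C": 2.0},
            n_per_site=3, components=((0.05, 1.0),), noise_sd=0.05, seed=4,
        )
        mask = np.ones((3, 3, 3), bool)
        maps = [feature_pipeline(v, TR, "alff", fwhm_mm=0.0) for v in vols]
        fm = stack_feature_maps(maps, mask, cov.subject_ids, modality="ALFF")
        codes = cov.site_codes()
        means = [fm.values[codes == l].mean() for l in range(3)]
        assert means[0] < means[1] < means[2]
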
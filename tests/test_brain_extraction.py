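"""Otsu split, peak finding, and the morphological skull-stripping chain."""

import numpy as np
import pytest
from scipy import ndimage

from brainseg.brain_extraction import (
    IntensityHistogram,
    PeakTriple,
    StructuringElement,
    extract_brain,
    find_peaks,
    intensity_histogram,
    largest_connected_component,
    otsu_threshold,
)
from brainseg.volumes_io import Volume


def brute_otsu(counts):
    """Exhaustive between-class variance maximization over all thresholds."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    levels = np.arange(counts.size)
    best_t, best_v = None, -1.0
    for t in range(counts.size - 1):
        w0 = counts[: t + 1].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / counts[: t + 1].sum()
        mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / counts[t + 1 :].sum()
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:  # strict: ties keep the lowest threshold
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    def test_two_spike_histogram_separates_the_spikes(self):
        counts = np.zeros(256)
        counts[40] = 1000
        counts[160] = 1000
        t = otsu_threshold(IntensityHistogram(counts))
        assert 40 <= t < 160

    def test_matches_exhaustive_search_on_random_histograms(self, rng):
        for _ in range(30):
            counts = rng.integers(0, 50, size=64).astype(float)
            if np.count_nonzero(counts) < 2:
                continue
            hist = IntensityHistogram(counts)
            assert otsu_threshold(hist) == brute_otsu(counts)

    def test_single_bin_histogram_rejected(self):
        counts = np.zeros(16)
        counts[5] = 10
        with pytest.raises(ValueError):
            otsu_threshold(IntensityHistogram(counts))


class TestFindPeaks:
    def test_noiseless_phantom_modes_recovered(self):
        # three sharp modes at the canonical CSF/GM/WM gray levels
        counts = np.zeros(256)
        for mu, mass in ((40, 4000), (110, 6000), (160, 5000)):
            x = np.arange(256)
            counts += mass * np.exp(-0.5 * ((x - mu) / 2.0) ** 2)
        peaks = find_peaks(IntensityHistogram(counts), bandwidth=2.0)
        assert not peaks.csf_is_fallback
        assert (peaks.mu_csf, peaks.mu_gm, peaks.mu_wm) == (40, 110, 160)

    def test_two_mode_histogram_uses_valley_fallback(self):
        x = np.arange(256)
        counts = 6000 * np.exp(-0.5 * ((x - 110) / 8.0) ** 2)
        counts += 5000 * np.exp(-0.5 * ((x - 170) / 8.0) ** 2)
        counts[30:] += 100  # low shoulder, no CSF peak
        peaks = find_peaks(IntensityHistogram(counts), bandwidth=2.0)
        assert peaks.csf_is_fallback
        assert peaks.mu_csf < peaks.mu_gm == 110
        assert peaks.mu_wm == 170

    def test_order_strictly_increasing_on_random_trimodal_histograms(self, rng):
        x = np.arange(256)
        for _ in range(10):
            mus = np.sort(rng.choice(np.arange(30, 230), size=3, replace=False))
            if np.diff(mus).min() < 30:
                continue
            counts = sum(
                rng.uniform(2000, 8000) * np.exp(-0.5 * ((x - m) / 5.0) ** 2)
                for m in mus
            )
            p = find_peaks(IntensityHistogram(counts), bandwidth=2.0)
            assert p.mu_csf < p.mu_gm < p.mu_wm

    def test_unimodal_histogram_raises(self):
        x = np.arange(64)
        counts = np.exp(-0.5 * ((x - 30) / 5.0) ** 2) * 1000
        with pytest.raises(ValueError, match="bandwidth"):
            find_peaks(IntensityHistogram(counts))


class TestMorphology:
    def test_sphere_offsets_symmetric_and_contain_origin(self):
        se = StructuringElement(3)
        offs = {tuple(o) for o in se.offsets}
        assert (0, 0, 0) in offs
        assert all((-a, -b, -c) in offs for a, b, c in offs)
        assert all(a * a + b * b + c * c <= 9 for a, b, c in offs)

    def test_erosion_dilation_match_set_definition_oracle(self, rng):
        # erosion: every offset lands inside; dilation: some offset hits
        se = StructuringElement(2)
        fp = se.footprint
        offsets = se.offsets
        for _ in range(5):
            mask = rng.random((12, 12, 12)) > 0.6
            eroded = ndimage.binary_erosion(mask, structure=fp)
            dilated = ndimage.binary_dilation(mask, structure=fp)
            idx = rng.integers(2, 10, size=(60, 3))
            for x, y, z in idx:
                inside = all(
                    0 <= x + a < 12 and 0 <= y + b < 12 and 0 <= z + c < 12
                    and mask[x + a, y + b, z + c]
                    for a, b, c in offsets
                )
                assert eroded[x, y, z] == inside
                hits = any(
                    0 <= x + a < 12 and 0 <= y + b < 12 and 0 <= z + c < 12
                    and mask[x + a, y + b, z + c]
                    for a, b, c in offsets
                )
                assert dilated[x, y, z] == hits

    def test_opening_anti_extensive_dilation_extensive(self, rng):
        fp = StructuringElement(2).footprint
        for _ in range(5):
            mask = rng.random((14, 14, 14)) > 0.45
            opened = ndimage.binary_opening(mask, structure=fp)
            assert not np.any(opened & ~mask)  # opened subset of mask
            dilated = ndimage.binary_dilation(mask, structure=fp)
            assert not np.any(mask & ~dilated)  # mask subset of dilated

    def test_lcc_keeps_the_larger_blob_exactly(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[2:12, 2:12, 2:12] = True  # 1000 voxels
        mask[25:30, 25:33, 25:30] = True  # 200 voxels
        lcc = largest_connected_component(mask)
        expect = np.zeros_like(mask)
        expect[2:12, 2:12, 2:12] = True
        np.testing.assert_array_equal(lcc, expect)


class TestExtractBrain:
    def test_mask_multiplication_identity(self, clean_phantom):
        gray = clean_phantom.volume
        hist = intensity_histogram(gray, mask=gray.data > 0)
        peaks = find_peaks(hist)
        i2, m1 = extract_brain(gray, peaks, n_dilations=2)
        assert np.all(i2.data[~m1] == 0)
        np.testing.assert_array_equal(i2.data[m1], gray.data[m1])

    def test_mask_grows_with_each_dilation(self, clean_phantom):
        gray = clean_phantom.volume
        peaks = find_peaks(intensity_histogram(gray, mask=gray.data > 0))
        sizes = []
        for nd in (0, 1, 2):
            _, m1 = extract_brain(gray, peaks, n_dilations=nd)
            sizes.append(m1.sum())
        assert sizes[0] < sizes[1] < sizes[2]

    def test_opening_removes_the_thin_bridges(self, clean_phantom):
        gray = clean_phantom.volume
        peaks = find_peaks(intensity_histogram(gray, mask=gray.data > 0))
        _, m1 = extract_brain(gray, peaks, n_dilations=0)
        skull = clean_phantom.truth.labels == 4
        # with no dilation the mask must not reach the skull shell at all
        assert not np.any(m1 & skull)

    def test_empty_mask_after_opening_raises(self):
        data = np.zeros((48, 48, 48))
        data[20:22, 20:22, 20:22] = 200.0  # far smaller than the opening ball
        vol = Volume(data)
        peaks = PeakTriple(mu_csf=40, mu_gm=110, mu_wm=160, sigmas=(5, 5, 5))
        with pytest.raises(ValueError, match="alpha"):
            extract_brain(vol, peaks)
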
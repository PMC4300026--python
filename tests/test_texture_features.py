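"""GLCM counting, Haralick statistics, and the 130-feature extraction."""

import numpy as np
import pytest

from brainseg.texture_features import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    GLCM,
    QuantizedVolume,
    extract_features,
    glcm_3d,
    haralick,
    quantize,
)
from brainseg.volumes_io import Volume


def brute_glcm(qdata, window, direction, distance, n):
    """Triple-loop pair counter, symmetrized: the definitional oracle."""
    (x0, x1), (y0, y1), (z0, z1) = window
    off = tuple(distance * d for d in direction)
    C = np.zeros((n, n))
    for x in range(x0, x1):
        for y in range(y0, y1):
            for z in range(z0, z1):
                xx, yy, zz = x + off[0], y + off[1], z + off[2]
                if x0 <= xx < x1 and y0 <= yy < y1 and z0 <= zz < z1:
                    a, b = qdata[x, y, z], qdata[xx, yy, zz]
                    if a >= 0 and b >= 0:
                        C[a, b] += 1
    return C + C.T


def reference_haralick(P):
    """Independent straightforward re-implementation of the 13 statistics.

    Scalar loops, no shared helpers with the package code path.
    """
    n = P.shape[0]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def h(vals):
        return -sum(v * np.log2(v) for v in np.ravel(vals) if v > 0)

    contrast = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    asm = (P**2).sum()
    variance = sum((i - mu_x) ** 2 * P[i, j] for i in range(n) for j in range(n))
    corr = 0.0
    if sx * sy > 1e-12:
        corr = (
            sum(i * j * P[i, j] for i in range(n) for j in range(n)) - mu_x * mu_y
        ) / (sx * sy)
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    sum_ent = h(p_sum)
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    mu_d = sum(k * p_diff[k] for k in range(n))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    ent = h(P)
    diff_ent = h(p_diff)
    hx, hy = h(px), h(py)
    hxy1 = -sum(
        P[i, j] * np.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0 and P[i, j] > 0
    )
    # 0*log0 = 0 also inside HXY1: P=0 terms drop
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - ent))))
    return np.array(
        [contrast, asm, variance, corr, sum_avg, idm, sum_ent, sum_var,
         diff_var, ent, diff_ent, imc1, imc2]
    )


class TestQuantize:
    def test_ramp_splits_into_equal_quarters(self):
        data = np.linspace(0, 255, 64).reshape(4, 4, 4)
        q = quantize(Volume(data), levels=4)
        assert set(np.unique(q.data)) == {0, 1, 2, 3}
        counts = np.bincount(q.data.ravel())
        assert counts.max() - counts.min() <= 1

    def test_monotone_in_intensity(self, rng):
        data = rng.uniform(0, 100, size=(6, 6, 6))
        q = quantize(Volume(data), levels=8)
        flat_v = data.ravel()
        flat_q = q.data.ravel()
        order = np.argsort(flat_v)
        assert np.all(np.diff(flat_q[order]) >= 0)

    def test_identity_on_full_range_integers(self):
        data = np.arange(256, dtype=float).repeat(2)[:256].reshape(4, 8, 8)
        data = np.arange(256, dtype=float).reshape(4, 8, 8)
        q = quantize(Volume(data), levels=256)
        np.testing.assert_array_equal(q.data, data.astype(np.int16))

    def test_constant_volume_maps_to_level_zero(self):
        q = quantize(Volume(np.full((3, 3, 3), 42.0)), levels=16)
        assert np.all(q.data == 0)

    def test_masked_voxels_are_ignored(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = 100.0
        mask = np.ones((4, 4, 4), bool)
        mask[0, 0, 0] = False
        q = quantize(Volume(data), mask=mask, levels=4)
        assert q.data[0, 0, 0] == -1


class TestGLCM:
    def test_constant_window_all_mass_on_origin(self):
        q = QuantizedVolume(np.zeros((5, 5, 5), dtype=np.int16), 4)
        g = glcm_3d(q, ((0, 5), (0, 5), (0, 5)), (0, 0, 1), 1)
        P = g.normalized
        assert P[0, 0] == 1.0

    def test_matches_brute_force_on_random_windows(self, rng):
        q = QuantizedVolume(rng.integers(0, 4, size=(6, 6, 6)).astype(np.int16), 4)
        win = ((1, 6), (0, 5), (1, 5))
        for dist in (1, 2):
            for direction in DIRECTIONS_13:
                g = glcm_3d(q, win, direction, dist)
                bf = brute_glcm(q.data, win, direction, dist, 4)
                np.testing.assert_array_equal(g.counts, bf)

    def test_alternating_pattern_along_z(self):
        data = np.zeros((4, 4, 4), dtype=np.int16)
        data[:, :, 1::2] = 1
        q = QuantizedVolume(data, 2)
        g = glcm_3d(q, ((0, 4), (0, 4), (0, 4)), (0, 0, -1), 1)
        P = g.normalized
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0

    def test_direction_reversal_gives_identical_symmetrized_matrix(self, rng):
        q = QuantizedVolume(rng.integers(0, 5, size=(7, 7, 7)).astype(np.int16), 5)
        win = ((0, 7), (0, 7), (0, 7))
        for direction in DIRECTIONS_13:
            fwd = glcm_3d(q, win, direction, 1)
            rev = glcm_3d(q, win, tuple(-d for d in direction), 1)
            np.testing.assert_array_equal(fwd.counts, rev.counts)

    def test_window_with_no_pairs_flagged(self):
        q = QuantizedVolume(np.zeros((5, 5, 5), dtype=np.int16), 2)
        g = glcm_3d(q, ((0, 1), (0, 1), (0, 1)), (0, 0, 1), 1)
        assert not g.has_pairs
        with pytest.raises(ValueError, match="no valid pairs"):
            _ = g.normalized


class TestHaralick:
    def test_uniform_diagonal_closed_form(self):
        n = 8
        g = GLCM(np.eye(n), (1, 0, 0), 1)
        hv = haralick(g)
        assert hv.contrast == 0.0
        assert hv.angular_second_moment == pytest.approx(1.0 / n)

    def test_two_cell_closed_form(self):
        n = 8
        a, b = 2, 5
        counts = np.zeros((n, n))
        counts[a, b] = 1.0
        counts[b, a] = 1.0  # symmetrized single off-diagonal pair
        hv = haralick(GLCM(counts, (1, 0, 0), 1))
        assert hv.entropy == pytest.approx(1.0)  # two cells at 1/2: 1 bit
        assert hv.contrast == pytest.approx((a - b) ** 2)

    def test_matches_independent_reference_on_random_glcms(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            raw = rng.random((n, n))
            raw = raw + raw.T
            g = GLCM(raw, (1, 0, 0), 1)
            mine = haralick(g).values
            ref = reference_haralick(g.normalized)
            np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_range_invariants_on_random_glcms(self, rng):
        for _ in range(20):
            raw = rng.random((6, 6)) + 1e-6
            raw = raw + raw.T
            hv = haralick(GLCM(raw, (1, 0, 0), 1))
            assert hv.entropy >= 0
            assert 0 < hv.angular_second_moment <= 1
            assert hv.contrast >= 0
            assert np.all(np.isfinite(hv.values))


class TestExtractFeatures:
    def test_feature_vector_has_130_entries(self, rng):
        data = rng.uniform(0, 100, size=(26, 26, 26))
        q = quantize(Volume(data), levels=8)
        feats, clipped = extract_features(q, np.array([[13, 13, 13]]))
        assert feats.shape == (1, 130)
        assert len(FEATURE_NAMES) == 130
        assert not clipped[0]
        assert np.all(np.isfinite(feats))

    def test_duplicate_centers_identical_vectors(self, rng):
        data = rng.uniform(0, 100, size=(16, 16, 16))
        q = quantize(Volume(data), levels=8)
        feats, _ = extract_features(
            q, np.array([[8, 8, 8], [8, 8, 8]]), window_size=9, distances=(1, 2)
        )
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_edge_windows_clipped_and_flagged(self, rng):
        data = rng.uniform(0, 100, size=(16, 16, 16))
        q = quantize(Volume(data), levels=8)
        feats, clipped = extract_features(
            q, np.array([[0, 0, 0], [8, 8, 8]]), window_size=9, distances=(1,)
        )
        assert clipped[0] and not clipped[1]
        assert np.all(np.isfinite(feats))

    def test_isotropic_noise_has_small_directional_spread(self, rng):
        # i.i.d. noise has no preferred direction: the SD-across-directions
        # features must be small relative to their mean counterparts
        data = rng.normal(0, 1, size=(30, 30, 30))
        q = quantize(Volume(data), levels=8)
        feats, _ = extract_features(q, np.array([[15, 15, 15]]), distances=(1,))
        mean_entropy = feats[0, FEATURE_NAMES.index("d1_entropy_mean")]
        sd_entropy = feats[0, FEATURE_NAMES.index("d1_entropy_sd")]
        assert sd_entropy < 0.05 * mean_entropy

    def test_center_outside_volume_rejected(self, rng):
        q = quantize(Volume(rng.random((8, 8, 8))), levels=4)
        with pytest.raises(ValueError, match="inside"):
            extract_features(q, np.array([[8, 0, 0]]))

    def test_batch_agrees_with_per_window_route(self, rng):
        data = rng.uniform(0, 50, size=(14, 14, 14))
        mask = rng.random((14, 14, 14)) > 0.1
        q = quantize(Volume(data), mask=mask, levels=6)
        centers = rng.integers(0, 14, size=(6, 3))
        feats, _ = extract_features(q, centers, window_size=7, distances=(1, 3))
        half = 3
        for ci, (cx, cy, cz) in enumerate(centers):
            win = tuple((int(c) - half, int(c) + half + 1) for c in (cx, cy, cz))
            for di, dist in enumerate((1, 3)):
                per = []
                for direction in DIRECTIONS_13:
                    g = glcm_3d(q, win, direction, dist)
                    per.append(haralick(g).values if g.has_pairs else np.zeros(13))
                per = np.array(per)
                expect = np.empty(26)
                expect[0::2] = per.mean(axis=0)
                expect[1::2] = per.std(axis=0)
                np.testing.assert_allclose(
                    feats[ci, di * 26 : (di + 1) * 26], expect, atol=1e-12
                )
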
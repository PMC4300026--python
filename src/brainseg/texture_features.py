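"""3-D gray-level co-occurrence (Haralick) texture features.

For a quantized volume Q with N gray levels, the co-occurrence matrix for
displacement d = distance * direction counts pairs

    G(i, j) = #{ x : Q(x) = i  and  Q(x + d) = j }

with both endpoints inside the analysis window and unmasked.  Matrices are
always symmetrized (counts plus their transpose), so the 26-neighborhood
reduces to 13 canonical directions (one of each +/- pair).  From each
normalized matrix 13 classical second-order statistics are computed; per
distance the mean and standard deviation of each statistic over the 13
directions give 26 features, and distances 1..5 give the 130-entry feature
vector per voxel of interest (VOI).

Feature vector layout (fixed, see :data:`FEATURE_NAMES`): for each distance
d = 1..5, for each Haralick statistic in :data:`HARALICK_ORDER`, first the
mean then the SD over the 13 directions:
``index = (d-1)*26 + stat_index*2 + (0 for mean, 1 for SD)``.

Windows at the volume edge are clipped, never padded (padding would
fabricate texture) and the affected VOIs are flagged.  Logarithms are base
2 with 0*log0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the batched window pair-counting ~50x
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


from .volumes_io import Volume

__all__ = [
    "DIRECTIONS_13",
    "HARALICK_ORDER",
    "FEATURE_NAMES",
    "QuantizedVolume",
    "GLCM",
    "HaralickVector",
    "quantize",
    "glcm_3d",
    "haralick",
    "extract_features",
    "feature_names",
]

#: canonical half of the 26-neighborhood offsets (one of each +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

HARALICK_ORDER: tuple[str, ...] = (
    "contrast",
    "angular_second_moment",
    "variance",
    "correlation",
    "sum_average",
    "inverse_difference_moment",
    "sum_entropy",
    "sum_variance",
    "difference_variance",
    "entropy",
    "difference_entropy",
    "info_measure_corr_1",
    "info_measure_corr_2",
)

DEFAULT_DISTANCES: tuple[int, ...] = (1, 2, 3, 4, 5)
DEFAULT_WINDOW = 21
DEFAULT_LEVELS = 16


def feature_names(
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
) -> list[str]:
    """The documented feature ordering: d{dist}_{stat}_{mean|sd}."""
    names = []
    for d in distances:
        for stat in HARALICK_ORDER:
            names.append(f"d{d}_{stat}_mean")
            names.append(f"d{d}_{stat}_sd")
    return names


FEATURE_NAMES: list[str] = feature_names()


@dataclass
class QuantizedVolume:
    """Integer grid with values 0..levels-1; -1 marks ignored (masked) voxels."""

    data: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 3:
            raise ValueError("QuantizedVolume requires a 3-D array")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.data.max() >= self.levels or self.data.min() < -1:
            raise ValueError("codes must lie in {-1} union [0, levels-1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def quantize(
    volume: Volume, mask: np.ndarray | None = None, levels: int = DEFAULT_LEVELS
) -> QuantizedVolume:
    """Equal-width quantization of the in-mask intensity range into ``levels``.

    Monotone in intensity; a constant volume maps to level 0 everywhere
    (documented, not an error).  Out-of-mask voxels become -1 (ignored by
    all pair counting).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    data = volume.data
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sel = data[mask]
    if sel.size == 0:
        raise ValueError("mask is empty")
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        q = np.zeros(data.shape, dtype=np.int16)
    else:
        q = np.floor((data - lo) / (hi - lo) * levels).astype(np.int16)
        np.clip(q, 0, levels - 1, out=q)
    q[~mask] = -1
    return QuantizedVolume(data=q, levels=levels)


@dataclass
class GLCM:
    """Symmetrized co-occurrence counts for one (direction, distance)."""

    counts: np.ndarray
    direction: tuple[int, int, int]
    distance: int
    has_pairs: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        self.has_pairs = bool(self.counts.sum() > 0)

    @property
    def normalized(self) -> np.ndarray:
        """Probabilities summing to 1; undefined (raises) when no pair exists."""
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("normalized view undefined: window has no valid pairs")
        return self.counts / total


def _clip_window(
    window: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    shape: tuple[int, int, int],
) -> tuple[tuple[int, int], ...]:
    out = []
    for (lo, hi), s in zip(window, shape):
        out.append((max(int(lo), 0), min(int(hi), s)))
    return tuple(out)


def glcm_3d(
    q: QuantizedVolume,
    window: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    direction: tuple[int, int, int],
    distance: int = 1,
) -> GLCM:
    """Co-occurrence counts over a cubic window (half-open bounds per axis).

    Pairs (x, x + distance*direction) are counted when both endpoints lie
    inside the (volume-clipped) window and neither is masked; the matrix is
    then symmetrized by adding its transpose.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    off = tuple(int(distance * d) for d in direction)
    (x0, x1), (y0, y1), (z0, z1) = _clip_window(window, q.shape)
    n = q.levels
    counts = np.zeros((n, n), dtype=np.float64)
    # source range: x in window and x+off in window
    src = []
    dst = []
    for (lo, hi), o in zip(((x0, x1), (y0, y1), (z0, z1)), off):
        s_lo = max(lo, lo - o)
        s_hi = min(hi, hi - o)
        if s_hi <= s_lo:
            return GLCM(counts, tuple(direction), distance, has_pairs=False)
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo + o, s_hi + o))
    a = q.data[tuple(src)].ravel()
    b = q.data[tuple(dst)].ravel()
    valid = (a >= 0) & (b >= 0)
    if valid.any():
        flat = np.bincount(a[valid].astype(np.int64) * n + b[valid], minlength=n * n)
        counts = flat.reshape(n, n).astype(np.float64)
    counts = counts + counts.T
    return GLCM(counts=counts, direction=tuple(direction), distance=distance)


@dataclass
class HaralickVector:
    """The 13 statistics in :data:`HARALICK_ORDER`; ``degenerate`` flags
    features that were set to 0 because their denominators vanished."""

    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(HARALICK_ORDER),):
            raise ValueError("values must have one entry per Haralick statistic")

    def __getattr__(self, name: str):
        try:
            return self.values[HARALICK_ORDER.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HARALICK_ORDER, self.values.tolist()))


def _plog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _haralick_batch(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized statistics for a stack of normalized symmetric GLCMs.

    Parameters: P of shape (M, N, N), each slice summing to 1.
    Returns (features (M, 13), degenerate flags (M,)).
    """
    M, n, _ = P.shape
    i = np.arange(n, dtype=np.float64)
    diff2 = (i[:, None] - i[None, :]) ** 2
    ij = i[:, None] * i[None, :]

    px = P.sum(axis=2)  # (M, n)
    py = P.sum(axis=1)
    mu_x = px @ i
    mu_y = py @ i
    var_x = ((i[None, :] - mu_x[:, None]) ** 2 * px).sum(axis=1)
    var_y = ((i[None, :] - mu_y[:, None]) ** 2 * py).sum(axis=1)

    # marginal distributions of i+j (0..2n-2) and |i-j| (0..n-1)
    ksum = (i[:, None] + i[None, :]).astype(int).ravel()
    kdiff = np.abs(i[:, None] - i[None, :]).astype(int).ravel()
    Pf = P.reshape(M, n * n)
    sum_onehot = np.zeros((n * n, 2 * n - 1))
    sum_onehot[np.arange(n * n), ksum] = 1.0
    diff_onehot = np.zeros((n * n, n))
    diff_onehot[np.arange(n * n), kdiff] = 1.0
    p_sum = Pf @ sum_onehot  # (M, 2n-1)
    p_diff = Pf @ diff_onehot  # (M, n)
    k_s = np.arange(2 * n - 1, dtype=np.float64)
    k_d = np.arange(n, dtype=np.float64)

    contrast = (Pf * diff2.ravel()[None, :]).sum(axis=1)
    asm = (Pf**2).sum(axis=1)
    variance = ((i[None, :] - mu_x[:, None]) ** 2 * px).sum(axis=1)
    sxsy = np.sqrt(var_x * var_y)
    corr_num = (Pf * ij.ravel()[None, :]).sum(axis=1) - mu_x * mu_y
    degenerate = sxsy <= 1e-12
    correlation = np.where(degenerate, 0.0, corr_num / np.where(degenerate, 1.0, sxsy))
    sum_average = p_sum @ k_s
    idm = (Pf / (1.0 + diff2.ravel())[None, :]).sum(axis=1)
    sum_entropy = -_plog2(p_sum).sum(axis=1)
    sum_variance = ((k_s[None, :] - sum_average[:, None]) ** 2 * p_sum).sum(axis=1)
    mu_d = p_diff @ k_d
    difference_variance = ((k_d[None, :] - mu_d[:, None]) ** 2 * p_diff).sum(axis=1)
    entropy = -_plog2(Pf).sum(axis=1)
    difference_entropy = -_plog2(p_diff).sum(axis=1)

    hx = -_plog2(px).sum(axis=1)
    hy = -_plog2(py).sum(axis=1)
    # HXY1 = -sum p(i,j) log2(px(i) py(j)); HXY2 = -sum px py log2(px py)
    pxy = px[:, :, None] * py[:, None, :]
    logpxy = np.zeros_like(pxy)
    nz = pxy > 0
    logpxy[nz] = np.log2(pxy[nz])
    hxy1 = -(P * logpxy).reshape(M, -1).sum(axis=1)
    hxy2 = -(pxy * logpxy).reshape(M, -1).sum(axis=1)
    hmax = np.maximum(hx, hy)
    imc_degen = hmax <= 1e-12
    imc1 = np.where(imc_degen, 0.0, (entropy - hxy1) / np.where(imc_degen, 1.0, hmax))
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None))

    feats = np.stack(
        [
            contrast, asm, variance, correlation, sum_average, idm,
            sum_entropy, sum_variance, difference_variance, entropy,
            difference_entropy, imc1, imc2,
        ],
        axis=1,
    )
    return feats, degenerate | imc_degen


def haralick(glcm: GLCM) -> HaralickVector:
    """The 13 second-order statistics of one normalized symmetric GLCM."""
    P = glcm.normalized  # raises when undefined
    feats, degen = _haralick_batch(P[None, :, :])
    return HaralickVector(values=feats[0], degenerate=bool(degen[0]))


# ---------------------------------------------------------------------------
# batch feature extraction


def _pair_code_volume(q: QuantizedVolume, off: tuple[int, int, int]) -> np.ndarray:
    """Flattened pair codes a*N+b per source voxel; -1 where invalid."""
    n = q.levels
    shape = q.shape
    code = np.full(shape, -1, dtype=np.int32)
    src, dst = [], []
    for s, o in zip(shape, off):
        src.append(slice(max(0, -o), s - max(0, o)))
        dst.append(slice(max(0, -o) + o, s - max(0, o) + o))
    a = q.data[tuple(src)]
    b = q.data[tuple(dst)]
    valid = (a >= 0) & (b >= 0)
    code[tuple(src)] = np.where(valid, a.astype(np.int32) * n + b, -1)
    return code


@_njit(cache=False)
def _count_boxes_numba(code, lo, hi, nn):  # pragma: no cover - exercised via wrapper
    K = lo.shape[0]
    out = np.zeros((K, nn), dtype=np.int64)
    for k in range(K):
        for x in range(lo[k, 0], hi[k, 0]):
            for y in range(lo[k, 1], hi[k, 1]):
                for z in range(lo[k, 2], hi[k, 2]):
                    c = code[x, y, z]
                    if c >= 0:
                        out[k, c] += 1
    return out


def _count_boxes_numpy(code, lo, hi, nn):
    out = np.zeros((lo.shape[0], nn), dtype=np.int64)
    for k in range(lo.shape[0]):
        sub = code[lo[k, 0] : hi[k, 0], lo[k, 1] : hi[k, 1], lo[k, 2] : hi[k, 2]].ravel()
        sub = sub[sub >= 0]
        if sub.size:
            out[k] = np.bincount(sub, minlength=nn)
    return out


def _pair_counts(
    code: np.ndarray, nn: int, boxes_lo: np.ndarray, boxes_hi: np.ndarray
) -> np.ndarray:
    """Pair-code histograms over many boxes.

    ``code`` holds one pair code per source voxel (-1 = none); boxes are
    (K, 3) inclusive-lo / exclusive-hi voxel bounds.  Returns (K, nn).
    """
    lo = np.ascontiguousarray(boxes_lo, dtype=np.int64)
    hi = np.ascontiguousarray(boxes_hi, dtype=np.int64)
    counter = _count_boxes_numba if _HAVE_NUMBA else _count_boxes_numpy
    return counter(code, lo, hi, nn)


def _window_boxes(
    centers: np.ndarray, shape: tuple[int, int, int], window_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped window bounds per center; also flags clipped windows."""
    half = window_size // 2
    lo = centers - half
    hi = centers + half + 1
    clipped = (lo < 0).any(axis=1) | (hi > np.asarray(shape)[None, :]).any(axis=1)
    np.clip(lo, 0, None, out=lo)
    np.clip(hi, None, np.asarray(shape)[None, :], out=hi)
    return lo, hi, clipped


def extract_features(
    q: QuantizedVolume,
    voi_centers: np.ndarray,
    window_size: int = DEFAULT_WINDOW,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-VOI texture feature vectors (len 26 * len(distances); 130 default).

    For each distance: one symmetrized GLCM per canonical direction over the
    VOI's window, 13 statistics per matrix, then the mean and SD of each
    statistic across the 13 directions.  Returns (features, clipped flags).
    Directionless windows (no valid pair for a direction) contribute
    all-zero statistics for that direction.

    All VOIs are batched through a compiled window pair counter that is
    exactly equivalent to counting pairs window by window.
    """
    centers = np.atleast_2d(np.asarray(voi_centers, dtype=np.int64))
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("voi_centers must be (K, 3)")
    shape = np.asarray(q.shape)
    if (centers < 0).any() or (centers >= shape[None, :]).any():
        raise ValueError("VOI centers must lie inside the volume")
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    K = centers.shape[0]
    n = q.levels
    nn = n * n
    lo, hi, clipped = _window_boxes(centers, q.shape, window_size)

    n_stats = len(HARALICK_ORDER)
    features = np.empty((K, 2 * n_stats * len(distances)), dtype=np.float64)
    tri_i, tri_j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for di, dist in enumerate(distances):
        per_dir = np.zeros((len(DIRECTIONS_13), K, n_stats))
        for gi, direction in enumerate(DIRECTIONS_13):
            off = tuple(dist * d for d in direction)
            code = _pair_code_volume(q, off)
            # source box: x in window and x+off in window
            box_lo = np.maximum(lo, lo - np.asarray(off)[None, :])
            box_hi = np.minimum(hi, hi - np.asarray(off)[None, :])
            empty = (box_hi <= box_lo).any(axis=1)
            box_lo2 = np.where(empty[:, None], 0, box_lo)
            box_hi2 = np.where(empty[:, None], 0, box_hi)
            counts = _pair_counts(code, nn, box_lo2, box_hi2)
            mats = counts.reshape(K, n, n).astype(np.float64)
            mats = mats + mats.transpose(0, 2, 1)  # symmetrize
            totals = mats.sum(axis=(1, 2))
            ok = totals > 0
            if ok.any():
                P = mats[ok] / totals[ok][:, None, None]
                feats, _ = _haralick_batch(P)
                per_dir[gi, ok, :] = feats
        mean = per_dir.mean(axis=0)  # (K, 13)
        sd = per_dir.std(axis=0)
        block = np.empty((K, 2 * n_stats))
        block[:, 0::2] = mean
        block[:, 1::2] = sd
        features[:, di * 2 * n_stats : (di + 1) * 2 * n_stats] = block
    return features, clipped
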
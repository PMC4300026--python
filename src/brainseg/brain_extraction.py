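"""Histogram- and morphology-based background and skull removal.

The stage assumes (a) the brain connects to skull/scalp only through thin
bridges, mostly darker than GM, and (b) the brain is the largest connected
component of the head.  Steps: Otsu foreground split; locate the CSF/GM/WM
histogram peaks; threshold at t_m = mu_GM - alpha*sigma_GM; binary opening
with a spherical structuring element (radius 3 voxels) to cut the bridges;
keep the largest connected component; dilate; multiply the mask back into
the image (I2 = I1 * M1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks as _scipy_find_peaks

from .volumes_io import Volume

__all__ = [
    "IntensityHistogram",
    "PeakTriple",
    "StructuringElement",
    "intensity_histogram",
    "otsu_threshold",
    "find_peaks",
    "extract_brain",
]


@dataclass
class IntensityHistogram:
    """Counts per integer gray level 0..W-1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def levels(self) -> int:
        return int(self.counts.size)


def intensity_histogram(
    volume: Volume, levels: int = 256, mask: np.ndarray | None = None
) -> IntensityHistogram:
    """Histogram of an integer-valued gray volume over 0..levels-1."""
    data = volume.data[mask] if mask is not None else volume.data.ravel()
    idx = np.rint(data).astype(np.int64)
    if idx.min() < 0 or idx.max() >= levels:
        raise ValueError("intensities outside [0, levels-1]; rescale first")
    return IntensityHistogram(np.bincount(idx, minlength=levels))


@dataclass(frozen=True)
class PeakTriple:
    """Gray-level locations of the three tissue modes, mu_CSF < mu_GM < mu_WM.

    ``sigmas`` are half the full width at half maximum of each mode in the
    smoothed histogram; ``csf_is_fallback`` marks a CSF location derived
    from the valley left of GM because the CSF class showed no peak of its
    own (common after Otsu thresholding removes the darkest voxels).
    """

    mu_csf: float
    mu_gm: float
    mu_wm: float
    prominences: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigmas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    csf_is_fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.mu_csf < self.mu_gm < self.mu_wm):
            raise ValueError(
                f"peaks must be strictly ordered CSF < GM < WM, got "
                f"({self.mu_csf}, {self.mu_gm}, {self.mu_wm})"
            )


@dataclass(frozen=True)
class StructuringElement:
    """Digitized sphere: integer offsets within Euclidean distance ``radius``."""

    radius: int

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        r = self.radius
        ax = np.arange(-r, r + 1)
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        return dx**2 + dy**2 + dz**2 <= r**2

    @property
    def offsets(self) -> np.ndarray:
        fp = self.footprint
        r = self.radius
        return np.argwhere(fp) - r


def otsu_threshold(hist: IntensityHistogram) -> int:
    """Threshold maximizing between-class variance; foreground is > t.

    Ties in the criterion are broken toward the lowest threshold.  A
    histogram with fewer than two occupied bins has no split and raises.
    """
    counts = hist.counts
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram needs >= 2 nonzero bins for a threshold")
    w = counts / counts.sum()
    levels = np.arange(hist.levels, dtype=np.float64)
    omega = np.cumsum(w)
    mu = np.cumsum(w * levels)
    mu_total = mu[-1]
    # class split at t: background <= t, foreground > t
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    sigma_b[-1] = -1.0  # t = W-1 leaves no foreground
    return int(np.argmax(sigma_b))


def _half_fwhm(smoothed: np.ndarray, peak: int) -> float:
    """Half of the full width at half maximum around a local maximum."""
    half = smoothed[peak] / 2.0
    left = peak
    while left > 0 and smoothed[left] > half:
        left -= 1
    right = peak
    n = smoothed.size
    while right < n - 1 and smoothed[right] > half:
        right += 1
    return max((right - left) / 2.0, 1.0)


def find_peaks(
    hist: IntensityHistogram,
    bandwidth: float = 2.0,
    min_prominence_frac: float = 0.01,
) -> PeakTriple:
    """Locate the tissue modes of a foreground (post-Otsu) histogram.

    The histogram is KDE-smoothed at ``bandwidth`` gray levels and local
    maxima are found with prominence at least ``min_prominence_frac`` of the
    tallest mode.  With three or more candidates the three most prominent
    are taken as (CSF, GM, WM) in gray-level order.  With two, they are GM
    and WM and the CSF location falls back to halfway between the first
    occupied level and the valley left of GM ("the C1 class does not always
    display a peak").
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    smoothed = gaussian_filter1d(hist.counts, sigma=bandwidth, mode="constant")
    peaks, props = _scipy_find_peaks(
        smoothed, prominence=min_prominence_frac * smoothed.max()
    )
    if peaks.size < 2:
        raise ValueError(
            f"found {peaks.size} histogram mode(s); the stage needs at least "
            "GM and WM — try a larger smoothing bandwidth"
        )
    order = np.argsort(props["prominences"])[::-1][:3]
    chosen = np.sort(peaks[order])
    proms = {p: float(pr) for p, pr in zip(peaks, props["prominences"])}

    if chosen.size == 3:
        c, g, wv = (int(x) for x in chosen)
        fallback = False
    else:
        g, wv = (int(x) for x in chosen)
        occupied = np.nonzero(hist.counts)[0]
        lo = int(occupied[0])
        valley = lo + int(np.argmin(smoothed[lo:g])) if g > lo else lo
        c = (lo + valley) // 2
        if c >= g:
            c = max(g - 1, 0)
        fallback = True

    sig = tuple(
        _half_fwhm(smoothed, p) if not (fallback and i == 0) else _half_fwhm(smoothed, g)
        for i, p in enumerate((c, g, wv))
    )
    return PeakTriple(
        mu_csf=float(c),
        mu_gm=float(g),
        mu_wm=float(wv),
        prominences=(proms.get(c, 0.0), proms.get(g, 0.0), proms.get(wv, 0.0)),
        sigmas=sig,  # type: ignore[arg-type]
        csf_is_fallback=fallback,
    )


def largest_connected_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component of a boolean mask."""
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }[connectivity]
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    return labeled == int(np.argmax(sizes))


def extract_brain(
    I1: Volume,
    peaks: PeakTriple,
    alpha: float = 2.0,
    se_radius: int = 3,
    n_dilations: int = 3,
    connectivity: int = 26,
) -> tuple[Volume, np.ndarray]:
    """Strip skull and scalp from the foreground-thresholded volume I1.

    mask = I1 > t_m with t_m = mu_GM - alpha*sigma_GM, opened with a
    spherical structuring element of ``se_radius`` voxels (cuts the thin
    brain-skull bridges), reduced to the largest ``connectivity``-connected
    component, then dilated ``n_dilations`` times with the same element.
    Returns (I2, M1) with I2 = I1 * M1 voxel-by-voxel.
    """
    se = StructuringElement(se_radius).footprint
    sigma_gm = peaks.sigmas[1]
    t_m = peaks.mu_gm - alpha * sigma_gm
    mask = I1.data > t_m
    opened = ndimage.binary_opening(mask, structure=se)
    if not opened.any():
        raise ValueError(
            f"mask is empty after opening at t_m={t_m:.1f}; try a smaller alpha"
        )
    lcc = largest_connected_component(opened, connectivity=connectivity)
    m1 = lcc
    for _ in range(n_dilations):
        m1 = ndimage.binary_dilation(m1, structure=se)
    i2 = np.where(m1, I1.data, 0.0)
    return Volume(i2, I1.spacing, I1.affine), m1
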
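"""Synthetic head phantom with ground truth, emulating simulated brain MRI.

The phantom reproduces the statistical structure of simulated T1-weighted
brain scans used to benchmark tissue segmentation: three brain tissue
classes (CSF < GM < WM mean intensity), Rician noise quoted as a percentage
of the brightest tissue mean, a smooth multiplicative bias field quoted as
peak-to-trough percentage (20% -> field in [0.90, 1.10]), and a skull-like
bright distractor shell connected to the brain only through thin bridges —
the geometric assumption the morphological brain-extraction stage relies
on.  Geometry is nested ellipsoids (WM core, GM shell, CSF shell, gap,
skull shell), scaled to the grid, so generation is fast and fully
deterministic given a seed.

What it deliberately does not emulate: cortical folding, partial-volume
mixing at tissue interfaces, and pulse-sequence physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes_io import (
    LABEL_CSF,
    LABEL_GM,
    LABEL_OTHER,
    LABEL_WM,
    LabelVolume,
    Volume,
)

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "add_rician_noise",
    "apply_bias_field",
]

# Ellipsoid semi-axes as fractions of each axis' half-extent.  The CSF
# shell is deliberately thick (~17% of the half-extent) so that the
# default brain-extraction dilation schedule (3 passes of an r=3 ball,
# ~9 voxels of growth on a 96-voxel grid) lands near the true brain
# surface.
_FRAC_WM = 0.44
_FRAC_GM = 0.56
_FRAC_CSF = 0.73
_FRAC_SKULL_IN = 0.80
_FRAC_SKULL_OUT = 0.85

_MIN_DIM = 32


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the defaults are the package's study conditions.

    ``noise_pct`` follows the simulated-MRI convention of {0,1,3,5,7,9}%
    of the brightest tissue mean; ``bias_pct`` the {0,20,40}% peak-to-trough
    convention.  ``tissue_sds`` add small-scale correlated within-tissue
    texture so co-occurrence features are class-discriminative even at
    noise 0.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.0,
            "csf": 50.0,
            "gm": 110.0,
            "wm": 160.0,
            "skull": 120.0,
        }
    )
    tissue_sds: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.0,
            "csf": 3.0,
            "gm": 4.0,
            "wm": 5.0,
            "skull": 10.0,
        }
    )
    noise_pct: float = 3.0
    bias_pct: float = 20.0
    bridge_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.tissue_means
        if not (m["background"] < m["csf"] < m["gm"] < m["wm"]):
            raise ValueError(
                "tissue means must be ordered background < CSF < GM < WM "
                f"(T1-weighted ordering), got {m}"
            )
        if self.noise_pct < 0 or self.bias_pct < 0:
            raise ValueError("noise_pct and bias_pct must be >= 0")
        if len(self.shape) != 3 or min(self.shape) < _MIN_DIM:
            raise ValueError(
                f"shape must be 3-D with every dimension >= {_MIN_DIM} to "
                f"contain the nested shells, got {self.shape}"
            )
        if self.bridge_width < 1:
            raise ValueError("bridge_width must be >= 1")


@dataclass
class PhantomResult:
    """Simulated volume plus everything a benchmark needs."""

    volume: Volume
    truth: LabelVolume
    brain_truth: np.ndarray  # bool: truth in {CSF, GM, WM}
    true_field: np.ndarray  # multiplicative bias field actually applied


def add_rician_noise(
    volume: Volume, noise_pct: float, reference_mean: float, seed: int = 0
) -> Volume:
    """Corrupt with Rician (magnitude-MRI) noise.

    Each voxel v becomes sqrt((v+n1)^2 + n2^2) with n1, n2 i.i.d. zero-mean
    Gaussian of SD = noise_pct/100 * reference_mean, the reference being the
    brightest tissue mean (the simulated-MRI convention).
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    if noise_pct == 0:
        return Volume(volume.data.copy(), volume.spacing, volume.affine)
    sigma = noise_pct / 100.0 * float(reference_mean)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=volume.shape)
    n2 = rng.normal(0.0, sigma, size=volume.shape)
    noisy = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return Volume(noisy, volume.spacing, volume.affine)


def _normalized_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis coordinates scaled to [-1, 1], broadcastable to the grid."""
    axes = []
    for i, s in enumerate(shape):
        c = (np.arange(s, dtype=np.float64) - (s - 1) / 2.0) / ((s - 1) / 2.0)
        shp = [1, 1, 1]
        shp[i] = s
        axes.append(c.reshape(shp))
    return axes


def _random_smooth_surface(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """A random 3-D polynomial of degree <= 2 over normalized coordinates."""
    u, v, w = _normalized_coords(shape)
    monomials = [u, v, w, u * v, u * w, v * w, u * u, v * v, w * w]
    coeffs = rng.normal(0.0, 1.0, size=len(monomials))
    f = np.zeros(shape, dtype=np.float64)
    for c, m in zip(coeffs, monomials):
        f = f + c * m
    return f


def apply_bias_field(
    volume: Volume, bias_pct: float, seed: int = 0
) -> tuple[Volume, np.ndarray]:
    """Multiply by a smooth random low-order polynomial bias field.

    The field is range-normalized to exactly [1 - bias_pct/200,
    1 + bias_pct/200] (20% -> 0.90..1.10, the peak-to-trough convention).
    Returns (biased volume, field).
    """
    if bias_pct < 0:
        raise ValueError("bias_pct must be >= 0")
    if bias_pct == 0:
        field_ = np.ones(volume.shape, dtype=np.float64)
        return Volume(volume.data.copy(), volume.spacing, volume.affine), field_
    rng = np.random.default_rng(seed)
    raw = _random_smooth_surface(volume.shape, rng)
    lo, hi = 1.0 - bias_pct / 200.0, 1.0 + bias_pct / 200.0
    rmin, rmax = float(raw.min()), float(raw.max())
    if rmax - rmin < 1e-12:  # degenerate draw: fall back to a linear ramp
        raw = _normalized_coords(volume.shape)[0] + np.zeros(volume.shape)
        rmin, rmax = float(raw.min()), float(raw.max())
    field_ = lo + (raw - rmin) / (rmax - rmin) * (hi - lo)
    return Volume(volume.data * field_, volume.spacing, volume.affine), field_


def _ellipsoid(shape: tuple[int, int, int], frac: float) -> np.ndarray:
    u, v, w = _normalized_coords(shape)
    return (u / frac) ** 2 + (v / frac) ** 2 + (w / frac) ** 2 <= 1.0


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int16)
    skull = _ellipsoid(shape, _FRAC_SKULL_OUT) & ~_ellipsoid(shape, _FRAC_SKULL_IN)
    labels[skull] = LABEL_OTHER
    labels[_ellipsoid(shape, _FRAC_CSF)] = LABEL_CSF
    labels[_ellipsoid(shape, _FRAC_GM)] = LABEL_GM
    labels[_ellipsoid(shape, _FRAC_WM)] = LABEL_WM

    # Thin bridges ("infrequent connections") from the GM surface out to the
    # skull shell, along +x, -y and +z.  Labeled `other`: part of the
    # distractor, not of the brain.
    cx, cy, cz = [(s - 1) // 2 for s in shape]
    bw = spec.bridge_width
    half_lo, half_hi = bw // 2, (bw + 1) // 2
    gm_r = int(_FRAC_GM * (min(shape) - 1) / 2)
    sk_r = int(_FRAC_SKULL_OUT * (min(shape) - 1) / 2) + 1

    def carve(axis: int, sign: int) -> None:
        sl: list[slice] = [
            slice(cx - half_lo, cx + half_hi),
            slice(cy - half_lo, cy + half_hi),
            slice(cz - half_lo, cz + half_hi),
        ]
        center = (cx, cy, cz)[axis]
        if sign > 0:
            sl[axis] = slice(center + gm_r - 1, min(center + sk_r, shape[axis]))
        else:
            sl[axis] = slice(max(center - sk_r, 0), center - gm_r + 2)
        region = labels[tuple(sl)]
        region[(region == 0) | (region == LABEL_CSF)] = LABEL_OTHER
        labels[tuple(sl)] = region

    carve(0, +1)
    carve(1, -1)
    carve(2, +1)
    return labels


_LABEL_TO_TISSUE = {
    0: "background",
    LABEL_CSF: "csf",
    LABEL_GM: "gm",
    LABEL_WM: "wm",
    LABEL_OTHER: "skull",
}


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom head volume with ground truth.

    Construction order: piecewise-constant tissue means -> within-tissue
    correlated texture -> multiplicative bias field -> Rician noise.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec)
    data = np.zeros(spec.shape, dtype=np.float64)
    for code, tissue in _LABEL_TO_TISSUE.items():
        data[labels == code] = spec.tissue_means[tissue]

    # Within-tissue texture: per-class correlated noise (Gaussian white
    # noise smoothed at ~1.5 voxels, re-normalized to unit SD) scaled to the
    # class SD.  Distinct fields per class give class-specific texture.
    for code, tissue in _LABEL_TO_TISSUE.items():
        sd = spec.tissue_sds.get(tissue, 0.0)
        if sd <= 0:
            continue
        white = rng.normal(0.0, 1.0, size=spec.shape)
        smooth = gaussian_filter(white, sigma=1.5)
        smooth /= smooth.std()
        sel = labels == code
        data[sel] = np.maximum(data[sel] + sd * smooth[sel], 0.0)

    vol = Volume(data, spacing=(1.0, 1.0, 1.0))
    vol, field_ = apply_bias_field(vol, spec.bias_pct, seed=spec.seed + 1)
    vol = add_rician_noise(
        vol, spec.noise_pct, reference_mean=spec.tissue_means["wm"], seed=spec.seed + 2
    )

    truth = LabelVolume(labels=labels, spacing=vol.spacing, affine=vol.affine)
    brain = truth.mask_for(LABEL_CSF, LABEL_GM, LABEL_WM)
    return PhantomResult(volume=vol, truth=truth, brain_truth=brain, true_field=field_)


def noisier(spec: PhantomSpec, noise_pct: float) -> PhantomSpec:
    """Same phantom conditions at a different noise level (paired designs)."""
    return replace(spec, noise_pct=noise_pct)
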
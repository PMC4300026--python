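"""N3-style correction of smooth multiplicative intensity inhomogeneity.

The measured signal is modeled as v(x) = u(x) f(x) + n(x) with u the true
tissue signal and f a smooth multiplicative bias field; the additive noise
n is neglected (the standard simplification) and the log transform makes
the model additive: log v = log u + log f.  In the log-intensity histogram
the field acts as a blurring kernel F, so the density of the measured
signal is the convolution V = F * U.  The algorithm iterates:

1. build the log-intensity histogram V over the mask;
2. sharpen it — estimate U by regularized (Wiener) deconvolution of F;
3. map every voxel to the posterior mean E[u | v] under U and F;
4. smooth the residual log v − E[u|v] spatially to get the field update;
5. accumulate the field, re-normalize it to zero mean over the mask, and
   stop when its coefficient of variation stabilizes.

The corrected volume is exp(log v − log f̂).  The spatial step uses masked
Gaussian smoothing (normalized convolution) at ``field_smooth_scale``,
interpreted as the Gaussian FWHM in mm; a naive frequency-domain division
by F is numerically invalid and is not offered — only the Wiener form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes_io import Volume

__all__ = [
    "LogHistogram",
    "BlurKernel",
    "N3Params",
    "BiasFieldEstimate",
    "to_log_domain",
    "sharpen_distribution",
    "expected_true_signal",
    "correct_bias",
]

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # fwhm * this = sigma


@dataclass
class LogHistogram:
    """Probability density over uniform bins in the log-intensity domain."""

    bin_centers: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.bin_centers.shape != self.density.shape or self.bin_centers.ndim != 1:
            raise ValueError("bin_centers and density must be matching 1-D arrays")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        if self.bin_centers.size > 1:
            steps = np.diff(self.bin_centers)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("bins must be uniform in the log domain")
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"density must sum to 1, got {total}")

    @property
    def bin_count(self) -> int:
        return int(self.bin_centers.size)

    @property
    def bin_width(self) -> float:
        if self.bin_centers.size < 2:
            return 1.0
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class BlurKernel:
    """Gaussian blurring kernel F, width in log-intensity units."""

    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def sample(self, offsets: np.ndarray) -> np.ndarray:
        """Unnormalized Gaussian profile at the given log-intensity offsets."""
        return np.exp(-0.5 * (offsets / self.sigma) ** 2)


@dataclass(frozen=True)
class N3Params:
    """Tunables of the correction; defaults follow common N3 practice."""

    fwhm: float = 0.15
    wiener_noise_floor: float = 0.01
    field_smooth_scale: float = 50.0  # Gaussian FWHM, mm
    max_iters: int = 50
    tol: float = 1e-3
    histogram_bins: int = 200

    def __post_init__(self) -> None:
        for name in ("fwhm", "wiener_noise_floor", "field_smooth_scale", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_iters < 1 or self.histogram_bins < 8:
            raise ValueError("max_iters >= 1 and histogram_bins >= 8 required")


@dataclass
class BiasFieldEstimate:
    """Additive log-domain field (zero mean over the mask) and metadata."""

    log_field: np.ndarray
    iterations_run: int
    converged: bool

    @property
    def multiplicative(self) -> np.ndarray:
        return np.exp(self.log_field)


def to_log_domain(volume: Volume, mask: np.ndarray, epsilon: float = 1e-4) -> Volume:
    """Log-transform intensities inside the mask, flooring at epsilon.

    Out-of-mask voxels are set to the in-mask minimum so the output stays
    finite; they are excluded from every histogram computation downstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match volume")
    if not mask.any():
        raise ValueError("mask is empty")
    if np.any(volume.data[mask] < 0):
        raise ValueError("intensities inside the mask must be >= 0")
    logv = np.log(np.maximum(volume.data, epsilon))
    out = np.where(mask, logv, logv[mask].min())
    return Volume(out, volume.spacing, volume.affine)


def _log_histogram(values: np.ndarray, bins: int, rng: tuple[float, float]) -> LogHistogram:
    counts, edges = np.histogram(values, bins=bins, range=rng)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples in histogram range")
    return LogHistogram(bin_centers=centers, density=counts / total)


def sharpen_distribution(V: LogHistogram, F: BlurKernel, Z: float = 0.01) -> LogHistogram:
    """Wiener-deconvolve the blur F out of the measured density V.

    In the frequency domain Û = conj(F̂) / (|F̂|² + Z) · V̂; the result is
    clipped at zero and renormalized to sum 1.  The transform is zero-padded
    to twice the bin count so the deconvolution is linear, not circular —
    circular wraparound would leak ringing from one end of the intensity
    range into the other.
    """
    if Z <= 0:
        raise ValueError("noise floor Z must be > 0")
    n = V.bin_count
    m = 2 * n
    offsets = (np.arange(m) - m // 2) * V.bin_width
    k = F.sample(offsets)
    k /= k.sum()
    f_hat = np.fft.fft(np.fft.ifftshift(k))
    v_hat = np.fft.fft(V.density, n=m)
    u = np.real(np.fft.ifft(np.conj(f_hat) / (np.abs(f_hat) ** 2 + Z) * v_hat))[:n]
    np.clip(u, 0.0, None, out=u)
    total = u.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an all-zero density")
    return LogHistogram(bin_centers=V.bin_centers.copy(), density=u / total)


def expected_true_signal(
    V: LogHistogram, U: LogHistogram, F: BlurKernel
) -> np.ndarray:
    """Posterior-mean mapping E[u | v] evaluated at every bin of V.

    E[u|v] = sum_u u F(v-u) U(u) / sum_u F(v-u) U(u).  Bins where the
    denominator vanishes fall back to the identity (v itself).  Monotone
    non-decreasing in v for the Gaussian kernel.  Values between bins are
    obtained by linear interpolation (see :func:`correct_bias`).
    """
    if U.bin_count != V.bin_count or not np.allclose(U.bin_centers, V.bin_centers):
        raise ValueError("U and V must share the same bins")
    centers = V.bin_centers
    diff = centers[:, None] - centers[None, :]  # (v, u) offsets
    w = F.sample(diff) * U.density[None, :]
    denom = w.sum(axis=1)
    numer = (w * centers[None, :]).sum(axis=1)
    mapping = np.where(denom > 1e-300, numer / np.where(denom > 0, denom, 1.0), centers)
    return mapping


def _masked_gaussian_smooth(
    values: np.ndarray, mask: np.ndarray, sigma_voxels: np.ndarray
) -> np.ndarray:
    """Normalized convolution: Gaussian smoothing that ignores out-of-mask
    voxels and extrapolates the field smoothly beyond the mask."""
    m = mask.astype(np.float64)
    num = gaussian_filter(values * m, sigma=sigma_voxels)
    den = gaussian_filter(m, sigma=sigma_voxels)
    out = np.zeros_like(num)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def correct_bias(
    volume: Volume, mask: np.ndarray, params: N3Params = N3Params()
) -> tuple[Volume, BiasFieldEstimate]:
    """Estimate and remove a smooth multiplicative bias field.

    Returns the corrected volume exp(log v − log f̂) and the field
    estimate.  Non-convergence within ``max_iters`` is reported through
    ``converged=False`` (with a logged warning), never an exception.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    logv_vol = to_log_domain(volume, mask)
    logv = logv_vol.data
    in_mask = logv[mask]
    lo, hi = float(in_mask.min()), float(in_mask.max())
    F = BlurKernel(fwhm=params.fwhm)
    # pad the range past the kernel's support so the posterior mean and the
    # deconvolution ringing have symmetric room at both ends
    pad = max(0.05 * (hi - lo + 1e-9), 4.0 * F.sigma)
    hist_range = (lo - pad, hi + pad)
    sigma_voxels = np.array(
        [params.field_smooth_scale * _FWHM_TO_SIGMA / s for s in volume.spacing]
    )

    log_field = np.zeros_like(logv)
    prev_cv = np.inf
    converged = False
    iters = 0
    for iters in range(1, params.max_iters + 1):
        current = logv - log_field
        V = _log_histogram(current[mask], params.histogram_bins, hist_range)
        U = sharpen_distribution(V, F, params.wiener_noise_floor)
        mapping = expected_true_signal(V, U, F)
        eu = np.interp(current, V.bin_centers, mapping)
        residual = current - eu
        increment = _masked_gaussian_smooth(residual, mask, sigma_voxels)
        log_field = log_field + increment
        log_field = log_field - log_field[mask].mean()

        mult = np.exp(log_field[mask])
        cv = float(mult.std() / mult.mean())
        # relative change of the field's coefficient of variation
        if np.isfinite(prev_cv) and abs(cv - prev_cv) < params.tol * max(prev_cv, 1e-12):
            converged = True
            break
        prev_cv = cv

    if not converged:
        logger.warning(
            "bias correction did not converge in %d iterations (last CV change check failed)",
            params.max_iters,
        )
    corrected = np.exp(logv - log_field)
    # outside the mask keep the original intensities (field is undefined there)
    corrected = np.where(mask, corrected, volume.data)
    est = BiasFieldEstimate(log_field=log_field, iterations_run=iters, converged=converged)
    return Volume(corrected, volume.spacing, volume.affine), est
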
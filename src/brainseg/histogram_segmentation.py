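"""Three-Gaussian histogram model: fit, classify, and flag ambiguous voxels.

The brain-tissue histogram is modeled as a sum of three Gaussian bumps

    p'(i; v) = sum_k p_k exp(-1/2 ((i - mu_k)/sigma_k)^2),   k = 1..3

with v = (p_k, mu_k, sigma_k) and class semantics C1 = CSF (plus residual
background), C2 = GM, C3 = WM.  Note p_k is an amplitude in histogram-count
units — there is deliberately no 1/(sigma sqrt(2 pi)) factor.  The optimal
parameters minimize the sum of squared deviations from the observed
histogram p(i) over the W gray levels, solved by Levenberg–Marquardt with
an analytic Jacobian; initial values come from the KDE-smoothed histogram's
peaks.  Voxels are then assigned the class of largest likelihood; voxels
brighter than mu_3 + 3 sigma_3 form the small fourth class ("other").
Voxels whose top-two likelihood ratio is below ``rho``, or that touch a
differently-labeled 18-connected neighbor, are flagged ambiguous — they are
the refinement stage's target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .brain_extraction import IntensityHistogram, PeakTriple
from .volumes_io import (
    LABEL_CSF,
    LABEL_GM,
    LABEL_OTHER,
    LABEL_WM,
    LabelVolume,
    Volume,
)

__all__ = [
    "GaussianMixtureParams",
    "FitResult",
    "KDEConfig",
    "ClassificationOutput",
    "kde_smooth",
    "initialize_params",
    "mixture_model",
    "fit_mixture",
    "classify",
]

logger = logging.getLogger(__name__)

_SIGMA_MIN = 0.5


@dataclass
class GaussianMixtureParams:
    """Amplitudes, means and widths of the three class Gaussians (C1<C2<C3)."""

    p: np.ndarray  # (3,) amplitudes, histogram-count units
    mu: np.ndarray  # (3,) gray levels
    sigma: np.ndarray  # (3,) gray levels

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if not (self.p.shape == self.mu.shape == self.sigma.shape == (3,)):
            raise ValueError("p, mu, sigma must each have shape (3,)")
        if np.any(self.p <= 0) or np.any(self.sigma <= 0):
            raise ValueError("amplitudes and widths must be > 0")
        if not (self.mu[0] < self.mu[1] < self.mu[2]):
            raise ValueError(f"means must satisfy mu1 < mu2 < mu3, got {self.mu}")

    def sorted_by_mean(self) -> "GaussianMixtureParams":
        order = np.argsort(self.mu)
        return GaussianMixtureParams(self.p[order], self.mu[order], self.sigma[order])


@dataclass
class FitResult:
    v_star: GaussianMixtureParams
    sse: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class KDEConfig:
    """Gaussian kernel density smoothing of the discrete histogram."""

    bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


@dataclass
class ClassificationOutput:
    labels: LabelVolume
    confidence: np.ndarray  # top-1 / top-2 likelihood ratio, >= 1 in mask
    ambiguous: np.ndarray  # bool, subset of the brain mask
    brain_mask: np.ndarray


def kde_smooth(hist: IntensityHistogram, cfg: KDEConfig = KDEConfig()) -> np.ndarray:
    """Kernel density estimate over the W gray levels, normalized to sum 1.

    Discrete convolution of the histogram with a Gaussian kernel of SD
    ``bandwidth`` (in gray levels).  A bandwidth much smaller than the bin
    width returns the normalized histogram itself.
    """
    counts = hist.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    h = cfg.bandwidth
    if h < 0.1:  # effectively a delta kernel at integer bins
        return counts / total
    radius = int(np.ceil(4 * h))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (x / h) ** 2)
    kernel /= kernel.sum()
    smoothed = np.convolve(counts, kernel, mode="same")
    return smoothed / smoothed.sum()


def initialize_params(
    hist: IntensityHistogram, peaks: PeakTriple, cfg: KDEConfig = KDEConfig()
) -> GaussianMixtureParams:
    """Initial parameter vector from the smoothed histogram's peaks.

    Means come from the located peaks (the CSF one possibly a valley
    fallback), amplitudes from the smoothed histogram height at each mean
    (in count units), widths from each mode's half-FWHM.
    """
    counts = hist.counts
    if counts.sum() <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram")
    density = kde_smooth(hist, cfg)
    smoothed_counts = density * counts.sum()
    mu = np.array([peaks.mu_csf, peaks.mu_gm, peaks.mu_wm], dtype=np.float64)
    idx = np.clip(np.rint(mu).astype(int), 0, hist.levels - 1)
    p = np.maximum(smoothed_counts[idx], 1e-3)
    sigma = np.maximum(np.asarray(peaks.sigmas, dtype=np.float64), _SIGMA_MIN)
    return GaussianMixtureParams(p=p, mu=mu, sigma=sigma)


def mixture_model(i: np.ndarray, params: GaussianMixtureParams) -> np.ndarray:
    """Evaluate p'(i; v) at gray levels i."""
    i = np.asarray(i, dtype=np.float64)
    out = np.zeros_like(i)
    for k in range(3):
        out += params.p[k] * np.exp(
            -0.5 * ((i - params.mu[k]) / params.sigma[k]) ** 2
        )
    return out


# --- parameter transform: internal unconstrained theta <-> bounded (p, mu, sigma)
#
# p = exp(a) > 0;  mu_k = lo_k + (hi_k - lo_k) * expit(b_k), per-component
# bounds defaulting to [0, W-1]; sigma = smin + (W/2 - smin) * expit(c) in
# [smin, W/2].  Per-component mean bounds let a caller anchor each class to
# its histogram mode, preventing a superfluous component from migrating
# onto a neighboring peak when the histogram shows fewer than three modes.


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(y: np.ndarray) -> np.ndarray:
    y = np.clip(y, 1e-9, 1 - 1e-9)
    return np.log(y / (1.0 - y))


def _default_mu_bounds(levels: int) -> np.ndarray:
    return np.array([[0.0, levels - 1.0]] * 3)


def _theta_from_params(
    params: GaussianMixtureParams, levels: int, mu_bounds: np.ndarray | None = None
) -> np.ndarray:
    mb = _default_mu_bounds(levels) if mu_bounds is None else np.asarray(mu_bounds, float)
    shi = levels / 2.0
    a = np.log(params.p)
    b = _logit((np.clip(params.mu, mb[:, 0], mb[:, 1]) - mb[:, 0]) / (mb[:, 1] - mb[:, 0]))
    c = _logit((np.clip(params.sigma, _SIGMA_MIN, shi) - _SIGMA_MIN) / (shi - _SIGMA_MIN))
    return np.concatenate([a, b, c])


def _params_from_theta(
    theta: np.ndarray, levels: int, mu_bounds: np.ndarray | None = None
) -> GaussianMixtureParams:
    mb = _default_mu_bounds(levels) if mu_bounds is None else np.asarray(mu_bounds, float)
    shi = levels / 2.0
    p = np.exp(np.clip(theta[0:3], -50.0, 50.0))
    mu = mb[:, 0] + (mb[:, 1] - mb[:, 0]) * _expit(theta[3:6])
    sigma = _SIGMA_MIN + (shi - _SIGMA_MIN) * _expit(theta[6:9])
    obj = object.__new__(GaussianMixtureParams)
    obj.p, obj.mu, obj.sigma = p, mu, sigma  # may be unordered mid-fit
    return obj


def _model_and_jac(
    theta: np.ndarray, i: np.ndarray, levels: int, mu_bounds: np.ndarray | None = None
):
    """Model values and the analytic Jacobian w.r.t. the 9 internal params."""
    mb = _default_mu_bounds(levels) if mu_bounds is None else np.asarray(mu_bounds, float)
    shi = levels / 2.0
    # clip keeps the amplitude finite during aggressive solver line searches
    p = np.exp(np.clip(theta[0:3], -50.0, 50.0))
    eb = _expit(theta[3:6])
    ec = _expit(theta[6:9])
    mu = mb[:, 0] + (mb[:, 1] - mb[:, 0]) * eb
    sigma = _SIGMA_MIN + (shi - _SIGMA_MIN) * ec
    model = np.zeros_like(i)
    jac = np.empty((i.size, 9))
    for k in range(3):
        z = (i - mu[k]) / sigma[k]
        g = np.exp(-0.5 * z**2)
        term = p[k] * g
        model += term
        # chain rule through the transforms
        dmu_db = (mb[k, 1] - mb[k, 0]) * eb[k] * (1 - eb[k])
        dsig_dc = (shi - _SIGMA_MIN) * ec[k] * (1 - ec[k])
        jac[:, k] = term  # d/da = p_k g since p = e^a
        jac[:, 3 + k] = term * z / sigma[k] * dmu_db
        jac[:, 6 + k] = term * z**2 / sigma[k] * dsig_dc
    return model, jac


def fit_mixture(
    hist: IntensityHistogram,
    v0: GaussianMixtureParams,
    tol: float = 1e-8,
    max_iter: int = 200,
    mu_bounds: np.ndarray | None = None,
) -> FitResult:
    """Levenberg–Marquardt least-squares fit of the 9-parameter model.

    Minimizes sum_i [p(i) - p'(i; v)]^2 over the W gray levels.  Internally
    the parameters are transformed so amplitudes stay positive, means stay
    in [0, W-1] and widths in [0.5, W/2] (prevents component collapse on
    noisy histograms); the solver sees an unconstrained problem and the
    damping handles near-singular Jacobians.  Optional per-component
    ``mu_bounds`` (3, 2) anchor each mean to its histogram mode — useful
    when the foreground split leaves fewer than three visible modes, where
    an unanchored component would otherwise migrate onto a neighbor's
    peak.  Components are re-sorted so mu1 < mu2 < mu3 on return.
    """
    counts = hist.counts
    levels = hist.levels
    i = np.arange(levels, dtype=np.float64)
    theta0 = _theta_from_params(v0, levels, mu_bounds)

    def residuals(theta: np.ndarray) -> np.ndarray:
        model, _ = _model_and_jac(theta, i, levels, mu_bounds)
        return model - counts

    def jac(theta: np.ndarray) -> np.ndarray:
        _, J = _model_and_jac(theta, i, levels, mu_bounds)
        return J

    result = least_squares(
        residuals,
        theta0,
        jac=jac,
        method="lm",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter * 10,
    )
    fitted = _params_from_theta(result.x, levels, mu_bounds)
    order = np.argsort(fitted.mu)
    mu, p, sigma = fitted.mu[order], fitted.p[order], fitted.sigma[order]
    # strict ordering can collapse if two components land on one mode
    for k in (1, 2):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + 1e-6
    v_star = GaussianMixtureParams(p=p, mu=mu, sigma=sigma)
    sse = float(2 * result.cost)
    converged = bool(result.status > 0)
    if not converged:
        logger.warning("mixture fit did not converge: %s", result.message)
    return FitResult(
        v_star=v_star, sse=sse, iterations=int(result.nfev), converged=converged
    )


def _class_likelihoods(values: np.ndarray, v: GaussianMixtureParams) -> np.ndarray:
    """(n, 3) likelihoods p_k exp(-1/2 ((i-mu_k)/sigma_k)^2)."""
    out = np.empty(values.shape + (3,))
    for k in range(3):
        out[..., k] = v.p[k] * np.exp(-0.5 * ((values - v.mu[k]) / v.sigma[k]) ** 2)
    return out


_CLASS_TO_LABEL = np.array([LABEL_CSF, LABEL_GM, LABEL_WM], dtype=np.int16)


def classify(
    volume: Volume,
    brain_mask: np.ndarray,
    v_star: GaussianMixtureParams,
    rho: float = 1.5,
    zero_label: int | None = None,
) -> ClassificationOutput:
    """Assign each in-mask voxel its maximum-likelihood tissue class.

    Ties break toward the lower class index.  Voxels brighter than
    mu_3 + 3 sigma_3 become `other` (C4).  Confidence is the top-1/top-2
    likelihood ratio; the ambiguous set is {confidence < rho} union
    {voxels with a differently-labeled 18-connected in-mask neighbor}.

    ``zero_label``: in a foreground-thresholded volume, in-mask voxels at
    exactly 0 were removed by the Otsu split and sit below every modeled
    component; when set they are assigned this label directly with full
    confidence (the C1 "background, noise and CSF" reading).
    """
    if rho < 1:
        raise ValueError("rho must be >= 1")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != volume.shape:
        raise ValueError("mask shape must match volume")
    levels_hi = 2 * v_star.mu[2] + 10 * v_star.sigma[2]  # generous clamp bound
    vals = volume.data[brain_mask]
    if vals.size and (vals.min() < 0 or vals.max() > levels_hi):
        logger.warning("intensities outside the modeled gray range; clamping")
        vals = np.clip(vals, 0, levels_hi)

    lik = _class_likelihoods(vals, v_star)
    order = np.argsort(lik, axis=1)
    top1 = lik[np.arange(vals.size), order[:, 2]]
    top2 = lik[np.arange(vals.size), order[:, 1]]
    # argmax with ties toward the lower class index
    best = np.argmax(lik, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        conf = np.where(top2 > 0, top1 / np.maximum(top2, 1e-300), np.inf)

    labels = np.zeros(volume.shape, dtype=np.int16)
    labels[brain_mask] = _CLASS_TO_LABEL[best]
    other = np.zeros(volume.shape, dtype=bool)
    other[brain_mask] = vals > v_star.mu[2] + 3.0 * v_star.sigma[2]
    labels[other] = LABEL_OTHER

    confidence = np.zeros(volume.shape)
    confidence[brain_mask] = conf

    if zero_label is not None:
        zeroed = brain_mask & (volume.data == 0)
        labels[zeroed] = zero_label
        confidence[zeroed] = np.inf

    low_conf = brain_mask & (confidence < rho)

    # boundary voxels: any 18-connected in-mask neighbor with another label
    struct = ndimage.generate_binary_structure(3, 2)
    lab_for_max = np.where(brain_mask, labels, -1)
    lab_for_min = np.where(brain_mask, labels, np.int16(99))
    mx = ndimage.maximum_filter(lab_for_max, footprint=struct)
    mn = ndimage.minimum_filter(lab_for_min, footprint=struct)
    boundary = brain_mask & ((mx > labels) | (mn < labels))

    ambiguous = brain_mask & (low_conf | boundary)
    lv = LabelVolume(
        labels=labels,
        spacing=volume.spacing,
        affine=volume.affine,
        confidence=np.where(np.isfinite(confidence), np.minimum(confidence, 1e12), 1e12),
    )
    return ClassificationOutput(
        labels=lv, confidence=confidence, ambiguous=ambiguous, brain_mask=brain_mask
    )
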
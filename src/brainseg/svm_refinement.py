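"""Soft-margin kernel SVM refinement of ambiguous voxels.

The separating function is f(x) = w^T phi(x) + b, trained by minimizing
(1/2) w^T w + C sum_i xi_i subject to y_i (w^T phi(x_i) + b) >= 1 - xi_i,
xi_i >= 0, extended to the tissue classes by a one-against-the-others
strategy.  C defaults to 100 and training draws 10 000 samples per image
from the histogram stage's confident voxels (pseudo-labels; ground-truth
labels can be supplied in benchmark mode).  Kernels: Gaussian RBF
exp(-gamma ||x-x'||^2) (default) or Laplacian RBF exp(-gamma ||x-x'||_1).
The quadratic program is delegated to scikit-learn's SVC behind the
:class:`TrainedClassifier` contract; re-deriving SMO is out of scope.

Refinement then iterates over the ambiguous set: extract features for the
current frontier, predict, relabel; the next frontier is the 18-connected
neighbors of relabeled voxels that were themselves ambiguous.  Confident
voxels are never altered.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage
from sklearn.metrics.pairwise import laplacian_kernel
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .histogram_segmentation import ClassificationOutput
from .volumes_io import LabelVolume

__all__ = [
    "SVMConfig",
    "TrainedClassifier",
    "sample_training_voxels",
    "train",
    "refine",
]

logger = logging.getLogger(__name__)

KERNELS = ("gaussian_rbf", "laplacian_rbf")


@dataclass(frozen=True)
class SVMConfig:
    """Penalty C=100 and 10 000 samples/image are the method's settings."""

    C: float = 100.0
    kernel: str = "gaussian_rbf"
    gamma: float | None = None  # None -> 1/n_features on standardized input
    samples_per_image: int = 10_000
    seed: int = 0
    max_refine_iters: int = 10

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.samples_per_image < 20:
            raise ValueError("samples_per_image must allow >= 10 per class")
        if self.max_refine_iters < 1:
            raise ValueError("max_refine_iters must be >= 1")


def _make_laplacian(gamma: float) -> Callable:
    def kernel(X, Y):
        return laplacian_kernel(X, Y, gamma=gamma)

    return kernel


@dataclass
class TrainedClassifier:
    """Deterministic predict/decision_values over standardized feature rows.

    Carries the standardization parameters and the selected-feature list so
    a persisted model is self-describing.
    """

    model: OneVsRestClassifier
    config: SVMConfig
    gamma: float
    classes_: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.mean_ is not None:
            X = (X - self.mean_) / self.scale_
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self._prep(X))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores, shape (n, n_classes) (1-D for two classes)."""
        return self.model.decision_function(self._prep(X))

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "brainseg-svm-v1",
            "model": self.model,
            "config": self.config,
            "gamma": self.gamma,
            "classes": self.classes_,
            "feature_names": self.feature_names,
            "mean": self.mean_,
            "scale": self.scale_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "brainseg-svm-v1":
            raise ValueError(f"not a brainseg classifier file: {path}")
        return cls(
            model=payload["model"],
            config=payload["config"],
            gamma=payload["gamma"],
            classes_=payload["classes"],
            feature_names=payload["feature_names"],
            mean_=payload["mean"],
            scale_=payload["scale"],
        )


def sample_training_voxels(
    classification: ClassificationOutput,
    n: int,
    seed: int = 0,
    min_per_class: int = 10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stratified draw of confident (non-ambiguous) voxels for training.

    Per-class counts are proportional to the confident-set class mix with a
    floor of ``min_per_class``; classes with no confident voxel are skipped
    with a warning.  Returns (coords (k,3), labels (k,), exhausted flag) —
    the flag is set when ``n`` exceeds the confident-voxel count, in which
    case all confident voxels are returned.
    """
    labels = classification.labels.labels
    confident = classification.brain_mask & ~classification.ambiguous
    coords = np.argwhere(confident)
    labs = labels[confident]
    present = np.unique(labs)
    if present.size < 2:
        raise ValueError("need confident voxels from at least two classes")
    total = coords.shape[0]
    if n >= total:
        logger.warning("requested %d samples but only %d confident voxels", n, total)
        return coords, labs, True

    rng = np.random.default_rng(seed)
    counts = {c: int((labs == c).sum()) for c in present}
    quota = {}
    for c in present:
        share = int(round(n * counts[c] / total))
        quota[c] = min(max(share, min_per_class), counts[c])
    take_coords, take_labs = [], []
    for c in present:
        idx = np.nonzero(labs == c)[0]
        pick = rng.choice(idx, size=quota[c], replace=False)
        take_coords.append(coords[pick])
        take_labs.append(labs[pick])
    out_c = np.concatenate(take_coords)
    out_l = np.concatenate(take_labs)
    order = rng.permutation(out_c.shape[0])
    return out_c[order], out_l[order], False


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig = SVMConfig(),
    feature_names: list[str] | None = None,
    standardize: bool = True,
) -> TrainedClassifier:
    """Fit one-vs-rest soft-margin kernel SVMs.

    ``X`` is standardized internally by default (the parameters are stored
    on the classifier).  gamma defaults to 1/n_features on the
    standardized rows.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) with one label per row")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training needs at least two classes")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X
    gamma = config.gamma if config.gamma is not None else 1.0 / X.shape[1]
    if config.kernel == "gaussian_rbf":
        base = SVC(C=config.C, kernel="rbf", gamma=gamma, cache_size=500)
    else:
        base = SVC(C=config.C, kernel=_make_laplacian(gamma), cache_size=500)
    model = OneVsRestClassifier(base)
    model.fit(Xs, y)
    return TrainedClassifier(
        model=model,
        config=config,
        gamma=gamma,
        classes_=classes,
        feature_names=list(feature_names or []),
        mean_=mean,
        scale_=scale,
    )


def refine(
    initial: ClassificationOutput,
    feature_provider: Callable[[np.ndarray], np.ndarray],
    classifier: TrainedClassifier,
    config: SVMConfig = SVMConfig(),
) -> LabelVolume:
    """Iteratively relabel ambiguous voxels with the trained classifier.

    ``feature_provider`` maps voxel coordinates (k, 3) to feature rows in
    the classifier's input space (already reduced to the selected
    features; standardization is the classifier's job).  Confident voxels
    are structurally frozen.  Terminates when a pass changes no label or
    after ``max_refine_iters`` passes.
    """
    labels = initial.labels.labels.copy()
    ambiguous = initial.ambiguous
    if not ambiguous.any():
        return LabelVolume(
            labels=labels,
            spacing=initial.labels.spacing,
            affine=initial.labels.affine,
            confidence=initial.labels.confidence,
        )
    struct = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
    frontier = ambiguous.copy()
    for _ in range(config.max_refine_iters):
        coords = np.argwhere(frontier)
        if coords.size == 0:
            break
        feats = feature_provider(coords)
        pred = classifier.predict(feats).astype(labels.dtype)
        old = labels[tuple(coords.T)]
        changed = pred != old
        if not changed.any():
            break
        labels[tuple(coords.T)] = pred
        # next frontier: ambiguous 18-neighbors of voxels that changed
        changed_mask = np.zeros_like(frontier)
        changed_mask[tuple(coords[changed].T)] = True
        grown = ndimage.binary_dilation(changed_mask, structure=struct)
        frontier = grown & ambiguous & ~changed_mask
    return LabelVolume(
        labels=labels,
        spacing=initial.labels.spacing,
        affine=initial.labels.affine,
        confidence=initial.labels.confidence,
    )
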
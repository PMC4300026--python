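"""Stepwise discriminant analysis (SDA) over the texture feature table.

Classical forward-selection-with-backward-elimination driven by Wilks'
lambda, the determinant ratio det(W)/det(T) of the within-class and total
scatter matrices restricted to the candidate subset.  At each step the
unselected feature with the largest partial F enters if it clears
``f_enter``; any selected feature whose partial F falls below ``f_remove``
is then dropped.  Ties break toward the lowest column index, so selection
is fully deterministic.  Features are standardized (zero mean, unit
variance over the table) before scatter computation and the standardization
parameters are kept for prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SDAResult", "wilks_lambda", "sda_select"]


@dataclass
class FeatureTable:
    """Samples-by-features matrix with a class label per row."""

    X: np.ndarray
    y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains missing/non-finite values")
        if np.unique(self.y).size < 2:
            raise ValueError("at least two classes required")
        if not self.names:
            self.names = [f"f_{j:03d}" for j in range(self.X.shape[1])]
        if len(self.names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df["label"] = self.y
        return df


@dataclass
class SDAResult:
    """Ordered selection with the Wilks trace and partial-F audit trail."""

    selected: list[int]
    wilks_trace: list[float]
    f_stats: list[float]
    steps: list[dict] = field(default_factory=list)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def selected_names(self, table: FeatureTable) -> list[str]:
        return [table.names[j] for j in self.selected]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize with the stored parameters and keep selected columns."""
        if self.mean_ is None or self.scale_ is None:
            raise ValueError("selection was run without standardization state")
        return (X[:, self.selected] - self.mean_[self.selected]) / self.scale_[
            self.selected
        ]


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (W) and total (T) scatter of the full table."""
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in np.unique(y):
        G = X[y == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def wilks_lambda(table: FeatureTable, subset: list[int] | np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) restricted to the given feature subset.

    Lambda is 1 for features with no between-class separation and tends to
    0 as class means separate relative to within-class spread.  A singular
    within-class scatter (collinear features) raises, naming the subset.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    W, T = _scatter_matrices(table.X[:, subset], table.y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        bad = [table.names[j] for j in subset]
        raise ValueError(f"singular scatter matrix: collinear features among {bad}")
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int) -> float:
    """Partial F for the feature whose addition changed lambda small -> big.

    ``p`` is the subset size *without* the candidate.  F follows
    F((g-1), (n-g-p)) under the null of no added discrimination.
    """
    dof = n - g - p
    if dof <= 0 or lam_big <= 0:
        return 0.0
    return (lam_small / lam_big - 1.0) * dof / (g - 1)


def sda_select(
    table: FeatureTable,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_features: int = 30,
    standardize: bool = True,
) -> SDAResult:
    """Stepwise feature selection by Wilks' lambda partial-F statistics.

    Deterministic given the table; no internal randomness.  If no feature
    reaches ``f_enter`` at the first step, an empty selection is returned
    (flagged in ``steps``), not an error.
    """
    if not (f_enter > f_remove > 0):
        raise ValueError("need f_enter > f_remove > 0")
    X = table.X
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        X = (X - mean) / scale
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    work = FeatureTable(X=X, y=table.y, names=list(table.names))
    n, g = table.n_samples, table.classes.size

    selected: list[int] = []
    lam_current = 1.0
    trace: list[float] = []
    fstats: list[float] = []
    steps: list[dict] = []
    seen_states: set[tuple[int, ...]] = set()

    # scatter is bilinear, so the subset-restricted W and T are submatrices
    # of the full-table scatter — compute those once
    W_full, T_full = _scatter_matrices(work.X, work.y)

    def lam_of(subset: list[int]) -> float:
        ix = np.ix_(subset, subset)
        sign_w, logdet_w = np.linalg.slogdet(W_full[ix])
        sign_t, logdet_t = np.linalg.slogdet(T_full[ix])
        if sign_w <= 0 or sign_t <= 0:
            return np.nan  # collinear candidate: never preferred
        return float(np.exp(logdet_w - logdet_t))

    while len(selected) < max_features:
        state = tuple(sorted(selected))
        if state in seen_states:
            break  # enter/remove cycle guard
        seen_states.add(state)

        # --- forward step
        best_j, best_f, best_lam = -1, -np.inf, np.nan
        for j in range(work.n_features):
            if j in selected:
                continue
            lam_j = lam_of(selected + [j])
            if not np.isfinite(lam_j):
                continue
            f_j = _partial_f(lam_current, lam_j, n, g, len(selected))
            if f_j > best_f + 1e-12:  # strict improvement; ties keep lowest j
                best_j, best_f, best_lam = j, f_j, lam_j
        entered = False
        if best_j >= 0 and best_f >= f_enter:
            selected.append(best_j)
            lam_current = best_lam
            trace.append(lam_current)
            fstats.append(best_f)
            steps.append(
                {"action": "enter", "feature": work.names[best_j], "index": best_j,
                 "partial_f": best_f, "wilks": lam_current}
            )
            entered = True
        elif not selected:
            steps.append({"action": "none", "note": "no feature reached f_enter"})
            break

        # --- backward step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst_j, worst_f = -1, np.inf
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = lam_of(rest)
                if not np.isfinite(lam_rest):
                    continue
                f_j = _partial_f(lam_rest, lam_current, n, g, len(selected) - 1)
                if f_j < worst_f:
                    worst_j, worst_f = j, f_j
            if worst_j >= 0 and worst_f < f_remove:
                selected.remove(worst_j)
                lam_current = lam_of(selected)
                steps.append(
                    {"action": "remove", "feature": work.names[worst_j],
                     "index": worst_j, "partial_f": worst_f, "wilks": lam_current}
                )
                removed = True

        if not entered:
            break

    return SDAResult(
        selected=selected,
        wilks_trace=trace,
        f_stats=fstats,
        steps=steps,
        mean_=mean,
        scale_=scale,
    )
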
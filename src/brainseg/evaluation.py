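"""Overlap metrics for segmentations against ground truth.

The kappa index used here is the set-overlap measure

    k(S1, S2) = |S1 n S2| / ( |S1 u S2| - 1/2 (|S1 \\ S2| + |S2 \\ S1|) )

which simplifies algebraically to the Dice coefficient
2 |S1 n S2| / (|S1| + |S2|) — the denominator is
|S1 n S2| + 1/2(|S1|+|S2|-2|S1 n S2|) = (|S1|+|S2|)/2.  The Jaccard index
|S1 n S2| / |S1 u S2| is reported alongside; they satisfy
kappa = 2 j / (1 + j).  Both-empty sets score 1 by default (perfect
agreement on absence), configurable to NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes_io import LABEL_NAMES, LABEL_PALETTE, LabelVolume

__all__ = ["OverlapReport", "kappa_index", "jaccard_index", "evaluate", "aggregate_reports"]

_DEFAULT_TISSUES = ("CSF", "GM", "WM")
_NAME_TO_CODE = {v: k for k, v in LABEL_NAMES.items()}


def _as_bool_sets(S1: np.ndarray, S2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S1 = np.asarray(S1, dtype=bool)
    S2 = np.asarray(S2, dtype=bool)
    if S1.shape != S2.shape:
        raise ValueError(f"mismatched grids: {S1.shape} vs {S2.shape}")
    return S1, S2


def kappa_index(S1: np.ndarray, S2: np.ndarray, empty_value: float = 1.0) -> float:
    """Kappa (= Dice) overlap of two voxel sets on the same grid."""
    S1, S2 = _as_bool_sets(S1, S2)
    a, b = int(S1.sum()), int(S2.sum())
    if a + b == 0:
        return empty_value
    inter = int(np.logical_and(S1, S2).sum())
    return 2.0 * inter / (a + b)


def jaccard_index(S1: np.ndarray, S2: np.ndarray, empty_value: float = 1.0) -> float:
    """Intersection over union of two voxel sets on the same grid."""
    S1, S2 = _as_bool_sets(S1, S2)
    union = int(np.logical_or(S1, S2).sum())
    if union == 0:
        return empty_value
    inter = int(np.logical_and(S1, S2).sum())
    return inter / union


@dataclass
class OverlapReport:
    """Per-tissue overlap plus the full confusion matrix over the palette."""

    per_tissue: dict[str, dict[str, float]]
    confusion: np.ndarray  # (5, 5): rows = truth code, cols = predicted code
    tissues: tuple[str, ...] = _DEFAULT_TISSUES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_tissue, orient="index")

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "tissue"
        with open(path, "w") as fh:
            df.to_csv(fh)
            fh.write("\n# confusion matrix (rows truth, cols predicted)\n")
            conf = pd.DataFrame(
                self.confusion,
                index=[f"true_{LABEL_NAMES[c]}" for c in LABEL_PALETTE],
                columns=[f"pred_{LABEL_NAMES[c]}" for c in LABEL_PALETTE],
            )
            conf.to_csv(fh)


def evaluate(
    pred: LabelVolume,
    truth: LabelVolume,
    tissues: tuple[str, ...] = _DEFAULT_TISSUES,
    empty_value: float = 1.0,
) -> OverlapReport:
    """One-vs-rest overlap per tissue and the palette confusion matrix.

    ``tissues`` selects which classes are reported (CSF can be excluded,
    mirroring common practice on real scans with unreliable CSF truth).
    """
    if pred.shape != truth.shape:
        raise ValueError(f"mismatched shapes: {pred.shape} vs {truth.shape}")
    unknown = set(tissues) - set(_NAME_TO_CODE)
    if unknown:
        raise ValueError(f"unknown tissue names: {sorted(unknown)}")
    per: dict[str, dict[str, float]] = {}
    for name in tissues:
        code = _NAME_TO_CODE[name]
        p = pred.labels == code
        t = truth.labels == code
        tp = int(np.logical_and(p, t).sum())
        fp = int(np.logical_and(p, ~t).sum())
        fn = int(np.logical_and(~p, t).sum())
        j = jaccard_index(p, t, empty_value=empty_value)
        per[name] = {
            "kappa": kappa_index(p, t, empty_value=empty_value),
            "jaccard": j,
            "tp": tp,
            "fp": fp,
            "fn": fn,
        }
    n_codes = len(LABEL_PALETTE)
    confusion = np.bincount(
        truth.labels.ravel().astype(np.int64) * n_codes + pred.labels.ravel(),
        minlength=n_codes * n_codes,
    ).reshape(n_codes, n_codes)
    return OverlapReport(per_tissue=per, confusion=confusion, tissues=tuple(tissues))


def aggregate_reports(paths: list[str | Path]) -> pd.DataFrame:
    """Mean and SD of kappa/jaccard per tissue across several report CSVs."""
    frames = []
    for p in paths:
        df = pd.read_csv(p, comment="#")
        df = df[df["tissue"].isin(LABEL_NAMES.values())]
        frames.append(df.set_index("tissue")[["kappa", "jaccard"]].astype(float))
    stacked = pd.concat(frames, keys=range(len(frames)))
    return stacked.groupby(level=1).agg(["mean", "std"])
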
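"""Volumetric image and label-map I/O and the shared grid conventions.

All modules in this package operate on :class:`Volume` (a 3-D scalar
intensity grid with voxel spacing in mm), :class:`LabelVolume` (per-voxel
tissue codes) and plain boolean masks.  Indexing is 0-based ``(x, y, z)``
with ``x`` fastest-varying; spacing is per-axis in mm.

Label palette
-------------
``0`` background, ``1`` CSF, ``2`` gray matter, ``3`` white matter,
``4`` other (skull, scalp, bright non-brain tissue).  The palette is
embedded in the NIfTI header ``descrip`` field on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
    "LABEL_OTHER",
    "LABEL_PALETTE",
    "LABEL_NAMES",
    "Volume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "rescale_to_gray",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_OTHER = 4
LABEL_PALETTE = (LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM, LABEL_OTHER)
LABEL_NAMES = {0: "background", 1: "CSF", 2: "GM", 3: "WM", 4: "other"}

_PALETTE_DESCRIP = b"labels:0=bg,1=CSF,2=GM,3=WM,4=other"


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing metadata.

    Parameters
    ----------
    data
        3-D floating array of intensities (finite, non-negative after load).
    spacing
        Per-axis voxel size in mm, all entries > 0.
    affine
        4x4 voxel-to-world matrix, carried opaquely.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires a 3-D array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite (no NaN/Inf)")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Per-voxel tissue assignment over the palette, plus optional confidence."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"LabelVolume requires a 3-D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int16)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("label codes must be integers")
            self.labels = as_int
        else:
            self.labels = self.labels.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.labels), np.asarray(LABEL_PALETTE))
        if bad.size:
            raise ValueError(f"label codes outside palette {LABEL_PALETTE}: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=np.float64)
            if self.confidence.shape != self.labels.shape:
                raise ValueError("confidence must match label shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask_for(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given palette codes."""
        return np.isin(self.labels, codes)


def _load_image(path: str | Path) -> nib.spatialimages.SpatialImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3-D image, got shape {tuple(img.shape)}; "
            "4-D/functional series are not supported"
        )
    return img


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI (.nii/.nii.gz) or Analyze volume.

    Data are cast to float64; negative values (occasionally produced by
    scanner interpolation) are clipped to zero so downstream log/histogram
    stages see non-negative intensities.
    """
    img = _load_image(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite intensities in image data")
    np.clip(data, 0.0, None, out=data)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI; `.nii.gz` suffix selects gzip compression."""
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("refusing to write non-finite intensities")
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data, affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabelVolume:
    """Read a label map; codes outside the palette raise with the offending code."""
    img = _load_image(path)
    raw = np.asarray(img.get_fdata())
    labels = np.rint(raw).astype(np.int16)
    if not np.allclose(raw, labels):
        raise ValueError(f"{path}: label image contains non-integer values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=labels, spacing=spacing, affine=np.asarray(img.affine))


def write_labels(lv: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(lv.labels.astype(np.int16), affine=lv.affine)
    img.header.set_zooms(lv.spacing)
    img.header["descrip"] = _PALETTE_DESCRIP
    nib.save(img, str(path))


def rescale_to_gray(volume: Volume, levels: int = 256, mask: np.ndarray | None = None) -> Volume:
    """Rescale intensities linearly onto the integer gray range ``[0, levels-1]``.

    The histogram stages sum over ``W`` gray levels, so they expect an
    integer-valued volume on this range.  Rescaling is on request, never
    automatic.  When a mask is given the in-mask range defines the mapping
    and out-of-mask voxels are clipped into range.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    data = volume.data
    sel = data[mask] if mask is not None else data
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        gray = np.zeros_like(data)
    else:
        gray = np.floor((data - lo) / (hi - lo) * levels)
        np.clip(gray, 0, levels - 1, out=gray)
    return Volume(data=gray, spacing=volume.spacing, affine=volume.affine)
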
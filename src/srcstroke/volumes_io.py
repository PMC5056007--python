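"""Volume I/O, intensity rescaling and brain-mask extraction.

A study is the co-registered triplet of diffusion-weighted volumes acquired
for a stroke patient: the b=0 (T2-weighted) volume ``b0``, the high-b
diffusion-weighted volume ``dwi`` and the apparent-diffusion-coefficient map
``adc``.  Axial slices run along the third array axis.  All downstream
processing assumes the three channels share a voxel grid and have been
rescaled to the common [0, 255] intensity range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "DWStudy",
    "ValidationError",
    "load_study",
    "save_study",
    "rescale_volume",
    "compute_brain_mask",
]

CHANNELS = ("b0", "dwi", "adc")


class ValidationError(ValueError):
    """Raised when an input volume violates a geometric or content contract."""


@dataclass
class DWStudy:
    """Co-registered B0 / DWI / ADC triplet with grid metadata and brain mask.

    Intensities are floating point; after :func:`rescale_volume` (or
    :meth:`rescaled`) every channel lies in [0, 255].  ``brain_mask`` is a
    {0, 1} uint8 volume on the same grid.
    """

    b0: np.ndarray
    dwi: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None
    subject_id: str = "anonymous"
    gt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {c: getattr(self, c).shape for c in CHANNELS}
        ref = shapes["b0"]
        for name, shp in shapes.items():
            if shp != ref:
                raise ValidationError(
                    f"channel {name!r} has shape {shp}, expected {ref} (from b0)"
                )
        if self.brain_mask is not None and self.brain_mask.shape != ref:
            raise ValidationError(
                f"brain_mask has shape {self.brain_mask.shape}, expected {ref}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.b0.shape

    def rescaled(self) -> "DWStudy":
        """Return a copy with every channel min–max rescaled to [0, 255]."""
        return replace(
            self,
            b0=rescale_volume(self.b0),
            dwi=rescale_volume(self.dwi),
            adc=rescale_volume(self.adc),
        )

    def with_brain_mask(self) -> "DWStudy":
        """Return a copy whose brain mask is derived from the rescaled B0."""
        if self.brain_mask is not None:
            return self
        return replace(self, brain_mask=compute_brain_mask(rescale_volume(self.b0)))


def load_study(
    paths: Mapping[str, str | Path],
    subject_id: str | None = None,
) -> DWStudy:
    """Load a study from per-channel NIfTI files.

    Parameters
    ----------
    paths
        Mapping with keys ``b0``, ``dwi``, ``adc`` and optionally
        ``brain_mask`` and ``gt``, each a NIfTI file path.
    subject_id
        Identifier; defaults to the stem of the b0 file.

    Raises
    ------
    ValidationError
        If a required channel is missing or grids disagree.
    """
    missing = [c for c in CHANNELS if c not in paths]
    if missing:
        raise ValidationError(f"missing channel path(s): {missing}")

    volumes: dict[str, np.ndarray] = {}
    affine = None
    for name in CHANNELS + ("brain_mask", "gt"):
        if name not in paths:
            continue
        p = Path(paths[name])
        if not p.exists():
            raise ValidationError(f"file for channel {name!r} not found: {p}")
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj).astype(np.float64)
        if affine is None:
            affine = img.affine
            ref_shape = arr.shape
        elif arr.shape != ref_shape:
            raise ValidationError(
                f"channel {name!r} shape {arr.shape} mismatches b0 shape {ref_shape}"
            )
        elif not np.allclose(img.affine, affine, atol=1e-4):
            raise ValidationError(f"channel {name!r} affine mismatches b0 affine")
        volumes[name] = arr

    zooms = nib.load(str(Path(paths["b0"]))).header.get_zooms()[:3]
    mask = volumes.get("brain_mask")
    gt = volumes.get("gt")
    return DWStudy(
        b0=volumes["b0"],
        dwi=volumes["dwi"],
        adc=volumes["adc"],
        spacing=tuple(float(z) for z in zooms),
        brain_mask=None if mask is None else (mask > 0.5).astype(np.uint8),
        gt=None if gt is None else (gt > 0.5).astype(np.uint8),
        subject_id=subject_id or Path(paths["b0"]).name.split(".")[0],
    )


def save_study(study: DWStudy, out_dir: str | Path, prefix: str | None = None) -> dict[str, Path]:
    """Write a study's channels (and masks, if present) as NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or study.subject_id
    affine = np.diag(list(study.spacing) + [1.0])
    written: dict[str, Path] = {}
    for name in CHANNELS:
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(getattr(study, name).astype(np.float32), affine), str(p))
        written[name] = p
    for name in ("brain_mask", "gt"):
        vol = getattr(study, name)
        if vol is not None:
            p = out_dir / f"{prefix}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.uint8), affine), str(p))
            written[name] = p
    return written


def save_mask(mask: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a binary mask as an unsigned 8-bit NIfTI volume."""
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine), str(path))


def rescale_volume(v: np.ndarray) -> np.ndarray:
    """Affinely map a volume's intensity range onto [0, 255].

    The minimum maps to 0 and the maximum to 255; intensity order is
    preserved.  A constant volume has no contrast to stretch and is returned
    as all zeros with a warning.
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValidationError("volume contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("constant volume: degenerate contrast, returning zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) * (255.0 / (hi - lo))


def compute_brain_mask(b0: np.ndarray) -> np.ndarray:
    """Extract a binary brain mask from the rescaled B0 volume.

    Otsu threshold on the intensity histogram, largest 3D connected
    component (26-connectivity), then per-axial-slice hole filling.
    """
    b0 = np.asarray(b0, dtype=np.float64)
    thr = threshold_otsu(b0)
    fg = b0 > thr
    if not fg.any():
        raise ValidationError("empty foreground: cannot derive a brain mask")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise ValidationError("no connected foreground component found")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return mask.astype(np.uint8)
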
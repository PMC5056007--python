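"""Rule-based candidate-infarct region of interest (ROI) derivation.

The ROI confines voxel classification to plausible ischemic tissue and
rejects "shine-through" DWI hyperintensities whose ADC is not reduced.
Rules, applied to the rescaled study:

1. ADC_ref = the most frequent ADC value over brain voxels (unit-width
   histogram bins on [0, 255]; ties take the lowest bin).
2. Tier 1: voxels with ADC <= 0.75 * ADC_ref form per-slice 2D connected
   components (8-connectivity); a component is kept iff its mean DWI is at
   least mean + std of brain-voxel DWI on that axial slice.  Kept
   components form the initial region R1.
3. Tier 2: per-slice components of voxels with ADC strictly inside
   (0.75, 0.85) * ADC_ref join R1 if any of their voxels is 26-adjacent to
   R1 (bridging across slices is allowed).
4. R1 is dilated in-plane with a disk of radius R_d.
5. The dilated content of the extreme occupied slices z0 and zn is pasted
   onto slices z0 - 1 and zn + 1 (clipped to the volume and brain mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volumes_io import DWStudy, ValidationError

__all__ = ["ROIMask", "intensity_mode", "compute_adc_ref", "derive_roi"]

_STRUCT_2D_8 = np.ones((3, 3), dtype=bool)
_STRUCT_3D_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ROIMask:
    """Candidate-lesion region plus the pre-dilation initial region R1."""

    mask: np.ndarray
    initial_mask: np.ndarray
    adc_ref: float
    R_d: int

    def __post_init__(self) -> None:
        if (self.initial_mask.astype(bool) & ~self.mask.astype(bool)).any():
            raise ValidationError("initial_mask must be contained in mask")


def intensity_mode(vol: np.ndarray, mask: np.ndarray) -> float:
    """Most frequent intensity over masked voxels (unit bins on [0, 255]).

    Bin k covers [k - 0.5, k + 0.5); ties are resolved toward the lowest
    bin centre.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty mask")
    vals = np.asarray(vol, dtype=np.float64)[mask]
    idx = np.clip(np.floor(vals + 0.5).astype(np.int64), 0, 255)
    counts = np.bincount(idx, minlength=256)
    return float(np.argmax(counts))  # argmax takes the first (lowest) maximum


def compute_adc_ref(adc: np.ndarray, brain_mask: np.ndarray) -> float:
    """ADC reference value: the most frequent ADC over brain voxels."""
    return intensity_mode(adc, brain_mask)


def _tier1_region(study: DWStudy, adc_ref: float) -> np.ndarray:
    """Per-slice DWI-validated components of strongly reduced ADC."""
    brain = study.brain_mask.astype(bool)
    low = (study.adc <= 0.75 * adc_ref) & brain
    r1 = np.zeros_like(low)
    for z in range(low.shape[2]):
        sl = low[:, :, z]
        if not sl.any():
            continue
        bz = brain[:, :, z]
        if not bz.any():
            continue
        dwi_sl = study.dwi[:, :, z]
        thresh = dwi_sl[bz].mean() + dwi_sl[bz].std()
        labels, n = ndimage.label(sl, structure=_STRUCT_2D_8)
        if n == 0:
            continue
        means = ndimage.mean(dwi_sl, labels=labels, index=np.arange(1, n + 1))
        keep = np.nonzero(means >= thresh)[0] + 1
        if keep.size:
            r1[:, :, z] = np.isin(labels, keep)
    return r1


def _tier2_merge(study: DWStudy, adc_ref: float, r1: np.ndarray) -> np.ndarray:
    """Add moderately-reduced-ADC components touching R1 (26-adjacency)."""
    brain = study.brain_mask.astype(bool)
    mid = (study.adc > 0.75 * adc_ref) & (study.adc < 0.85 * adc_ref) & brain
    if not mid.any() or not r1.any():
        return r1
    touch = ndimage.binary_dilation(r1, structure=_STRUCT_3D_26)
    out = r1.copy()
    for z in range(mid.shape[2]):
        sl = mid[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT_2D_8)
        for comp in range(1, n + 1):
            comp_mask = labels == comp
            if (comp_mask & touch[:, :, z]).any():
                out[:, :, z] |= comp_mask
    return out


def derive_roi(study: DWStudy, R_d: int = 2) -> ROIMask:
    """Derive the candidate-infarct ROI from a preprocessed study.

    Returns an empty ROI (with a warning) when no tier-1 component passes
    the per-slice DWI test; segmentation will then output an empty mask.
    """
    if study.brain_mask is None:
        raise ValidationError("study has no brain mask; run preprocessing first")
    if R_d < 0:
        raise ValidationError("R_d must be >= 0")
    brain = study.brain_mask.astype(bool)
    adc_ref = compute_adc_ref(study.adc, brain)

    r1 = _tier1_region(study, adc_ref)
    if not r1.any():
        warnings.warn("no tier-1 ROI components survive; ROI is empty", stacklevel=2)
        empty = np.zeros(study.shape, dtype=np.uint8)
        return ROIMask(mask=empty, initial_mask=empty.copy(), adc_ref=adc_ref, R_d=R_d)
    r1 = _tier2_merge(study, adc_ref, r1)

    # in-plane dilation with a disk of radius R_d
    dilated = r1.copy()
    if R_d > 0:
        se = disk(R_d).astype(bool)
        for z in range(r1.shape[2]):
            if r1[:, :, z].any():
                dilated[:, :, z] = ndimage.binary_dilation(r1[:, :, z], structure=se)

    # paste extreme occupied slices outward by one
    zs = np.nonzero(dilated.any(axis=(0, 1)))[0]
    z0, zn = int(zs.min()), int(zs.max())
    if z0 - 1 >= 0:
        dilated[:, :, z0 - 1] |= dilated[:, :, z0]
    if zn + 1 < dilated.shape[2]:
        dilated[:, :, zn + 1] |= dilated[:, :, zn]

    dilated &= brain
    r1 &= brain
    return ROIMask(
        mask=dilated.astype(np.uint8),
        initial_mask=r1.astype(np.uint8),
        adc_ref=adc_ref,
        R_d=R_d,
    )
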
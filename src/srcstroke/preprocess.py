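"""Asymmetry-map construction: DWI-ADC difference, midsagittal plane, ASYM.

Hyperacute infarcts are hyperintense on DWI and hypointense on ADC, so the
clamped difference DWI_ADC = max(DWI - ADC, 0) emphasises them.  Because
infarction is almost always unilateral, a voxel whose DWI_ADC value exceeds
everything in a small neighbourhood of its mirror position across the
midsagittal plane (MSP) carries additional evidence; that positive excess is
the asymmetry map ASYM.

The MSP is estimated per axial slice as the reflection line (in-plane angle
theta, offset c) that maximises the masked correlation between the B0 slice
and its own reflection, followed by median-based outlier rejection of the
per-slice offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes_io import ValidationError

__all__ = [
    "MidsagittalPlane",
    "AsymmetryMap",
    "compute_dwi_adc",
    "estimate_msp",
    "compute_asym",
]

MAX_TILT_DEG = 15.0


@dataclass
class MidsagittalPlane:
    """Per-slice midline parameters of the brain's sagittal symmetry plane.

    The midline of axial slice ``z`` is the line through the slice centre
    rotated by ``theta[z]`` radians from the image vertical (the second
    in-plane axis), shifted so that its first-axis coordinate in the rotated
    frame is ``c[z]`` (voxels, absolute).  Reflection across it is an
    involution.
    """

    theta: np.ndarray  # radians, one per slice, |theta| <= 15 deg
    c: np.ndarray      # midline first-axis position per slice, voxels
    shape: tuple[int, int, int]
    symmetry_score: float = 0.0

    def reflect(self, x, y, z):
        """Map in-plane coordinates to their mirror across the slice midline.

        Accepts scalars or arrays; returns float coordinates (callers round
        to the nearest voxel when indexing).
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        th = self.theta[z]
        cx = (self.shape[0] - 1) / 2.0
        cy = (self.shape[1] - 1) / 2.0
        ct, st = np.cos(th), np.sin(th)
        # rotate into the frame where the midline is the column u = c
        u = ct * (x - cx) + st * (y - cy) + cx
        v = -st * (x - cx) + ct * (y - cy) + cy
        u2 = 2.0 * self.c[z] - u
        x2 = ct * (u2 - cx) - st * (v - cy) + cx
        y2 = st * (u2 - cx) + ct * (v - cy) + cy
        return x2, y2

    def mirror_index_maps(self, z: int) -> tuple[np.ndarray, np.ndarray]:
        """Rounded mirrored voxel indices for every (x, y) of slice ``z``."""
        nx, ny = self.shape[0], self.shape[1]
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        x2, y2 = self.reflect(xs, ys, z)
        return np.rint(x2).astype(np.int64), np.rint(y2).astype(np.int64)


@dataclass
class AsymmetryMap:
    """Non-negative asymmetry volume ASYM, zero outside the brain mask."""

    asym: np.ndarray
    neighborhood_halfwidth: int = 2

    def __post_init__(self) -> None:
        if (self.asym < 0).any():
            raise ValidationError("ASYM must be non-negative")


def compute_dwi_adc(dwi: np.ndarray, adc: np.ndarray) -> np.ndarray:
    """Clamped difference max(DWI - ADC, 0), voxelwise."""
    dwi = np.asarray(dwi, dtype=np.float64)
    adc = np.asarray(adc, dtype=np.float64)
    if dwi.shape != adc.shape:
        raise ValidationError(f"shape mismatch: DWI {dwi.shape} vs ADC {adc.shape}")
    return np.maximum(dwi - adc, 0.0)


def _masked_ncc(a: np.ndarray, b: np.ndarray, m: np.ndarray) -> float:
    """Pearson correlation of two slices restricted to mask ``m``."""
    if m.sum() < 16:
        return -1.0
    av = a[m]
    bv = b[m]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom <= 0:
        return -1.0
    return float((av @ bv) / denom)


def _best_reflection_1d(sl: np.ndarray, msk: np.ndarray, t_range) -> tuple[float, float]:
    """Best vertical-midline reflection of a (possibly rotated) slice.

    The reflection x -> t - x (t = 2c) maps the flipped slice onto a shift of
    itself, so candidate offsets are scanned as integer shifts.  Returns
    (best t, best correlation).
    """
    nx = sl.shape[0]
    fl = sl[::-1, :]
    fm = msk[::-1, :]
    best_t, best_r = t_range[0], -1.0
    for t in t_range:
        # mirrored(x) = sl[t - x] = fl[x + (nx - 1 - t)]
        s = nx - 1 - t
        if s >= 0:
            a, b = sl[: nx - s, :], fl[s:, :]
            m = msk[: nx - s, :] & fm[s:, :]
        else:
            a, b = sl[-s:, :], fl[: nx + s, :]
            m = msk[-s:, :] & fm[: nx + s, :]
        r = _masked_ncc(a, b, m)
        if r > best_r:
            best_r, best_t = r, t
    return best_t, best_r


def estimate_msp(
    b0: np.ndarray,
    brain_mask: np.ndarray,
    angle_step_deg: float = 1.0,
    max_tilt_deg: float = MAX_TILT_DEG,
    offset_halfrange: int = 8,
) -> MidsagittalPlane:
    """Estimate the midsagittal plane from B0 by reflection-correlation search.

    For each candidate in-plane angle the slice is rotated so the candidate
    midline is vertical, and integer/half-integer offsets around the brain
    centroid are scanned for the reflection maximising the masked correlation
    of the slice with its mirror.  A single angle (the one maximising the
    mean per-slice correlation) is kept for the whole stack; per-slice
    offsets deviating more than 2 voxels from their median are replaced by
    the median ("outlier removal").

    Falls back to the geometric midline of the brain bounding box, with a
    warning, when the best mean correlation is below 0.2.
    """
    b0 = np.asarray(b0, dtype=np.float64)
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty brain mask")
    nz = b0.shape[2]
    xs = np.nonzero(mask)[0]
    cx_brain = xs.mean()
    angles = np.arange(-max_tilt_deg, max_tilt_deg + 1e-9, angle_step_deg)
    # candidate t = 2c values (half-voxel resolution in c)
    t0 = int(round(2 * cx_brain))
    t_range = range(t0 - 2 * offset_halfrange, t0 + 2 * offset_halfrange + 1)

    scores = np.full((angles.size, nz), -1.0)
    offsets = np.zeros((angles.size, nz))
    # pre-smooth so rotation interpolation (which damps noise) cannot bias
    # the correlation toward nonzero angles
    b0s = ndimage.gaussian_filter(b0, (1.0, 1.0, 0.0))
    for ai, ang in enumerate(angles):
        for z in range(nz):
            msk = mask[:, :, z]
            if msk.sum() < 16:
                continue
            sl = b0s[:, :, z]
            if ang != 0.0:
                # rotate by -ang so a midline tilted by +ang becomes vertical
                sl = ndimage.rotate(sl, -ang, reshape=False, order=1)
                msk = ndimage.rotate(msk.astype(np.float32), -ang, reshape=False, order=0) > 0.5
            t, r = _best_reflection_1d(sl, msk, t_range)
            scores[ai, z] = r
            offsets[ai, z] = t / 2.0

    valid = scores > -1.0
    mean_per_angle = np.where(
        valid.any(axis=1), np.where(valid, scores, 0.0).sum(axis=1) / np.maximum(valid.sum(axis=1), 1), -1.0
    )
    ai = int(np.argmax(mean_per_angle))
    score = float(mean_per_angle[ai])
    if score < 0.2:
        warnings.warn(
            f"low symmetry score {score:.3f}: falling back to geometric midline",
            stacklevel=2,
        )
        c = np.full(nz, (xs.min() + xs.max()) / 2.0)
        return MidsagittalPlane(theta=np.zeros(nz), c=c, shape=b0.shape, symmetry_score=score)

    c = offsets[ai].copy()
    ok = valid[ai]
    med = float(np.median(c[ok])) if ok.any() else cx_brain
    c[~ok] = med
    c[np.abs(c - med) > 2.0] = med  # outlier removal across slices
    theta = np.full(nz, np.deg2rad(angles[ai]))
    return MidsagittalPlane(theta=theta, c=c, shape=b0.shape, symmetry_score=score)


def compute_asym(
    dwi_adc: np.ndarray,
    msp: MidsagittalPlane,
    brain_mask: np.ndarray,
    halfwidth: int = 2,
) -> AsymmetryMap:
    """Asymmetry map: positive excess of DWI_ADC over the mirrored-neighbourhood max.

    For each brain voxel the (2*halfwidth+1)^2 in-plane neighbourhood of the
    mirrored coordinate is searched for its maximum DWI_ADC value;
    ASYM = max(DWI_ADC - that maximum, 0).  Neighbourhoods are clipped at the
    volume border; a mirrored neighbourhood falling entirely outside the
    volume contributes 0 (the voxel keeps its full DWI_ADC value).
    """
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    vol = np.asarray(dwi_adc, dtype=np.float64)
    mask = np.asarray(brain_mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValidationError("dwi_adc and brain_mask shapes differ")
    h = halfwidth
    nx, ny, nz = vol.shape
    out = np.zeros_like(vol)
    size = 2 * h + 1
    for z in range(nz):
        if not mask[:, :, z].any():
            continue
        sl = vol[:, :, z]
        padded = np.pad(sl, h, mode="constant", constant_values=-np.inf)
        mx = ndimage.maximum_filter(padded, size=size, mode="constant", cval=-np.inf)
        x2, y2 = msp.mirror_index_maps(z)
        # clip mirrored centres into the padded index range; centres farther
        # than h outside the slice have an empty clipped neighbourhood
        inside = (x2 >= -h) & (x2 <= nx - 1 + h) & (y2 >= -h) & (y2 <= ny - 1 + h)
        xi = np.clip(x2 + h, 0, mx.shape[0] - 1)
        yi = np.clip(y2 + h, 0, mx.shape[1] - 1)
        sampled = mx[xi, yi]
        max_term = np.where(inside & np.isfinite(sampled), sampled, 0.0)
        out[:, :, z] = np.maximum(sl - max_term, 0.0)
    out[~mask] = 0.0
    return AsymmetryMap(asym=out, neighborhood_halfwidth=h)
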
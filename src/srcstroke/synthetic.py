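"""Seeded synthetic DW-imaging phantoms with ground-truth infarcts.

Every other module is testable without clinical data through these
phantoms.  A phantom is an elliptical "brain" symmetric about a vertical
midline, filled with mirror-symmetric smooth background texture plus
independent per-voxel noise, into which are painted:

* lesions — hyperintense on DWI (contrast given in units of the background
  DWI standard deviation) and hypointense on ADC (level given as a fraction
  < 1 of the background ADC mode), optionally with blurred (ill-defined)
  borders and multiplicative intensity inhomogeneity;
* shine-through mimics — hyperintense on DWI but with ADC at or above the
  background mode, which a correct ROI must exclude.

Background channel modes are fixed at B0 110, DWI 100, ADC 120 (rescaled
units) so that the ADC reference mode recovered downstream is predictable.
All channels are clipped at zero, which makes the later min–max rescale to
[0, 255] purely multiplicative and preserves ADC ratios exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes_io import DWStudy, ValidationError

__all__ = ["Blob", "PhantomSpec", "Phantom", "generate_phantom", "generate_suite"]

B0_LEVEL = 110.0
DWI_LEVEL = 100.0
ADC_LEVEL = 120.0


@dataclass(frozen=True)
class Blob:
    """An ellipsoidal lesion or mimic.

    center, radii
        Voxel coordinates / semi-axes (x, y, z).
    dwi_contrast
        DWI hyperintensity in units of the background DWI standard deviation.
    adc_fraction
        Target ADC level as a fraction of the background ADC mode; < 1 for
        lesions, >= 1 for shine-through mimics.
    edge_blur_sd
        In-plane Gaussian blur of the blob's support (0 = sharp edges).
    inhomogeneity
        Amplitude of multiplicative intensity inhomogeneity inside the blob.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    dwi_contrast: float = 4.0
    adc_fraction: float = 0.6
    edge_blur_sd: float = 0.0
    inhomogeneity: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic study."""

    shape: tuple[int, int, int] = (64, 64, 18)
    midline_x: float | None = None  # default: (nx - 1) / 2
    rotation_deg: float = 0.0
    brain_semiaxes: tuple[float, float, float] | None = None
    background_sd: float = 3.0  # smooth symmetric texture amplitude
    noise_sd: float = 2.0  # independent per-voxel noise (hemisphere-independent)
    lesions: tuple[Blob, ...] = ()
    mimics: tuple[Blob, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.lesions:
            if not (0.0 < b.adc_fraction < 1.0):
                raise ValidationError("lesion ADC fraction must be in (0, 1)")
        for b in self.mimics:
            if b.adc_fraction < 1.0:
                raise ValidationError("mimic ADC fraction must be >= 1")


@dataclass
class Phantom:
    """Generated study with analytic masks."""

    study: DWStudy
    gt: np.ndarray
    mimic_mask: np.ndarray
    brain: np.ndarray = field(repr=False)
    spec: PhantomSpec = field(repr=False, default=None)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    xs, ys, zs = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
    )
    return q <= 1.0


def _symmetric_field(shape, midline_x, sd, rng, smooth=4.0) -> np.ndarray:
    """Smooth texture exactly symmetric under x -> 2*midline_x - x."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), (smooth, smooth, smooth / 2))
    s = f.std()
    if s > 0:
        f *= sd / s
    nx = shape[0]
    xs = np.arange(nx)
    xm = np.rint(2 * midline_x - xs).astype(np.int64)
    ok = (xm >= 0) & (xm < nx)
    half = xs < midline_x
    out = f.copy()
    src = half & ok
    out[xm[src], :, :] = f[xs[src], :, :]  # mirror the left half onto the right
    return out


def _blob_support(shape, blob: Blob) -> tuple[np.ndarray, np.ndarray]:
    """(hard GT support, soft support in [0, 1] after optional edge blur)."""
    hard = _ellipsoid(shape, blob.center, blob.radii)
    soft = hard.astype(np.float64)
    if blob.edge_blur_sd > 0:
        soft = ndimage.gaussian_filter(soft, (blob.edge_blur_sd, blob.edge_blur_sd, 0.0))
        soft = np.clip(soft / max(soft.max(), 1e-12), 0.0, 1.0)
    return hard, soft


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a deterministic phantom study from its spec.

    GT is the pre-blur lesion support; the mimic mask is returned separately
    and never overlaps GT.
    """
    nx, ny, nz = spec.shape
    midline = spec.midline_x if spec.midline_x is not None else (nx - 1) / 2.0
    semi = spec.brain_semiaxes or (0.40 * nx, 0.44 * ny, 0.62 * nz)
    center = (midline, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain = _ellipsoid(spec.shape, center, semi)

    rng = np.random.default_rng(spec.seed)
    tex = _symmetric_field(spec.shape, midline, spec.background_sd, rng)
    b0 = np.where(brain, B0_LEVEL + tex, 0.0)
    dwi = np.where(brain, DWI_LEVEL + tex, 0.0)
    adc = np.where(brain, ADC_LEVEL + tex, 0.0)

    gt = np.zeros(spec.shape, dtype=bool)
    mimic_mask = np.zeros(spec.shape, dtype=bool)
    for blob, is_mimic in [(b, False) for b in spec.lesions] + [(b, True) for b in spec.mimics]:
        hard, soft = _blob_support(spec.shape, blob)
        if not (hard <= brain).all():
            raise ValidationError(f"blob at {blob.center} extends outside the brain")
        inhom = 1.0
        if blob.inhomogeneity > 0:
            f = ndimage.gaussian_filter(rng.standard_normal(spec.shape), (3, 3, 1.5))
            s = f.std()
            inhom = 1.0 + blob.inhomogeneity * (f / s if s > 0 else f)
            inhom = np.clip(inhom, 0.3, None)
        dwi += blob.dwi_contrast * spec.background_sd * soft * inhom
        adc += soft * (blob.adc_fraction * ADC_LEVEL - ADC_LEVEL)
        b0 += 0.5 * spec.background_sd * soft  # mild T2 effect
        if is_mimic:
            mimic_mask |= hard
        else:
            gt |= hard

    if spec.noise_sd > 0:
        b0 += np.where(brain, rng.normal(0, spec.noise_sd, spec.shape), 0.0)
        dwi += np.where(brain, rng.normal(0, spec.noise_sd, spec.shape), 0.0)
        adc += np.where(brain, rng.normal(0, spec.noise_sd, spec.shape), 0.0)

    if spec.rotation_deg != 0.0:
        rot = lambda v, order: np.stack(  # noqa: E731
            [
                ndimage.rotate(v[:, :, z], spec.rotation_deg, reshape=False, order=order)
                for z in range(nz)
            ],
            axis=2,
        )
        b0, dwi, adc = rot(b0, 1), rot(dwi, 1), rot(adc, 1)
        brain = rot(brain.astype(np.float32), 0) > 0.5
        gt = rot(gt.astype(np.float32), 0) > 0.5
        mimic_mask = rot(mimic_mask.astype(np.float32), 0) > 0.5

    b0, dwi, adc = (np.clip(v, 0.0, None) for v in (b0, dwi, adc))
    study = DWStudy(
        b0=b0,
        dwi=dwi,
        adc=adc,
        spacing=(1.0, 1.0, 5.0),
        subject_id=f"phantom-{spec.seed}",
        gt=gt.astype(np.uint8),
    )
    return Phantom(study=study, gt=gt.astype(np.uint8), mimic_mask=mimic_mask.astype(np.uint8), brain=brain.astype(np.uint8), spec=spec)


def _random_lesion(rng: np.random.Generator, spec_shape, midline, suite: str) -> Blob:
    nx, ny, nz = spec_shape
    rx = rng.uniform(4.0, 6.0)
    ry = rng.uniform(4.0, 6.0)
    rz = rng.uniform(1.5, 2.5)
    side = rng.choice([-1.0, 1.0])
    cx = midline + side * rng.uniform(8.0, 14.0)
    cy = (ny - 1) / 2.0 + rng.uniform(-8.0, 8.0)
    cz = (nz - 1) / 2.0 + rng.uniform(-2.0, 2.0)
    if suite == "hard":
        return Blob(
            center=(cx, cy, cz),
            radii=(rx, ry, rz),
            dwi_contrast=rng.uniform(2.0, 3.0),
            adc_fraction=0.6,
            edge_blur_sd=1.5,
            inhomogeneity=0.3,
        )
    return Blob(
        center=(cx, cy, cz),
        radii=(rx, ry, rz),
        dwi_contrast=rng.uniform(4.0, 5.0),
        adc_fraction=0.6,
        edge_blur_sd=0.0,
        inhomogeneity=0.0,
    )


def _random_mimic(rng: np.random.Generator, spec_shape, midline, lesion: Blob) -> Blob:
    nx, ny, nz = spec_shape
    # opposite hemisphere from the lesion, away from its mirror position
    side = -np.sign(lesion.center[0] - midline) or 1.0
    cx = midline + side * rng.uniform(8.0, 14.0)
    cy = (ny - 1) / 2.0 + rng.uniform(-10.0, 10.0)
    cz = (nz - 1) / 2.0 + rng.uniform(-3.0, 3.0)
    return Blob(
        center=(cx, cy, cz),
        radii=(rng.uniform(2.5, 4.0), rng.uniform(2.5, 4.0), rng.uniform(1.0, 2.0)),
        dwi_contrast=rng.uniform(4.0, 5.0),
        adc_fraction=rng.uniform(1.0, 1.1),
    )


def generate_suite(name: str, n: int, seed: int) -> list[Phantom]:
    """Generate a named suite of phantoms.

    easy
        Sharp-edged homogeneous lesions, DWI contrast >= 4 background sd,
        ADC fraction 0.6.
    hard
        Blurred edges (sd 1.5 voxels), inhomogeneity amplitude 0.3, DWI
        contrast 2-3 sd.
    mimic
        Easy lesions plus 1-2 shine-through blobs per study.
    clean
        Lesion-free symmetric phantoms (for specificity checks).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if name not in ("easy", "hard", "mimic", "clean"):
        raise ValidationError(f"unknown suite {name!r}")
    shape = (64, 64, 18)
    midline = (shape[0] - 1) / 2.0
    children = np.random.SeedSequence(seed).spawn(n)
    phantoms = []
    for i, ss in enumerate(children):
        child_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child_seed)
        lesions: tuple[Blob, ...] = ()
        mimics: tuple[Blob, ...] = ()
        if name != "clean":
            lesion = _random_lesion(rng, shape, midline, name)
            lesions = (lesion,)
            if name == "mimic":
                k = int(rng.integers(1, 3))
                mimics = tuple(_random_mimic(rng, shape, midline, lesion) for _ in range(k))
        spec = PhantomSpec(
            shape=shape,
            lesions=lesions,
            mimics=mimics,
            seed=child_seed,
        )
        ph = generate_phantom(spec)
        ph.study = replace(ph.study, subject_id=f"{name}-{i:02d}")
        phantoms.append(ph)
    return phantoms
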
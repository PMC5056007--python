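"""Patch feature extraction and boundary-focused training-sample selection.

Every sample voxel is described by the raw intensities of small patches
centred on it, one patch per channel (B0, DWI, ADC, ASYM), flattened in
row-major order and concatenated in channel order.  With patch radius R_p
the side length is d = 2*R_p + 1 and the feature length is |channels|*d^2
for 2D (in-plane) patches or |channels|*d^3 for 3D patches.

Training samples: positives are all ground-truth (GT) infarct voxels;
negatives are the non-infarct voxels swept up by iteratively dilating GT
with a unit-radius structuring element until at least as many new voxels as
|GT| are included — the voxels nearest the lesion boundary, which are the
hardest to classify and whose inclusion balances the two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import AsymmetryMap
from .volumes_io import DWStudy, ValidationError

__all__ = [
    "PatchConfig",
    "SampleSet",
    "extract_features",
    "select_training_samples",
]

DEFAULT_CHANNELS = ("b0", "dwi", "adc", "asym")


@dataclass(frozen=True)
class PatchConfig:
    """Patch geometry and channel selection.

    radius
        R_p >= 1; patch side d = 2*R_p + 1.
    mode
        "2d" for in-plane square patches, "3d" for cubes.
    channels
        Ordered subset of ("b0", "dwi", "adc", "asym").
    """

    radius: int = 1
    mode: str = "2d"
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValidationError("patch radius must be >= 1")
        if self.mode not in ("2d", "3d"):
            raise ValidationError(f"unknown patch mode {self.mode!r}")
        bad = [c for c in self.channels if c not in DEFAULT_CHANNELS]
        if bad:
            raise ValidationError(f"unknown channels {bad}")

    @property
    def side(self) -> int:
        return 2 * self.radius + 1

    @property
    def feature_length(self) -> int:
        per = self.side ** 2 if self.mode == "2d" else self.side ** 3
        return len(self.channels) * per


@dataclass
class SampleSet:
    """Labelled feature matrices for dictionary training.

    ``positives`` / ``negatives`` are (n, m) arrays of feature vectors;
    ``provenance`` records how the negatives were drawn.
    """

    positives: np.ndarray
    negatives: np.ndarray
    positive_voxels: np.ndarray = field(repr=False)
    negative_voxels: np.ndarray = field(repr=False)
    provenance: str = "boundary"


def _channel_volumes(study: DWStudy, asym: AsymmetryMap | None, cfg: PatchConfig):
    vols = {"b0": study.b0, "dwi": study.dwi, "adc": study.adc}
    if "asym" in cfg.channels:
        if asym is None:
            raise ValidationError("ASYM channel requested but no asymmetry map given")
        vols["asym"] = asym.asym
    return [np.asarray(vols[c], dtype=np.float64) for c in cfg.channels]


def extract_features(
    study: DWStudy,
    asym: AsymmetryMap | None,
    voxels: np.ndarray,
    cfg: PatchConfig,
) -> np.ndarray:
    """Extract concatenated patch features at the given voxels.

    Parameters
    ----------
    voxels
        (n, 3) integer array of (x, y, z) patch centres, all inside the
        volume.  Patches crossing the border are completed by nearest-voxel
        replication.

    Returns
    -------
    (n, m) float array, one feature vector per voxel, m = cfg.feature_length.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
    if voxels.size == 0:
        return np.empty((0, cfg.feature_length))
    shape = study.shape
    bad = (
        (voxels < 0).any(axis=1)
        | (voxels[:, 0] >= shape[0])
        | (voxels[:, 1] >= shape[1])
        | (voxels[:, 2] >= shape[2])
    )
    if bad.any():
        raise ValidationError(f"voxels outside volume: {voxels[bad][:10].tolist()}")

    r = cfg.radius
    d = cfg.side
    offs = np.arange(-r, r + 1)
    if cfg.mode == "2d":
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        ox, oy = ox.ravel(), oy.ravel()
        oz = np.zeros_like(ox)
    else:
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        ox, oy, oz = ox.ravel(), oy.ravel(), oz.ravel()

    # replicate-pad via index clipping
    xi = np.clip(voxels[:, 0, None] + ox[None, :], 0, shape[0] - 1)
    yi = np.clip(voxels[:, 1, None] + oy[None, :], 0, shape[1] - 1)
    zi = np.clip(voxels[:, 2, None] + oz[None, :], 0, shape[2] - 1)

    vols = _channel_volumes(study, asym, cfg)
    parts = [v[xi, yi, zi] for v in vols]
    return np.concatenate(parts, axis=1)


def _dilate_until_balanced(gt: np.ndarray, brain: np.ndarray) -> np.ndarray:
    """Dilate GT with the unit cross until the new non-GT brain voxels >= |GT|."""
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connected unit ball
    n_gt = int(gt.sum())
    dilated = gt.copy()
    max_iters = int(np.sum(brain.shape))
    for _ in range(max_iters):
        dilated = ndimage.binary_dilation(dilated, structure=struct)
        ring = dilated & brain & ~gt
        if int(ring.sum()) >= n_gt:
            return ring
    return dilated & brain & ~gt


def select_training_samples(
    gt: np.ndarray,
    brain_mask: np.ndarray,
    study: DWStudy,
    asym: AsymmetryMap | None,
    cfg: PatchConfig,
    provenance: str = "boundary",
    rng: np.random.Generator | None = None,
    extra_global_negatives: bool = False,
) -> SampleSet:
    """Build a balanced training sample set from a ground-truth mask.

    provenance
        "boundary" (default): negatives from the dilated-GT shell.
        "random": same number of negatives drawn uniformly from non-GT brain
        voxels (ablation mode); requires ``rng``.
    extra_global_negatives
        Add an equal extra portion of negatives drawn uniformly from brain
        voxels outside the dilated shell (used when training the whole-brain,
        no-ROI variant); requires ``rng``.
    """
    gt = np.asarray(gt).astype(bool)
    brain = np.asarray(brain_mask).astype(bool)
    if not gt.any():
        raise ValidationError("empty ground-truth mask")
    if (gt & ~brain).any():
        warnings.warn("GT extends outside the brain mask; clipping", stacklevel=2)
        gt = gt & brain

    pos_vox = np.argwhere(gt)
    if provenance == "boundary":
        ring = _dilate_until_balanced(gt, brain)
        if not ring.any():
            raise ValidationError("no negatives available: GT fills the brain mask")
        neg_vox = np.argwhere(ring)
    elif provenance == "random":
        if rng is None:
            raise ValidationError("random provenance requires an rng")
        pool = np.argwhere(brain & ~gt)
        if pool.shape[0] == 0:
            raise ValidationError("no negatives available: GT fills the brain mask")
        k = min(pos_vox.shape[0], pool.shape[0])
        neg_vox = pool[rng.choice(pool.shape[0], size=k, replace=False)]
    else:
        raise ValidationError(f"unknown provenance {provenance!r}")

    label = provenance
    if extra_global_negatives:
        if rng is None:
            raise ValidationError("extra_global_negatives requires an rng")
        shell = np.zeros_like(gt)
        shell[tuple(neg_vox.T)] = True
        pool = np.argwhere(brain & ~gt & ~shell)
        if pool.shape[0] > 0:
            k = min(neg_vox.shape[0], pool.shape[0])
            extra = pool[rng.choice(pool.shape[0], size=k, replace=False)]
            neg_vox = np.concatenate([neg_vox, extra], axis=0)
        label = provenance + "+global"

    return SampleSet(
        positives=extract_features(study, asym, pos_vox, cfg),
        negatives=extract_features(study, asym, neg_vox, cfg),
        positive_voxels=pos_vox,
        negative_voxels=neg_vox,
        provenance=label,
    )
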
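"""End-to-end training, segmentation, evaluation and cross-validation.

The full method: rescale the study to [0, 255], build the asymmetry map,
derive the candidate-infarct ROI, extract 4-channel patch features, and
classify each candidate voxel by sparse-representation classification
against per-class dictionaries learned with the elastic net.  Defaults are
the configuration found optimal for this method (lambda1 = 0.3,
lambda2 = 0.1, patch radius R_p = 1, ROI dilation R_d = 2, K = 200 atoms
per class, 2D patches, all four channels).

A whole-brain variant (``use_roi=False``) classifies every brain voxel and
cleans the result with connected-component post-processing; a simple
asymmetry-threshold baseline is also provided for comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import PatchConfig, extract_features, select_training_samples
from .preprocess import AsymmetryMap, MidsagittalPlane, compute_asym, compute_dwi_adc, estimate_msp
from .roi import ROIMask, derive_roi, intensity_mode
from .sparse_model import (
    ClassDictionary,
    ElasticNetParams,
    classify_batch,
    learn_dictionary,
    unit_normalize,
)
from .volumes_io import DWStudy, ValidationError, compute_brain_mask, rescale_volume

__all__ = [
    "PipelineConfig",
    "PreparedStudy",
    "SegmentationResult",
    "ModelBundle",
    "prepare_study",
    "train",
    "segment",
    "postprocess_no_roi",
    "asym_threshold_baseline",
    "evaluate",
    "cross_validate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Frozen defaults of the method; every field overridable."""

    patch: PatchConfig = field(default_factory=PatchConfig)
    enet: ElasticNetParams = field(
        default_factory=lambda: ElasticNetParams(lambda1=0.3, lambda2=0.1, max_iter=60, tol=1e-4)
    )
    K: int = 200
    R_d: int = 2
    use_roi: bool = True
    normalize_features: bool = True
    negatives: str = "boundary"  # or "random" (ablation)
    dict_mode: str = "online"
    epochs: int = 5
    batch_size: int = 256


@dataclass
class PreparedStudy:
    """Rescaled study with brain mask, DWI-ADC map, MSP and asymmetry map."""

    study: DWStudy
    msp: MidsagittalPlane
    dwi_adc: np.ndarray
    asym: AsymmetryMap


@dataclass
class SegmentationResult:
    """Predicted infarct mask with confusion counts and overlap metrics."""

    mask: np.ndarray
    confusion: dict[str, int] | None = None
    metrics: dict[str, float] | None = None


@dataclass
class ModelBundle:
    """Trained per-class dictionaries plus the configuration that made them."""

    D_infarct: ClassDictionary
    D_normal: ClassDictionary
    config: PipelineConfig
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.config.patch.feature_length
        if self.D_infarct.m != m or self.D_normal.m != m:
            raise ValidationError(
                f"dictionary atom dim ({self.D_infarct.m}) does not match "
                f"patch feature length ({m})"
            )


def prepare_study(study: DWStudy, asym_halfwidth: int = 2) -> PreparedStudy:
    """Rescale channels, derive the brain mask, the MSP and the asymmetry map."""
    rs = study.rescaled()
    if rs.brain_mask is None:
        rs = replace(rs, brain_mask=compute_brain_mask(rs.b0))
    dwi_adc = compute_dwi_adc(rs.dwi, rs.adc)
    msp = estimate_msp(rs.b0, rs.brain_mask)
    asym = compute_asym(dwi_adc, msp, rs.brain_mask, halfwidth=asym_halfwidth)
    return PreparedStudy(study=rs, msp=msp, dwi_adc=dwi_adc, asym=asym)


def train(
    prepared: list[PreparedStudy],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Learn the infarct / normal dictionaries from studies with ground truth.

    Boundary-focused samples are pooled across studies; with
    ``cfg.use_roi=False`` an equal extra portion of negatives is drawn from
    the rest of the brain so the normal dictionary also represents distant
    tissue.  Fully reproducible from ``seed``.
    """
    cfg = cfg or PipelineConfig()
    if not prepared:
        raise ValidationError("empty training set")
    rng = np.random.default_rng(seed)
    pos_parts, neg_parts = [], []
    n_pos = n_neg = 0
    for ps in prepared:
        if ps.study.gt is None or not ps.study.gt.any():
            raise ValidationError(f"study {ps.study.subject_id!r} has empty ground truth")
        ss = select_training_samples(
            ps.study.gt,
            ps.study.brain_mask,
            ps.study,
            ps.asym,
            cfg.patch,
            provenance=cfg.negatives,
            rng=rng,
            extra_global_negatives=not cfg.use_roi,
        )
        pos_parts.append(ss.positives)
        neg_parts.append(ss.negatives)
        n_pos += ss.positives.shape[0]
        n_neg += ss.negatives.shape[0]

    positives = np.concatenate(pos_parts, axis=0)
    negatives = np.concatenate(neg_parts, axis=0)
    if cfg.normalize_features:
        positives = unit_normalize(positives)
        negatives = unit_normalize(negatives)
    # independent deterministic streams for the two dictionaries
    s_inf, s_norm = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(2))
    D_inf = learn_dictionary(
        positives, cfg.K, cfg.enet, epochs=cfg.epochs, seed=s_inf,
        mode=cfg.dict_mode, batch_size=cfg.batch_size, class_label="infarct",
    )
    D_norm = learn_dictionary(
        negatives, cfg.K, cfg.enet, epochs=cfg.epochs, seed=s_norm,
        mode=cfg.dict_mode, batch_size=cfg.batch_size, class_label="normal",
    )
    manifest = {
        "seed": seed,
        "n_positives": int(n_pos),
        "n_negatives": int(n_neg),
        "n_studies": len(prepared),
        "negatives_provenance": cfg.negatives + ("" if cfg.use_roi else "+global"),
        "evaluation_domain": "brain_mask",
    }
    return ModelBundle(D_infarct=D_inf, D_normal=D_norm, config=cfg, manifest=manifest)


def _classify_voxels(
    ps: PreparedStudy, model: ModelBundle, voxels: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    labels = np.zeros(voxels.shape[0], dtype=bool)
    for lo in range(0, voxels.shape[0], chunk):
        feats = extract_features(ps.study, ps.asym, voxels[lo : lo + chunk], model.config.patch)
        if model.config.normalize_features:
            feats = unit_normalize(feats)
        lab, _ = classify_batch(feats.T, model.D_infarct, model.D_normal, model.config.enet)
        labels[lo : lo + feats.shape[0]] = lab
    return labels


def segment(
    ps: PreparedStudy,
    model: ModelBundle,
    use_roi: bool | None = None,
    roi: ROIMask | None = None,
) -> SegmentationResult:
    """Segment a prepared study with a trained model.

    With the ROI, only candidate voxels are classified and everything else
    is normal; without it every brain voxel is classified and the mask is
    cleaned by :func:`postprocess_no_roi`.  Metrics are attached when the
    study carries ground truth.
    """
    if use_roi is None:
        use_roi = model.config.use_roi
    brain = ps.study.brain_mask.astype(bool)
    if use_roi:
        roi = roi or derive_roi(ps.study, model.config.R_d)
        voxels = np.argwhere(roi.mask.astype(bool))
    else:
        voxels = np.argwhere(brain)

    mask = np.zeros(ps.study.shape, dtype=np.uint8)
    if voxels.shape[0]:
        labels = _classify_voxels(ps, model, voxels)
        mask[tuple(voxels[labels].T)] = 1
    if not use_roi:
        mask = postprocess_no_roi(mask, ps.study)

    result = SegmentationResult(mask=mask)
    if ps.study.gt is not None:
        ev = evaluate(mask, ps.study.gt, brain)
        result.confusion, result.metrics = ev.confusion, ev.metrics
    return result


def postprocess_no_roi(mask: np.ndarray, study: DWStudy) -> np.ndarray:
    """Clean a whole-brain classification mask.

    Drops 3D connected components (26-connectivity) with fewer than 3
    voxels, with mean DWI below the most frequent brain DWI value, or with
    mean ADC above the most frequent brain ADC value.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask.astype(np.uint8)
    brain = study.brain_mask.astype(bool)
    dwi_mode = intensity_mode(study.dwi, brain)
    adc_mode = intensity_mode(study.adc, brain)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels=labels, index=idx)
    mean_dwi = ndimage.mean(study.dwi, labels=labels, index=idx)
    mean_adc = ndimage.mean(study.adc, labels=labels, index=idx)
    keep = idx[(sizes >= 3) & (mean_dwi >= dwi_mode) & (mean_adc <= adc_mode)]
    return np.isin(labels, keep).astype(np.uint8)


def asym_threshold_baseline(asym: AsymmetryMap, t: float, brain_mask: np.ndarray) -> np.ndarray:
    """Baseline segmentation: brain voxels whose asymmetry exceeds t."""
    if t < 0:
        raise ValidationError("threshold must be >= 0")
    return ((asym.asym > t) & np.asarray(brain_mask).astype(bool)).astype(np.uint8)


def evaluate(pred: np.ndarray, gt: np.ndarray, eval_mask: np.ndarray) -> SegmentationResult:
    """Confusion counts and overlap metrics over the evaluation mask.

    DC = 2 TP / (FP + 2 TP + FN); sensitivity, specificity, PPV and NPV are
    the usual ratios.  Conventions for empty denominators: DC = 1 when both
    prediction and ground truth are empty; a ratio with zero denominator is
    reported as NaN (missing).
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    dom = np.asarray(eval_mask).astype(bool)
    if not (pred.shape == gt.shape == dom.shape):
        raise ValidationError("pred, gt and eval_mask shapes differ")
    p, g = pred[dom], gt[dom]
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))

    def ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    dc = 1.0 if (tp + fp + fn) == 0 else 2.0 * tp / (fp + 2.0 * tp + fn)
    metrics = {
        "DC": dc,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }
    return SegmentationResult(
        mask=pred.astype(np.uint8),
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        metrics=metrics,
    )


def cross_validate(
    studies: list[DWStudy],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    prepared: list[PreparedStudy] | None = None,
) -> pd.DataFrame:
    """2-fold cross-validation over studies with ground truth.

    The studies are randomly split into two equal groups (seeded); each
    group's model segments the other group.  Returns one metric row per
    study plus the fold assignment; summarise with ``df.mean()`` /
    ``df.std()``.
    """
    cfg = cfg or PipelineConfig()
    if len(studies) < 2:
        raise ValidationError("cross-validation needs at least 2 studies")
    if prepared is None:
        prepared = [prepare_study(s) for s in studies]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(prepared))
    half = len(prepared) // 2
    folds = [order[:half], order[half:]]

    rows = []
    for fi in (0, 1):
        train_idx, test_idx = folds[1 - fi], folds[fi]
        model = train([prepared[i] for i in train_idx], cfg, seed=seed + fi)
        for i in test_idx:
            res = segment(prepared[i], model)
            row = {"subject_id": prepared[i].study.subject_id, "fold": fi}
            row.update(res.metrics or {})
            row.update(res.confusion or {})
            rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: ModelBundle, out_dir: str | Path) -> None:
    """Write a model bundle: per-class atom matrices + a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "D_infarct.npy", model.D_infarct.atoms)
    np.save(out / "D_normal.npy", model.D_normal.atoms)
    cfg = model.config
    manifest = {
        "lambda1": cfg.enet.lambda1,
        "lambda2": cfg.enet.lambda2,
        "max_iter": cfg.enet.max_iter,
        "tol": cfg.enet.tol,
        "K": cfg.K,
        "R_d": cfg.R_d,
        "use_roi": cfg.use_roi,
        "normalize_features": cfg.normalize_features,
        "negatives": cfg.negatives,
        "dict_mode": cfg.dict_mode,
        "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
        "patch_radius": cfg.patch.radius,
        "patch_mode": cfg.patch.mode,
        "channels": list(cfg.patch.channels),
        "training": model.manifest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(model_dir: str | Path) -> ModelBundle:
    """Load a model bundle written by :func:`save_model`."""
    d = Path(model_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = PipelineConfig(
        patch=PatchConfig(
            radius=manifest["patch_radius"],
            mode=manifest["patch_mode"],
            channels=tuple(manifest["channels"]),
        ),
        enet=ElasticNetParams(
            lambda1=manifest["lambda1"],
            lambda2=manifest["lambda2"],
            max_iter=manifest["max_iter"],
            tol=manifest["tol"],
        ),
        K=manifest["K"],
        R_d=manifest["R_d"],
        use_roi=manifest["use_roi"],
        normalize_features=manifest.get("normalize_features", True),
        negatives=manifest["negatives"],
        dict_mode=manifest["dict_mode"],
        epochs=manifest["epochs"],
        batch_size=manifest["batch_size"],
    )
    return ModelBundle(
        D_infarct=ClassDictionary(np.load(d / "D_infarct.npy"), "infarct"),
        D_normal=ClassDictionary(np.load(d / "D_normal.npy"), "normal"),
        config=cfg,
        manifest=manifest.get("training", {}),
    )
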
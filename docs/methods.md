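# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish.

## Model and assumptions

The segmenter is a patch-based sparse-representation classifier.  Its core
assumptions are:

* The three input volumes (B0, DWI, ADC) are co-registered on a common
  grid with axial slices along the third axis; no registration is
  performed.
* Infarcts are hyperintense on DWI and hypointense on ADC, and are
  unilateral enough that the mirrored-neighbourhood asymmetry map carries
  signal.  Bilateral symmetric lesions would be invisible to the ASYM
  channel (they remain visible to the other three).
* Local appearance is informative: a voxel's class is decided from the
  raw intensities of small patches around it, with no global shape prior.

### Elastic-net sparse coding

A sample `s ∈ R^m` is coded against a dictionary `D` by minimising
`½‖s − Dα‖² + λ₁‖α‖₁ + (λ₂/2)‖α‖²`.  The L2 term matters because patches
from homogeneous tissue are strongly correlated: with a pure lasso the
coefficient path flips between near-duplicate atoms, while the elastic net
distributes weight stably.  The solver is cyclic coordinate descent; each
coordinate update is the exact scalar minimiser
`αⱼ ← S(dⱼᵀr + gⱼαⱼ, λ₁)/(gⱼ + λ₂)` (S = soft threshold, gⱼ = ‖dⱼ‖²), so
the objective is monotone and the iterate satisfies the elastic-net KKT
conditions at convergence.  The implementation is vectorised across
samples sharing a dictionary, which is what makes whole-ROI classification
cheap.

Correctness is audited two independent ways in the tests: against a
proximal-gradient (ISTA) solver and against scikit-learn's coordinate
descent under the appropriate objective rescaling, plus closed forms on
orthonormal dictionaries.

### Dictionary learning

Per-class dictionaries (unit-L2 atoms, K = 200 by default) are learned by
alternating sparse coding with a block coordinate-descent atom update.
Two modes exist:

* **batch** — codes are warm-started from the previous epoch and each atom
  update is the exact column minimiser on the unit sphere, so the
  epoch-level objective is provably non-increasing (the property the test
  suite asserts to 1e−8).
* **online** (default for training) — mini-batches with accumulated
  sufficient statistics, after the classical stochastic-approximation
  scheme; much faster on tens of thousands of samples, monotone only in
  expectation.

Initial atoms are K distinct samples drawn by a seeded generator and
normalised; if fewer distinct samples exist, seeded random unit atoms pad
the dictionary (with a warning).  All randomness flows from explicit
seeds; identical seeds reproduce dictionaries bit for bit.

### Feature normalisation

Feature vectors are unit-L2-normalised before learning and encoding
(`PipelineConfig.normalize_features`, on by default).  The penalty weights
λ₁ = 0.3, λ₂ = 0.1 are calibrated for unit-scale samples, the convention
of the SRC literature and of the common sparse-coding toolboxes.  On raw
[0, 255]-scale patches (norms of several hundred) the penalties are
negligible, codes are dense and slow to converge, and the class residues
become an ill-conditioned comparison: on the easy phantom suite this
costs roughly half the Dice score (≈ 0.50 vs ≈ 1.0, driven by a ring of
false positives around the lesion boundary).  Normalisation only rescales
each sample, so the residue comparison between the two class
sub-dictionaries is unaffected in structure.

### Training samples

Positives are all ground-truth voxels.  Negatives are taken from the
shell produced by iteratively dilating the ground truth with the
6-connected unit structuring element until at least |GT| new non-lesion
brain voxels are covered.  The stopping rule is read as a class-balance
condition (the literal "dilated size ≥ original size" is satisfied by any
dilation).  These boundary voxels are the hardest negatives — their
patches straddle the lesion edge — and training on them is what keeps the
classifier from over-calling the dilated ROI ring.  Ablation mode draws
the same number of negatives uniformly from non-lesion brain instead; the
no-ROI variant adds an equal extra portion of global negatives so the
normal dictionary also represents distant tissue.

### ROI rules and tie-breaks

* ADC_ref is the mode of brain ADC on unit-width bins over [0, 255]; ties
  take the lowest bin.  Volumes are kept floating point after rescale so
  relative thresholds (0.75·ADC_ref, 0.85·ADC_ref) are exact.
* Tier-1 components are per-slice 2D (8-connectivity) because the DWI
  validation statistic is defined per axial slice; tier-2 adjacency is
  tested in 3D (26-connectivity) so moderately reduced ADC can bridge
  slices.  Tier-1 uses ≤, tier-2 the open interval.
* Dilation is in-plane (disk of radius R_d): slices are ~5 mm apart, so
  out-of-plane dilation would be anatomically aggressive; the z direction
  is handled by pasting the extreme occupied slices one slice outward.
  Pasted content is clipped to the brain mask.
* An empty tier-1 result yields an empty ROI (and hence an empty
  segmentation) with a warning rather than an error: a lesion-free study
  is a legitimate input.

### Midsagittal plane

The MSP is found by exhaustive search: for each candidate in-plane angle
(±15°, 1° steps) the slice is rotated so the candidate midline is
vertical and reflection offsets are scanned at half-voxel resolution
around the brain centroid, scoring masked Pearson correlation between the
slice and its mirror.  One angle (best mean correlation) is kept for the
stack; per-slice offsets deviating more than 2 voxels from the median are
replaced by it.  B0 is pre-smoothed (σ = 1 voxel in-plane) before
scoring — rotation interpolation damps noise, and without pre-smoothing
that systematically biases the correlation toward nonzero angles.  If the
best mean correlation is below 0.2 the estimator falls back to the
geometric midline of the brain bounding box with a warning.  Mirrored
coordinates are rounded to the nearest voxel before the neighbourhood max
(the asymmetry rule indexes discrete voxels; interpolation would change
max semantics).  A mirrored neighbourhood that is entirely outside the
volume contributes 0, so a hyperintensity with no contralateral
counterpart keeps its full value.

### Classification conventions

Residue ties classify as normal (conservative toward false positives).
Evaluation counts true negatives inside the brain mask only — the
stricter convention; the manifest records it so users can recompute
whole-volume variants.  Dice with empty prediction and empty ground truth
is defined as 1 (identity of empty sets); ratios with empty denominators
are reported as missing (NaN).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| λ₁ | 0.3 | L1 weight; sparsity of the code |
| λ₂ | 0.1 | L2 weight; stability under correlated atoms |
| R_p | 1 | patch radius (voxels); d = 2R_p+1 |
| patch mode | 2d | in-plane patches; 3d available |
| K | 200 | atoms per class dictionary |
| R_d | 2 | in-plane ROI dilation radius (voxels) |
| asym halfwidth | 2 | 5×5 mirrored neighbourhood |
| solver tol / max_iter | 1e−6 / 1000 | coordinate-descent stopping (strict default) |
| pipeline solver | 1e−4 / 60 | relaxed stopping used inside training/segmentation |

The relaxed pipeline solver trades exactness of individual codes (which
the residue comparison does not need) for an order-of-magnitude faster
end-to-end run; all solver-correctness checks run at the strict setting.

## Synthetic phantoms

The generator emulates the study conditions the method is designed for:
an elliptical brain symmetric about a (optionally tilted) midline,
mirror-symmetric smooth background texture plus hemisphere-independent
Gaussian noise, channel modes fixed at B0 110 / DWI 100 / ADC 120 so the
recovered ADC reference is predictable, lesions with DWI contrast in
units of the background sd and ADC lowered to a stated fraction of the
ADC mode, optional edge blur and multiplicative inhomogeneity, and
shine-through mimics (bright DWI, ADC ≥ mode).  Channels are clipped at
zero so the [0, 255] rescale is purely multiplicative and mode-relative
ADC thresholds survive preprocessing exactly.  Suites: **easy** (sharp
edges, contrast 4–5 sd, ADC fraction 0.6), **hard** (blur sd 1.5,
inhomogeneity 0.3, contrast 2–3 sd), **mimic** (easy + 1–2 shine-through
blobs), **clean** (lesion-free).

What the phantoms do **not** model: Rician noise, coil bias fields,
partial-volume effects, anatomical texture, bilateral or multifocal
disease, registration error between channels.  Passing the phantom suite
therefore demonstrates that the algorithmic chain is implemented
correctly and behaves as designed under its own assumptions — not that
clinical-grade accuracy would be achieved on scanner data, where reported
overlap is far below the near-perfect phantom values.

## Problem sizes

Phantoms are 64×64×18 with single lesions of ~150–350 voxels; the
standard suites have 20 studies.  Cross-validation is 2-fold with a
seeded equal split.  The solver audit uses 100 random problems at
m = 10, K = 12; the classifier audit uses two 16-dimensional Gaussian
clusters at 5σ mean separation, 300 training and 500 test samples per
class, K = 40, λ₁ = λ₂ = 0.1.  These sizes keep a full test run in a few
minutes on one CPU while leaving every assertion comfortably clear of its
threshold.

## Known limitations

* The MSP search assumes per-slice midlines with a shared tilt; a truly
  oblique 3D plane (strong head rotation about the anterior-posterior
  axis) is out of scope.
* The ROI rules inherit the method's reliance on ADC reduction: a lesion
  with pseudo-normalised ADC would be excluded from the ROI (the no-ROI
  variant exists for exactly this trade-off).
* Online dictionary learning is monotone only in expectation; use batch
  mode when a certified objective decrease matters.
* `estimate_msp` is the most expensive preprocessing step (~1 s per
  64×64×18 study); its angle grid is configurable if speed matters.
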
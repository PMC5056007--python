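# srcstroke

Sparse-representation classification (SRC) of hyperacute cerebral infarcts
from diffusion-weighted MR imaging.

Within the first hours after stroke onset, infarcted tissue is hyperintense
on the diffusion-weighted image (DWI) and hypointense on the apparent
diffusion coefficient (ADC) map, but its appearance is highly variable:
intensity inhomogeneity, ill-defined edges, and "shine-through" artifacts
(bright DWI without ADC reduction) defeat simple thresholding.  `srcstroke`
segments such lesions from a co-registered B0/DWI/ADC study by learning what
infarct and normal tissue patches look like and letting the two models
compete voxel by voxel.

## Method

1. **Preprocessing.** Each channel is rescaled to [0, 255].  The difference
   volume `DWI_ADC = max(DWI − ADC, 0)` emphasises infarcts.  The
   midsagittal plane (MSP) is estimated per axial slice by maximising the
   masked correlation of the B0 slice with its own reflection; the asymmetry
   map is the positive excess over the mirrored neighbourhood:

   `ASYM(x,y,z) = max( DWI_ADC(x,y,z) − max_{(u,v) ∈ N₅ₓ₅(x₀,y₀)} DWI_ADC(u,v,z), 0 )`

   where (x₀, y₀) mirrors (x, y) across the slice midline.

2. **Features.** Each voxel is described by the concatenated intensities of
   patches (radius `R_p`, 2D or 3D) from the four channels B0, DWI, ADC,
   ASYM — a vector of length `4·(2R_p+1)²` for 2D patches.

3. **Dictionary learning.** Per class (infarct / normal), a dictionary
   `D ∈ R^{m×K}` with unit-norm atoms is learned by minimising the mean
   elastic-net objective

   `min_{D,α} (1/n) Σᵢ [ ½‖sᵢ − Dαᵢ‖² + λ₁‖αᵢ‖₁ + (λ₂/2)‖αᵢ‖² ]`.

   Positive samples are all ground-truth voxels; negatives come from the
   shell obtained by dilating the ground truth until the classes balance —
   the boundary voxels that are hardest to tell apart.

4. **ROI derivation.** Candidate voxels are confined to regions with
   ADC ≤ 0.75·ADC_ref (ADC_ref = most frequent brain ADC) whose per-slice
   mean DWI exceeds the slice mean + std, extended by moderately reduced
   ADC components touching them, dilated in-plane by `R_d`, and grown one
   slice outward.  Shine-through mimics fail the ADC test and are excluded.

5. **Classification.** Each candidate's feature vector is sparse-coded
   against the concatenated dictionary `D = [D_infarct, D_normal]` (elastic
   net, cyclic coordinate descent); the voxel takes the class whose own
   atoms reconstruct it with the smaller residue `rᵢ = ‖s − Dᵢ δᵢ(α̂)‖²`.

Defaults: `λ₁ = 0.3, λ₂ = 0.1, R_p = 1, R_d = 2, K = 200`, 2D patches, all
four channels.  Performance is quantified by the Dice coefficient
`DC = 2TP / (FP + 2TP + FN)`, sensitivity, specificity, PPV and NPV.

## Worked example

Everything runs on seeded synthetic phantoms, so no clinical data is
needed:

```python
from srcstroke import (PipelineConfig, cross_validate, generate_suite)

suite = generate_suite("easy", 20, seed=7)          # 20 phantom studies
df = cross_validate([ph.study for ph in suite], PipelineConfig(), seed=11)
print(df[["DC", "sensitivity", "specificity"]].mean().round(4))
```

prints

```
DC             0.9986
sensitivity    0.9998
specificity    1.0000
```

i.e. 2-fold cross-validated segmentation of sharp-edged phantom lesions is
essentially perfect: every lesion voxel is recovered (sensitivity ≈ 1) with
almost no false positives inside the brain (specificity ≈ 1), giving a mean
Dice overlap of ≈ 0.999 between predicted and true lesions.  Harder
phantoms (`generate_suite("hard", ...)`: blurred edges, inhomogeneity, low
contrast) yield substantially lower DC, mirroring the difficulty ordering
seen in clinical data.  The same pipeline is scriptable from the shell:

```sh
srcstroke simulate --suite easy -n 4 --seed 7 -o studies/
srcstroke train -i studies/ -o model/ --seed 3
srcstroke segment -i studies/ -m model/ -o seg/   # writes masks + metrics.csv
```

See `examples/` for short narrative scripts, one per capability.

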
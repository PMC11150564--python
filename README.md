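# dtialps

A tested, reusable implementation of the **DTI-ALPS** (diffusion tensor image
analysis **a**long the **p**erivascular **s**pace) pipeline, as applied in
studies comparing glymphatic-related diffusion between Type 2 Diabetes
Mellitus (T2DM) patients and healthy controls (HC): tensor fitting and scalar
maps, axis-wise diffusivity extraction in fiber-specific ROIs, the ALPS
index, skeleton-restricted voxelwise group inference with TFCE and
permutation-based family-wise-error correction, and the cohort-level
statistical battery (normality-gated group comparisons, covariate-adjusted
GLM with a VIF screen, Spearman and partial correlation).

Because subject-level DWI from such studies is rarely deposited, the package
ships first-class synthetic-data generators — DWI phantoms with the ALPS
fiber geometry and a *closed-form* ground-truth index, and cohort tables
with prescribed group effects and rank correlations — so every stage can be
exercised end to end against known truth.

## The index

At the level of the lateral-ventricle body, medullary veins run along the
image x axis, perpendicular to the projection fibers (z) and association
fibers (y). With `Dxx`, `Dyy`, `Dzz` the diagonal diffusivities of the
fitted tensor in the image frame, measured in 6-mm circular ROIs on the
axial FA slice:

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

An index of 1 means no preferential diffusion along the perivascular (x)
axis; healthy adult white matter typically yields ≈ 1.4–1.6, and reductions
have been reported in neurodegeneration and in T2DM.

Tensors are estimated per voxel by log-linear least squares
(`S = S0·exp(−b·gᵀDg)`), weighted (WLS) by default; derived maps follow the
usual conventions (AD = λ₁, RD = (λ₂+λ₃)/2, MD = trace/3, FA the normalised
eigenvalue dispersion). Voxelwise inference uses a mean-FA>0.2 skeleton
mask, per-voxel GLM t statistics, TFCE (E=0.5, H=2, dh=peak/100,
26-connectivity), and Freedman–Lane permutation of nuisance residuals with
the max-TFCE null distribution.

## Worked example

Simulate two noisy phantom subjects (SNR 30), fit tensors, and compute the
index with automatic ROI placement from the ground-truth sidecar:

```bash
dtialps simulate-phantom --out-dir sim --n-subjects 2 --snr 30 --seed 7
# wrote sub-000 (true ALPS 1.4296)
# wrote sub-001 (true ALPS 1.4991)
dtialps fit-tensor --dwi sim/sub-000/dwi.nii.gz --bval sim/sub-000/dwi.bval \
        --bvec sim/sub-000/dwi.bvec --out-dir maps/sub-000
cp sim/sub-000/truth.json maps/sub-000/
dtialps alps --auto --subject-dir maps/sub-000 --out alps.csv
cat alps.csv
# subject_id,Dxproj,Dxassoc,Dyproj,Dzassoc,alps,mode
# sub-000,0.000570,0.000556,0.000402,0.000392,1.4183,roi_mean
```

The estimated index 1.418 recovers the subject's true 1.4296 within ~1%;
the four columns are the axis-wise diffusivities (mm²/s) entering the ratio.

Cohort statistics on a synthetic 41-vs-27 subject table calibrated to the
published demographics (ALPS 1.30±0.13 vs 1.44±0.11, ALPS–MoCA Spearman
target 0.39 in the patient group):

```bash
dtialps simulate-cohort --out cohort.csv --seed 7
dtialps cohort-stats --cohort cohort.csv --out-dir stats
```

`stats/stats_report.json` from this run contains a GLM group effect of
−0.200 (p = 7.7e−06, all VIF ≤ 1.26) and a within-patients ALPS–MoCA
Spearman r = 0.255 (p = 0.108, n = 41) — single-cohort draws scatter around
the generating values (−0.14 and 0.39); the acceptance script below averages
over many seeds to show the calibration.

As a library:

```python
from dtialps import (PhantomSpec, simulate_phantom, fit_tensor, scalar_maps,
                     compute_mask, resolve_rois, extract_alps_inputs,
                     compute_alps_index, ScalarMap)

spec = PhantomSpec(snr=30.0).with_alps_index(1.44)
vol, truth = simulate_phantom(spec, seed=0)
b0 = ScalarMap(vol.data[..., 0], vol.affine, "b0")
maps = scalar_maps(fit_tensor(vol, mask=compute_mask(b0)))
rois = resolve_rois("auto", maps.FA, maps, sidecar=truth)
print(compute_alps_index(extract_alps_inputs(maps, rois)).index)
```

## Scope notes

Inputs are assumed voxel-aligned: eddy/motion correction, nonlinear
registration to standard space, TBSS skeleton thinning/projection, and
atlas-based cluster labelling are out of scope (see `docs/methods.md` for
what this implies for real data). Brain extraction is replaced by Otsu
thresholding of the b=0 image.
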
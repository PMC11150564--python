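# Methods

This note documents the models, parameter choices, and numerical decisions
behind `dtialps`, and what the synthetic-data tests do and do not establish
about real data.

## Signal model and tensor estimation

The forward model is the mono-exponential diffusion tensor:
`S(b, g) = S0 · exp(−b · gᵀ D g)` with `D` symmetric, in mm²/s. Gradient
directions are interpreted in the image (voxel-axis) frame, the FSL
bval/bvec dialect, with no radiological flip; the ALPS axes are image axes,
and the phantom generator uses the same frame, so the convention is
self-consistent end to end. b-values below 50 s/mm² count as b≈0
(configurable; the conventional cutoff).

Estimation is log-linear least squares in the seven unknowns
(ln S0, six tensor components). Two variants are provided:

- **OLS** — one pass on log signals; exact for noiseless data.
- **WLS** (default) — weights equal to the squared OLS-predicted signals,
  the standard correction for the noise distortion introduced by the log
  transform.

Signals are clamped to `max(S, 1e-6·S0_proxy)` before the log (S0_proxy =
per-voxel mean b≈0 signal), so non-positive samples cannot produce −∞.
Negative-eigenvalue voxels are kept as fitted (no constrained fit): the
ALPS ROIs sit in high-SNR white matter where this is immaterial. Eigenvalues
are reported in non-increasing order; AD = λ₁, RD = (λ₂+λ₃)/2, MD = trace/3,
and FA = √(3/2)·‖λ − MD‖/‖λ‖ with FA = 0 at identically zero tensors.

Brain extraction is replaced by Otsu thresholding of the b≈0 image followed
by largest-connected-component retention. Eddy-current/motion correction is
intentionally absent: the synthetic inputs are distortion-free. **For real
data this is a pipeline gap** — both steps (and the registration steps
below) would have to be performed upstream.

## ALPS index

ROIs are circles of 6 mm diameter (default) on a single axial slice of the
FA map, one per fiber class: projection fibers (principal axis z),
association fibers (y), optionally subcortical fibers (x). The ROI voxel set
is every voxel of the slice whose in-plane world distance to the center is
≤ diameter/2; on the default 2 mm grid that is a 3×3 patch (the diagonal
neighbours sit at 2.83 mm < 3 mm).

Two extraction modes are provided, because descriptions of the procedure in
the literature mention both ROI-level measurement and selecting the single
voxel of maximal orientation:

- `roi_mean` (default) — mean of the axis map (Dxx for Dx, Dyy for Dy,
  Dzz for Dz) over the ROI voxels; more robust to noise.
- `max_orientation_voxel` — the single ROI voxel maximising |V1·e_axis|
  (z for projection, y for association, x for subcortical); ties break to
  the smallest linear index, and voxels with undefined V1 are skipped.

The index is `((Dx_proj + Dx_assoc)/2) / ((Dy_proj + Dz_assoc)/2)`. It is
scale invariant by construction and equals 1 when the four inputs are equal.
Hemisphere: single (left by convention) ROI set by default; when both
hemispheres supply an ROI of a class, the two values are averaged. The mode
and per-ROI voxel counts are carried in the output.

## Voxelwise inference

Spatial normalisation is out of scope: subjects are assumed voxel-aligned,
and the "skeleton" is simply `mean FA > 0.2` (no thinning or projection).
This preserves the inferential machinery — the part that carries the
statistics — while removing the dependence on external templates. Results
on real, unregistered data would require the standard TBSS spatial steps
first.

- **GLM**: per-voxel OLS with intercept, 0/1 group indicator (patients = 1),
  and nuisance covariates (age, sex by default in the CLI);
  t = cᵀβ̂ / √(σ̂²·cᵀ(XᵀX)⁻¹c), df = n − rank(X). Zero-residual-variance
  voxels get t = 0 rather than NaN.
- **TFCE**: TFCE(p) = Σ_h e(h,p)^E · h^H · dh with E = 0.5, H = 2,
  dh = peak/100, 26-connectivity — the conventional defaults. Negative
  statistics are enhanced by transforming −t and negating. Integration uses
  midpoint-rule thresholds h_k = (k−½)·dh: midpoints never coincide with
  data values, which makes the discrete sum stable under rescaling of the
  map (the scaling identity TFCE(c·t) = c^{H+1}·TFCE(t) then holds to
  floating-point accuracy) and reduces quadrature bias to O(dh²); the
  single-voxel analytic value v³/3 is matched to ~0.003%.
  Two implementations exist: an incremental union-find over descending
  thresholds (numba-compiled; used everywhere) and a per-threshold
  `ndimage.label` reference; a test asserts their equality on random masked
  maps.
- **Permutation FWE**: Freedman–Lane — residuals of the nuisance-only model
  are row-permuted, the nuisance fit is added back, and the full-model t and
  its TFCE are recomputed; the maximum TFCE over the skeleton is recorded
  per tail. `p_tail(v) = (1 + #{maxima ≥ TFCE_obs(v)})/(n_perm+1)`, and the
  reported corrected p is `min(1, 2·min(p⁺, p⁻))` (two-sided via separate
  tails with a Bonferroni factor — slightly conservative, and exact-level by
  construction within each tail). With an intercept-only nuisance the scheme
  reduces exactly to label permutation. All permutations derive from one
  seed; results are bit-reproducible.
- **Clusters**: connected components (same connectivity) of
  {p_corr < α}, reported with voxel count and minimum-p peak, largest first.

Null calibration (20 subjects, 500 permutations, 200 Monte-Carlo
repetitions on a 10×10×4 map — sizes chosen to make the calibration cheap
while keeping the binomial band informative) lands the empirical FWE at
0.045–0.050 against the nominal 0.05.

## Cohort statistics

- **Normality gate**: Shapiro–Wilk per group at α = 0.05; the pooled
  (Student) two-sample t is used only when both groups pass, otherwise
  Mann–Whitney U. The pooled variant is the default because the comparison
  tables being emulated pair t-tests with equal-variance reporting; Welch is
  available.
- **Summary-statistic t**: the same pooled/Welch formulas evaluated from
  (mean, SD, n) per group, so published table rows can be re-tested; the
  raw-data path computes its sample moments and calls the same formula, so
  the two agree algebraically (tested to 1e−12). Note a limit this exposes:
  p-values recomputed from summaries printed at 2 decimals inherit an
  uncertainty of roughly ±0.001 (BMI row) to ±0.016 (cholesterol row), so
  3-decimal agreement with a published p is not generally achievable from
  the printed numbers alone.
- **Mann–Whitney U**: exact enumeration when n₁+n₂ ≤ 12 and tie-free,
  otherwise the tie-corrected normal approximation without continuity
  correction (a centred statistic then gives exactly p = 1). The normal
  approximation deviates from enumeration by up to ~0.06 in the mid-p range
  at n = 6+6; it is within 0.02 by n = 20+20.
- **Chi-square**: Pearson on the 2×2 sex table, df = 1, *no* Yates
  correction — the convention that reproduces the published sex-comparison
  p (with correction the same counts give ≈ 0.37 instead of ≈ 0.251).
- **GLM**: OLS of the ALPS index on group plus eight covariates (age, sex
  0/1, education years, BMI, triglyceride, total cholesterol, LDL, HDL),
  complete cases (≥ 15 required). VIF_j = 1/(1−R²_j) from the auxiliary
  regression of covariate j on the other covariates with intercept; the
  group indicator is excluded from the screen. Exactly orthogonal
  covariates give VIF = 1.
- **Correlations**: Spearman as Pearson-of-midranks with the t
  approximation (df = n−2); partial correlation residualises x and y on the
  covariates by least squares and correlates the residuals, with
  df = n − k − 2. The partial correlation is rank-based by default
  (midrank-transform everything first), so with no covariates it reduces
  exactly to Spearman; plain-Pearson mode is retained. A variable exactly
  linearly dependent on the covariates has partial correlation 0 by
  convention (nothing left to correlate).
- No multiple-testing correction is applied across demographics-table rows,
  matching the emulated reporting convention.

## Synthetic data

**Phantom.** 32×32×8 voxels at 2 mm isotropic (large enough for 6-mm ROIs,
small enough for seconds-scale tests); 64 diffusion directions from a
deterministic antipodally-symmetric electrostatic-repulsion point set, one
b = 0 volume, b = 1000 s/mm² (the field-standard DTI shell; the emulated
acquisition reports only the direction count). Geometry: an isotropic
tissue block (0.8×10⁻³ mm²/s) containing three disjoint fiber slabs ordered
lateral→medial along x — subcortical (principal axis x), association (y),
projection (z) — with eigenvalues (1.4, 0.4, 0.4)×10⁻³ laid along the class
axis, surrounded by zero-signal background. A perivascular increment δ is
added to the xx component of the projection and association tensors, making
the ground truth available in closed form:
`ALPS_true = (0.4e−3 + δ)/0.4e−3`; `PhantomSpec.with_alps_index` inverts
this. Noise is Rician, `√((S+ε₁)² + ε₂²)` with ε ~ N(0, σ²), σ = S0/SNR;
the background mean matches the Rayleigh value σ√(π/2) (tested to 2%).
Everything is deterministic given the seed.

The phantom has uniform regions, no partial volume, no crossing fibers, no
anatomy, and no distortions. Passing its tests therefore demonstrates the
*correctness of the computation* (fit, extraction, index, inference), not
robustness to the segmentation, registration, and placement difficulties of
real brains — manual ROI placement variability in particular is explicitly
outside what these tests can show.

**Cohort.** Group sizes 41 (T2DM) vs 27 (HC); per-variable group means/SDs
taken from the emulated study's demographics table; sex Bernoulli at the
published proportions; education years 12±3 in both groups (not tabulated
in the source; groups were education-matched). ALPS is 1.30±0.13 vs
1.44±0.11. Within the patient group, (ALPS, MoCA) are drawn from a Gaussian
copula whose latent Pearson correlation is `2·sin(π·ρ_s/6)` — the exact
bivariate-normal inverse of the Spearman target (default 0.39). Cognitive
scores are rounded to integers and clipped to instrument ranges (MoCA/MMSE
0–30, SDMT 0–110) after sampling; laboratory values are clipped to small
physiological floors. The rounding attenuates the realised rank correlation
by well under 0.01 at n = 10⁵ (tested). Covariates are mutually independent
— the source table publishes no covariance structure — so partial
correlations on synthetic cohorts are not attenuated the way real,
correlated covariates would attenuate them. A power fact worth recording:
with these exact parameters the pooled-t power at two-sided α = 0.001 is
0.871 (noncentral t), so "significant at 0.001" holds in roughly 87% of
synthetic cohorts, not all of them.

## Determinism and seeds

Every stochastic routine takes a seed; batch drivers and the CLI derive
per-stage seeds from one base seed by CRC32 hashing of the stage label
(`derive_seed`), keeping all derived seeds below 2³¹. Identical
spec + seed ⇒ bit-identical outputs, including permutation p-values.

## Known limitations

- No spatial preprocessing (eddy, registration, skeleton projection) — see
  above; the voxelwise module expects aligned inputs.
- Single-tensor model only; no DKI/NODDI, no crossing-fiber handling.
- ROI discs are single-slice and axial; the fiber-class axis mapping
  (Dx→Dxx etc.) assumes the image axes are the anatomical x/y/z of the
  ALPS construction.
- The bvec sign convention of scanner exports varies; the image-frame
  interpretation used here is a declared convention, not inferred from any
  particular scanner.
- p-values recomputed from rounded published summaries carry irreducible
  uncertainty (see cohort statistics above).
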
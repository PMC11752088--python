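# Methods

`sandicortex` reproduces, end to end on synthetic data, a cortical-lesion
microstructure analysis: soma and neurite density imaging (SANDI) of
multi-shell diffusion MRI, perilesional shell regions around cortical
lesions, and the group-level statistical battery that quantifies the
lesional → perilesional → normal-appearing gradient in people with
multiple sclerosis (MS) versus healthy controls (HC).

## Signal model

Each voxel's direction-averaged (powder) attenuation at diffusion
weighting b is a three-compartment mixture,

    S(b)/S(0) = f_is A_sphere(b; R_s, D_is)
              + f_in A_stick(b; D_in)
              + f_ec A_ball(b; D_ec),

with nonnegative signal fractions summing to one.

* **Ball** (extracellular water): `exp(-b D_ec)`.
* **Stick** (neurites, powder-averaged): `sqrt(pi/(4 b D_in)) erf(sqrt(b D_in))`.
* **Sphere** (somas): restricted diffusion in an impermeable sphere of
  radius `R_s` under a pulsed-gradient spin-echo (pulse duration δ,
  separation Δ), evaluated with the Gaussian-phase-distribution (GPD)
  series over the roots of `j1'(x)` (first root ≈ 2.0816), truncated at 30
  terms (truncation error < 1e-8 over the dictionary's radius range).

Units are b in ms/μm², diffusivities in μm²/ms, radii in μm; the
gyromagnetic ratio, δ, Δ and the gradient amplitude satisfy
`b = γ² g² δ² (Δ − δ/3)` without conversion factors.

**Validity of the GPD series.** A random-walk Monte-Carlo simulator
(`sandicortex.montecarlo`) provides the independent numerical ground
truth: spins diffuse inside a reflecting sphere while accruing gradient
phase, and one trajectory ensemble yields the attenuation at every
gradient amplitude. Where the Gaussian-phase approximation is applicable
(small spheres at every shell; larger spheres in the weak-attenuation
regime) the series and the simulator agree to better than 2%. At
Connectom-class gradient strengths (here up to ≈283 mT/m) and large radii
the GPD approximation genuinely overestimates attenuation — by ≈8% for
R = 10 μm at b = 1500 s/mm² and by more than an order of magnitude in the
near-zero tail at b = 6000 s/mm². This is a known property of the
approximation, not a transcription error; the test suite carries both a
whole-regime comparison (which documents the deviation) and a
valid-regime transcription check (which must pass). The pipeline is
internally consistent because simulation and fitting use the same forward
model.

## Acquisition scheme

The default protocol mirrors a strong-gradient research acquisition:
Δ = 19 ms, eight shells (b = 50, 350, 800, 1500 s/mm² × 32 directions and
b = 2400, 3450, 4750, 6000 s/mm² × 64 directions), one b = 0 volume every
16 volumes (410 volumes total). δ is not part of the published protocol
text; the default δ = 8 ms is a documented assumption consistent with the
scanner's gradient limit (the b = 6000 shell then needs 283 mT/m).
Directions are deterministic spherical-Fibonacci sets with a seeded
random rotation per shell; since all fitting happens on spherical means,
the particular direction set is immaterial.

## Dictionary fit

The inverse problem is linearized dictionary estimation on per-shell
spherical means (normalized by the mean b = 0 signal, with an implicit
unit b = 0 row). Shell rows are weighted by their direction counts, which
reproduces the least-squares objective of the full per-volume acquisition
and whitens the shell-mean noise.

A free NNLS spectrum over all atoms (12 sphere radii × stick and ball
diffusivity grids) is severely degenerate with only eight shell means:
whole-compartment weight can move between sphere, stick and ball atoms at
negligible residual cost, so any ridge penalty reshapes the fractions by
0.05–0.13. The estimator therefore enumerates *compact candidate models*
that match the biophysical model's structure — exactly one sphere atom,
one stick atom, one ball atom, plus a free-water atom — and selects the
candidate with the smallest unpenalized residual. Each candidate is a
tiny well-conditioned NNLS problem solved exactly by batched active-set
enumeration. The ridge weight λ2 (default 0.005) is then applied within
the winning support only, where it stabilizes coefficients without
re-opening degenerate atom exchanges; at λ2 = 0 the noiseless on-grid fit
is exact to solver tolerance.

Design choices that matter for accuracy, all validated on ground-truth
ensembles during development:

* **Free-water compartment.** At 2 mm isotropic resolution cortical
  voxels carry CSF partial volume. The ball atom at the free-water
  diffusivity (3.0 μm²/ms) is always available to the fit and excluded
  from the tissue-fraction normalization, so reported fractions are
  tissue fractions. Its coefficient is deliberately *sign-unconstrained*:
  a nonnegativity bound would truncate its noise one-sidedly and inflate
  f_is by ≈ +0.06 wherever true CSF content is small.
* **Single sphere atom per candidate.** Candidates with two adjacent
  sphere atoms (radius interpolation inside the solver) are nearly
  collinear; the nonnegativity clamps on such a pair bias f_is by
  +0.03–0.04 under noise. With a single sphere atom the per-candidate
  problem is almost linear in the data and the fraction estimates are
  unbiased to ≤ 0.01 for cortex-like parameters at SNR 50.
* **Sub-grid soma radius.** R_s is refined off-grid by parabolic
  interpolation of the residual profile along the radius grid (clamped to
  the neighbouring grid points, hence always inside the grid's convex
  hull). Noiseless off-grid radii are recovered to ≈0.05 μm.
* **Fixed default diffusivities in the pipeline.** Model selection over a
  5 × 5 diffusivity-pair grid is noise-dominated at SNR 50 (eight shell
  means cannot separate the pairs; fraction SDs exceed 0.2 and regional
  contrasts invert). The cohort pipeline therefore fixes D_in = D_ec =
  2.0 μm²/ms and D_is = 3.0 μm²/ms (`FitConfig.pipeline_default()`), the
  same values the phantom uses as ground truth; the exploratory
  `FitConfig()` keeps the full grids (22-atom dictionary).
* **Rician noise-floor correction.** Shell means are computed from second
  moments, `sqrt(mean(m²) − 2σ̂²)`, with σ̂² estimated per voxel from the
  interleaved b = 0 volumes. Without this, the magnitude noise floor
  masquerades as restricted signal at high b and inflates f_is by ≈ +0.1
  at SNR 50. Disable with `rician_floor_correction=False`.

Voxels whose fit carries no sphere weight have undefined R_s; they are
excluded from regional R_s means but retained for fraction means. No
post-hoc clipping of implausible values is applied.

## Synthetic cohort

The phantom emulates the study conditions, not cortical anatomy:

* **Geometry.** Concentric spheres on a 96³ 1-mm grid — WM core
  (r < 28 mm), cortical ribbon (28–31.5 mm), CSF (to 36 mm). Partial
  volumes at the 2-mm analysis grid come from exact 2×2×2 block
  aggregation. A spherical cortex preserves exactly what the regional
  analysis consumes — distances and partial-volume fractions — while
  avoiding any registration machinery. The 3.5-mm ribbon (cortex is
  3 ± 1 mm) keeps the fraction of pure-GM voxels reasonable; thinner
  ribbons inflate WM/CSF partial-volume contamination of the regional
  means.
* **Lesions.** Leukocortical: spheres centered on the GM/WM interface.
  Count per subject is lognormal (median 8, log-SD 0.8, rounded, min 1);
  per-lesion radius is lognormal (median 1.55 mm, log-SD 0.25, min 1 mm),
  calibrated once so the cohort median total lesion volume is ≈0.16 mL.
  With 41 subjects the *cohort median* count still carries sampling noise
  of about ±2; individual master seeds can land at 6 or 10.
* **Ground truth.** Each subject draws one value per region per measure
  from the preset Normal distributions (MS: normal-appearing cortex,
  outer/inner perilesional layers, lesions; HC: whole cortex), with
  fractions renormalized to sum to one and small within-region jitter
  (SD 0.01 for fractions, 0.05 μm for radius). The presets use the
  published cross-sectional group means and SDs, which conflates
  biological and measurement variance — a documented simplification.
  WM (f_in 0.45 / f_is 0.35 / f_ec 0.20, R_s 9 μm) and CSF (free water,
  D = 3.0) are fixed plumbing, chosen so that their partial-volume
  contamination of PV-weighted cortical means stays within ≈0.02.
* **DWI simulation.** Per 2-mm voxel the noiseless signal is the
  PV-weighted sum of each tissue's powder attenuation, replicated across
  directions within a shell; Rician corruption
  `S' = sqrt((S + ε₁)² + ε₂²)` with σ = S(b=0)/SNR (default SNR 50).
  Everything derives deterministically from the master seed (spawned
  per-subject seed sequences; the DWI noise stream from the stored
  subject seed).

What the phantom does *not* model: cortical folding, the
insular/temporal lesion topography, atrophy (so normalized cortical
volume is nearly constant across subjects and volume-loss regressions
are not exercised by default), directional signal dependence, scanner
artifacts, and subpial lesion subtypes. Passing tests demonstrate that
the estimator and statistics recover the generator's structure — not
that they would behave identically on folded, artifact-laden in vivo
data.

## Regions and aggregation

Perilesional layers are Euclidean-distance bands from the (thresholded,
lesion PV > 0.25) lesion mask over voxel centers on the 2-mm grid: inner
(0, 2] mm, outer (2, 4] mm, both restricted to cortex (GM PV > 0); shells
of multiple lesions merge by union, so voxels join the band of their
nearest lesion. Normal-appearing cortex is the remaining cortex. Regional
summaries are partial-volume-weighted means, `Σ wᵢ xᵢ / Σ wᵢ`; the weight
is the cortical GM partial volume, except for the lesion region where the
lesion partial volume itself is used (phantom lesions are ≈0.02 mL
against 8 mm³ voxels — a GM-weighted lesion mean would mostly measure
non-lesion tissue). Rows with fewer than 3 contributing voxels are
flagged invalid. Normalized cortical volume divides the cortical
partial-volume sum by the intracranial (non-background) volume.

## Statistics

* MS-vs-HC comparisons: two-sided pooled-variance t-tests (pooled rather
  than Welch, for self-consistency with pooled-SD effect sizes), mean
  difference with 95% CI and Hedges' g with small-sample correction
  J = 1 − 3/(4·df − 1); g is positive when the control group exceeds MS.
  Lesional/perilesional rows are compared against the HC whole-cortex
  distribution.
* Within-subject gradient: one-way repeated-measures ANOVA across the
  four MS regions with the Greenhouse–Geisser correction applied
  unconditionally (fractional degrees of freedom), paired t-tests as
  post-hocs, listwise exclusion of subjects with any invalid region.
* Multiple comparisons: Benjamini–Hochberg FDR within each analysis
  family (group comparisons; within-subject contrasts; regressions) —
  family membership is explicit, not inferred.
* Z-scores against the HC distribution, covariate-adjusted OLS (age,
  sex) and cognitive domain-score aggregation (impairment at z ≤ −1.5)
  round out the battery.

The RM-ANOVA/FDR/OLS computations run on pingouin and statsmodels; the
test suite checks every routine against independent from-scratch
implementations (first-principles t and BH step-up formulas, a
sums-of-squares + covariance-matrix oracle for the GG-corrected ANOVA)
to 1e-10, and verifies ≈5% type-I error of the within-subject ANOVA over
500 null-generator cohorts.

## Problem sizes and determinism

The default end-to-end run (41 MS + 34 HC subjects, 410-volume DWI on a
48³ analysis grid, ≈7000 fitted voxels per subject) completes in a few
minutes on one CPU; the Monte-Carlo sphere validation uses 1.2×10⁵ spins
per radius at a 0.01 ms time step. Identical master seeds produce
bit-identical cohorts, tables and summaries.

## Known limitations

* The estimator's lesion-tissue f_is retains a small positive bias
  (≈ +0.02 at SNR 50) from estimator nonlinearity; regional lesion means
  additionally mix in surrounding tissue through partial volume.
* Absolute regional means inherit the free-water/WM partial-volume
  handling; different choices there shift whole-cortex f_is by ≈0.02.
* With only eight shell means, per-voxel estimates are noisy (f_is SD
  ≈0.1); the pipeline's precision comes from regional and cohort
  averaging.
* The GPD forward model is trusted in exactly the regime the fit uses
  it; it is not exact at the strongest shells for the largest somas (see
  above).
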
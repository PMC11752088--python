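# sandicortex

Soma and neurite density imaging (SANDI) of cortical lesions on synthetic
multi-shell diffusion MRI — a reusable, tested pipeline for the
perilesional-gradient analysis used in multiple sclerosis research.

Cortical lesions are focal demyelinated areas in the cortex of people
with multiple sclerosis (MS). Advanced diffusion MRI can characterize
the tissue around them: fitting a three-compartment model
(restricted **sphere** = cell bodies, **stick** = neurites, **ball** =
extracellular water) to powder-averaged multi-shell signals yields the
intra-soma, intra-neurite and extracellular signal fractions
(f_is, f_in, f_ec) and an apparent soma radius (R_s) per voxel. Published
cohort studies report a spatial gradient: lesional cortex shows lower
f_is and larger R_s than the surrounding perilesional layers, which in
turn differ from normal-appearing cortex and healthy-control cortex.
Because the underlying patient data are not publicly deposited, this
package provides everything needed to reproduce that analysis end to end
on synthetic data:

* `sandicortex.scheme` — the pulsed-gradient acquisition table (8 shells,
  b = 50–6000 s/mm², Δ = 19 ms) with FSL bval/bvec I/O;
* `sandicortex.signal` — ball, powder-averaged stick, and
  Gaussian-phase-distribution (GPD) restricted-sphere attenuation;
* `sandicortex.montecarlo` — an independent random-walk simulator used to
  validate the sphere model;
* `sandicortex.dictfit` — voxelwise estimation by compact-model
  nonnegative least squares with λ2 regularization, a free-water
  compartment and Rician noise-floor correction;
* `sandicortex.phantom` — the synthetic cohort generator: spherical
  cortical geometry, leukocortical lesion burden sampler, per-region
  ground-truth draws, Rician DWI simulation;
* `sandicortex.regions` — perilesional shells (0–2 mm "inner", 2–4 mm
  "outer") by Euclidean distance transform and partial-volume-weighted
  regional means;
* `sandicortex.stats` — pooled t-tests with Hedges' g,
  Greenhouse–Geisser-corrected repeated-measures ANOVA, paired post-hocs,
  z-scores, adjusted regression, Benjamini–Hochberg FDR per analysis
  family;
* `sandicortex.pipeline` / `sandicortex.cli` — the simulate → fit →
  aggregate → test orchestration, also available as the `sandicortex`
  command with `simulate`, `fit`, `analyze`, `run-all` and `dump-config`
  subcommands.

See `docs/methods.md` for the model, the estimator design and the
phantom's assumptions.

## Worked example

Run the default two-group cohort (41 MS, 34 healthy controls, SNR 50)
and print the headline regional means:

```python
from sandicortex import RunConfig, run_cohort_analysis

result = run_cohort_analysis(RunConfig(master_seed=1))
regions = result["summary"]["regions"]
for key in ("MS:lesion:f_is", "MS:na_cortex:f_is", "HC:cortex:f_is",
            "MS:lesion:r_s", "MS:inner_layer:r_s", "MS:na_cortex:r_s"):
    print(key, round(regions[key]["mean"], 3))
print(result["summary"]["lesions"])
```

Output (a few minutes on one CPU):

```
MS:lesion:f_is 0.5
MS:na_cortex:f_is 0.554
HC:cortex:f_is 0.555
MS:lesion:r_s 10.106
MS:inner_layer:r_s 9.98
MS:na_cortex:r_s 9.846
{'count_median': 6.0, 'count_iqr': [4.0, 12.0], 'volume_ml_median': 0.159,
 'volume_ml_iqr': [0.093, 0.326]}
```

Reading this: lesional cortex has a clearly lower intra-soma fraction
(0.50) than normal-appearing cortex (0.55), and the apparent soma radius
decreases monotonically moving outward from lesions (10.11 → 9.98 →
9.85 μm) — the perilesional gradient the analysis is designed to detect.
The lesion burden sampler targets a median count of 8 and median total
volume of 0.16 mL per subject; at this particular seed the 41-subject
count median lands at 6 (the cohort median of a heavy-tailed count
distribution is itself noisy), while the volume median is 0.159 mL.
`result["within_anova"]` and `result["within_posthoc"]` hold the
FDR-corrected within-subject statistics across the four regions, and
`result["group_stats"]` the MS-vs-HC table with Hedges' g.

The same run from the shell:

```bash
sandicortex --seed 1 run-all --out runs/demo
```

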
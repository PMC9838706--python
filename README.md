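# medvox

Voxel-wise causal mediation analysis for lifespan cognitive neuroscience,
driven entirely by a synthetic-cohort generator with known ground truth.

## The problem

Fluid intelligence declines steadily across the adult lifespan. One
mechanistic hypothesis is that part of this decline is carried by the
brain's response to cognitive demand: as the demand-related BOLD response
in frontoparietal cortex weakens with age, performance falls with it. In
mediation terms, with age `A`, a per-voxel brain response `B`, and an
IQ-like outcome `C`, the question is whether (and where) the indirect
path `A → B → C` accounts for a share of the total age effect:

```
C = i1 + c·A                  + e1     (total effect)
C = i2 + b·B + c'·A           + e2     (direct + mediator)
B = i3 + a·A                  + e3     (age effect on the mediator)
C = i4 + b·B + c'·A + d·A·B   + e4     (moderation-by-age check)
```

The indirect effect is `ab = a·b = c − c'`. Mediation is declared by
joint significance — a two-tailed test of `a` and a one-tailed test that
`b` has the sign opposite to `a` — with the conjunction p equal to the
maximum of the two, controlled across voxels by Benjamini–Hochberg FDR
in a hierarchy: age-path FDR mask → moderation screen (Cohen's
f² < 0.02 and p > 0.05 for `d`) → conjunction FDR.

Because claims like this rest on strong assumptions, the pipeline also
implements the accompanying inferential machinery:

* **Spatially aware map correlation** (Moran spectral randomization):
  tests whether mediation strength tracks response strength across
  voxels without being fooled by spatial smoothness.
* **LOVE sensitivity analysis**: how strongly an unmodeled confounder
  would have to correlate with mediator and outcome to erase `ab`.
* **ICA-LiNGAM causal direction**: with non-Gaussian structural errors,
  estimates which way each pairwise arrow points, with a
  watershed-cluster bootstrap and bias-corrected CIs.
* **Moderated mediation**: lets a lifestyle moderator shift every path;
  simple effects at ±1 SD, compound-path deltas by BC bootstrap.
* **Diagnostics and motion control**: RESET specification test,
  White/Wooldridge heteroscedasticity test, latent-score construction,
  framewise-displacement summaries, and global residualization.

Real cohorts of this kind are access-restricted, so the package ships a
first-class generator (`medvox.simulate`) producing cohorts and voxel
stacks with known mediation, moderation, confounding, spatial and
error-distribution structure — every stage has a parameter-recovery test
with no downloads.

## Worked example

```python
import numpy as np
import medvox as mv

cfg = mv.SimulationConfig(seed=42)          # the default synthetic study
cohort, stack, truth = mv.simulate_study(cfg)
maps = mv.run_voxelwise(cohort, stack, q=0.05, floor=100)
M = mv.summary_mediator(maps, stack)        # mean over summary voxels
A, C = cohort["A"].to_numpy(), cohort["C"].to_numpy()
fit = mv.fit_mediation(A, M, C)
boot = mv.bootstrap_ab(A, M, C, n_boot=15_000, seed=1)
```

which prints, via the obvious format strings:

```
mediation voxels: 118 (true region: 144)
a = -0.0171 mediator units/y (p = 6.31e-17)
b = 9.842 IQ points per mediator unit (one-tailed p = 3.45e-08)
total c = -0.671, direct c' = -0.503 IQ points/y
indirect ab = -0.168 (25% of the total)
95% BC bootstrap CI for ab: [-0.253, -0.101]
```

Reading: the demand response falls by 0.017 units per year of age; each
unit of response is worth ~9.8 IQ points after adjusting for age; the
indirect path explains about a quarter of the −0.67 points/year total
decline in this draw (the generating truth is −0.15 of −0.72, i.e. 21%),
and the bias-corrected interval excludes zero.

## The analysis, as scripts

`analysis/` holds numbered drivers that run the full study end to end
and write tables/maps under `results/`:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | simulate the default cohort + voxel stack, write TSV/NIfTI/YAML |
| `02_voxelwise_maps.py` | per-voxel mediation, hierarchical FDR masks, statistic maps |
| `03_summary_mediation.py` | summary-voxel mediation fit + 15,000-resample BC bootstrap, ROI fits |
| `04_spatial_correlation.py` | MSR test of \|ab\| vs contrast d across voxels |
| `05_sensitivity.py` | LOVE surface and confounding thresholds |
| `06_causal_direction.py` | ICA-LiNGAM + watershed-cluster bootstrap CIs |
| `07_moderated_mediation.py` | per-moderator path deltas across 2 SDs |
| `08_diagnostics_motion.py` | RESET/White diagnostics, motion residualization |

Run them in order from the repository root: `python analysis/01_simulate_cohort.py`, etc.

## Layout

```
src/medvox/         the library: config, simulate, mediation, voxelwise,
                    spatial, sensitivity, lingam, modmed, diagnostics
analysis/           numbered drivers (above)
tests/              pytest suite incl. statistical acceptance checks
docs/methods.md     model, assumptions, parameter choices, limitations
```
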
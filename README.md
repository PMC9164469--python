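# seedspec

Performance assessment of optical (spectral) seed-classification models
through controlled training-data manipulations.

Given a table of per-seed average reflectance profiles with binary
germination labels, `seedspec` quantifies how ten-fold cross-validated
accuracy of an LDA or linear-SVM classifier responds to three
experimental degradations of the training data:

1. **Assignment error** — a known fraction of each class is randomly
   relabeled (grid 0–50%).
2. **Spectral noise** — every reflectance value *v* becomes
   *v*·(1+*u*), *u* ~ Uniform(−*r*, +*r*), for noise ranges 0–10%
   (one-sided and band-windowed variants included).
3. **Training-set reduction** — a known fraction of each class is
   randomly removed (grid 0–90%).

Each sweep yields an accuracy-vs-level curve, an OLS regression (slope,
intercept, adjusted R²), and a paired t-test comparing the two
classifier families on identical perturbed data. A parsimony guard
warns whenever the number of spectral bands exceeds
⌊(objects − classes)/3⌋. Trained models can also predict per-subsample
germination percentages, scored by RMSE against known values.

Because the original hyperspectral seed data are not public, the
package ships a seeded synthetic generator (`seedspec.synthetic_data`)
producing datasets with the same structure: two varieties × seed lots
with shifted mean profiles, 221 bands over 432–1025 nm, a small
multiplicative germination effect centered at 650 nm, and a
`calibrate_separability` routine that bisects the effect amplitude to a
chosen ten-fold baseline accuracy (e.g. ~70%).

## CLI

```bash
# synthesize a training table (presets: variety1, variety2)
seedspec generate --preset variety1 --seed 1 --out train.csv

# sweep all three manipulations with both families
seedspec assess --input train.csv --seed 1 --out results/
# ... or a custom slice
seedspec assess --input train.csv --kinds assignment_error \
    --levels 0,10,30 --families LDA --k 10 --seed 1 --out results/

# per-subsample germination prediction + RMSE
seedspec validate --train train.csv --validation val.csv \
    --known known.csv --out report.csv
```

`assess` writes a tidy `sweep.csv` (kind, level, replicate, family,
accuracy), a `summary.json` (regressions, paired t-tests, parsimony
guard) and a `record.json` capturing resolved defaults, seeds and
library versions for bit-identical re-runs. All randomness flows from
`--seed` through named substreams.

## Library sketch

```python
from seedspec import (
    ManipulationPlan, ModelSpec, fit_linear, generate, preset, run_sweep,
)
from seedspec.synthetic_data import calibrate_separability

config = calibrate_separability(preset("variety1", rng_seed=1),
                                target_accuracy=70.0, tolerance=3.0)
dataset = generate(config)
plan = ManipulationPlan.default("assignment_error", rng_seed=17)
curve = run_sweep(dataset, plan, ModelSpec("LDA"), k=10)
print(fit_linear(curve))  # slope ≈ −(2·a0 − 100)/100 per flip %
```

## Layout

- `src/seedspec/spectra_core.py` — band grid / profile / dataset model,
  lossless CSV I/O
- `src/seedspec/synthetic_data.py` — seeded generator, presets,
  separability calibration
- `src/seedspec/perturbations.py` — the three manipulations
- `src/seedspec/evaluation.py` — CV accuracy, model handles,
  germination %, RMSE
- `src/seedspec/assessment.py` — sweeps, OLS, paired t-tests,
  parsimony guard
- `src/seedspec/cli.py` — `seedspec generate | assess | validate`
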
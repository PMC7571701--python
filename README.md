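# mscrepair

Predicting mesenchymal-stem-cell (MSC) cartilage-repair outcomes from
sparse, heterogeneous meta-analysis records.

Pooled MSC therapy studies — clinical trials and animal models together —
form small tables with mixed-type conditions (species, body weight, tissue
source, implanted cell number and concentration, defect geometry, damage
type), an outcome reported on incompatible clinical instruments, and many
missing cells, because no two studies record the same things. `mscrepair`
is built for exactly that shape of data. It provides, for biostatisticians
and cell-therapy researchers:

- **A self-consistent network.** One model `f` maps the encoded property
  vector `x = (x_1, …, x_I)` (conditions in slots `1..I−1`, the
  unit-interval repair score in slot `I`) to a prediction of itself:
  `y_j = Σ_h C_hj tanh(Σ_i A_ihj x_i + B_hj) + D_j`, with the structural
  constraint `A_jhj = 0` so each slot is predicted without its own value.
  Solving `f(x) ≈ x` away from the identity makes one model both the
  outcome predictor and the imputer of any missing condition.
- **Imputation by fixed-point iteration.** Missing slots start at training
  means and relax through `x ← γx + (1−γ)f(x)` (γ = 0.5) to
  self-consistency, so every incomplete record still contributes all of
  its information.
- **Ensemble uncertainty.** Many independently seeded networks; the mean
  is the prediction, the member standard deviation the uncertainty,
  calibrated by a residual-tempered sampling phase (see
  `docs/methods.md`). Predictions can then be confidence-filtered, and
  entries standing more than one standard deviation from their prediction
  are flagged for re-examination.
- **Validation and screening.** Leave-one-out cross-validated R²,
  single-property screens, forward descriptor selection with an
  overfitting diagnostic, correlation screening, R²-drop property
  influence, and 3-NN / mean baselines.
- **Clinical readouts.** Dose-response curves and defect-severity
  surfaces with per-point uncertainty and extrapolation flags.
- **A synthetic generator** with planted ground truth, so the entire
  pipeline is testable without any external download.

## Worked example

```python
from mscrepair import (SynthConfig, TrainConfig, generate, mask_missing,
                       single_property_screen, forward_selection,
                       loocv, confidence_filtered_r2, flag_anomalies)

# a 44-entry synthetic therapy database, 20% of three condition columns hidden
ds, truth = generate(SynthConfig(n=44, noise_sd=0.05, seed=1))
ds = mask_missing(ds, truth, {"defect_area_pct": 0.2, "body_weight_kg": 0.2,
                              "cell_number": 0.2}, seed=2)

# screen descriptors one at a time, keep the individually predictive ones
screen = single_property_screen(ds, train_cfg=TrainConfig(sample_steps=0),
                                n_members=8, base_seed=9)
sel = forward_selection(screen, ds, train_cfg=TrainConfig(sample_steps=0),
                        n_members=8, base_seed=9, with_trace=False)
print("selected descriptors:", sel.chosen)

cv = loocv(sel.dataset, TrainConfig(), n_members=20, base_seed=3)
print(f"LOOCV R^2 = {cv.r2:.3f} over {cv.n} entries")
print(f"R^2 on the 75% most confident predictions = "
      f"{confidence_filtered_r2(cv, 0.75):.3f}")
print(flag_anomalies(cv).head(3)[["entry", "actual", "pred", "std", "z"]].round(3))
```

prints (seeds as above):

```
selected descriptors: ['cell_number', 'defect_depth_pct', 'defect_area_pct', 'body_weight_kg']
LOOCV R^2 = 0.492 over 44 entries
R^2 on the 75% most confident predictions = 0.669
   entry  actual   pred    std      z
0     22   0.473  0.695  0.079  2.797
1      2   0.649  0.782  0.058  2.300
2     37   0.623  0.717  0.055  1.694
```

Reading: the screen recovers exactly the four planted drivers and drops the
two nuisance indicators; the selected ensemble explains about half the
outcome variance under leave-one-out cross-validation despite the missing
cells; restricting to the 75 % of entries with the smallest ensemble
uncertainty raises R² to 0.67 — the uncertainty knows where the model is
unsure — and the anomaly table lists the entries whose observed outcome
sits furthest (in standard deviations) from its prediction, the ones a
meta-analyst would re-examine first.

A command-line interface mirrors the library
(`mscrepair synth|impute|train|loocv|screen|anomalies|curve`), reading and
writing the documented CSV schema.

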
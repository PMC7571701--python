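# Methods

`mscrepair` models a small meta-analysis database of mesenchymal-stem-cell
(MSC) cartilage-repair studies. One entry is one study condition — species,
body weight, tissue source, implanted cell number and concentration, defect
geometry (absolute and as a percentage of knee cartilage area/depth), damage
type — together with a repair outcome reported on one of ten clinical or
histological instruments, linearly rescaled to [0, 1] with 1 = healthy
tissue. The package predicts that unit-interval repair score, imputes
missing conditions, and attaches an uncertainty to every prediction.

## The self-consistent network

Entries are encoded as property vectors `x = (x_1, …, x_I)`: slots
`1..I−1` hold the scaled conditions, slot `I` the outcome. A single model
`f` maps the vector to a prediction of *itself*:

    y_j = Σ_h C_hj · tanh( Σ_i A_ihj · x_i + B_hj ) + D_j ,

one hidden tanh layer per predicted slot, with the structural constraint
`A_jhj = 0`: slot `j` is predicted without access to its own value. A
useful `f` therefore satisfies the fixed-point property `f(x) ≈ x` on the
data without being the identity, which is what makes the same network a
predictor of the outcome *and* an imputer of any missing condition.

The training objective is the mean summed squared error over observed
slots,

    σ = (1/N) Σ_{x∈X} Σ_j m_j (f_j(x) − x_j)² ,

with `m_j` the observation mask. Note the deliberate convention: no square
root is taken in `rmse_cost` even though the quantity is usually described
in RMSE terms; human-facing error reports use `sqrt(σ)`.

### Training schedule

Each network trains in three phases, all deterministic given its seed:

1. **Greedy random walk** (default 200 steps). Gaussian proposals over all
   parameters, accepted only on cost improvement; the proposal scale adapts
   per member (×1.05 on accept, ×0.97 on reject, clipped to
   [1e−4, 1]). This is the classical robust phase; the accepted-cost trace
   is non-increasing by construction.
2. **Adam refinement** (default 300 steps, learning rate 0.05) on the
   analytic gradient, with the self-weight mask re-zeroed after every
   update. The best-cost parameters seen anywhere are retained, so the
   final cost never exceeds the initial one.
3. **Residual-tempered scatter** (default 400 steps). Parameters of
   different output slots are disjoint, so a Metropolis walk around the
   optimum factorizes per output block. The temperature of block `j` is
   `T_j = σ̂²_j · s · (1 + n_j/p_j)` where `σ̂²_j = RSS_j / max(n_j − p_j, 3)`
   is the block's residual variance at the fit, `n_j` its observation
   count, `p_j = H(I+1)+1` its parameter count, and `s = 2` the tempering
   multiplier (`TrainConfig.sample_temper`).

Phase 3 is what makes the ensemble's spread meaningful. Independently
trained networks that all converge collapse onto the same fit, and their
disagreement then reflects optimizer trivia rather than uncertainty. A
posterior-matched temperature (`T_j = σ̂²_j`) restores the *epistemic*
spread, but held-out residuals also contain the observation noise itself;
in the linear-leverage approximation the predictive variance is
`(1 + h)σ²` against an epistemic `hσ²` with `h ≈ p/n`, hence the
`(1 + n/p)` inflation. The multiplier `s = 2` compensates for the
effective dimension of a tanh block being smaller than its parameter count
and for the finite chain length; it was fixed once, on simulations from
the package's own generator, such that roughly two thirds of held-out
outcomes fall within one reported standard deviation — the calibration the
uncertainty is designed to have. On noise-free data `σ̂² ≈ 0`, the
temperature collapses, and members stay at the optimum: accuracy is not
traded away.

Hidden-node count defaults to `H = 4`; a few dozen entries do not support
more, and `mscrepair.evaluation.hidden_sweep` re-evaluates the choice by
cross-validation when in doubt.

## Ensemble uncertainty

`train_ensemble` trains `M` members (100 by default; cross-validation
utilities default to 20 for speed) from derived seeds `base_seed + k`.
Members never share state; batched evaluation is a performance detail. The
prediction is the member mean, the uncertainty the *population* standard
deviation (`ddof=0`; immaterial at M = 100, documented for determinacy).
No bootstrap resampling is used — every member sees the full training set,
and diversity comes from the training procedure itself.

## Imputation

Missing slots start at training-set column means and are relaxed to
self-consistency by `x^{n+1} = γ x^n + (1−γ) f(x^n)` on the missing slots
only; observed slots are clamped (`update_known=True` restores the literal
whole-vector update for comparison). `f` is held fixed across iterations;
the converged vector is returned. Defaults: `γ = 0.5`, tolerance `1e−4` on
the max absolute change over missing slots, 100-iteration cap
(non-convergence warns and returns the best iterate rather than raising).
`γ` shapes the path, not the limit — for a contractive model the converged
point is γ-independent — and an oscillation guard halves `1−γ` if the
change metric grows five iterations in a row. When uncertainty is needed
for an incomplete vector, the iteration runs separately through each
ensemble member so that member spread propagates into the imputed slots.

## Cross-validation and evaluation

Leave-one-out: each entry with a known outcome is predicted by an ensemble
trained on all the others, the held-out outcome hidden and read back from
the converged imputation. Two determinism choices matter:

- training rows are put in a canonical (lexicographic) order inside each
  fold, and the fold seed derives from a content digest of the held-out
  row, so fold results are bitwise invariant to how the dataset is sorted;
- per-fold seeds stay below 2³¹.

`R²` is computed against the identity line; `confidence_filtered_r2` keeps
the fraction of entries with the smallest ensemble standard deviation
(stable ties, subset's own mean in the denominator by default — the
full-set-mean variant is a switch) and reproduces the overall `R²` exactly
at fraction 1. Anomalies are flagged by standard-deviations-out
`z = (pred − actual)/std`, positive = overprediction, split into over- and
under-predicted tables ordered most-extreme-first.

Descriptor screening trains one-condition models per property and ranks
them by LOOCV `R²` (uncertainty: standard deviation of member-wise `R²`).
Forward selection keeps the individually positive properties, reports the
combined `R²` of every top-k prefix (a declining prefix trace past some k
is the overfitting signature), and merges the bone-marrow and adipose
tissue-source indicators into a single property when both survive.
Correlation screening reports pairwise-complete Pearson and Spearman
matrices; no multiple-testing correction is applied to screening values.
Property influence is the drop in LOOCV `R²` on removing one property.
Baselines: 3-nearest-neighbour regression (Euclidean, mean-filled vectors,
stable ties) and the training-fold mean.

## Response analyses

`response_curve` / `response_surface` sweep one or two descriptors over a
grid while the others sit at a reference vector (column means; indicator
slots rounded to the modal level), impute the outcome per member at every
grid point, and normalize the predicted score against the full range of
observed outcomes in the database. Grid points outside the training range
of a varied descriptor are flagged as extrapolation.
`detect_thresholds` flags intervals whose finite-difference slope is
negative and below the steepest-quartile threshold — an exploratory
readout of the fitted model, not a constant of the method: printed
breakpoints depend on the model and the database supplied.

## Synthetic data

The generator emulates the statistical shape of the study database, not
its joint distribution: default 44 entries; body weight log-uniform on
0.02–70 kg, implanted cells log-uniform on 1e5–1e9, defect area/depth
percentages uniform on 1–60 % and 10–100 %; tissue source and damage type
drawn at documented frequencies; outcome = planted function + Gaussian
noise (default sd 0.05), clipped to [0, 1]; per-column MCAR masking with
recorded ground truth. The composite family's clinical axes are correlated
the way pooled study data are — lesion area and depth share a severity
latent, implanted dose scales with body size (pairwise correlations
≈ 0.5) — which is the cross-property structure imputation feeds on. Three
plants: a single-hidden-node tanh network (the estimator can represent it
exactly — used for recovery and calibration checks), an additive per-input
tanh plant whose drivers are marginally detectable by construction (used
for screening experiments; a shared-node plant can hide a driver behind
its co-drivers, which no marginal screen can see), and a clinically shaped
composite (score falls with defect severity, responds to log-dose through
a bell centred at 2×10⁷ cells, rises mildly with body
weight). A heteroscedastic mode makes the outcome noisiest where
conditions are sparsely sampled, the typical shape of pooled animal
studies. What the generator does *not* emulate: study-design-driven
(MAR-by-study-type) missingness beyond an optional mode, correlated
predictors, instrument-specific discreteness of scores. Passing tests on
this generator therefore demonstrate the machinery's correctness and
calibration under its stated assumptions, not performance on any
particular real database.

## Problem sizes

Cross-validation experiments in the test suite and the acceptance script
use 30–60 entries and 10–100 ensemble members depending on the check —
the scale of the scientific problem itself (a 44-entry database), with
member counts chosen per experiment so the whole suite stays quick to run.

## Known limitations

- Uncertainty calibration rests on the linear-leverage approximation and a
  fixed tempering multiplier; strongly misspecified models (large bias)
  push coverage below nominal because bias is invisible to the spread.
- A single noise level per output slot: heteroscedastic uncertainty is
  detected only through sampling density, not modelled.
- The fixed-point iteration assumes a contractive model near the data;
  the γ-softening and oscillation guard are safeguards, not a proof.
- Min–max encodings clip out-of-range values at encode time; predictions
  for conditions far outside the database range are extrapolations and are
  flagged as such, not trustworthy readouts.
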
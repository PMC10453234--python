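# Methods

## Problem setting

A food-safety surveillance campaign produces one record per (sample,
detection item): a free-text result, the regulatory maximum limit, and the
assay's standard detection limit. The package turns those records into a
dense detection matrix, derives a fine-grained composite risk value per
sample by grey relational analysis (GRA), and trains a TabNet regressor to
map detection rows straight to that risk value so new batches can be
scored without re-running the analysis.

## Preprocessing rules

Five rules, applied in `detection_io`:

1. Only the requested indicator columns are kept; samples missing any
   requested indicator are dropped and reported.
2. Format conversion: a leading `<` (left-censoring at the reporting
   bound) is stripped to the bound itself. Decimal parsing accepts the
   `.` radix only; thousands separators are rejected in results (but
   accepted in printed *limit* fields such as `10,000`).
3. Redundant data: semicolon-separated replicate values (and duplicate
   records for one sample/indicator pair) reduce to their maximum.
4. `"Not Detected"` is filled with half the standard detection limit —
   the conventional substitution for values below the limit of detection —
   never with zero.
5. Outlier screening: the default rule flags a sample when any value
   exceeds K × its indicator's maximum limit (K = 50). The rule is
   unit-aware and reproducible; any callable over the matrix can replace
   it. No exclusion count is imposed by default — flags are returned to
   the caller.

Indicators whose limit field reads "shall not be used" (substances not
permitted at any level) fall back to the detection limit as hazard
denominator, so any detected amount scores a hazard quotient ≥ 1 at the
assay floor. The fallback is configurable per indicator.

Orientation: matrices are stored samples × indicators; the GRA equations
run on the transposed (indicators × samples) view, handled at the module
boundary.

## Grey relational analysis

Per indicator row, min-max normalization `y = (x − min)/(max − min)`;
constant rows map to all zeros (avoiding 0/0, and behaving as maximally
flat sequences downstream). With each indicator serving as reference once,
the grey relational coefficient is

ξ_i(k) = (Δmin + ρΔmax) / (Δ_i(k) + ρΔmax)

with Δ ranges taken over the comparison indicators *excluding the
reference itself*, and ρ = 0.5 (the customary default; exposed as
`GRAConfig.rho`, valid on (0, 1)). If Δmax = 0 (all comparison sequences
identical to the reference) all coefficients are defined as 1. The
relational matrix γ holds mean coefficients per (reference, comparison)
pair; the diagonal is set to 1 by self-identity rather than computed, and
the matrix is deliberately *not* symmetrized — the Δ scopes differ per
reference. Weights are row means of γ (diagonal included) normalized to
sum 1; they are strictly positive because every coefficient is positive.

Composite risk is the weight-weighted sum of hazard quotients
d_ik = x_ik / l_i. Exact invariants verified in tests: weights sum to 1
within 1e-12; permuting samples permutes risks identically; rescaling one
indicator leaves weights unchanged (normalization removes scale) and
scales its hazard row; if all d_ik ≤ 1 then r_k ≤ 1 (convex combination).

## TabNet regressor

Architecture per decision step i = 1…n_steps (defaults n_d = n_a = 8,
n_steps = 3):

- **Attentive transformer**: scores = BN(FC(a[i−1])) ⊙ P[i−1], mask
  M[i] = sparsemax(scores) row-wise. Sparsemax is the Euclidean
  projection onto the probability simplex (sorted-threshold algorithm),
  so each sample's feature weights are sparse and sum to exactly 1.
  The projection support is restricted to features with strictly positive
  prior; with all-positive priors this equals plain sparsemax, and it
  makes the relaxation-1 single-use property exact: a feature fully
  selected once has prior 0 and receives exactly zero weight afterwards.
  Sparsemax outputs are row-renormalized to absorb the last-ulp rounding
  of the threshold, so a fully selected coordinate is exactly 1.
- **Prior update**: P[i] = P[i−1] ⊙ (relaxation − M[i]), P[0] = 1.
  Relaxation defaults to 1.3 (≥ 1 enforced, else priors could go
  negative); at 1.0 each feature can be used at only one step.
- **Feature transformer**: the masked features M[i] ⊙ c pass through two
  blocks shared across steps plus two step-specific blocks; each block is
  an affine map to twice the width, ghost batch normalization, and a gated
  linear unit, with residual additions scaled by √0.5 after the first
  block. `c = BN(X)` is the initial full-batch normalization; per the
  stated initialization (a[0] = 0, P[0] = 1) there is no pre-step feature
  transform before the first attentive transformer.
- **Aggregation**: d_out = Σ_i ReLU(d[i]) where (d[i], a[i]) is the
  n_d/n_a split of the transformer output; a final affine head maps d_out
  to one risk value.

Training: Adam (lr 0.01 default), plain mean squared error; an optional
mask-entropy sparsity penalty exists but is off by default. Full-batch
training is the default (batch_size = None), with seeded mini-batching
available. All randomness — initialization and shuffling — derives from
the config seed, so identical seeds give identical runs.

### Autodiff substrate

The network runs on a minimal reverse-mode automatic-differentiation
engine over numpy arrays (`tabgra._autodiff`): broadcast-aware elementwise
ops, matmul, axis reductions, relu/sigmoid/sqrt/log, row/column slicing,
row concatenation, and a sparsemax primitive with its exact
Jacobian-vector product (on the active support S: dz = g − mean_S(g)).
Every op and the composed batch-norm expression are gradient-checked
against central finite differences in the test suite.

### Ghost batch normalization and train/inference consistency

Ghost batch normalization computes statistics over virtual chunks of at
most `virtual_batch_size` rows (default 128). Plain ghost BN leaves a
gap between training-mode (per-chunk statistics) and inference-mode
(running statistics) forward passes; because sparsemax masks switch
features discontinuously, that gap destabilizes inference badly in this
architecture. The layers therefore use *batch renormalization* within
each virtual chunk: the chunk-normalized activations are corrected by the
detached factors r = σ_chunk/σ_run and d = (μ_chunk − μ_run)/σ_run, with
running statistics updated (momentum 0.02) from the batch's chunk
statistics before use. The forward value then equals running-statistic
normalization exactly while gradients still flow through the virtual-chunk
statistics, so training-mode and inference-mode predictions agree at
convergence. Inference always uses the fixed running statistics and is a
deterministic per-row map (predictions are permutation-equivariant).
BN epsilon is 1e-5.

Models serialize to a single archive (config as JSON, parameters and
running statistics as arrays, per-epoch loss log) and reload bit-stably.

## Synthetic data generator

The generator emulates the structure of provincial cooked-meat
surveillance records over nine indicators: lead 0.5, cadmium 0.1,
chromium 1.0, total arsenic 0.5, nitrite 30 (mg/kg); sorbic acid 0.075,
benzoic acid not-permitted with 0.005 detection-limit fallback (g/kg);
total bacterial count 10 000, coliform group 10 (CFU/g). In-control
contamination is log-normal with median at 0.1 × limit (heavy-tailed, the
standard model for contaminant concentrations) and log-scale σ = 0.8,
truncated at the limit so that only injected exceedances cross it — this
makes the `exceedance_prob = 0` configuration provably bound every hazard
quotient by 1. Exceedances are injected per cell with probability 0.03 at
uniform(1.05, 3) × limit; chemical assays report "Not Detected" with
probability 0.15 (clean value: half the detection limit) and values below
the detection limit as "<LOD" (clean value: the bound, exactly as the
parser recovers it); count indicators emit five replicate plate counts
with probability 0.3, reduced to their maximum. Chemical values are
rendered to 4 decimals and counts to integers, so the clean matrix equals
the parsed raw records exactly (verified over 20 seeds).

What the generator does **not** model: real covariance between indicators,
seasonal or product-category structure, per-product limit variation, and
laboratory batch effects. Passing tests therefore demonstrate that the
pipeline recovers risks whose structure matches its assumptions, not
performance on any particular real surveillance dataset.

## Evaluation

RMSE and MAE with per-sample absolute errors; MAE ≤ RMSE always
(power-mean inequality, property-tested). The model-comparison harness
accepts any object with fit/predict and reports a table sorted by RMSE.
The default split holds out the chronological tail — max(50, 5 % of n)
most recent samples — because surveillance data arrive in time order and
deployment predicts forward in time; a seeded random split is available.

## Risk levels and reporting

With warning threshold t (default 1.0, the natural exceedance point of
the hazard-quotient scale): high if r > t, medium if t/2 ≤ r ≤ t, low if
r < t/2. Boundary ties resolve to the interior (more cautious) category.
Quartiles use inclusive linear interpolation. Report export writes a
fixed-format assignments CSV and a sorted-keys summary JSON (byte-stable
across re-export), plus optional static plots: a risk scatter/level bar
figure and a parallel-coordinate hazard-composition view.

## Problem sizes used in the checks

The simulation-based end-to-end check trains on 1 900 of 2 000 synthetic
samples for 200 epochs (full batch, virtual batch 128) across five seeds
and evaluates on the chronological 100-sample tail; the GRA oracle check
uses 100 random matrices with m ≤ 6, n ≤ 12; sparsemax is checked against
a brute-force simplex projection on a dense 3-vector grid. These sizes
keep the full suite to a few minutes on one CPU while exercising every
code path at realistic shapes.

## Known limitations

- The GRA weights depend on the observed batch (through min-max
  normalization and Δ ranges), so risks are comparable within a campaign,
  not across campaigns with different weight vectors.
- The TabNet feature-transformer internals follow the canonical
  two-shared/two-specific gated-block design; the underlying description
  treats this module as a black box, and other depths are plausible.
- Left-censored values are imputed at fixed points (bound, or half the
  detection limit); no distributional censoring model is attempted.
- Single-threaded CPU training only; the autodiff engine favors clarity
  and testability over speed and is sized for tabular problems of this
  scale (thousands of rows, tens of features).
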
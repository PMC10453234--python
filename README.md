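# tabgra

Food-safety surveillance programmes collect large tables of contaminant
detection results — heavy metals, preservatives, microbial counts — and need
a fast way to turn a new batch of detections into a per-sample risk score
for early warning. `tabgra` implements that pipeline for regulators and
food-science analysts:

1. **Preprocessing** of raw detection records: left-censored results
   (`"<0.005"` → `0.005`), replicate plate counts (`"80; 70; 90;50; 180"` →
   maximum), and `"Not Detected"` entries filled with half the assay's
   standard detection limit.
2. **Grey relational analysis (GRA)** to weight the m risk indicators.
   With `y_i(k)` the min-max normalized value of indicator i in sample k,
   the grey relational coefficient of a comparison indicator against a
   reference is

   ξ_i(k) = (Δmin + ρ·Δmax) / (Δ_i(k) + ρ·Δmax),  Δ_i(k) = |y_ref(k) − y_i(k)|

   with adjustment parameter ρ = 0.5. Relational degrees γ_iq (mean of
   ξ over samples, each indicator serving as reference once) are reduced to
   row means and normalized into weights **W**. The composite risk of a
   sample is the weighted sum of its hazard quotients,

   r_k = Σ_i w_i · x_ik / l_i,

   where l_i is indicator i's regulatory maximum limit, so r_k > 1 implies
   at least one weighted exceedance.
3. **A from-scratch TabNet regressor** — sequential decision steps with
   sparsemax attentive feature masks M[i] = sparsemax(P[i−1] ⊙ h_i(a[i−1])),
   prior update P[i] = Π_j (γ − M[j]), gated-linear-unit feature
   transformers with ghost batch normalization, and a ReLU-aggregated
   decision output — trained with Adam on mean squared error so new
   detection rows map straight to composite risk without re-running the
   GRA. Built on a small reverse-mode autodiff engine in numpy; no GPU
   needed.
4. **Evaluation and reporting**: RMSE/MAE against any fit/predict
   regressor, chronological held-out splits, warning-threshold risk levels
   (green < ½·threshold ≤ yellow ≤ threshold < red) and deterministic
   CSV/JSON/plot export.

A synthetic-data module generates full raw-record datasets (nine
indicators, per-indicator limits, censoring, replicate counts) so every
stage is testable without access to proprietary surveillance data.

## Worked example

```python
from tabgra import (GeneratorConfig, TabNetConfig, TabNetRegressor,
                    ConstantMeanBaseline, chronological_split, error_metrics,
                    simulate_dataset)

dataset = simulate_dataset(GeneratorConfig(n_samples=800, seed=1))
X, y = dataset.clean_matrix.values, dataset.true_risks
train_idx, test_idx = chronological_split(len(y), 50)

model = TabNetRegressor(TabNetConfig(max_epochs=200, seed=1))
model.fit(X[train_idx], y[train_idx])
print(error_metrics(y[test_idx], model.predict(X[test_idx])))
```

Running `python examples/03_train_tabnet_regressor.py` (the same
computation) prints

```
held-out RMSE 0.0287, MAE 0.0210 (n=50)
constant-mean baseline RMSE 0.1225
```

— the encoder predicts the GRA composite risk of the 50 most recent
held-out samples about four times more accurately than the no-information
baseline, and the aggregate mask importances it prints show which
indicators the sparse attention selected. The other scripts in
`examples/` walk through record parsing, GRA weighting, and risk-level
reporting; the `tabgra` command line exposes the same stages
(`tabgra simulate | preprocess | weights | label | train | predict |
evaluate | report | pipeline`).

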
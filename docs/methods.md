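# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Censoring substitution

Laboratory non-detects are left-censored at the LOD (default 0.2
μg/kg). The WHO substitution convention is applied with the censored
share computed **once over the whole campaign**, not per city: share
≤ 60% → each non-detect becomes LOD/2; share > 60% → LOD. The global
pooling is a deliberate choice — the rule describes a campaign-level
data-quality regime, and a per-city rule would value identical
measurements differently across cities. The operation is idempotent
(its output contains no non-detects).

Aggregation to (city, week) keeps three statistics because the three
indices consume different ones: the median (cancer-risk index), the
mean (exposure/margin of exposure) and the maximum (pollution index).
Medians of even-sized groups are the mean of the two central values.
City-weeks with no samples are absent from the summaries; gap handling
is deferred to forecasting (forward-fill).

## Risk indices

`ILCR = C·TEF·Ir·Ep·SF·CF/(BW·TA)` is implemented exactly as this
standard parameterization is printed in the food-risk literature,
including CF = 10⁻⁶ with C in mg/kg. The published constant set mixes
units (CF is quoted as mg/ng); we do not re-derive a "corrected" scale
because every downstream consumer (grading) min–max-normalizes the
indicator, so any constant factor cancels. The absolute ILCR scale is
therefore convention-dependent and should not be compared across
software. The exposure duration Ed (70 a) is carried in `IlcrParams`
for documentation but the formula's right-hand side uses only Ep and
TA (= Ed·Ep under defaults).

Category boundaries: both ends of the ILCR acceptable band (10⁻⁶,
10⁻⁴) are inclusive; an MOE of exactly 10,000 is classed
attention-required (the very-low-risk reading is strict >). MOE at
zero exposure raises an explicit error rather than returning infinity.

NIPI per city-week is computed from the stored mean/max summary
statistics; because every pollution index is the sample concentration
divided by the same fixed limit Sj, this equals the definition applied
to the raw sample collection (cross-checked in tests). A pooled
per-province annual NIPI is exposed separately for reporting.

## Risk grading

Min–max normalization maps each indicator to [0, 1]; the MOE axis is
reflected (1 − scaled) because a large margin of exposure means *less*
risk, and the cluster-ranking rule below is only coherent if every
axis is risk-increasing. New points are clipped to the training cube
before assignment.

k-means uses Euclidean distance, k-means++ seeding and 10 restarts.
Clusters are ranked into levels by the Euclidean distance of their
centers from the origin of the normalized space — farther = riskier.
Nearest-center ties at assignment go to the higher level
(conservative for food safety).

**Elbow selection.** The SSE(k) curve is fitted for k = 1..8. Beyond
the usual restarts, each k also tries a warm start built from the
previous k's best centers plus the farthest point, which makes the
reported curve non-increasing by construction. The selected k
maximizes the discrete curvature of **log** SSE, i.e. the second
difference log SSE(k−1) − 2·log SSE(k) + log SSE(k+1) over interior
candidates. The raw-scale second difference was evaluated first and
rejected: on SSE curves that decay roughly geometrically (ratio ≈ 3–4
per step, which is what both a single blob and clean 3-cluster data
produce here) it is dominated by the first interior point and selects
k = 2 on essentially any input. The log form is scale-invariant and
peaks where the *relative* per-step improvement collapses — which is
what the eye reads as the elbow.

## Forecasting

Each (city, indicator) weekly series is forward-filled onto a complete
week grid (leading gaps back-filled), windowed into seven-lag vectors
predicting the next value, and split 6:4 chronologically — the split
index is computed on the series, and a window belongs to the training
set only if its *target* precedes the cut, so no training target
postdates any test lag source.

*Recurrent model.* A compact stacked LSTM implemented on numpy
(`oilrisk.nn`): two hidden layers (64 and 32 units) with dropout 0.2,
dense linear output, sigmoid cell activation (tanh available), MAE
loss, Adam at initial rate 0.05, global gradient-norm clipping at 1,
150 epochs with batches of 8. Inputs and targets are min–max scaled
internally and predictions inverse-transformed; constant series are
scaled by their own magnitude so the residual fitting error stays
proportional to the data scale. All randomness flows from one seed and
fits are bit-reproducible. Backpropagation through time is exact and
verified against central finite differences (relative error < 10⁻⁴) in
the test suite. Widths, dropout and epochs are free choices; the layer
count, lag length, loss, optimizer, learning rate and clipping follow
the published construction this pipeline implements.

*Tree model.* XGBoost regression (squared-error objective) on the same
seven lag values — no calendar features. Defaults: learning rate 0.1,
max depth 3, 200 trees, no subsampling, `n_jobs=1` for reproducible
reruns. Optional tuning runs an exhaustive grid (learning rate
0.05–0.2, gamma, subsample, column sampling, depth 3–6) scored by mean
validation RMSE over **ten contiguous blocked folds** of the training
windows. Plain shuffled folds would let near-identical neighboring
windows straddle the train/validation boundary; contiguous blocks keep
the spirit of ten-fold cross-validation while limiting that leakage.
Tuning is off by default in the pipeline (the fixed defaults are
adequate at this problem size and keep the run deterministic and
fast).

## Inverse-error combination

Weights ω1 = ε2/(ε1+ε2), ω2 = ε1/(ε1+ε2) sum to one by construction;
ε1 = ε2 = 0 yields (0.5, 0.5). The error statistic εᵢ is the
root-mean-square of model i's recent residuals — RMS is chosen because
the weights then minimize the variance of the combined error under
independence, and the choice is recorded in output metadata. Two modes:

* **static** — εᵢ computed once from the in-sample (training-window)
  residuals;
* **rolling** (default, window 7) — at each forecast origin the last
  seven *realized* residuals are used, folding in test-period
  residuals as their weeks pass; before any test residual exists the
  history is the in-sample tail. With no history at all the weights
  fall back to (0.5, 0.5) with a logged notice.

Weights are computed per (city, indicator) series, never globally,
since error structure is series-local. For any *fixed* convex pair the
combined MAE and RMSE are bounded by the worse single model (triangle
and Minkowski inequalities); with time-varying weights the bound is
not a theorem, and is instead observed empirically on the benchmark.

## Evaluation

RMSE and MAE per (model, indicator) on the test weeks. Risk-level
scores are one-vs-rest precision, recall and F1 per level from the
confusion matrix, macro-averaged (unweighted over levels; the
averaging scheme is stated in the report metadata). A level absent
from both truth and prediction has undefined scores and is excluded
from the macro mean with a logged notice. Reference levels come from
grading the *observed* triples with the same fitted grader, so the
comparison isolates forecasting error from grading error; a
planted-truth variant is available for recovery tests.

## Synthetic benchmark

The generator emulates a national surveillance year: 4 provinces × 3
cities, 53 weekly rounds, 8 samples per city-week (5,088 records),
LOD 0.2 μg/kg, target non-detect share 0.4. Each city carries one
latent concentration regime (low/medium/high, lognormal means 0.5 /
2.0 / 6.0 μg/kg before censoring calibration, CV 0.4, city shares
0.5 / 0.35 / 0.15 by largest-remainder apportionment with every regime
guaranteed present). Censoring thresholds draws at the LOD; when the
natural left-tail mass misses the target share by more than 0.05, a
common log-location offset solved from the mixture CDF shifts all
regimes together — ratios between regimes, and hence the normalized
cluster geometry, are preserved. Consumption is uniform per city in
0.04–0.05 kg/d with body weight 60 kg; the band is deliberately narrow
(per-capita oil intake varies little between cities) because intake
multiplies into ILCR and MOE, and a wide band would confound the
concentration regimes the benchmark plants.

What the benchmark does *not* emulate: province-specific consumption
statistics, seasonality, regime drift within a city (a per-week drift
switch exists in design but one-regime-per-city is the default so
recovery tests are unambiguous), laboratory-specific LODs, or
measurement uncertainty. Passing tests therefore demonstrate that the
pipeline recovers structure it is designed to represent — three
separated regimes under ~40% censoring — not that real campaign data
are this clean; on real data the level scores in the report should be
expected to drop substantially.

## Problem sizes and determinism

Default runs use 12 cities × 53 weeks (636 triples, 36 forecast
series); the full pipeline completes in well under a minute on one
CPU, and the test suite in about a minute. One global seed fans out to
per-stage seeds by hashing the stage name (CRC32, kept below 2³¹), so
stages are independently reproducible; two identical runs produce
byte-identical CSVs and reports (the manifest's timings differ).

## Known limitations

* The absolute ILCR scale inherits the published constant set's unit
  mixture (see above); rankings and gradings are unaffected.
* The elbow criterion needs at least three candidate k and an SSE
  curve with a genuine bend; near-flat curves (single blob) yield an
  arbitrary small k rather than a refusal.
* Level names are fixed to three (low/medium/high) when k = 3;
  other k fall back to generic ordinal names.
* The recurrent model is CPU-only and sized for weekly series of tens
  to hundreds of points, not for large-scale training.
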
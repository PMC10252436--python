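# oilrisk

Food-safety risk assessment and short-horizon risk forecasting for
benzo[a]pyrene (BaP) residues in edible oils, built for surveillance
analysts who work from weekly city-level sampling campaigns and
per-capita consumption statistics.

BaP is a carcinogenic polycyclic aromatic hydrocarbon that enters edible
oil during seed roasting, hot pressing and drying. Given weekly
laboratory measurements (left-censored below a limit of detection, LOD)
and a city's daily oil intake, the package computes three complementary
risk indicators per city-week, grades city-weeks into low / medium /
high risk by clustering, forecasts next-week indicators with two
heterogeneous models, fuses the forecasts with inverse-error weights,
and scores the predicted risk levels.

## The indicators

With median concentration *C* (mg/kg), intake *Ir* (kg/d), body weight
*BW* (kg):

* **Incremental Lifetime Cancer Risk**
  `ILCR = C · TEF · Ir · Ep · SF · CF / (BW · TA)` with TEF = 1,
  Ep = 365 d/a, SF = 7.3 kg·d/mg, CF = 10⁻⁶, TA = 25,550 d.
  Bands: < 10⁻⁶ negligible; 10⁻⁶–10⁻⁴ acceptable (inclusive); > 10⁻⁴
  non-negligible.
* **Margin of Exposure** `MOE = BMDL10 / Exp`,
  `Exp = Fi · Ci / (BW · 1000)` with BMDL10 = 0.07 mg/(kg·d) and the
  mean concentration *Ci* in μg/kg. MOE strictly above 10,000 is of
  very low concern.
* **Nemerow Integrated Pollution Index**
  `NIPI = sqrt((P_max² + P_ave²) / 2)` over single-sample pollution
  indices `P_i = X_i / Sj`, Sj = 0.01 mg/kg.

Non-detects are valued by the WHO substitution rule before any index is
computed: LOD/2 when the campaign's censored share is ≤ 60%, LOD
otherwise (LOD defaults to 0.2 μg/kg).

## Grading and forecasting

Indicator triples are min–max normalized with the MOE axis reflected so
that every axis is risk-increasing; k-means clusters (k chosen by the
elbow criterion on the SSE curve, measured as maximum curvature of the
log-SSE profile) are ranked into levels by their centers' distance from
the origin. Each (city, indicator) weekly series is windowed (seven
lags → next value, 6:4 chronological split) and forecast by a stacked
recurrent network (MAE loss, Adam at 0.05, gradient clipping at 1) and
by XGBoost on the same lags; the two forecasts are combined as
`f_t = ω1·f1_t + ω2·f2_t` with `ω1 = ε2/(ε1+ε2)`, `ω2 = ε1/(ε1+ε2)`,
the εᵢ being rolling RMS residuals. Forecast quality is reported as
RMSE/MAE per indicator and precision/recall/F1 (macro) on the predicted
risk levels.

A seeded synthetic-data generator emulates a national campaign (53
weekly rounds, ~40% non-detects, three planted concentration regimes),
so the full pipeline runs with no external data.

## Worked example

```bash
oilrisk run-all --seed 42 --out runs/demo
```

runs every stage (simulate → preprocess → index → grade → forecast →
combine → evaluate) and prints the final scoreboard; on the default
configuration (12 cities, 53 weeks, 5,088 samples) it completes in
under a minute and prints:

```
# Risk level prediction

| Model | P% | R% | F1% |
|---|---|---|---|
| LSTM | 100.00% | 100.00% | 100.00% |
| XGBoost | 100.00% | 100.00% | 100.00% |
| LSTM-XGBoost | 100.00% | 100.00% | 100.00% |

# Forecast errors

| Model | Indicator | RMSE | MAE |
|---|---|---|---|
| LSTM | ilcr | 0.00192054 | 0.000554411 |
...
```

The perfect level scores say that on this synthetic campaign every
test-week city lands in its correct risk cluster under all three
forecasters — the planted regimes are well separated, so level
classification is easier than the underlying regression (whose RMSE/MAE
rows show the fused model tracking the better base model per
indicator). Intermediate artifacts (indicators.csv, grade_model.json,
predictions.csv, combined.csv, report.json, manifest.json with seeds
and versions) are left in `runs/demo/`.

Library use mirrors scikit-learn:

```python
from oilrisk import SyntheticConfig, generate, RiskGrader
from oilrisk.preprocessing import substitute_nondetects, summarize
from oilrisk.indices import compute_triples

sampling, consumption, truth = generate(SyntheticConfig(seed=42))
triples = compute_triples(summarize(substitute_nondetects(sampling)), consumption)
grader = RiskGrader(k="auto", random_state=0).fit(triples)
print(grader.k_, grader.predict(triples)[:5])
```

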
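# glucovar

Long-horizon glucose forecasting and glycemic-variability (GV) analysis for
continuous glucose monitor (CGM) data, aimed at researchers working with
automated insulin delivery (AID) datasets.

People using open-source AID systems generate months to years of 5-minute
CGM readings. Most published glucose forecasters stop at 30–120 minute
horizons; clinically, one also wants to know whether a model forecasting a
far longer window — up to 48 h — preserves the *variability* character of a
profile, not just its point accuracy. `glucovar` implements that analysis
end to end as a tri-stage pipeline:

1. **Data** — simulate synthetic CGM traces with realistic marginal
   structure (or ingest CSV / Nightscout-style JSON exports), with a
   cleaning stage for duplicates, gaps and out-of-range values, and
   resampling onto a regular 5-minute grid.
2. **Profiling** — descriptive statistics (mean, SD, CV, quartiles,
   skewness class) plus stationarity labelling (ADF + KPSS) and
   autocorrelation-based seasonality detection.
3. **Forecast & compare** — fit ARIMA(7,1,0), gradient-boosted trees,
   random forests (and optionally an LSTM) on 30 or 60 days of glucose;
   predict a 48-h window in rolling one-step or recursive multi-step mode;
   score MAE/RMSE; and compare 19 GV metrics between the predicted and
   observed windows.

## The metrics

For a window of glucose readings *g* (mg/dL) the package computes: mean,
SD, CV; time below/in/above the 70–180 mg/dL target range (TBR/TIR/TAR);
SD of the rate of change; the blood-glucose risk indices built on
*f*(*g*) = 1.509·((ln *g*)^1.084 − 5.381), with LBGI/HBGI the mean of
10·*f*² on the low/high branch; GMI = 3.31 + 0.02392·mean; J-index =
0.001·(mean + SD)²; CONGA(*n*) — SD of differences *n* hours apart; the
lability index (squared hourly changes in mmol/L per week); GRADE —
capped mean of 425·(log₁₀log₁₀(*g*/18.016) + 0.16)²; MODD — mean |24-h
difference|; MAGE — mean amplitude of excursions exceeding 1 SD; ADRR —
mean per-day maximum low plus high risk; the M-value (reference
120 mg/dL); and MAG — absolute change per hour.

Predicted-vs-observed metric pairs are compared with a **relative error**
(100·|p − e|/|e|, unstable when e → 0, as for TBR on well-controlled
profiles) and a **proportional error** (max/min magnitude ratio, ≥ 1 and
symmetric), aggregated cohort-style as min/avg/max per metric and model.

## Worked example

```
$ glucovar simulate --days 4 --seed 7 --out trace.csv
$ glucovar gv --in trace.csv --out gv.json
```

`gv.json` holds the 19 metrics of the 4-day window, e.g.:

```json
{"mean": 137.23, "sd": 53.32, "cv": 38.86,
 "tbr": 3.04, "tir": 82.03, "tar": 14.93,
 "lbgi": 1.04, "hbgi": 4.05, "gmi": 6.59, "j_index": 36.31,
 "mage": 66.44, "conga": 32.51, "modd": 52.79, "adrr": 35.70, ...}
```

A mean of 137.2 mg/dL maps to an HbA1c-like GMI of 6.59%; 82% of readings
sit in the 70–180 mg/dL target range; the MAGE of 66 mg/dL says a typical
qualifying excursion swings about 1.2 SDs peak-to-nadir. Forecasting and
scoring the final day from a 2-day training window:

```
$ glucovar forecast --in trace.csv --model gbtree --train-days 2 \
      --horizon-hours 24 --seed 7 --out fc.csv
$ glucovar evaluate --forecast fc.csv --out err.json
```

gives a rolling one-step MAE of 12.85 mg/dL (RMSE 18.88) and per-metric
errors such as mean: expected 169.34, predicted 165.08 → relative error
2.52%, proportional error 1.026.

The numbered scripts under `analysis/` run the same stages cohort-wide on
19 simulated profiles (`01_simulate_cohort.py` … `04_forecast_and_errors.py`),
writing their tables under `results/`.

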
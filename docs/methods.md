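# Methods

## Synthetic CGM generation

The simulator targets the marginal structure observed in real AID cohorts:
per-profile mean 98–158 mg/dL, SD 31–60 mg/dL, CV 26–44 %, skewness −0.12
to 1.46, stationary, with no daily seasonality strong enough to push any
autocorrelation peak above 0.9.

The construction is a Gaussian copula: a latent AR(1) process
z_t = φ·z_{t−1} + √(1−φ²)·ε_t with standard-normal stationary marginal is
pushed through Φ and then through the quantile function of a skewed
marginal moment-matched to the target (mean, SD, skewness). Values are
clamped to a physiologic [40, 400] mg/dL afterwards.

* **Marginal family.** The default is the skew-normal, whose 3-parameter
  moment map is closed-form; its |skewness| is bounded by ≈ 0.9953, so
  requesting more with `marginal="skewnorm"` raises an error naming the
  bound. The `auto` family (default) switches to a moment-matched shifted
  log-normal above that bound, covering the full observed skewness range;
  negative skewness mirrors the positive construction. Clamping attenuates
  extreme-tail skewness somewhat; the recovery contract covers mean, SD
  and lag-1 correlation only.
* **Latent standardization.** At φ = 0.98 a 30-day trace has an effective
  sample size of roughly 90, so a raw realization's sample mean wanders
  ±5 mg/dL around the target. The latent realization is standardized to
  exactly zero mean and unit variance before the marginal transform; this
  is what makes the generator's moment contract (sample mean within
  2 mg/dL, SD within 10 %) hold per realization rather than only in
  expectation. Stationarity and the lag-1 correlation are unaffected.
* **Defaults.** Mean 137.56, SD 50.15, skewness 0.8 — the cohort averages
  of the population the simulator emulates. `lag1_corr = 0.98` at 5-minute
  sampling makes traces smooth enough that the SD of the per-minute rate
  of change lands in the observed 0.8–2.1 mg/dL/min range.
* **What is not modelled.** Meals, insulin dynamics, sensor drift,
  circadian structure. The forecasting task here is univariate, so the
  generator deliberately produces the simplest process matching the
  published marginal and dependence summaries; passing tests demonstrate
  pipeline correctness on such processes, not clinical realism.

Artifact injection (duplicate timestamps, Poisson-placed dropout gaps,
unparsable or out-of-range values, timestamp jitter) is driven by
independent substreams of one seed, so each artifact kind is reproducible
in isolation. With all rates zero the records reproduce the series
verbatim, which gives the cleaning stage an exact round-trip test.

## Cleaning and gridding

Raw records are sorted (stable), de-duplicated keeping the first occurrence
per timestamp, parsed, and filtered to [39, 400] mg/dL — common CGM
reporting limits; the bounds are configurable because upstream cleaning
conventions differ. Every input record lands in exactly one bucket of the
cleaning log (kept, duplicate, unparsable, out-of-range), an invariant the
tests enforce. mmol/L sources are converted with 18.016 mg/dL per mmol/L.

Gridding anchors at the first timestamp floored to the interval; each slot
takes the nearest observation within half an interval. Missing runs of at
most 30 minutes are linearly interpolated (counted separately); longer
gaps stay missing so that difference-based metrics (CONGA, MODD, SD-ROC)
are never computed across invented data. All GV metrics use complete-pair
analysis over present readings rather than imputation.

Train/test splitting takes the final `horizon_hours` (48 h → 576 slots) as
the test window and the `train_days` (30 or 60) immediately preceding as
the training window, adjacent on the grid with no overlap.

## Profile statistics

Sample SD uses the n−1 denominator; quartiles use linear interpolation
between order statistics; skewness is the adjusted Fisher–Pearson
coefficient. Skewness classes: |s| ≤ 0.5 symmetrical, 0.5 < |s| ≤ 1
moderately skewed, |s| > 1 highly skewed — boundary values go to the
milder class (the verbal convention "between −0.5 and 0.5" is inclusive-
ambiguous; this choice is pinned by tests).

**Stationarity.** A profile is labelled *stationary* when ADF rejects its
unit-root null and KPSS does not reject its level-stationarity null, both
at α = 0.05 (configurable); ADF-only gives *difference stationary*,
KPSS-only *trend stationary*, neither *non-stationary*. KPSS has severe
size distortion when consecutive observations are almost perfectly
correlated, as 5-minute CGM samples are: applied naively it labels a large
share of genuinely stationary traces non-stationary. Since stationarity is
invariant to subsampling, the tested sequence is thinned by stride
doubling until its lag-1 correlation is ≤ 0.8, keeping at least 300
points. Over 40 simulated 30-day traces this labels 35 stationary (the
residual failures are borderline KPSS rejections, consistent with the
test's 5 % size); white noise and random walks classify correctly in
37/40 and 38/40. An AR(1) plug-in (Andrews) bandwidth was evaluated as an
alternative and rejected: it repairs the size but destroys KPSS power
against unit roots (23/40 random walks detected).

**Seasonality.** A profile is seasonal when the autocorrelation exceeds
0.9 at some candidate period between 1 hour and 7 days. Two details
matter: the *adjusted* (unbiased) autocorrelation estimator is used,
because the default divisor damps exactly the day-scale lags being tested;
and a period must be a local maximum of the ACF on the hourly candidate
grid, because smooth traces trivially exceed 0.9 at short lags without
being seasonal. The smallest qualifying lag is reported as the fundamental
period.

## GV metrics

Formulas follow the canonical literature definitions; the two that are
closed-form functions of a window's mean and SD (GMI, J-index) are pinned
by exact 2-decimal agreement with all 19 rows of the packaged reference
cohort. Conventions chosen where the classic definitions leave room:

* Risk transform constants 1.509, 1.084, 5.381, factor 10, mg/dL input;
  the low/high split point falls at ≈ 112.4 mg/dL.
* GRADE works in mmol/L internally, caps each reading's contribution at
  50, and averages. Within the physiologic clamp the cap never binds
  (h(400 mg/dL) ≈ 35.5; the cap engages above ≈ 600 mg/dL).
* CONGA uses n = 1 h and the sample SD of grid-aligned differences.
* MAGE merges monotone runs (plateaus collapsed), takes interior turning
  points only — so partial first/last legs never count — and by default
  averages both ascending and descending qualifying excursions
  (`mage_direction: both|asc|desc`). On a sinusoid of amplitude A this
  recovers 2A.
* MODD is the complete-pair mean over all 24-h-apart grid pairs; ADRR
  requires a UTC calendar day to be ≥ 80 % complete to contribute.
* The M-value uses reference 120 mg/dL without the small-sample range
  correction (CGM windows are large).
* The lability index normalizes by the window length in weeks, counting
  hourly bins from first to last; only consecutive present hourly means
  contribute.
* SD-ROC is the sample SD of rates over consecutive present pairs at most
  15 minutes apart, reported per minute (configurable).
* TBR/TIR/TAR count threshold values as in-range (strict outer
  inequalities) and always sum to 100.

## Forecasting

Hyperparameter defaults per family: ARIMA order (7,1,0) fit by maximum
likelihood (in-sample residual mean/SD recorded as the adequacy
diagnostic); gradient boosting with learning rate 0.1, 100 estimators,
subsample 1, max depth 3; random forest with unlimited depth, 100
estimators, min samples split 2; LSTM with 1 lag, 15 epochs, batch size 1,
50 neurons on train-standardized inputs. Tree models see 7 lagged values
(mirroring the ARIMA order) as features; the construction is configurable.
The gradient-boosting backend is scikit-learn's (the hyperparameters map
1:1); `backend="xgboost"` selects xgboost when installed. The LSTM backend
(torch) is optional: without it the family raises `BackendUnavailable` and
the other three families cover the pipeline. An SVR family is recognised
but deliberately unsupported — its training cost grows worse than
quadratically with samples.

Two prediction modes are always labelled, never conflated. *Rolling*
one-step advances the model state with observed values (ARIMA by Kalman
filtering without refit; lag models by rebuilding features from actuals)
and is the default evaluation mode: only at one-step cadence are
single-digit MAE values over a 48-h window attainable. *Recursive*
multi-step feeds the model its own predictions for the full horizon.
Forecasts are clamped to [39, 400] mg/dL before GV analysis, whose risk
transforms need positive physiologic inputs. A persistence (last-value)
forecaster provides the noise-floor baseline: its one-step MAE equals the
mean absolute consecutive change of the test window.

Wall time and peak traced memory are recorded per fit for cost logging
only; nothing in the analysis depends on them.

## Error comparison

Relative error 100·|p − e|/|e| is undefined at e = 0 (flagged, not
infinite — zero TBR windows are common and desirable); both-zero counts
as 0. Proportional error max(|p|,|e|)/min(|p|,|e|) is symmetric, ≥ 1,
equal to 1 iff the magnitudes agree, and undefined for zero or
opposite-sign pairs. Cohort aggregation reports min/avg/max per metric,
excluding undefined entries and reporting the exclusion count. These two
definitions reproduce the observable structure of published error tables
(relative minima at 0, proportional minima at 1, TBR the least stable
metric); they are isolated behind two one-line functions so a different
convention is a local change.

## Problem sizes and determinism

The test suite and analysis scripts run at deliberately modest sizes: the
moment-recovery and stationarity checks use 30-day traces; forecaster
sanity checks use 7-day training and 12-h test windows over 5 seeds; the
cohort-scale analysis scripts use 32-day profiles (30 training days plus
the 48-h test window) and a 4-profile × 3-family forecasting run. One
global seed drives every random draw through named substreams, and
re-running any stage with the same config is byte-identical (manifest
resource logs excepted).

## Known limitations

* The synthetic generator matches first/second moments, skewness and
  lag-1 dependence, but real CGM traces carry meal/insulin structure,
  sensor artifacts and mild circadian rhythm it does not emulate; absolute
  forecast MAE on synthetic traces is therefore not comparable to values
  reported on real cohorts (synthetic one-step innovations are larger).
* Upstream cleaning conventions for real AID exports vary; the rules here
  (range, duplicate policy, 30-minute interpolation cap) are explicit,
  configurable stand-ins.
* Stationarity labelling at 30-day scale is inherently borderline for
  very persistent traces; expect a ~10 % difference-stationary rate on
  simulated profiles even though the generating process is stationary.
* The LSTM family is untested in environments without a torch backend
  beyond its error path.
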
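# Methods

This note documents the model, its operationalisation choices, the
synthetic data world, and the numerical decisions made where the design
was genuinely open.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signals and features

Input is one trader-day of wristband channels — blood volume pulse
(BVP, 64 Hz), electrodermal activity (EDA, 4 Hz, μS), skin temperature
(TEMP, 4 Hz, °C), heart rate (HR, 1 Hz, QC only), 3-axis acceleration
(32 Hz, parsed and passed through only) — plus the inter-beat-interval
(IBI) stream of beat times and RR intervals.  Eleven features are
evaluated on a 1 Hz grid, each over a *trailing* window `(t − w, t]` so
that no feature at `t` depends on later samples:

| feature | definition | window | units |
|---|---|---|---|
| mHR | 60 / mean(RR) | 300 s | beats/min |
| mRRi | mean RR | 300 s | ms |
| SDNN | sample SD (ddof 1) of RR | 300 s | ms |
| RMSSD | RMS of successive RR differences | 300 s | ms |
| mAmp | mean skin conductance | 300 s | μS |
| Slope | mean abs. first difference × rate | 300 s | μS/s |
| Events | count of SCR detections | 300 s | — |
| BVPmeanAbs / BVPmin / BVPmax | mean abs / min / max of BVP | 300 s | device |
| TEMPslope | trailing least-squares slope | 60 s | °C/s |

Decisions taken where the operational definition was open:

* The 5-minute window is stated for the HRV family; the EDA and BVP
  windows are not stated and default to the same 300 s for
  homogeneity (configurable via `FeatureConfig`).
* "Instantaneous rate of change" of TEMP is operationalised as the
  least-squares slope over a trailing 60 s window — long enough to
  suppress 4 Hz quantisation noise, short against episode time scales.
* Slope is rate-normalised (μS/s, not μS/sample) so the feature is
  invariant to the device's sampling rate.
* mHR/mRRi/SDNN/RMSSD all come from the IBI stream (single source of
  truth); the device HR channel is retained only for quality control.
  RMSSD uses only *successive* beat pairs — a pair whose time gap
  exceeds its recorded RR implies dropped beats and is excluded.
* A skin-conductance response (SCR) is a maximal strictly-rising run
  of the EDA signal containing a sub-segment shorter than 5 s that
  rises by more than 0.05 μS.  One rising run counts as at most one
  event regardless of how many sub-segments qualify; this prevents a
  single long rise from being counted many times.
* Missing samples are NaN; a feature row is valid only when every
  feature is computable and every family's window lies fully inside
  the session.  No imputation is performed.  HRV features need ≥ 2
  beats in the window, RMSSD ≥ 3.

## Activation

Activation is the squared Mahalanobis distance

    d_M(y_t) = (y_t − μ_t)' Σ_t^{−1} (y_t − μ_t)

where μ_t and Σ_t are the sample mean and covariance (ddof 1) of the
valid feature rows from the start of the day through `t` *inclusive*.
The expanding ("from the day's start") reading of the baseline follows
the definition's y_1 … y_t enumeration; a fixed-width alternative
would re-adapt to sustained shifts and was not adopted.  The quadratic
(not square-rooted) form is kept exactly as defined.  Under a
stationary Gaussian baseline with oracle moments, d_M ~ χ²_d (d = 11
for the overall score; per-family scores use the 4 HRV, 3 EDA, 3 BVP,
or 1 TEMP columns).

Numerical choices:

* **Burn-in.**  A row is scored only after ≥ 300 s of history *and*
  ≥ 5·d valid rows (and > d rows so Σ_t can have full rank).  The
  integer SCR-count column is frequently constant early in a day, so
  early covariances are ill-conditioned.
* **Ridge.**  Σ_t is inverted as Σ_t + ε·mean(diag Σ_t)·I with
  ε = 1e-6 — scale-free, and vanishing relative to the data.  An
  exactly-zero residual scores 0 even when Σ_t is singular.
* **Implementation.**  Scores are computed with globally centred
  prefix sums and one batched linear solve; the suite verifies
  agreement with per-row brute-force recomputation to ≤ 1e-8 and
  χ²_11 calibration (mean and 95th-percentile exceedance) at
  n = 20 000.

Day statistics μ, σ (ddof 1) of d_M are taken over all valid scored
samples of the day, *including* activated periods; thresholding is
therefore in-sample, which slightly inflates thresholds on heavy days.
Mild/extreme labels are d_M > μ + 1.5σ / μ + 3σ; episodes are maximal
contiguous supra-threshold runs of valid 1 Hz samples, broken by
invalid samples and not gap-merged.  The mild proportion counts every
sample above the mild threshold (inclusive of extreme samples) since
the band convention was not stated; activation length averages over
mild episodes (pooling levels would double-count, as every extreme run
lies inside a mild run).

## Granger causality

The 1 Hz activation series is averaged within calendar minutes
(floor(epoch/60); partial boundary minutes and minutes without valid
samples are dropped), intersected with the market series' minutes, and
both are first-differenced (consecutive minutes only).  The null
"market changes do not Granger-cause activation changes" is tested
with the SSR χ² statistic, n_eff·(SSR_r − SSR_u)/SSR_u with
df = lag order, restricted model = own lags 1..p plus constant,
unrestricted adding the market's lags.  The "lag of 10 minutes" is
read as a fixed lag order p = 10, not a search over 1..10.  Tests for
one index across all trader-days form the Holm-Bonferroni family at
α = 0.05; days are pooled across traders (whether the original
analysis pooled a trader's days is unknowable; per-trader pooling is a
caller-side regrouping of the returned per-test records).  Per-index
one-sample Kolmogorov–Smirnov statistics against Uniform[0,1] (p-value
from the asymptotic Kolmogorov distribution of √n·D) diagnose global
departures from the null.  The implementation is independent of
statsmodels; the suite checks exact agreement with
`grangercausalitytests`' `ssr_chi2test` and `multipletests('holm')`,
and verifies empirical size ∈ [0.03, 0.08] and power ≥ 0.8 against a
planted lag-3 coupling with the roles reversed falling back to size.

## Attribution regression

Average daily activation is regressed by OLS on: business division
(one-hot, first alphabetical level dropped), gender (binary code,
second alphabetical level = 1), mean transaction dollar volume of the
day (untransformed; `log_amount` applies log1p), trading experience
(years), transaction count, and the per-index daily market volatility
(SD of minute first differences, ddof 1).  Zero-trade days keep
amt = 0 rather than being dropped, preserving the panel.  Classical
(homoskedastic) standard errors by default; cluster-by-trader errors
are available since trader-days repeat within traders.  The gender
effect is reported as the coded-variable coefficient (equivalently the
male−female contrast).

An identifiability caveat discovered in testing: market volatility
varies only across days, so with D distinct trading days shared by the
whole cohort, at most D − 1 volatility columns are identifiable beside
the intercept.  (In a field deployment where traders are measured in
different calendar weeks this is not binding; in a single-week
synthetic cohort it is.)  `fit_attribution` fails loudly on
rank-deficient designs, naming the collinear columns.

## Event study

z-scored activation (per trader-day, using that day's μ, σ) is averaged
in twelve half-open 5-minute windows [−30, −25), …, [+25, +30) minutes
around each transaction — half-open so the bins partition [−30, +30).
Transactions whose ±30-minute neighbourhood is not fully covered with
valid samples are skipped; transactions less than an hour apart are
both included (no exclusion rule was stated).  Averaging is two-level
and unweighted: over a trader-day's transactions, then across
trader-days.  The 95% band is mean ± 1.96·sd/√n across trader-day
profiles (the dispersion unit was not stated; trader-days match the
averaging unit); a seeded bootstrap over trader-days is available.

## Synthetic data

The generator's role is to validate the *analysis*, not to be
physiologically realistic.  Defaults state the cohort's world once:
55 traders × 5 days × 6.5 h sessions; heart period AR(1) (mean 0.85 s,
sd 0.05 s, φ = 0.95 at beat scale); SCRs from a Poisson process
(2/min) with uniform 0.1–0.5 μS amplitudes, 2 s rise, 40 s exponential
decay over a slow tonic drift; BVP as a unit oscillation at the
instantaneous heart rate with slow multiplicative amplitude noise;
TEMP as a random walk (0.002 °C/√s); small Gaussian accelerometer
noise.  Where no value was stated we fixed field-plausible ones:
resting heart period/SD from normal adult HRV ranges, SCR rate and
kinetics from standard electrodermal practice, transaction rate 8/day
with log-normal amounts (median $1M), experience uniform on 1–25 y
(the study's stated range).

Planted episodes scale all four families at once (heart period −10%,
its variability −30%, SCR rate ×4, BVP amplitude ×1.5, TEMP slope
+0.003 °C/s; 30 s ramps), so overall-d_M detection is well-posed.
Market coupling injects a trader-day's minute-level driver into an
index's increments `lag` minutes earlier, making the market lead
activation in the tested direction.  Transaction bumps add episodes at
+15..+25 min (and half-magnitude at −5..0 min).  Covariate effects
(default: −0.02 per experience year) modulate episode magnitude
multiplicatively; this controls mean activation only approximately, so
regression recovery is tested on datasets synthesized directly from
the linear model (`synthesize_attribution_dataset`, with amounts in
millions of USD so regressor scales are comparable) rather than
through full physiology.  Every draw descends from the master seed via
`SeedSequence([seed, trader, day, stream])`, so cohorts are
reproducible under partial regeneration, and dropout removes an exact
quota round(rate·n) of trader-days (12% of 275 leaves 242).

What a green test does *not* establish: realism of circadian drift,
posture and motion artifacts, beat-detection error, order-book
microstructure, or the magnitude of real-world effect sizes.  Episode
recovery is assessed against the planted interval extended by the
300 s feature window, since trailing windows smear any physiological
change forward by up to one window length.

## Known limitations

* The expanding baseline adapts slowly after long activated stretches;
  days dominated by episodes bias μ_t, Σ_t upward and thresholds with
  them.
* Episode labelling is in-sample by construction (day statistics
  include the labelled periods).
* The event study's confidence band treats trader-day profiles as
  i.i.d.; overlapping transactions induce dependence between windows.
* No accelerometer-based artifact rejection: motion contaminates BVP
  and EDA features in real recordings.
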
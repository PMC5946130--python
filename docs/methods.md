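# Methods

## The measurement problem

A nest-gas probe feeding a cavity ring-down analyser yields a 1-Hz record of
CH₄ (ppm) and δ¹³C-CH₄ (‰ vs VPDB) from inside an ant mound, alongside
ambient-air checks, reference-gas runs, a camera pointed at the mound, a
weather station, and public earthquake catalogs. The scientific questions —
does the nest emit methane, from which source(s), and is degassing coupled
to biology or geophysics — reduce to: robust anomaly detection on two noisy
series, isotope mixing analysis on the anomalies, and association tests
against exogenous drivers.

## Two-reservoir mixing and the Keeling intercept

Nest gas is modelled as an atmospheric reservoir (concentration C_a,
signature δ_a) plus admixed source methane with excess concentration
C_e(t) ≥ 0 and fixed signature δ_s. Mass conservation of ¹²C and ¹³C gives

    C_obs = C_a + C_e
    δ_obs = (C_a δ_a + C_e δ_s) / C_obs
          = δ_s + C_a (δ_a − δ_s) · (1 / C_obs)

so noiseless mixing points are exactly linear in 1/C_obs and the intercept
at 1/C → 0 is δ_s. `keeling_fit` is OLS of δ on 1/C with the intercept CI
from the usual t-based standard error (n − 2 df). With several simultaneous
sources the observed δ is the excess-weighted mean of their signatures;
episodically separated sources (the campaign situation) are resolved per
peak window and grouped by 1-D two-means on the intercepts.

Assumptions: constant background during a window; source signature constant
within an event; measurement noise additive and symmetric. The regression
treats 1/C as fixed; concentration noise (0.005 ppm against a ≥0.2 ppm
signal range) makes errors-in-variables attenuation negligible here.

## Anomaly rules and coincidence

- CH₄ threshold: median + k·MAD of the whole channel, raw MAD (no 1.4826
  consistency factor), k = 2, strict `>` membership. `mad_threshold(...,
  scale=1.4826)` gives the scaled convention.
- δ¹³C: two rules ship. The *literal* fixed bounds (< −35‰ or > 0‰) are kept
  for fidelity to the published description, but a biogenic nest record can
  sit entirely below −35‰, in which case the literal rule flags everything
  and selects no episodes; the *deviation* rule |δ − median| > k·MAD is the
  pipeline default.
- Coincidence: true peaks are maximal runs flagged in both records at the
  same timestamps (optional dilation by `tolerance` seconds). Runs closer
  than `min_gap = 60 s` merge. A window survives only with ≥ `min_samples
  = 10` coincident samples of which ≥ `min_run = 5` are consecutive.

The consecutive-run requirement is the load-bearing guard: under the
deviation rule at k = 2 on pure noise, single samples exceed both
thresholds with probability ≈ 0.089 × 0.177 ≈ 1.6% — roughly 1,400 chance
coincidences per day at 1 Hz — but these are serially independent, so runs
of 5 have expected count ~10⁻⁴ per day, while genuine emission episodes
produce unbroken runs of hundreds. This makes the no-source false-positive
rate effectively zero at any record length without touching the k = 2
sensitivity.

## Which samples enter a Keeling fit

`keeling_per_window` defaults to fitting **all** samples inside a detected
window span, the standard Keeling-plot practice for an identified emission
episode. Restricting to only the threshold-exceeding samples
(`samples="flagged"`) conditions the δ noise on exceeding the deviation
threshold and tilts the line by ~1–1.5‰ on the shipped scenarios; the
window-span fit is unbiased (the window *boundaries* are data-dependent,
but interior samples enter unconditionally). Both options are exposed;
summary scripts that quote "intercept over flagged samples" use the flagged
variant and inherit that small, documented tilt.

## Activity estimation

Registration is an exhaustive integer-translation search (default ±5 px)
maximising mutual information (default 64 histogram bins, log₂ units), ties
broken by smaller shift norm then lexicographically — a minimal sufficient
model for wind-induced camera sway; no rotation or scale. The SAD statistic
sums |difference| inside the mound mask over the registered overlap; pixels
lost to the shift are excluded, making the statistic invariant to joint
translation of both frames. Calibration to manual activity categories
(non-negative reals, by convention 0–25) is least-squares polynomial on
centred/scaled SAD, degree 1 (day sensor) and 3 (night sensor); centring
constants are stored in the model. Activity is aggregated to 5-min medians
before any downstream statistic. Frames with missing timestamps are dropped
and logged, never interpolated.

## Environmental statistics

- **Weather PCA**: correlation-matrix PCA (centre, scale, SVD); loadings
  unit-norm with deterministic sign (largest-|loading| entry positive);
  constant columns are a named error.
- **PC regression**: OLS of the 5-min-median response on PC-1..PC-3 with
  sequential (type-I) sums of squares via statsmodels `anova_lm`. With
  complete alignment the PCs are orthogonal and term order is immaterial;
  rows with any missing value are dropped and counted.
- **Decomposition**: additive observed = trend + seasonal + residual.
  Trend by centred moving average (statsmodels, edge-extrapolated) or by a
  time polynomial (default degree 6, standardised time for conditioning);
  seasonal = centred period-position means of the detrended series;
  residual = exact remainder, so the identity holds everywhere.
- **Cross-correlation**: r(ℓ) = corr(x_t, y_{t+ℓ}) with overlap
  cross-products normalised by the full-series n, mean and SD — the
  standard sample CCF, bounded by 1 via Cauchy–Schwarz. Convention: a
  series y trailing x by k samples peaks at ℓ = +k. Note the estimator's
  (n−|ℓ|)/n attenuation: for very smooth signals neighbouring lags can
  differ by less than the attenuation step, so lag extrema are sharp only
  for signals that decorrelate within a few bins.
- **Epicenter KDE**: scipy Gaussian KDE with Silverman bandwidth, evaluated
  on a grid padded by 4 bandwidths (integral 1 within ~10⁻³ without
  renormalising). A numerically singular sample covariance (collinear
  epicenters) falls back to an independent per-axis product kernel with a
  warning rather than scipy's degenerate pseudo-inverse surface.
- **Tides**: displacement(t) = Σ Aᵢ cos(2π t/Tᵢ + φᵢ) with default
  constituents M2 (12.4206 h, 120 mm), S2 (12.0 h, 56 mm), K1 (23.9345 h,
  80 mm), O1 (25.8193 h, 57 mm), phases 0. This equilibrium-style harmonic
  model supplies correct tidal phase structure for correlation tests; it is
  **not** a lunisolar ephemeris with Love numbers and has no absolute
  geodetic accuracy. Only relative amplitudes and periods matter downstream.

## Synthetic campaigns: what they emulate, and what not

Preset conditions (all derived from the monitored system's published
operating envelope): 8 days at 1 Hz; background 1.82 ppm CH₄; background
δ¹³C −47‰ (a conventional modern-atmosphere value — the campaign never
measured ambient δ¹³C, so it is configurable and nothing downstream depends
on it); noise SDs 0.005 ppm and 0.8‰ (instrument-level precision);
ambient air 15 min every 4 h; reference gas 5 min every 8 h; eight
Gaussian-shaped injection events of 1 h duration, peak excesses
0.45–1.05 ppm, scheduled one per night inside the 17:39–06:54 UTC window;
weather at 5-min intervals with mean temperature 16.2 °C and a 8 °C diurnal
sine; humidity anti-correlated with temperature; sparse exponential
rainfall; one micro-earthquake (M 0.8, 3 km depth, 20 km away). The
`null-default` scenario is a 1-day no-source record: false-window
probability only grows with length, so one day is the conservative
desk-scale choice for false-positive calibration. All streams draw from
per-stream substreams of one seed; identical configs are bit-identical.

Deliberately not emulated: instrument drift nonlinearity (only linear drift,
for exercising the piecewise-linear reference correction), water-vapour or
CO₂ interference, diurnal background CH₄ cycles, correlated (red) noise,
weather-coupled emission, ant-activity coupling to gas. Passing tests
therefore demonstrate correctness of the estimators under the stated noise
model, not robustness to every field pathology — in particular, real
records with autocorrelated baselines will need the drift correction and
possibly a larger `min_run`.

Frame sequences: static smoothly-textured background, elliptical mound
mask, 3×3 bright blobs random-walking inside the mask, global integer
jitter ≤ `jitter_px` applied with wrap-around, day/night sensor flag from
hour-of-day. Ground truth returned per frame: applied jitter and the count
of jitter-free changed pixels.

## Numerical choices

- Quantiles: linear interpolation (type 7, numpy default); percentile-split
  membership is strict `>`.
- Registration tie-break: smallest ‖(dx,dy)‖², then lexicographic; shifts
  with empty overlap skipped.
- MI joint histograms bin over each image's own range; degenerate
  (constant) images have zero entropy and MI 0.
- Polynomial fits use numpy's polynomial module (ascending coefficients);
  calibration requires ≥ degree+1 distinct raw values and nonzero variance.
- CH₄ values below a configurable floor (default 10⁻³ ppm) after noise are
  clipped and logged.
- Two-means on intercepts uses deterministic extreme-point initialisation,
  so cluster labels are reproducible.
- Drift correction excludes reference runs whose offset exceeds 0.5 ppm /
  10‰ (implausible for a healthy analyser) with a warning.

## Campaign pipeline and archive dialect

`run_campaign` composes the stages from one `CampaignConfig` (scenario name
or file paths + thresholds + aggregation + seed) and writes `report.json`
with CSV sidecars; any stage failure is re-raised with the stage name. All
randomness flows from the single seed; re-running an identical config
reproduces the same numbers and a matching config digest.

`read_hf305` expects three CSV schemas: gas `datetime, ch4.ppm,
d13c.permil, channel`; weather `datetime, airt, pressure, dewp, rh, rain,
wspd`; activity `datetime, activity`. This fixture dialect is documented
here precisely because the archived campaign layout must be confirmed
against the archive itself; the reader errors loudly, listing the expected
schema, on anything else.

## Problem sizes

Tests and the acceptance script run the full 8-day, 1-Hz scenarios
(~0.7 M gas samples, seconds per run), 200 frame-pair registrations at
48×48 px, 100 seeded 1-day null campaigns, and 50-instance brute-force
oracle batteries — the whole suite completes in well under a minute on one
CPU.

## Known limitations

- The harmonic tide model has arbitrary phase origin; only lag *structure*
  against gas series is meaningful, not absolute tidal phase.
- The literal δ¹³C rule and the deviation rule can disagree wholesale on
  records lying entirely below −35‰; the package takes no position on which
  matches the original field analysis (both are exposed).
- Keeling fits assume a single source per window; overlapping events with
  different signatures yield an excess-weighted intermediate intercept.
- `cluster_intercepts` with k = 2 will happily split a single-source
  intercept cloud into two nearby centers; interpret cluster separation
  against the fits' CI widths.
- Registration is integer-translation only; sub-pixel sway and rotation
  alias into the SAD statistic (absorbed by calibration in practice).
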
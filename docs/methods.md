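# Methods

This note records the models implemented, the parameter choices that
matter, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Data model

Series are strictly uniform (relative spacing tolerance 1e-9) and gap-free;
irregular sampling or missing values are hard errors rather than silently
interpolated, because both detectors (lagged autocorrelation, sampled-
wavelet convolution) assume a constant sampling interval. Hourly series use
t = 0 at the start of the capacitating incubation; monthly series use a
month index 1..36 with index 1 = the first January and samples nominally
taken mid-month. Replicate panels carry mean ± SEM (sd/√n, ddof = 1).

Negative net percentages (treated − control) are preserved and flagged, not
clamped: clamping would bias time-course means upward. The third-quartile
exceedance gate uses the type-7 (linear interpolation) quantile — the
default of numpy, R and pandas, stated explicitly so ports agree — and a
strict inequality, so ties at the quartile do not count as exceeding it.

## Autocorrelation branch (ultradian and infradian)

* Estimator: biased (1/n) normalization with the global mean. It guarantees
  C(0) = 1 and |C(s)| ≤ 1 and matches the common default of statistics
  packages; a property test pins it to a double-loop reference to 1e-12,
  and another checks the known small-sample bias E[C(s)] ≈ −1/n for iid
  noise.
* max_lag defaults to ⌊n/2⌋ (12 lags for the 24-h design, 18 for 36
  months); the estimator is unreliable beyond half the series.
* Significance band ±2/√n (multiplier configurable). The band is the
  standard large-sample white-noise approximation; no source value exists
  for these data, so the classification rule below is this package's
  operationalization of "periodic vs random curve shape".
* Classification: *periodic* requires a local maximum of C above the +band
  preceded by some lag below the −band (the negative-then-positive
  alternation a cycle produces); *short-range stochastic* requires the
  coefficients to reach the band at some lag without that alternation;
  anything else (e.g. an undecayed trend) is *unclassified*. Plateau local
  maxima count at their left edge; the final lag counts as a maximum when
  the curve rises into it.
* Period = first significant local maximum, in whole sampling intervals (no
  sub-lag interpolation; the phenomena of interest have integer periods in
  the sampling unit).
* Detrending (ordinary least-squares line, residual mean 0) is on by
  default before the ACF: the indicators drift upward along incubation
  while the rhythm lives in the fluctuations. On 24 points a least-squares
  line absorbs a small fraction of a 2-h alternation (~0.12 of unit
  amplitude), which does not move the peak lag.

## Wavelet branch (infradian)

* Transform: W(a, b) = a^(−1/2) Σ_t x(t) ψ*((t−b)/a) Δt by direct
  convolution with the sampled mother wavelet, zero padding beyond the
  series. A property test pins the implementation to a brute-force direct
  sum at 1e-10. The sampled kernel is truncated at |t/a| ≤ 8 (envelope
  < e^−64).
* Mother wavelets: cmor with the standard (π·fb)^(−1/2) prefactor — the
  MATLAB/PyWavelets convention, L² norm 1/√(2π·fb), frozen in a test — and
  cgau of order m, the m-th derivative of e^(−it)·e^(−t²) rescaled to unit
  L² norm (polynomial recursion, quadrature normalization).
* Center frequencies: cmor1-1.5 has fc = 1.5 by definition; cgau's fc is
  the peak of its Fourier magnitude, located by FFT with parabolic
  refinement (cgau1: 0.3183 ≈ 1/π, matching the analytic argmax |ω| = 2 of
  |ω|·e^(−(ω+1)²/4)). period = a·Δt/fc throughout; the published monthly
  endpoints (scale 30 ↔ 20 months, 0.3 ↔ 0.2 months) hold exactly.
* Scale grid: 60 logarithmically spaced scales over [0.3, 30] (relative
  step < 6 %), giving uniform relative period resolution over 0.2–20
  months.
* Cone of influence: positions nearer an edge than the power e-folding
  distance a·√(fb/2) (≈ 0.707·a for fb = 1) are flagged. At the annual
  scale (a = 18) this leaves an 11-point clean interior on a 36-month
  series; scales whose cone swallows the whole series are skipped by the
  dominant-period search.
* Dominant period: argmax over scales of time-averaged |W|² outside the
  cone. Optional parabolic refinement (log power vs log scale, clipped to
  one grid step) removes grid quantization: the default grid has no point
  at exactly 12 months (neighbours 11.58/12.52), and the refined estimate
  of the ARi-like preset is 12.02 ± 0.07 months across seeds.
* Known small-scale caveat: for scales below ≈ 2·fc the sampled wavelet no
  longer resolves its own oscillation, and the discretized transform keeps
  a spurious DC response (a constant series yields |W| ≈ 0.6 at a = 2 but
  < 1e-6 at a ≥ 4). Detrending before the transform — the pipeline default
  — removes the offending mean; dominant-period searches on raw series
  should treat sub-resolution scales with suspicion.

## Synchrony

Re(W) of both series at the grid scale nearest the target period,
Spearman-correlated (average ranks on ties) over the overlap for every
integer offset d in [−max_offset, +max_offset]; ρ² is reported per offset
with the signed ρ kept alongside. Offset sign: d correlates a(t) with
b(t+d), so a positive best offset means the *first* series leads. Overlap
shrinks with |d| (no wraparound); fewer than 5 overlapping points is an
error. Cone masking is on by default; on a 36-point series this leaves
~11 clean points at the annual scale, so masked offset estimates are coarse
(±1 month) while unmasked scans use all 36 positions and recover noise-free
integer shifts exactly.

Periodic pairs also align in anti-phase (ρ → −1) half a period from the
true lag, and on edge-affected finite series that alias can outscore the
true offset. Because the scan estimates the lead/lag of a *shared* rhythm,
offsets with positive correlation take precedence; the anti-phase fallback
applies only when no positively correlated offset exists.

## Pipeline

analyze_rhythm chains detrend → ACF → classification, plus (infradian) the
cmor1-1.5 CWT as an independent cross-check: the verdict is "rhythmic with
period P" only when the ACF is periodic and, where the wavelet ran, the two
periods agree within 25 % relative; disagreement produces "aperiodic" with
an explanatory note instead of a silent preference. The ACF supplies the
reported period (the ultradian claim is ACF-based; the wavelet is the
seasonal cross-check). All thresholds (band multiplier, agreement
tolerance, wavelet and grid) live in a YAML-loadable config that rejects
unknown keys.

Peak-vs-valley comparison: extremal regions are located on the series
smoothed with a centered moving average of window round(period/2) (forced
odd), computed where the full window fits, with the smoothable-range
boundaries counting as candidate regions when the curve runs monotonically
into them (a seasonal peak sitting at the series edge). Regions must rise
or fall by ≥ 10 % of the smoothed range — noise micro-wiggles on flat
seasonal tops are not extrema — and each region is refined to the raw
extremum within half a window. Group means ± SEM are taken over the raw
values; the p-value is a two-sided Welch t-test (small unequal groups; the
two-group specialization of the usual ANOVA workflow). On the noise-free
seasonal construction (mean 29, amplitude 17, period 12) this returns
exactly 46 vs 12.

## Synthetic generators

The generators define the study conditions the detectors are validated
against; all randomness flows from a single integer seed through
numpy's Generator, and percentages are clipped to [0, 100] after noise.

* Hourly (24 points): x(t) = trend_max·t/(t+halftime) + osc + ε. The
  saturating (hyperbolic) trend mirrors plateauing indicator rises; the
  plateau values (Chex 15 %, halftime 6 h; ARi 30 %, halftime 8 h) are
  free calibration choices of realistic magnitude, not source claims.
  The Chex preset carries a 2-h, 3 %-amplitude oscillation with phase
  0.5 h — integer-hour sampling then hits the oscillation extremes (a 2-h
  sinusoid with zero phase vanishes identically on an hourly grid) — plus
  iid Gaussian noise (sd 1.5 %). The ARi preset has no oscillation and
  AR(1) noise (φ = 0.5, marginal sd 2 %): the short-range-correlated
  contrast the classifier must separate from genuine periodicity.
* Monthly (36 points): ARi = 29 + 17·cos(2π(m−11)/12) — November peak
  (southern-hemisphere spring), noise-free peak/valley exactly 46/12 —
  and Chex = 8.5 + 3.5·cos(2π(m−4)/6) — April and October peaks, levels
  exactly 12/5; an optional 12-month admixture for Chex exists behind a
  config field (amp 0 by default, keeping the pure 6-month reading of its
  rhythm). Monthly noise is iid per month with per-indicator sd (ARi
  2.5 %, Chex 1.2 %), scaled so peak/valley SEMs sit in the range of the
  reported ones (ARi ±3–6, Chex ±1–2); a single shared sd would
  over-noise the small-amplitude Chex component. Temperature is
  18 + 7·cos(2π(m−1.5)/12) °C (subtropical-site magnitudes, mid-January
  peak) with 1 °C noise; photoperiod is deterministic solar geometry
  (δ = −23.44°·cos(2π(day+10)/365.25), day length =
  (24/π)·arccos(−tan φ·tan δ)) at latitude −31.82°, sampled at mid-month
  days of a 365-day calendar (leap days ignored — a < 0.3 % day-length
  effect). Polar latitudes are rejected rather than clamped.
* Null models: white noise and stationary AR(1) (|φ| < 1 enforced,
  marginal-sd parameterization) for false-positive studies.

What the generators deliberately do not model: donor-to-donor variance
components (replicate noise is single-level iid), measurement rounding,
missing months, non-sinusoidal seasonal shapes, and any mechanistic link
between the meteorological series and the indicators (their phases are
set, not caused). Passing recovery tests therefore show the detectors work
under the stated statistical structure, not that real semen data satisfy
that structure.

## Default problem sizes

Recovery and power properties run at the study's natural sizes (24 hourly
points, 36 monthly points) over 100–200 seeds; oracle-equivalence
properties use 100 random series of length ≤ 48. The full suite completes
in a few seconds on one CPU.

## Known limitations

* ACF period resolution is one sampling interval; periods off the grid
  (e.g. 2.5 h sampled hourly) alias to neighbouring integer lags.
* The ±2/√n band is a large-sample approximation; at n = 24 it is wide
  (0.41), so weak rhythms classify as stochastic (conservative).
* Masked synchrony on 36 points rests on ~11 effective positions at the
  annual scale; wavelet smoothing leaves few effective degrees of freedom
  there, so independent series can show sizeable spurious ρ² (median ≈ 0.47
  masked vs 0.27 unmasked at offset 0). Lead/lag readings finer than
  ±1 month should not be over-interpreted at this series length.
* No red-noise significance testing of wavelet power and no wavelet
  coherence spectra; the dominant-period search assumes one rhythm
  dominates the analyzed band.
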
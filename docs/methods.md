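# Methods

This note records the models, conventions and numerical choices behind
`hrvperiod`, in the order the data flows through the package.

## Signal model and containers

An RR-interval series is a pair (beat times in s, intervals in ms) with
strictly increasing times and positive intervals. Validation is
one-sided: an interval may be *shorter* than the elapsed time since the
previous retained beat (artifact exclusion removes beats and leaves
gaps — excluded intervals are never interpolated), but can never exceed
it by more than 0.5 ms. Raw ECG and simulated oscillator outputs are
uniformly sampled traces with an explicit sampling rate.

## ECG preprocessing

- **Baseline removal**: zero-phase (forward–backward) 2nd-order
  Butterworth high-pass, default cutoff 0.5 Hz. Zero-phase filtering
  preserves R-peak timing; the reflect padding is stretched to
  3·fs/cutoff samples because the default padding leaves a visible edge
  transient at sub-hertz cutoffs. Edge samples within roughly one cutoff
  period of the record ends remain less trustworthy.
- **R-peak detection**: 5–40 Hz band-pass emphasis, squaring, adaptive
  threshold of 8× the 2-s rolling median of the squared amplitude with a
  global floor of 0.15× its 99th percentile (the floor stops noise from
  crossing threshold in stretches that contain no beats at all), then
  refinement to the raw-trace local maximum within ±20 ms and a 50 ms
  refractory period. 50 ms is safely below any physiologic rat RR
  interval (~130–200 ms); every constant is an argument.
- **RR extraction**: intervals outside configurable bounds (default
  80–400 ms) or beyond mean ± 4 SD of the in-bounds intervals are
  excluded, never interpolated, and the exclusion count is logged.
  Retained values are exactly the successive peak-time differences.
- **Epoching**: contiguous fixed-length windows by wall-clock time
  (default 150 s = 2.5 min), each labeled by the experimental period
  containing its midpoint; a trailing partial epoch is dropped and
  logged.

## Conventional HRV battery

Time domain (SDNN with the n−1 denominator, RMSSD, triangular index with
the conventional 1/128 s bin — derived for human RR histograms and kept
only for comparability; it is configurable and coarse for rodent RR
ranges), Lomb–Scargle band powers (LF 0.1–1 Hz and HF 1–3.5 Hz, rodent
conventions, each relative to the integrated 0.1–3.5 Hz total so that
LF + HF = 1 up to leakage), Poincaré SDs, DFA, and sample entropy
(m = 2, r = 0.2·SDNN).

Conventions worth making explicit:

- **Poincaré SD1** is the RMS of successive differences over √2 with *no*
  mean subtraction, making SD1 = RMSSD/√2 an exact identity rather than
  an approximation; SD2 is the sample SD of successive sums over √2.
- **DFA** integrates the mean-centered series, removes a per-box linear
  fit, and regresses log F(s) on log s over boxes of 4–16 beats (α1) and
  16–64 beats (α2) — the conventional short/long split.
- **Sample entropy** uses the Richman–Moorman convention: both template
  lengths are counted over the same N − m·τ starting points, so a fully
  regular series gives A = B and entropy exactly 0. The statistic is then
  reversal-invariant only up to O(1/N) boundary terms. An undefined
  entropy (no template matches) is reported as missing, never as
  infinity.

## Periodicity measures

- **Spectra** are classical Lomb–Scargle periodograms of the
  mean-centered values, evaluated at the series' own beat times (no
  resampling onto a uniform grid). The frequency grid spans the
  periodicity band (default 0.3–2 Hz) with spacing 1/(4·duration);
  4-fold oversampling stabilizes the peak location that maxPER reads off.
- **Relative spectrum**: frequencies below the band are excluded *before*
  normalization, and the denominator is the in-band total. That makes the
  relative power a probability distribution over the band, so the
  entropy argument behind tRSE holds exactly (uniform spectrum → every
  20-bin mass P(i) = 1/M → tRSE = 0). A config switch selects
  full-spectrum normalization for sensitivity analysis. Empty bins
  contribute 0 via the continuity limit 0·ln 0 := 0.
- **Detrending** for the ACF route: greedy binary segmentation over a
  piecewise-linear model. A split is accepted when it lowers the residual
  sum of squares by more than a BIC-like penalty of 3·log(N)·σ̂², with σ̂²
  estimated robustly as var(diff(x))/2; minimum segment length 30 beats.
  Slow drifts in the RR baseline would otherwise masquerade as
  long-range correlation in the ACF.
- **Autocorrelation** uses the 1/(N−d) normalization with population-SD
  standardization so R(0) = 1 exactly. Lags run to min(N/2, 200): the
  scoring window d = 25–50 (endpoints inclusive) needs 50, and 200 lags
  hold several oscillation periods at rodent heart rates while keeping
  the 1/(N−d) inflation at large lags negligible inside the window.
- **SE.ACF embedding selection.** The delay τ is the first local minimum
  of the histogram mutual information between R(d) and R(d+τ); the
  8-bin histogram is deliberately coarse because autocorrelograms are
  short (~200 lags) and finer binning saturates the MI estimate,
  flattening the minimum. If the MI has no interior minimum, τ falls
  back to 1 (logged). The pattern length m is the smallest dimension at
  which the false-nearest-neighbour fraction (distance-ratio criterion,
  ratio 10) drops below 5%, scanned from m = 2: one delay coordinate can
  never unfold an oscillation, and sampled periodic ACFs contain exact
  duplicates that blind the ratio test in one dimension. Distances at
  round-off scale are treated as duplicates, not neighbours. Tolerance
  r = 0.4 × the population SD of the ACF values.

## The synthetic benchmark

`simulate_vdp` integrates x'' = (1 − x²)x' − (ω + C·z)x with ω = 40
(small-oscillation frequency √40/2π ≈ 1.007 Hz, inside the 0.3–2 Hz
band) over t = 0–99.8 s with output every 0.2 s (500 samples at 5 Hz).
The noise z ~ N(0,1) is redrawn once per 0.2 s output step and held
constant over that interval — a plain Runge–Kutta scheme on a
stochastically forced system is only well defined with piecewise-constant
forcing. Within each interval the state is advanced by 20 internal
classical RK4 substeps: at large C, negative-stiffness excursions
(ω + C·z < 0) transiently push the state off the limit cycle into the
regime where the cubic damping is stiff, and a single 0.2 s RK4 step is
unstable there even though the exact flow stays bounded (|x| ≲ 8 at
C = 40). The initial state (2, 0) lies on the noise-free limit cycle, so
no burn-in is discarded. Overflow (|x| > 1e6) raises an integration
error naming the step.

The ensemble covers 21 noise levels spanning C = 0–40 (spacing 2) with
20 realizations each. Each cell (i, k) receives its own child generator
derived from the master seed by a counter scheme, so any single cell is
reproducible in isolation and the ensemble is bitwise reproducible.

**What the generator does and does not emulate.** The oscillator ladder
reproduces one property of real RR series — adjustable spectral
bandwidth around a ~1 Hz rhythm — and nothing else: no autonomic
baroreflex dynamics, no respiratory sinus arrhythmia waveform, no
nonstationary ventilator coupling, no beat-detection noise. The CMV-like
(single sinusoidal modulation line) and BVV-like (equal-power
band-limited modulation, a sum of 50 random-frequency sinusoids over
0.5–1.5 Hz) RR fixtures add the beat-time sampling structure of real RR
data. Passing tests on these fixtures therefore demonstrate that the
measures separate narrowband from broadband heart-rate modulation at
matched power, not that they recover any particular physiology.

## Degree of monotonicity

For a measure matrix S (r levels × k realizations), every pair i < j is
compared by a two-sided Wilcoxon rank-sum test (exact null distribution
up to n = 25 per group, normal approximation beyond; exact is what the
k = 20 protocol uses). h(i,j) is +1/−1 when the test rejects, signed by
which row is stochastically larger, else 0; identical constant rows are
degenerate and score 0 (logged). M = |2/(r(r−1)) Σ h| is rank-based,
hence invariant under strictly monotone transforms of the measure, and
the absolute value scores increasing and decreasing measures alike. No
multiple-testing correction is applied across the 210 pairs — the
benchmark uses a single stated α = 0.05. A measure that fails on a cell
causes its whole noise level to be excluded (never imputed), with a
warning; more than 10% failures abort.

## Problem sizes and runtime

The full benchmark protocol (420 simulations of 500 output steps, five
measures per signal, 210 exact rank-sum tests per measure) completes in
roughly half a minute on one CPU; the test suite, including a full
protocol run and a 2000-replicate type-I calibration of the rank-sum
test, in about one minute. Example scripts use reduced grids (e.g. 8×8)
purely for brevity.

## Known limitations

- The R-peak detector assumes a dominant positive R wave; inverted leads
  need sign-flipping upstream, and no morphology classification (e.g.
  ectopic-beat typing) is attempted.
- The triangular index default bin width is a human-standard constant.
- tRSE depends on the stated band and bin count; values are comparable
  only across runs with identical settings.
- SE.ACF on very short epochs (< ~120 beats) rests on few ACF lags and
  its embedding selection becomes unstable; the measure is flagged
  missing rather than extrapolated when templates cannot be formed.
- The degree of monotonicity is a benchmark statistic for measure
  *comparison*; it says nothing about absolute effect sizes in real
  recordings.
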
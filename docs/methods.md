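# Methods

## Problem and data model

Electronic valvometry records how far a bivalve's two shell valves are apart
by pairing a shell-mounted magnet with a Hall-effect sensor on the opposite
valve: the sensor's output voltage (0–5000 mV, nominally ~2500 mV) varies
with valve separation and is logged as tab-delimited text at 5-second ticks.
This package analyzes such records for photosymbiotic giant clams
(*Tridacna*) held in a large indoor mesocosm, together with environmental
series: PAR at 15-s intervals, and pH, dissolved oxygen, temperature,
chlorophyll-a and phycoerythrin fluorescence (RFU) at 15-min intervals.

Timestamps are naive local clock time with a fixed UTC offset (the
deployment region has no DST); missing ticks are explicit NaN and are never
interpolated at ingest. Alignment averages ticks into non-overlapping
windows (minute-scale for wavelet work); PAR is placed on the valve grid so
that every gape observation has an instantaneous light value.

## Sensor quality control

Two failure signatures are detected and masked (never repaired):

* **Rail faults** — saltwater intrusion or shorting drives the output to a
  supply rail. Any run of ≥ 5 min at ≤ 100 mV or ≥ 4900 mV is flagged. The
  persistence requirement avoids flagging single-tick electrical noise; both
  thresholds are configuration options.
* **Diurnal loss** — a broken weld yields a trace with no day/night signal.
  A 3-day window slides in 1-day steps; the fraction of mean-removed
  periodogram power in the 20–28 h band is compared with
  `power_ratio_min = 0.15`. `scripts/calibrate_qc.py` documents the
  separation: noise-only windows put ≲ 0.09 of their power in the band
  (95th percentile, hourly grid; ~10⁻³ at the minute grid) while clean
  diurnal traces put ≳ 0.93 there, so 0.15 sits between the noise ceiling
  and the signal floor. Detection is spectral rather
  than visual; zero-variance (flat) windows always flag.

Masked spans are excluded from every downstream statistic. QC is idempotent
and `masked_fraction` equals flagged duration over span duration.

## Normalization

Sensors drift day to day (neighboring clams "walk", shifting the magnetic
background), so voltages are standardized per local calendar day:

    z_t   = (mV_t − μ_day) / SD_day                      (sample SD, n−1)
    pct_t = (z_t − z_daymin) / (z_daymax − z_daymin) × 100

Percent closure rescales each day's observed range to 0 (most open) … 100
(most closed); it is invariant to any positive-gain affine transform of that
day's voltages, and a polarity flip maps pct → 100 − pct. Days with under
50% coverage or zero variance are dropped with a warning — extrema-based
scaling is fragile on sparse days. Because magnet/sensor geometry can invert
the voltage–closure sign per installation, `polarity="auto"` orients z so
the dark-hours median exceeds the bright-hours median (giant clams gape
open to bask and close partially at night).

Light regimes: an instant is **dark** when its clock-hour's mean PAR is
below 5 μmol photons/m²s, **bright** when instantaneous PAR exceeds
100 μmol photons/m²s, **low light** otherwise; "light present" is the
complement of dark.

## Closure-event delineation

A valve-clap is a transient spike in z. A sample is a candidate peak iff it
is the maximum of its centered 3-point window with ties to the earliest
index (3 points at 5-s logging resolve claps lasting beyond ~15 s while
rejecting single-sample noise). Prominence is the peak height above the
higher of the two flanking base minima (walking to the nearest strictly
higher sample or the segment edge); candidates below `min_prominence_z =
1.0` (one daily SD) are discarded. The event extends to the first samples at
or below `peak − 0.5 × prominence` on either side — the half-prominence
"reopening" convention — and overlapping events merge keeping the higher
peak. The prominence threshold and reopening fraction are declared
conventions: the source analyses of this kind typically state the window
but not an amplitude criterion, so absolute event counts are sensitive to
these settings (both are exposed in configuration, and a brute-force scan
in the test suite pins the implementation exactly).

Counts aggregate per local calendar day, split at the behavioral night
window [14:00, 04:00). Day-vs-night duration comparisons use the two-sided
Mann–Whitney/Wilcoxon rank-sum test; the reported W is the rank sum of the
first-named group (R's `wilcox.test` W equals this minus n₁(n₁+1)/2).

## Environmental covariate models

Daily closure counts join daily-mean covariates on date; RFU covariates
enter as natural logs floored at the smallest positive observed value (the
base only rescales the smooth's axis).

The additive model regresses counts on spline-smoothed log-chlorophyll,
log-phycoerythrin, pH and DO plus linear light. The smooth fit uses
penalized cubic B-splines (≤ 9 basis functions per term, smoothing
parameter by GCV). The reported table is the sequential Type-I ANOVA of the
terms' parametric (linear) components — one df per term, residual df =
n − 6 — the "ANOVA for parametric effects" convention of mainstream
additive-model software. Because these are exact F-tests on a linear model,
per-term type-I error is exactly calibrated, which the acceptance suite
verifies by simulation (100 null replicates at n = 50).

The cross-correlation function uses the classic estimator: r(k) correlates
x_t with y_{t+k}, divided by N and the lag-0 standard deviations, with
white-noise bounds ±1.96/√N. **Positive lag means closure lags the
covariate** — the convention is printed in output headers because it is the
perennial CCF trap. ccf(x, y) at lag k equals ccf(y, x) at −k.

## Wavelet rhythm analysis

The complex Morlet CWT (ω₀ = 6) is computed by the FFT algorithm with
zero-padding to a power of two, scales log-spaced at dj = 1/20 over periods
0.5 h – 7 days by default. The daughter normalization makes the expected
power of white noise equal the series variance at every scale, and power is
reported relative to the series variance (1 ≈ noise level). The cone of
influence is the e-folding distance of the wavelet envelope
(period = Fourier-factor × d/√2 at distance d from an edge). Note the
classic large-scale bias of this convention: a tone's ridge power grows
with scale, so cross-period comparisons should use power/scale.

Significance is assessed against AR(1) surrogates fitted to the series'
lag-1 autocorrelation and variance (100 surrogates by default, seedable);
the per-period null distribution is pooled over interior time columns
(valid because the null is stationary), and the mask is forced false
outside the cone of influence. On white noise the significant fraction
inside the cone sits at the nominal α = 0.05 within Monte-Carlo error.

Band reconstruction uses the delta-function inversion (C_δ = 0.776,
ψ₀(0) = π^(−1/4) for ω₀ = 6); the residual is defined as original minus
reconstruction, so their sum is exact by construction. Removing the
18–30 h band from a diurnal series and re-analyzing the residual exposes
ultradian (6 and 12 h) structure. A full-range reconstruction reproduces a
band-limited series' variance within a few percent; an 18–30 h band
captures ~97% of a pure 24-h tone's variance (the Gaussian scale envelope
leaks a few percent outside any finite band).

Wavelet coherence smooths the scale-normalized cross-spectrum with a boxcar
over one scale length in time and ±0.6 octave in scale (without smoothing,
coherence is identically 1). Phase is the argument of the smoothed
cross-spectrum: **positive phase = first series leads**; 0 is in phase
(right-pointing arrow), ±π anti-phased (left-pointing). A quarter-cycle lag
of the second series gives +π/2 at the shared period. Gaps are linearly
interpolated before any transform, capped at 20% missing (beyond that the
surrogate null is meaningless and the call fails).

## The simulator

`simulate` generates the study conditions with full ground truth,
deterministic under its seed:

* **Light**: an asymmetric solar hump (peak 540 μmol photons/m²s at 09:00,
  morning/afternoon flanks σ = 2 h, truncated below 1) over an LED square
  wave of 60 μmol photons/m²s from 08:00–20:00, so the daily maximum
  (~600) falls between 08:00 and 10:00, light drops below 100 in the early
  afternoon, and hourly means are < 5 through the night. Day-to-day
  lognormal weather variability (σ = 0.10) multiplies the solar term; an
  optional one-sample midnight logger artifact can be injected (off by
  default, and QC deliberately does not remove it).
* **Water chemistry**: pH 8.175 ± 0.06 clipped to [8.1, 8.25], DO
  8.4 ± 1.3 mg/L clipped to [6.89, 9.94], temperature 25 ± 0.1 °C. Their
  diurnal cycles peak at midnight: the emulated mesocosm is
  respiration-dominated at the diurnal scale, which makes pH and DO
  in phase with the clams' nocturnal closure and anti-phased with light —
  the phase structure the coherence analysis is designed to resolve.
  Chlorophyll is a lognormal AR(1) baseline (~5 RFU, 2-day memory) times
  an episodic bloom envelope (Gaussian rise over ~1 day, exponential
  die-off over ~3 days, one bloom per ~12 days); phycoerythrin is an
  independent copy at lower level.
* **Behavior**: baseline closure is a logistic function of instantaneous
  PAR crossing 100 μmol photons/m²s between the bright mean (0.127) and the
  dark mean (0.441), plus AR(1) posture jitter with 1-h correlation time
  and stationary SD 0.04 — large enough to give surrogate tests realistic
  autocorrelation, small enough that slow jitter humps stay below the
  one-daily-SD event threshold that claps (z ≈ 3.5) clear easily.
  Valve-claps arrive as an inhomogeneous Poisson process: 0.75/h per clam
  in the night window (14:00–04:00), 0.15/h by day, ~34 pooled claps/day
  across three clams. The nightly rate is multiplied by
  exp(gain × lagged log-chl anomaly) with a 4-day lag — blooms feed
  closure-rate, not posture — with per-clam gain factors (1.0, 0.9, 0.6)
  mimicking one less-synchronized individual. Clap durations are log-normal
  (median 40 s, σ = 0.715, so ~90% fall under 100 s); each clap rises to
  0.95 closure within ~10 s, holds, and reopens. Rare long daytime
  closures (0.15/day, median 15 min) emulate threat responses.
* **Transduction**: mV = offset (2500) + gain (800) × closure + Gaussian
  noise (8 mV) + linear drift (3 mV/day) + a daily random-walk drift,
  clipped to [0, 5000] and quantized to integer millivolts (set
  `quantize=False` for the exact affine map). Rail faults are injected
  from an explicit list and recorded in the ground truth. A negative gain
  simulates an inverted magnet orientation, which `polarity="auto"` must
  recover.

What the simulator does **not** emulate: tidal forcing (the emulated basin
has none), biophysical adductor dynamics, researcher-visit disturbances as
a separate labeled process, and realistic cross-clam synchrony beyond the
shared drivers plus gain variation. Passing recovery tests therefore shows
the pipeline recovers the encoded structure under realistic noise — not
that field data obeys that structure.

## Problem sizes and numerical choices

The test and acceptance runs use a 60-day, 3-clam simulation at the 5-s
grid for event work and minute/15-min grids for rhythm work; lag-recovery
uses 50 replicates of a fast daily-resolution path sharing the same rate
model; model calibration uses 100 null replicates at n = 50. Wavelet
surrogate counts default to 100 (smaller in some tests where only ridge
location is asserted). Ties in peak detection break to the earliest index;
constant days, empty regimes and zero-variance series raise named warnings
or errors rather than propagating NaN. Reported normalization identities
hold to 1e-9 relative; reconstruction identity is exact by construction.

## Known limitations

* Absolute event counts depend on the declared prominence/reopening
  conventions; only relative and rate-based statements are robust.
* The ANOVA table tests the linear component of each smooth term; a purely
  non-monotone effect with no linear projection will escape it (the smooth
  fit and its effective df are reported alongside for that reason).
* The CCF assumes (second-order) stationarity; strong trends should be
  removed first.
* Wavelet significance is pointwise; with ~5% of cells falsely significant
  under the null, isolated significant patches should not be over-read.
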
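# Methods

This note documents the measurement definitions, the synthetic-data model,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Recording model and conventions

A line-scan is a grid of fluorescence intensities indexed (pixel, time
sample): axis 0 is space (pitch in µm, default 0.397), axis 1 is time (line
interval in ms), 0-based, time measured from the first line. All analysis
operates on F/F₀; amplitudes are ΔF/F₀ = F/F₀ − baseline. No conversion to
[Ca²⁺] is attempted (indicator calibration is deliberately out of scope).

**Baseline F₀.** With a known quiescent window (e.g. the pre-stimulus
period), F₀ is the per-pixel mean over that window — unbiased, preferred.
Without one, F₀ falls back to the per-pixel 10th percentile of the whole
trace; under noise of SD σ this is biased low by ≈ 1.28 σ, which is
accepted and recorded in `baseline_method`. An optional per-pixel linear
photobleach detrend (off by default) and a constant-offset background
subtraction are available; both are recorded so every normalization is
reproducible.

## Global CaT measurements

Within a beat window: the peak is the earliest maximal sample; onset is the
last upward crossing of baseline + 10 % amplitude before the peak (linearly
interpolated); the beat baseline is the mean of the 50 ms preceding onset
(clipped to the window start — the first beat uses the recording start);
amplitude = peak − baseline; "decay time" is time from peak to 66 %
recovery toward baseline, interpolated between samples. Mono-exponential
decay constants come from a separate explicit least-squares fit of
y = A·exp(−t/τ) + C (initialised by log-linear regression, bounds A > 0,
τ > 0); both conventions are reported because twitch decays are summarised
by the 66 % time while pathway kinetics use τ.

Pacing staircases are summarised per frequency step over steady-state beats
only: the first 2 beats of each step are discarded (a fixed, documented
rule), steps with fewer than 3 beats are skipped with a warning.

## Per-pixel locCaT extraction

The frame's spatially averaged trace provides the global onset, the global
amplitude, and a *template* (smoothed global transient, baseline
subtracted, truncated to its support — the region above 5 % of peak, padded
25 ms each side, zero elsewhere).

Per pixel:

1. a provisional baseline (mean of the 50 ms before the global onset) is
   subtracted;
2. the pixel trace is cross-correlated against the template over lags up to
   ±150 ms; the correlation maximum gives the pixel's release lag, refined
   to sub-sample precision by a three-point parabola. Near-ties (within
   10⁻⁹ relative — exact ties occur in degenerate constructed frames) are
   resolved toward the pixel's own smoothed argmax;
3. the pixel's baseline is then re-estimated in the 50 ms before its *own*
   lag-shifted onset, and amplitude, SNR validity and the 66 % decay time
   are measured from the smoothed trace (boxcar, 10 ms default).

Two choices matter here. First, *why cross-correlation rather than a
smoothed argmax*: the transient kernel is flat around its peak (rise τ
~12 ms, decay τ ~150 ms), so at 2 ms sampling the argmax of a noisy pixel
trace wanders by ~10 ms even at SNR 20, while the correlation pools the
steep rising edge and locates the lag to well under 1 ms. The template is
built from the frame's own global mean, so no generator knowledge leaks
into the measurement. Because the template is a latency-broadened mixture,
absolute peak times carry a constant shape-dependent offset per frame; all
σ statistics and the dispersion structure are unaffected (validated by
parameter recovery and by an alignment-invariant RMSE test). Second, *why
the per-pixel baseline re-estimate*: pixels that release earlier than the
global onset would otherwise have their rising phase contaminate the shared
pre-onset baseline span, corrupting their amplitude and lag. Analysis
windows also reach up to 50 ms before their nominal start (when recorded
data exist) for the same reason.

Pixels with amplitude below 3× their baseline noise SD (estimated from the
smoothing residual) are masked invalid and excluded from every statistic;
the count is always reported and a >50 % exclusion raises a quality flag.
Time-to-peak is referenced to the global onset by default (`reference=
"window"` is available); decay time is the duration from the local peak.

## The σ statistics

- **spatial-σ**: population SD (ddof 0 — the pixels are the full census of
  the scanned line) of the metric over valid pixels of one beat; requires
  ≥ 16 valid pixels by default (parameterised).
- **temporal-σ**: per-pixel sample SD (ddof 1 — k beats are a sample)
  across k beats, divided by the Gaussian unbiasing constant c₄(k)
  (c₄(5) = 0.9400), averaged over pixels valid in *all* k beats. The
  all-beats inclusion rule is a documented decision.
- **structural-σ**: the k stimulus-aligned frames are averaged
  sample-by-sample (equal length enforced; shared pre-window context is
  carried along) and spatial-σ is computed on the mean frame. Averaging
  attenuates the jitter component by roughly √k (not exactly — the peak of
  a mean of shifted kernels is a nonlinear functional — which is why tests
  compare against an oracle that applies the same computation to the
  noiseless ground-truth field rather than a closed form).
- **synchrony efficiency**: global amplitude / mean local amplitude, both
  measured through the identical code path so the perfectly synchronous
  noiseless cell yields exactly 1.
- **local amplitude CV**: population SD / mean of valid local amplitudes.

Beat frames come from stimulus times when present, otherwise detected
global onsets; frame length is 2000 ms truncated to the shortest
inter-stimulus interval, rounded to whole samples. No spatial binning is
applied by default (single-pixel analysis at the native pitch); any binning
or smoothing applied is recorded in the result.

## Flux deconvolution

The six epochs (a–f) are contiguous half-open intervals with bath solutions
NT → 0Na/0Ca + tetracaine → caffeine/NT → (decay) → caffeine/0Na0Ca → NT
restored. Measurements are model-free, per epoch:

- **a** — mean twitch amplitude over steady beats (first beat skipped when
  possible) and the twitch decay τ from the last beat;
- **b** — RyR leak = mean of the 300 ms before the tetracaine marker minus
  the mean of the last 300 ms of the epoch; both segments are checked for
  steadiness (|slope| ≤ 5×10⁻⁵ /ms) and non-steady segments produce a
  recorded warning, not a silent failure; a negative drop is reported
  signed and flagged;
- **c** — SR content = caffeine peak (within 2 s of the marker) minus the
  300 ms pre-caffeine baseline;
- **d** — SERCA: `literal` mode reports τ of the caffeine-decay fit as
  such; `corrected` mode also reports k_SERCA = 1/τ_twitch − 1/τ_caffeine,
  the standard pathway subtraction, because caffeine holds RyRs open and
  renders SERCA uptake futile, so the caffeine decay itself reflects
  NCX + PMCA. Both are recorded; neither guesses intent;
- **e** — PMCA: OLS slope magnitude over 250 ms from the post-caffeine
  peak. The window is a linearization compromise: the underlying decay is
  exponential with τ ≈ 1/k_PMCA, so the mean slope over a window of length
  w underestimates the initial slope k_PMCA·c₀ by ≈ w/2τ (~6 % at 250 ms
  for τ = 2 s);
- **f** — NCX: k_NCX = 1/τ_f − 1/τ_e from the epoch-f and epoch-e
  exponential fits; τ_f ≥ τ_e is physically unexpected and flagged;
- **fractional release** = twitch amplitude / SR content by default
  (`amp_over_sr`, the fraction of the store released per beat); the inverse
  convention is selectable and always recorded, since both readings appear
  in the literature.

Decay fits start at the sample after the segment's peak; the first 100 ms
after a solution switch are excluded from fits (exchange artefacts), except
where the switch event itself is the measurand (the post-caffeine peak in
epoch e). All estimates are level differences, slopes or rates, hence
invariant to a constant trace offset. Per-epoch failures are recorded and
the remaining epochs still run.

## The synthetic-data generator

**Line-scans.** Per pixel x and beat b the release latency is
L(x,b) = mean_latency + struct(x) + orphan(x)·orphan_delay + jitter(x,b),
with struct ~ N(0, σ_struct²) fixed per pixel, jitter ~ N(0, σ_beat²)
redrawn per beat (a scaled Student-t option with matched SD exists as a
robustness stressor), and an orphan fraction of pixels carrying an extra
fixed delay as a t-tubule-loss surrogate. The local transient is a
unit-peak (1−e^(−u/τ_rise))·e^(−u/τ_decay) kernel (τ_rise 12 ms, τ_decay
150 ms — peak ~31 ms after release) scaled by a per-pixel amplitude
(mean 2.0 ΔF/F₀, CV 0.2, clipped at 5 % of the mean). Reference conditions:
64 pixels at 0.397 µm, 2 ms lines, 5 beats at 2000 ms with 200 ms
pre-stimulus quiescence, σ_struct = 8 ms, σ_beat = 6 ms, mean latency
25 ms, baseline F₀ 100 counts, Gaussian noise SD 0.1 F/F₀ units (SNR ≈ 20
against the mean amplitude); a photon-scaled Poisson model is available.
Optional Gaussian spatial blur (optics + dye diffusion) is applied to the
noiseless field before noise; its default is 0 µm because blur mixes
neighbouring latencies and attenuates the very dispersion whose recovery
the validation asserts — enabling it is a deliberate robustness experiment,
not part of the reference conditions. The ground truth carries every latent
draw plus the noiseless field, and the emitted recording is bit-identical
per (config, seed).

What the generator does *not* emulate: stochastic RyR gating and sparks,
motion artefacts, photobleaching, spatially correlated noise, transient
shape heterogeneity between pixels. Passing recovery tests therefore shows
the estimators are correct under the stated statistical structure, not that
real recordings satisfy that structure.

**Flux traces.** A single pool with
dc/dt = J_leak·leak_on − (k_SERCA·serca_on + k_NCX·ncx_on + k_PMCA)·c,
solution switches setting the flags (0Na/0Ca: NCX off; tetracaine: leak
off; caffeine: SERCA futile, leak off, instantaneous dump of the SR
content), impulse twitch releases of release_fraction × sr_content, and a
second caffeine dump at epoch e (amplitude a parameter — the generator does
not model store refilling between pulses). Within each
constant-coefficient segment the linear ODE is evaluated in closed form at
every sample, so the noiseless trace is exact; a stiffness guard refuses
steps above τ_min/10 for the contract's sake. Closed-form epoch constants
(τ_twitch = 1/Σk, τ_caffeine = 1/(k_NCX+k_PMCA), τ_e = 1/k_PMCA,
leak shift = J_leak/(k_SERCA+k_PMCA)) are stored in the ground truth and
drive the recovery tests. Default protocol timing (1 Hz × 6 beats;
tetracaine at 10 s with ≥ 4 s settled on each side; caffeine at 14.4 s with
a 3 s decay epoch; 4 s PMCA epoch; 6 s NCX epoch) was chosen once so every
fitted segment spans at least ~2 decay constants at the default rates.

## Numerical choices and degenerate inputs

- Boxcar smoothing uses nearest-edge padding; window = round(10 ms / dt)
  forced odd. Sub-sample refinement is a three-point parabola with the
  offset clamped to ±0.5 sample and a guard for vanishing curvature.
- Earliest-maximum tie-break everywhere a discrete argmax is taken.
- Epoch/window boundaries are half-open; a boundary between samples assigns
  the sample to the later interval.
- Exponential fits reject flat or net-rising input (`FitDegenerateError`)
  rather than returning a meaningless τ; pipeline wrappers record such
  failures per epoch and continue.
- A frame whose global amplitude is below 4× the global-trace noise SD
  raises a no-transient error rather than producing σ from noise.
- All σ computations ignore NaN metrics (e.g. a pixel that never recovers
  66 % within the frame keeps its rise metric but contributes no decay
  metric).
- Windows shorter than 5 samples, baselines ≤ 0, non-increasing stimulus
  times and mismatched shapes are rejected with specific exceptions at
  construction time.

## Validation design

Every estimator is validated two ways: (1) closed-form or constructed
cases with exact expectations (two-population σ = 5 ms, efficiency 0.5,
noiseless τ recovery to 10⁻⁶); (2) Monte-Carlo parameter recovery against
the generator at the reference conditions (100 cells / 100 traces in the
acceptance script; smaller replicate counts in unit tests to keep the suite
fast). The σ machinery is additionally checked against an independent
straight-line re-implementation (plain Python loops, no shared code) to
10⁻⁹ on 8-pixel × 3-beat grids. Problem sizes were chosen so the whole
suite runs in well under a minute on one CPU while keeping Monte-Carlo
standard errors far inside the asserted tolerances.

## Known limitations

- The template cross-correlation assumes all pixels share the transient
  shape up to shift and scale; strong shape heterogeneity (e.g. alternans
  restricted to part of the cell) biases lags toward best overlap rather
  than true peak alignment.
- Local decay times are measured directly on the smoothed trace and are
  the noisiest per-pixel quantity (the 66 % crossing sits on a shallow
  slope); decay-σ values at low SNR should be interpreted with the
  reported noise level in mind.
- The percentile F₀ fallback is biased under noise (documented above);
  supply a quiescent window whenever the protocol provides one.
- The flux pipeline assumes the solution-switch markers in the protocol
  are accurate; it does not detect switches from the trace.
- The single-pool flux generator ignores store refilling between caffeine
  pulses, cytosolic buffering nonlinearity and indicator saturation; it
  validates the measurement operations, not cardiac physiology.
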
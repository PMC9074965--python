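"""Whole-cell calcium transient (CaT) detection and kinetic measurements.

Operates on the spatially averaged trace of a normalized line-scan (or any
1-D fluorescence trace).  Conventions, fixed for determinism:

* a beat's baseline is the mean of the 50 ms preceding its onset (clipped to
  the window start);
* onset is the last upward crossing of baseline + 10% amplitude before the
  peak, linearly interpolated between samples;
* the peak is the earliest maximal sample;
* "decay time" is the time from peak to 66% recovery toward baseline
  (linearly interpolated); mono-exponential tau fits are separate, explicit
  operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .linescan_io import NormalizedRecording

__all__ = [
    "GlobalTransient",
    "ExponentialFit",
    "EmptyTraceError",
    "FitDegenerateError",
    "global_trace",
    "detect_global_transients",
    "measure_global_transient",
    "fit_mono_exponential",
    "fit_linear_slope",
    "frequency_response",
]

BASELINE_PRE_MS = 50.0       # pre-onset baseline averaging span
ONSET_FRACTION = 0.10        # onset = crossing of this fraction of amplitude
DECAY_RECOVERY_FRACTION = 0.66


class EmptyTraceError(ValueError):
    """No usable pixels / samples to build a trace from."""


class FitDegenerateError(ValueError):
    """Input does not contain a decay that a mono-exponential can describe."""


@dataclass(frozen=True)
class GlobalTransient:
    """Kinetic parameters of one whole-cell CaT within an analysis window.

    All times in ms from the start of the recording; levels in F/F0 units,
    amplitude in dF/F0 (peak minus baseline).
    """

    onset_time: float
    peak_time: float
    baseline_level: float
    peak_level: float
    amplitude: float
    time_to_peak: float
    decay_time_66: float | None
    tau: float | None
    window: tuple
    edge_truncated: bool = False

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset_time > self.peak_time + 1e-9:
            raise ValueError("onset_time must not exceed peak_time")
        if self.decay_time_66 is not None and not self.decay_time_66 > 0:
            raise ValueError("decay_time_66 must be > 0 when defined")
        if self.tau is not None and not self.tau > 0:
            raise ValueError("tau must be > 0 when defined")


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of y(t) = A exp(-t/tau) + C."""

    amplitude: float
    tau: float
    offset: float
    rss: float
    n_points: int

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-t / self.tau) + self.offset


# ---------------------------------------------------------------------------


def global_trace(norm: NormalizedRecording, valid_mask=None) -> np.ndarray:
    """Spatial mean of F/F0 across (valid) pixels, one value per time sample."""
    ratio = norm.ratio
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != (norm.n_pixels,):
            raise ValueError("valid_mask must have one flag per pixel")
        if not valid_mask.any():
            raise EmptyTraceError("all pixels are masked out")
        ratio = ratio[valid_mask]
    return ratio.mean(axis=0)


def _interp_crossing_up(t0, t1, y0, y1, level):
    """Time where a segment rising from y0 to y1 crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def detect_global_transients(
    trace,
    line_interval: float,
    stim_times=None,
    threshold_frac: float = 0.25,
    refractory_ms: float = 100.0,
    lead_ms: float = 50.0,
) -> list[tuple[float, float]]:
    """Partition a trace into per-beat analysis windows.

    With ``stim_times`` the windows are simply [stim_i, stim_{i+1}) with the
    last clipped to the trace duration.  Without them, upstrokes are detected
    where the trace crosses baseline + ``threshold_frac`` x (max - baseline)
    with a refractory period; each window starts ``lead_ms`` before its
    crossing (to preserve a baseline segment) and runs to the next window.

    Returns a list of (start_ms, end_ms) tuples; empty if nothing is found.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 50:
        raise ValueError("trace must be 1-D with >= 50 samples")
    duration = trace.size * line_interval

    if stim_times is not None:
        st = [float(s) for s in stim_times]
        if len(st) == 0:
            return []
        if np.any(np.diff(st) <= 0):
            raise ValueError("stim_times must be strictly increasing")
        if st[0] < 0 or st[-1] >= duration:
            raise ValueError("stim_times must lie within the trace")
        edges = st + [duration]
        return [(edges[i], edges[i + 1]) for i in range(len(st))]

    baseline = float(np.quantile(trace, 0.10))
    peak = float(trace.max())
    if peak <= baseline:
        return []
    level = baseline + threshold_frac * (peak - baseline)
    refractory = max(1, int(round(refractory_ms / line_interval)))

    crossings = []
    last = -refractory
    above = trace[0] >= level
    for i in range(1, trace.size):
        if not above and trace[i] >= level:
            if i - last >= refractory:
                t = _interp_crossing_up(
                    (i - 1) * line_interval, i * line_interval,
                    trace[i - 1], trace[i], level,
                )
                crossings.append(t)
                last = i
            above = True
        elif above and trace[i] < level:
            above = False
    if not crossings:
        return []

    starts = [max(0.0, c - lead_ms) for c in crossings]
    windows = []
    for i, s in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else duration
        windows.append((s, end))
    return windows


def _window_slice(n_samples: int, line_interval: float, window) -> tuple[int, int]:
    t0, t1 = float(window[0]), float(window[1])
    i0 = max(0, int(np.ceil(t0 / line_interval - 1e-9)))
    i1 = min(n_samples, int(np.ceil(t1 / line_interval - 1e-9)))
    if i1 - i0 < 5:
        raise ValueError(f"window [{t0}, {t1}) ms contains too few samples")
    return i0, i1


def measure_global_transient(
    trace,
    line_interval: float,
    window,
    fit_tau: bool = False,
) -> GlobalTransient:
    """Measure baseline, peak, amplitude, time-to-peak and 66% decay time.

    The peak is the earliest maximal sample in the window.  If the trace has
    not recovered by 66% before the window end, ``decay_time_66`` is None and
    the result is flagged ``edge_truncated``.
    """
    trace = np.asarray(trace, dtype=float)
    i0, i1 = _window_slice(trace.size, line_interval, window)
    seg = trace[i0:i1]
    t = (np.arange(i0, i1)) * line_interval

    pk = int(np.argmax(seg))  # earliest maximal sample
    peak_level = float(seg[pk])
    peak_time = float(t[pk])

    provisional = float(seg[: max(pk, 1)].min()) if pk > 0 else float(seg.min())
    amp0 = peak_level - provisional
    onset_time = float(t[0])
    if amp0 > 0 and pk > 0:
        level = provisional + ONSET_FRACTION * amp0
        onset_time = float(t[0])
        for j in range(pk, 0, -1):
            if seg[j - 1] < level <= seg[j]:
                onset_time = _interp_crossing_up(t[j - 1], t[j], seg[j - 1], seg[j], level)
                break

    b0 = max(t[0], onset_time - BASELINE_PRE_MS)
    bmask = (t >= b0) & (t < onset_time)
    if not bmask.any():
        bmask = np.zeros(seg.size, dtype=bool)
        bmask[: max(1, int(round(BASELINE_PRE_MS / line_interval)))] = True
        bmask &= np.arange(seg.size) <= pk
        if not bmask.any():
            bmask[0] = True
    baseline_level = float(seg[bmask].mean())
    amplitude = max(0.0, peak_level - baseline_level)

    decay_time = None
    edge = False
    target = peak_level - DECAY_RECOVERY_FRACTION * amplitude
    if pk == seg.size - 1 or amplitude == 0:
        edge = True
        if amplitude > 0:
            warnings.warn("peak at window edge; decay undefined", stacklevel=2)
    else:
        for j in range(pk + 1, seg.size):
            if seg[j] <= target:
                if seg[j] == seg[j - 1]:
                    decay_time = float(t[j] - peak_time)
                else:
                    tc = t[j - 1] + (seg[j - 1] - target) / (seg[j - 1] - seg[j]) * line_interval
                    decay_time = float(tc - peak_time)
                break
        if decay_time is None:
            edge = True
            warnings.warn("trace not recovered by 66% within window", stacklevel=2)

    tau = None
    if fit_tau and pk < seg.size - 10:
        try:
            fit = fit_mono_exponential(t[pk:] - t[pk], seg[pk:])
            tau = fit.tau
        except FitDegenerateError:
            tau = None

    return GlobalTransient(
        onset_time=min(onset_time, peak_time),
        peak_time=peak_time,
        baseline_level=baseline_level,
        peak_level=peak_level,
        amplitude=amplitude,
        time_to_peak=peak_time - min(onset_time, peak_time),
        decay_time_66=decay_time,
        tau=tau,
        window=(float(window[0]), float(window[1])),
        edge_truncated=edge,
    )


# ---------------------------------------------------------------------------
# curve fits


def fit_mono_exponential(t, y) -> ExponentialFit:
    """Fit y(t) = A exp(-t/tau) + C by least squares, A > 0, tau > 0.

    Initialized from a log-linear regression on (y - floor).  Raises
    :class:`FitDegenerateError` for flat or non-decaying input.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 10:
        raise ValueError("need >= 10 paired samples")
    span = float(y.max() - y.min())
    head = float(y[: max(3, y.size // 10)].mean())
    tail = float(y[-max(3, y.size // 10):].mean())
    if span == 0 or head <= tail:
        raise FitDegenerateError("input is not a decay (no net decrease)")

    t0 = t[0]
    ts = t - t0
    floor = tail - 0.05 * span
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log(np.maximum(y - floor, 1e-12))
    use = y - floor > 0.05 * span
    if use.sum() >= 2:
        slope, intercept = np.polyfit(ts[use], z[use], 1)
    else:
        slope, intercept = -1.0 / max(ts[-1], 1.0), np.log(span)
    tau0 = -1.0 / slope if slope < 0 else ts[-1] / 3 + 1e-6
    a0 = max(np.exp(intercept), 0.1 * span)
    p0 = (a0, max(tau0, 1e-3), floor)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(
            model, ts, y, p0=p0,
            bounds=([1e-12, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitDegenerateError(f"mono-exponential fit failed to converge: {exc}") from exc
    a, tau, c = (float(v) for v in popt)
    resid = y - model(ts, a, tau, c)
    return ExponentialFit(amplitude=a, tau=tau, offset=c, rss=float(resid @ resid), n_points=t.size)


def fit_linear_slope(t, y) -> float:
    """Ordinary least-squares slope of y against t (units of y per ms)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need >= 5 paired samples")
    return float(np.polyfit(t, y, 1)[0])


# ---------------------------------------------------------------------------
# pacing-frequency response


def frequency_response(
    norm: NormalizedRecording,
    stim_protocol,
    skip_beats: int = 2,
):
    """Per-frequency mean CaT parameters for a pacing staircase.

    ``stim_protocol`` is a sequence of ``(frequency_hz, start_ms, end_ms)``
    steps (or ``(frequency_hz, (start_ms, end_ms))``).  For each step the
    stimulus train is reconstructed from the frequency, the first
    ``skip_beats`` beats are discarded as non-steady-state, and the remaining
    beats are measured and averaged.  Steps with < 3 beats are skipped with a
    warning.  Returns a pandas DataFrame ordered like the protocol with
    columns: frequency_hz, n_beats, amplitude, peak, decay_time_66, baseline.
    """
    import pandas as pd

    trace = global_trace(norm)
    dt = norm.line_interval
    duration = norm.duration
    rows = []
    for step in stim_protocol:
        if len(step) == 2:
            freq, (start, end) = step
        else:
            freq, start, end = step
        freq, start, end = float(freq), float(start), float(end)
        if end > duration + 1e-9:
            raise ValueError("stimulus protocol extends beyond the recording")
        period = 1000.0 / freq
        stims = np.arange(start, end - 1e-9, period)
        if stims.size < 3:
            warnings.warn(
                f"{freq:g} Hz step has {stims.size} beats (< 3); skipped",
                stacklevel=2,
            )
            continue
        beats = []
        for i in range(skip_beats, stims.size):
            w_end = stims[i] + period if i + 1 <= stims.size - 1 else min(end, stims[i] + period)
            w_end = min(w_end, duration)
            try:
                beats.append(measure_global_transient(trace, dt, (stims[i], w_end)))
            except ValueError:
                continue
        if not beats:
            warnings.warn(f"{freq:g} Hz step produced no measurable beats; skipped", stacklevel=2)
            continue
        decays = [b.decay_time_66 for b in beats if b.decay_time_66 is not None]
        rows.append({
            "frequency_hz": freq,
            "n_beats": len(beats),
            "amplitude": float(np.mean([b.amplitude for b in beats])),
            "peak": float(np.mean([b.peak_level for b in beats])),
            "decay_time_66": float(np.mean(decays)) if decays else np.nan,
            "baseline": float(np.mean([b.baseline_level for b in beats])),
        })
    return pd.DataFrame(rows, columns=["frequency_hz", "n_beats", "amplitude", "peak", "decay_time_66", "baseline"])
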
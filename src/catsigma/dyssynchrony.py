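"""Per-pixel local calcium transient extraction and dyssynchrony statistics.

Release dyssynchrony is quantified as dispersion (sigma, in ms) of the time
course of the local calcium transient (locCaT) measured at every pixel of a
line-scan:

* **spatial sigma** — population SD across pixels of the local time-to-peak
  (or local 66% decay time) within a single beat;
* **temporal sigma** — for each pixel, the SD of its metric across k
  consecutive beats (k = 5 by default, sample SD corrected by the Gaussian
  c4(k) unbiasing constant); the cell's temporal sigma is the mean of the
  per-pixel SDs;
* **structural sigma** — spatial sigma recomputed on the frame obtained by
  averaging the k stimulus-aligned beat frames sample-by-sample, which
  cancels beat-to-beat jitter and leaves dispersion attributable to fixed
  subcellular structure (e.g. t-tubule disruption);
* **synchrony efficiency** — amplitude of the spatially averaged global CaT
  divided by the mean per-pixel local amplitude; 1 when release is perfectly
  synchronous, < 1 when local transients are staggered in time.

Per-pixel peak timing uses template cross-correlation: each pixel's
baseline-subtracted trace is correlated against the frame's own smoothed
global-mean transient, the correlation maximum nearest the pixel's smoothed
argmax is selected (locality-constrained tie-breaking), and the lag is
refined to sub-sample precision with a three-point parabola.  This is far
more noise-robust than a smoothed argmax because it pools the steep rising
edge of the transient rather than relying on the flat curvature at the peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .linescan_io import NormalizedRecording
from .transients import (
    BASELINE_PRE_MS,
    DECAY_RECOVERY_FRACTION,
    ONSET_FRACTION,
    _interp_crossing_up,
    _window_slice,
    detect_global_transients,
    global_trace,
)

__all__ = [
    "LocalTransientMap",
    "DyssynchronyResult",
    "NoTransientError",
    "AlignmentError",
    "extract_local_transients",
    "spatial_sigma",
    "temporal_sigma",
    "structural_sigma",
    "synchrony_efficiency",
    "local_amplitude_variability",
    "beat_windows",
    "analyze_dyssynchrony",
    "c4",
]

DEFAULT_SMOOTH_MS = 10.0
DEFAULT_MAX_LAG_MS = 150.0
DEFAULT_MIN_AMP_SNR = 3.0
DEFAULT_MIN_VALID = 16
DEFAULT_FRAME_MS = 2000.0
DEFAULT_N_BEATS = 5


class NoTransientError(ValueError):
    """The analysis window does not contain a usable global transient."""


class AlignmentError(ValueError):
    """Beat windows cannot be aligned sample-by-sample."""


def c4(k: int) -> float:
    """Gaussian small-sample unbiasing constant for the sample SD (E[s] = c4*sigma)."""
    if k < 2:
        raise ValueError("c4 requires k >= 2")
    return math.sqrt(2.0 / (k - 1)) * math.gamma(k / 2) / math.gamma((k - 1) / 2)


@dataclass(frozen=True)
class LocalTransientMap:
    """Per-pixel locCaT parameters for one analysed beat frame.

    ``time_to_peak`` is measured from the global CaT onset (or the window
    start, per ``reference``); ``local_decay_time`` is the time from the
    local peak to 66% recovery toward the local baseline (NaN when the pixel
    does not recover within the frame); amplitudes are dF/F0.  Pixels whose
    amplitude falls below ``min_amp_snr`` times their baseline noise SD are
    flagged invalid and excluded from every sigma computation.
    """

    pixel_index: np.ndarray
    time_to_peak: np.ndarray
    local_decay_time: np.ndarray
    local_amplitude: np.ndarray
    valid_mask: np.ndarray
    window: tuple
    onset_time: float
    reference: str
    global_amplitude: float
    smoothing: str
    low_quality: bool = False

    def __post_init__(self):
        n = self.pixel_index.shape[0]
        for name in ("time_to_peak", "local_decay_time", "local_amplitude", "valid_mask"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per pixel")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def metric(self, which: str) -> np.ndarray:
        if which == "rise":
            return self.time_to_peak
        if which == "decay":
            return self.local_decay_time
        raise ValueError("metric must be 'rise' or 'decay'")


@dataclass(frozen=True)
class DyssynchronyResult:
    """All sigma statistics and synchrony efficiency for one cell."""

    spatial_sigma_rise: float
    spatial_sigma_decay: float
    temporal_sigma_rise: float | None
    temporal_sigma_decay: float | None
    structural_sigma_rise: float | None
    structural_sigma_decay: float | None
    synchrony_efficiency: float
    local_amplitude_cv: float
    n_beats_used: int
    n_valid_pixels: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# per-pixel extraction


def _boxcar(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return y
    return uniform_filter1d(y, size=w, mode="nearest")


def _parabolic_delta(ym: float, y0: float, yp: float) -> float:
    """Sub-sample vertex offset (in samples, clamped to +-0.5) of a parabola
    through three equally spaced points around a discrete maximum."""
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < 1e-30:
        return 0.0
    delta = 0.5 * (ym - yp) / denom
    return min(0.5, max(-0.5, delta))


def _shifted_template_matrix(tmpl: np.ndarray, max_lag: int) -> np.ndarray:
    """Rows are the template shifted by lag l in [-max_lag, max_lag] (zeros
    outside the window)."""
    n = tmpl.size
    T = np.zeros((2 * max_lag + 1, n))
    for li, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            T[li, lag:] = tmpl[: n - lag]
        else:
            T[li, : n + lag] = tmpl[-lag:]
    return T


def extract_local_transients(
    norm: NormalizedRecording,
    window,
    min_amp_snr: float = DEFAULT_MIN_AMP_SNR,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
    reference: str = "onset",
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
) -> LocalTransientMap:
    """Measure the locCaT of every pixel within one beat window.

    Parameters
    ----------
    window : (start_ms, end_ms)
        Half-open analysis frame containing one global CaT.
    min_amp_snr : float
        Pixels with amplitude below this multiple of their baseline noise SD
        are masked invalid (default 3).
    smooth_ms : float
        Boxcar span for temporal smoothing before peak/decay measurements.
    reference : {'onset', 'window'}
        Zero point for time_to_peak: the detected global CaT onset (default)
        or the window start.
    """
    if reference not in ("onset", "window"):
        raise ValueError("reference must be 'onset' or 'window'")
    dt = norm.line_interval
    i0, i1 = _window_slice(norm.n_samples, dt, window)
    # pre-window context (up to one baseline span) so that baselines can be
    # estimated even when release latencies are short relative to the window
    ctx = int(round(BASELINE_PRE_MS / dt))
    ib0 = max(0, i0 - ctx)
    sub = norm.ratio[:, ib0:i1]
    n_pix, n = sub.shape
    t = np.arange(ib0, i1) * dt
    w0 = i0 - ib0  # first in-window sample

    w = max(1, int(round(smooth_ms / dt)))
    if w % 2 == 0:
        w += 1

    # --- global transient: template, onset, sub-sample peak time
    g = sub.mean(axis=0)
    gs = _boxcar(g, w)
    gpk = w0 + int(np.argmax(gs[w0:]))  # peak restricted to the window proper
    gb0 = float(gs[: gpk + 1].min())
    amp0 = float(gs[gpk]) - gb0
    g_noise = float(np.std(g - gs)) / math.sqrt(1.0 - 1.0 / w) if w > 1 else 0.0
    if amp0 <= 0 or (g_noise > 0 and amp0 < 4.0 * g_noise):
        raise NoTransientError(
            f"window [{window[0]:g}, {window[1]:g}) ms contains no global transient "
            f"(amplitude {amp0:.4g}, noise SD {g_noise:.4g})"
        )

    level = gb0 + ONSET_FRACTION * amp0
    onset_t = float(t[0])
    for j in range(gpk, 0, -1):
        if gs[j - 1] < level <= gs[j]:
            onset_t = float(_interp_crossing_up(t[j - 1], t[j], gs[j - 1], gs[j], level))
            break

    b0 = max(float(t[0]), onset_t - BASELINE_PRE_MS)
    bmask = (t >= b0) & (t < onset_t)
    if not bmask.any():
        bmask = np.zeros(n, dtype=bool)
        bmask[0] = True

    g_base = float(g[bmask].mean())
    tmpl = gs - g_base
    g_amp = float(gs[gpk]) - g_base

    # compact the template to the transient's support (5% of peak, padded
    # 25 ms each side, zero elsewhere): the correlation then measures
    # transient alignment and is invariant to per-pixel baseline offsets
    pad = int(round(25.0 / dt))
    thresh = 0.05 * tmpl[gpk]
    lo_s = 0
    for j in range(gpk, -1, -1):
        if tmpl[j] < thresh:
            lo_s = j
            break
    hi_s = n - 1
    for j in range(gpk, n):
        if tmpl[j] < thresh:
            hi_s = j
            break
    lo_s = max(0, lo_s - pad)
    hi_s = min(n - 1, hi_s + pad)
    tmpl = tmpl.copy()
    tmpl[:lo_s] = 0.0
    tmpl[hi_s + 1 :] = 0.0
    if gpk == 0 or gpk == n - 1:
        g_delta = 0.0
    else:
        g_delta = _parabolic_delta(gs[gpk - 1], gs[gpk], gs[gpk + 1])
    g_peak_time = float(t[gpk]) + g_delta * dt

    # --- cross-correlation of every pixel against the template
    max_lag = max(1, int(round(max_lag_ms / dt)))
    base = sub[:, bmask].mean(axis=1)
    yb = sub - base[:, None]
    ybs = _boxcar(yb, w) if w > 1 else yb
    if w > 1:
        resid = yb - ybs
        noise_sd = resid.std(axis=1) / math.sqrt(1.0 - 1.0 / w)
    else:
        noise_sd = np.zeros(n_pix)
    T = _shifted_template_matrix(tmpl, max_lag)
    C = yb @ T.T  # (n_pix, 2*max_lag+1)

    time_to_peak = np.full(n_pix, np.nan)
    decay_time = np.full(n_pix, np.nan)
    amplitude = np.zeros(n_pix)
    valid = np.zeros(n_pix, dtype=bool)
    ref_time = onset_t if reference == "onset" else float(t[w0])

    for p in range(n_pix):
        yp = ybs[p]
        p_arg = int(np.argmax(yp))  # earliest maximal sample

        # global correlation maximum; exact/near ties (multimodal frames)
        # resolved toward the pixel's own smoothed argmax.  With the compact
        # template the lag is invariant to the pixel's baseline offset.
        center = min(max(p_arg - gpk, -max_lag), max_lag)
        crow = C[p]
        cmax = float(crow.max())
        tol = 1e-9 * max(1.0, abs(cmax))
        best = None
        for li, cv in enumerate(crow):
            if cv >= cmax - tol:
                lag = li - max_lag
                key = (abs(lag - center), lag)
                if best is None or key < best[0]:
                    best = (key, lag)
        lag = best[1]

        # refine the pixel's baseline at its own (lag-shifted) onset: pixels
        # releasing earlier than the global onset would otherwise have their
        # rising phase contaminate the shared pre-onset baseline span
        p_onset = onset_t + lag * dt
        pb0 = max(float(t[0]), p_onset - BASELINE_PRE_MS)
        pbm = (t >= pb0) & (t < p_onset)
        base_p = float(sub[p, pbm].mean()) if pbm.any() else float(base[p])
        shift = float(base[p]) - base_p   # correction to the provisional baseline
        amp_p = float(yp[p_arg]) + shift
        amplitude[p] = amp_p
        if amp_p <= 0 or amp_p < min_amp_snr * noise_sd[p]:
            continue
        valid[p] = True

        if -max_lag < lag < max_lag:
            delta = _parabolic_delta(
                C[p, lag - 1 + max_lag], C[p, lag + max_lag], C[p, lag + 1 + max_lag]
            )
        else:
            delta = 0.0
        t_peak = g_peak_time + (lag + delta) * dt
        time_to_peak[p] = t_peak - ref_time

        # 66% recovery of the smoothed local trace, from its argmax
        target = (1.0 - DECAY_RECOVERY_FRACTION) * amp_p - shift
        for j in range(p_arg + 1, n):
            if yp[j] <= target:
                if yp[j] == yp[j - 1]:
                    t_cross = float(t[j])
                else:
                    t_cross = float(t[j - 1]) + (yp[j - 1] - target) / (yp[j - 1] - yp[j]) * dt
                dtc = t_cross - float(t[p_arg])
                if dtc > 0:
                    decay_time[p] = dtc
                break

    low_quality = valid.sum() < 0.5 * n_pix
    if low_quality:
        warnings.warn(
            f"{n_pix - int(valid.sum())}/{n_pix} pixels failed the amplitude/SNR "
            "criterion; sigma statistics may be unreliable",
            stacklevel=2,
        )

    return LocalTransientMap(
        pixel_index=np.arange(n_pix),
        time_to_peak=time_to_peak,
        local_decay_time=decay_time,
        local_amplitude=amplitude,
        valid_mask=valid,
        window=(float(window[0]), float(window[1])),
        onset_time=onset_t,
        reference=reference,
        global_amplitude=g_amp,
        smoothing=f"boxcar_{w}samples",
        low_quality=low_quality,
    )


# ---------------------------------------------------------------------------
# sigma statistics


def _metric_values(tmap: LocalTransientMap, metric: str) -> np.ndarray:
    vals = tmap.metric(metric)
    keep = tmap.valid_mask & np.isfinite(vals)
    return vals[keep]


def spatial_sigma(
    tmap: LocalTransientMap, metric: str = "rise", min_valid: int = DEFAULT_MIN_VALID
) -> float:
    """Population SD (ddof=0) of the per-pixel metric across valid pixels."""
    vals = _metric_values(tmap, metric)
    if vals.size < min_valid:
        raise ValueError(
            f"only {vals.size} valid pixels for metric '{metric}' (need >= {min_valid})"
        )
    return float(np.std(vals, ddof=0))


def temporal_sigma(
    norm: NormalizedRecording,
    windows,
    metric: str = "rise",
    min_valid: int = DEFAULT_MIN_VALID,
    bias_correct: bool = True,
    **extract_opts,
) -> float:
    """Beat-to-beat dyssynchrony: mean over pixels of each pixel's SD across
    k consecutive beats.

    A pixel contributes only if it is valid (and the metric finite) in every
    beat.  The per-pixel sample SD (ddof=1) is divided by the Gaussian c4(k)
    constant to remove small-sample bias (documented; c4(5) = 0.9400).
    """
    windows = list(windows)
    k = len(windows)
    if k < 2:
        raise ValueError("temporal sigma needs >= 2 beat windows")
    maps = [extract_local_transients(norm, win, **extract_opts) for win in windows]
    vals = np.stack([m.metric(metric) for m in maps])  # (k, n_pix)
    ok = np.all([m.valid_mask for m in maps], axis=0) & np.all(np.isfinite(vals), axis=0)
    if ok.sum() < min_valid:
        raise ValueError(
            f"only {int(ok.sum())} pixels usable across all {k} beats (need >= {min_valid})"
        )
    per_pixel_sd = np.std(vals[:, ok], axis=0, ddof=1)
    if bias_correct:
        per_pixel_sd = per_pixel_sd / c4(k)
    return float(per_pixel_sd.mean())


def _average_frames(norm: NormalizedRecording, windows) -> tuple[NormalizedRecording, tuple]:
    dt = norm.line_interval
    slices = []
    for win in windows:
        i0, i1 = _window_slice(norm.n_samples, dt, win)
        slices.append((i0, i1))
    lengths = {i1 - i0 for i0, i1 in slices}
    if len(lengths) != 1:
        raise AlignmentError(
            f"beat windows have unequal sample counts {sorted(lengths)}; "
            "stimulus-aligned equal-length frames are required"
        )
    # carry whatever pre-window context all frames share, so baselines of
    # early-releasing pixels remain measurable on the averaged frame
    lead = min(int(round(BASELINE_PRE_MS / dt)), min(i0 for i0, _ in slices))
    mean_frame = np.mean([norm.ratio[:, i0 - lead : i1] for i0, i1 in slices], axis=0)
    avg = NormalizedRecording(
        ratio=mean_frame,
        f0=np.ones(norm.n_pixels),
        baseline_method="beat_average",
        pixel_pitch=norm.pixel_pitch,
        line_interval=dt,
        stim_times=None,
        source_id=norm.source_id + ":beat_average",
    )
    return avg, (lead * dt, mean_frame.shape[1] * dt)


def structural_sigma(
    norm: NormalizedRecording,
    windows,
    metric: str = "rise",
    min_valid: int = DEFAULT_MIN_VALID,
    **extract_opts,
) -> float:
    """Spatial sigma of the beat-averaged frame.

    Averaging k stimulus-aligned frames sample-by-sample cancels beat-to-beat
    jitter, so the remaining dispersion reflects fixed (structural)
    differences between pixels.
    """
    avg, win = _average_frames(norm, windows)
    tmap = extract_local_transients(avg, win, **extract_opts)
    return spatial_sigma(tmap, metric=metric, min_valid=min_valid)


def synchrony_efficiency(norm: NormalizedRecording, window, **extract_opts) -> float:
    """Global CaT amplitude divided by the mean local CaT amplitude.

    Both amplitudes are measured through the identical code path (the global
    trace is treated as one more trace), so a perfectly synchronous noiseless
    cell gives exactly 1.0.
    """
    tmap = extract_local_transients(norm, window, **extract_opts)
    local = tmap.local_amplitude[tmap.valid_mask]
    mean_local = float(local.mean()) if local.size else 0.0
    if mean_local <= 0:
        raise ValueError("mean local amplitude is <= 0; cannot form the ratio")
    return tmap.global_amplitude / mean_local


def local_amplitude_variability(
    tmap: LocalTransientMap, min_valid: int = DEFAULT_MIN_VALID
) -> float:
    """Coefficient of variation (population SD / mean) of local amplitudes."""
    vals = tmap.local_amplitude[tmap.valid_mask]
    if vals.size < min_valid:
        raise ValueError(f"only {vals.size} valid pixels (need >= {min_valid})")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean local amplitude is <= 0")
    return float(np.std(vals, ddof=0)) / mean


# ---------------------------------------------------------------------------
# whole-cell driver


def beat_windows(
    norm: NormalizedRecording,
    n_beats: int = DEFAULT_N_BEATS,
    frame_ms: float = DEFAULT_FRAME_MS,
) -> list[tuple[float, float]]:
    """Equal-length stimulus-aligned beat frames.

    Uses the recording's stimulus times when present, otherwise detected
    global onsets.  The frame length is ``frame_ms`` truncated to the
    shortest inter-stimulus interval, rounded to whole samples.
    """
    dt = norm.line_interval
    if norm.stim_times is not None:
        anchors = list(norm.stim_times)
    else:
        detected = detect_global_transients(global_trace(norm), dt)
        anchors = [w[0] for w in detected]
    if not anchors:
        return []
    anchors = anchors[:n_beats]
    gaps = list(np.diff(anchors)) + [norm.duration - anchors[-1]]
    frame = min([frame_ms] + gaps)
    frame = math.floor(frame / dt) * dt
    return [(a, a + frame) for a in anchors]


def analyze_dyssynchrony(
    norm: NormalizedRecording,
    n_beats: int = DEFAULT_N_BEATS,
    frame_ms: float = DEFAULT_FRAME_MS,
    min_valid: int = DEFAULT_MIN_VALID,
    **extract_opts,
) -> DyssynchronyResult:
    """Run the full per-cell dyssynchrony analysis.

    Spatial sigma, synchrony efficiency and amplitude CV come from the first
    beat frame; temporal and structural sigma use all available frames and
    are None when fewer than 2 beats are found.
    """
    windows = beat_windows(norm, n_beats=n_beats, frame_ms=frame_ms)
    if not windows:
        raise NoTransientError("no beats found in recording")

    first = extract_local_transients(norm, windows[0], **extract_opts)
    sp_rise = spatial_sigma(first, "rise", min_valid)
    sp_decay = spatial_sigma(first, "decay", min_valid)
    eff = synchrony_efficiency(norm, windows[0], **extract_opts)
    cv = local_amplitude_variability(first, min_valid)

    tm_rise = tm_decay = st_rise = st_decay = None
    if len(windows) >= 2:
        tm_rise = temporal_sigma(norm, windows, "rise", min_valid, **extract_opts)
        tm_decay = temporal_sigma(norm, windows, "decay", min_valid, **extract_opts)
        st_rise = structural_sigma(norm, windows, "rise", min_valid, **extract_opts)
        st_decay = structural_sigma(norm, windows, "decay", min_valid, **extract_opts)

    return DyssynchronyResult(
        spatial_sigma_rise=sp_rise,
        spatial_sigma_decay=sp_decay,
        temporal_sigma_rise=tm_rise,
        temporal_sigma_decay=tm_decay,
        structural_sigma_rise=st_rise,
        structural_sigma_decay=st_decay,
        synchrony_efficiency=eff,
        local_amplitude_cv=cv,
        n_beats_used=len(windows),
        n_valid_pixels=first.n_valid,
    )
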
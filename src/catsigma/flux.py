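"""Six-epoch SR calcium flux-deconvolution protocol on whole-cell traces.

The protocol isolates the calcium uptake/extrusion pathways of a
cardiomyocyte by switching bath solutions while recording a whole-cell
Fluo-4 trace (F/F0):

========  =====================  ==========================================
epoch     solution               quantity
========  =====================  ==========================================
a         NT, field stimulated   basic CaT parameters, twitch decay tau
b         0Na/0Ca + tetracaine   RyR leak (diastolic level drop on TC)
c         caffeine in NT         SR content (caffeine peak amplitude)
d         caffeine in NT         SERCA (exponential fit of caffeine decay)
e         caffeine in 0Na/0Ca    PMCA (linear slope; only pathway left)
f         NT restored            NCX (accelerated decay; rate difference)
========  =====================  ==========================================

All measurement operations are model-free (steady levels, peaks, OLS slopes
and mono-exponential fits) exactly as stated for the protocol; the
single-pool rate model lives only in the simulator used for validation.
Fluorescence stays in dF/F0 units throughout (no indicator calibration).

SERCA has two reporting modes.  ``literal`` returns the tau of the epoch-d
caffeine-decay fit.  ``corrected`` additionally reports the standard
pathway-subtraction rate k_SERCA = 1/tau_twitch - 1/tau_caffeine_NT, which
accounts for caffeine rendering SERCA uptake futile (so the caffeine decay
reflects NCX + PMCA only); both are always recorded when requested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .transients import FitDegenerateError, fit_linear_slope, fit_mono_exponential

__all__ = [
    "SOLUTIONS",
    "Epoch",
    "ProtocolDefinition",
    "FluxProtocolTrace",
    "FluxEstimates",
    "ProtocolError",
    "read_trace",
    "segment_epochs",
    "estimate_ryr_leak",
    "estimate_sr_content",
    "estimate_serca",
    "estimate_pmca",
    "estimate_ncx",
    "fractional_release",
    "run_flux_pipeline",
]

SOLUTIONS = (
    "NT",
    "0Na0Ca",
    "0Na0Ca+TC",
    "caffeine_NT",
    "caffeine_0Na0Ca",
    "caffeine_NT_restore",
)
EPOCH_LABELS = ("a", "b", "c", "d", "e", "f")
MIN_EPOCH_MS = 500.0
SWITCH_ARTIFACT_MS = 100.0   # excluded after each solution change
STEADY_SPAN_MS = 300.0       # span used for steady diastolic levels
STEADY_SLOPE_MAX = 5e-5      # |dF/F0| per ms regarded as steady
PMCA_WINDOW_MS = 250.0       # linearization span from the epoch-e peak


class ProtocolError(ValueError):
    """Protocol definition invalid or inconsistent with the trace."""


@dataclass(frozen=True)
class Epoch:
    label: str
    start: float
    end: float
    solution: str
    stimulation: bool = False

    def __post_init__(self):
        if self.label not in EPOCH_LABELS:
            raise ProtocolError(f"unknown epoch label {self.label!r}")
        if self.solution not in SOLUTIONS:
            raise ProtocolError(f"unknown solution {self.solution!r}")
        if self.end - self.start < MIN_EPOCH_MS:
            raise ProtocolError(
                f"epoch {self.label} spans {self.end - self.start:g} ms (< {MIN_EPOCH_MS:g})"
            )


@dataclass(frozen=True)
class ProtocolDefinition:
    """Ordered, contiguous epochs a-f plus event markers.

    ``stim_times`` are the field-stimulus times (ms) within epoch a;
    ``tetracaine_time`` marks the TC application inside epoch b;
    ``caffeine_times`` mark the caffeine applications (first inside epoch c,
    second at/inside epoch e).
    """

    epochs: tuple
    stim_times: tuple = ()
    tetracaine_time: float | None = None
    caffeine_times: tuple = ()

    def __post_init__(self):
        epochs = tuple(self.epochs)
        labels = [e.label for e in epochs]
        if labels != list(EPOCH_LABELS[: len(labels)]) or len(labels) != 6:
            missing = sorted(set(EPOCH_LABELS) - set(labels))
            raise ProtocolError(
                f"protocol must define epochs a-f exactly once in order; missing {missing}"
            )
        for prev, nxt in zip(epochs, epochs[1:]):
            if abs(prev.end - nxt.start) > 1e-9:
                raise ProtocolError(
                    f"epochs {prev.label} and {nxt.label} are not contiguous"
                )
        object.__setattr__(self, "epochs", epochs)
        object.__setattr__(self, "stim_times", tuple(float(s) for s in self.stim_times))
        object.__setattr__(
            self, "caffeine_times", tuple(float(c) for c in self.caffeine_times)
        )

    def __getitem__(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def start(self) -> float:
        return self.epochs[0].start

    @property
    def end(self) -> float:
        return self.epochs[-1].end

    def to_dict(self) -> dict:
        return {
            "epochs": [
                {
                    "label": e.label,
                    "start_ms": e.start,
                    "end_ms": e.end,
                    "solution": e.solution,
                    "stimulation": e.stimulation,
                }
                for e in self.epochs
            ],
            "stim_times_ms": list(self.stim_times),
            "tetracaine_time_ms": self.tetracaine_time,
            "caffeine_times_ms": list(self.caffeine_times),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ProtocolDefinition":
        epochs = tuple(
            Epoch(
                label=e["label"],
                start=float(e["start_ms"]),
                end=float(e["end_ms"]),
                solution=e["solution"],
                stimulation=bool(e.get("stimulation", False)),
            )
            for e in data["epochs"]
        )
        return cls(
            epochs=epochs,
            stim_times=tuple(data.get("stim_times_ms", ())),
            tetracaine_time=data.get("tetracaine_time_ms"),
            caffeine_times=tuple(data.get("caffeine_times_ms", ())),
        )

    @classmethod
    def from_json(cls, path) -> "ProtocolDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FluxProtocolTrace:
    """Whole-cell F/F0 trace on a uniform time base (ms)."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size < 10:
            raise ValueError("time and values must be matching 1-D arrays (>= 10 samples)")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("time base must be uniform and increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", y)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def read_trace(path, normalized: bool = True, f0: float | None = None) -> FluxProtocolTrace:
    """Read a two-column delimited text trace (time_ms, fluorescence).

    ``normalized=True`` declares the second column to already be F/F0;
    otherwise it is divided by ``f0`` (or by the mean of its first 50
    samples when ``f0`` is None).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    skip = 0
    try:
        [float(v) for v in first.replace(",", " ").split()]
    except ValueError:
        skip = 1  # header row
    data = np.loadtxt(path, delimiter=delim, skiprows=skip)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path.name}: expected two columns (time_ms, fluorescence)")
    t, y = data[:, 0], data[:, 1]
    if not normalized:
        denom = float(f0) if f0 is not None else float(y[:50].mean())
        if denom <= 0:
            raise ValueError("F0 must be positive to normalize the trace")
        y = y / denom
    return FluxProtocolTrace(time=t, values=y)


# ---------------------------------------------------------------------------
# segmentation and per-epoch estimators


def segment_epochs(trace: FluxProtocolTrace, protocol: ProtocolDefinition) -> dict:
    """Split the trace into the six half-open epoch sub-traces.

    Boundaries falling between samples are assigned to the later epoch.
    """
    if protocol.end > trace.time[-1] + trace.dt + 1e-9:
        raise ProtocolError(
            f"protocol ends at {protocol.end:g} ms but trace ends at "
            f"{trace.time[-1]:g} ms"
        )
    out = {}
    for e in protocol.epochs:
        mask = (trace.time >= e.start - 1e-9) & (trace.time < e.end - 1e-9)
        out[e.label] = (trace.time[mask], trace.values[mask])
    return out


def _steady_level(t, y, t0, t1, warnings_out: list, tag: str) -> float:
    mask = (t >= t0) & (t < t1)
    if mask.sum() < 5:
        raise ProtocolError(f"{tag}: fewer than 5 samples in [{t0:g}, {t1:g}) ms")
    slope = fit_linear_slope(t[mask], y[mask])
    if abs(slope) > STEADY_SLOPE_MAX:
        warnings_out.append(
            f"{tag}: segment slope {slope:.3g}/ms exceeds steadiness threshold"
        )
    return float(y[mask].mean())


@dataclass
class EstimateDiagnostics:
    rss: float | None = None
    n: int = 0
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def estimate_ryr_leak(
    epoch_b, tetracaine_time: float
) -> tuple[float, EstimateDiagnostics]:
    """Diastolic level drop on tetracaine: RyR leak in dF/F0 units.

    Leak = mean of the 300 ms immediately before TC minus the mean of the
    last 300 ms of the epoch (after the TC response has settled).  Both
    segments are checked for steadiness; non-steady segments produce a
    recorded warning, not an error.
    """
    t, y = epoch_b
    diag = EstimateDiagnostics(n=t.size)
    if tetracaine_time is None:
        raise ProtocolError("epoch b requires a tetracaine application time")
    if tetracaine_time - t[0] < MIN_EPOCH_MS or t[-1] - tetracaine_time < MIN_EPOCH_MS:
        raise ProtocolError(
            "tetracaine marker must have >= 500 ms of trace on each side of epoch b"
        )
    pre = _steady_level(t, y, tetracaine_time - STEADY_SPAN_MS, tetracaine_time,
                        diag.warnings, "pre-tetracaine")
    post = _steady_level(t, y, t[-1] - STEADY_SPAN_MS, t[-1] + 1e-9,
                         diag.warnings, "post-tetracaine")
    leak = pre - post
    diag.extra = {"pre_level": pre, "post_level": post}
    if leak < 0:
        diag.warnings.append(f"negative leak estimate {leak:.4g} (reported signed)")
    return float(leak), diag


def estimate_sr_content(
    epoch_c, caffeine_time: float
) -> tuple[float, EstimateDiagnostics]:
    """Caffeine-transient amplitude: SR content in dF/F0 units."""
    t, y = epoch_c
    diag = EstimateDiagnostics(n=t.size)
    if caffeine_time is None:
        raise ProtocolError("epoch c requires a caffeine application time")
    if caffeine_time - t[0] < STEADY_SPAN_MS:
        raise ProtocolError("need >= 300 ms of pre-caffeine baseline in epoch c")
    bmask = (t >= caffeine_time - STEADY_SPAN_MS) & (t < caffeine_time)
    baseline = float(y[bmask].mean())
    pmask = (t >= caffeine_time) & (t < caffeine_time + 2000.0)
    if not pmask.any():
        raise ProtocolError("no samples within 2 s of the caffeine application")
    peak = float(y[pmask].max())
    if peak <= baseline:
        raise ProtocolError("no caffeine peak found within 2 s of application")
    diag.extra = {"baseline": baseline, "peak": peak}
    return peak - baseline, diag


def _decay_fit(t, y, skip_artifact: bool = True):
    """Mono-exponential fit starting at the sample after the segment's peak
    (and past the solution-switch artifact window)."""
    start = t[0] + (SWITCH_ARTIFACT_MS if skip_artifact else 0.0)
    mask = t >= start - 1e-9
    ts, ys = t[mask], y[mask]
    pk = int(np.argmax(ys))
    if ys.size - pk < 10:
        raise FitDegenerateError("decay segment too short after the peak")
    return fit_mono_exponential(ts[pk + 1 :], ys[pk + 1 :])


def _twitch_tau(epoch_a, stim_times) -> "tuple":
    """Tau of the last complete twitch decay in epoch a."""
    t, y = epoch_a
    stims = [s for s in stim_times if t[0] <= s < t[-1]]
    if not stims:
        raise ProtocolError("epoch a has no stimulus times; cannot fit twitch decay")
    last = stims[-1]
    mask = t >= last - 1e-9
    ts, ys = t[mask], y[mask]
    pk = int(np.argmax(ys))
    if ys.size - pk < 10:
        raise FitDegenerateError("not enough samples after the last twitch peak")
    return fit_mono_exponential(ts[pk + 1 :], ys[pk + 1 :])


def _cat_amplitude(epoch_a, stim_times, dt: float) -> tuple[float, EstimateDiagnostics]:
    """Mean twitch amplitude over the steady beats of epoch a (first beat
    skipped when more than one is available)."""
    t, y = epoch_a
    diag = EstimateDiagnostics(n=t.size)
    stims = [s for s in stim_times if t[0] <= s < t[-1]]
    if not stims:
        raise ProtocolError("epoch a has no stimulus times within the epoch")
    edges = stims + [t[-1] + dt]
    use = stims[1:] if len(stims) > 1 else stims
    amps = []
    for i, s in enumerate(stims):
        if s not in use:
            continue
        bmask = (t >= s - 50.0) & (t < s)
        wmask = (t >= s) & (t < edges[i + 1])
        if not bmask.any() or not wmask.any():
            continue
        amps.append(float(y[wmask].max()) - float(y[bmask].mean()))
    if not amps:
        raise ProtocolError("no measurable twitches in epoch a")
    diag.extra = {"n_beats": len(amps)}
    return float(np.mean(amps)), diag


def estimate_serca(
    epoch_a, epoch_d, stim_times, mode: str = "literal"
) -> tuple[dict, EstimateDiagnostics]:
    """SERCA from the caffeine-decay fit.

    ``literal``: tau of the epoch-d mono-exponential fit.  ``corrected``:
    additionally k_SERCA = 1/tau_twitch(epoch a) - 1/tau_caffeine(epoch d),
    the pathway-subtraction rate.  Returns a dict with ``serca_tau`` and,
    in corrected mode, ``serca_rate`` (1/ms) and ``twitch_tau``.
    """
    if mode not in ("literal", "corrected"):
        raise ValueError("mode must be 'literal' or 'corrected'")
    fit_d = _decay_fit(epoch_d[0], epoch_d[1], skip_artifact=False)
    diag = EstimateDiagnostics(rss=fit_d.rss, n=fit_d.n_points)
    out = {"serca_tau": fit_d.tau}
    if mode == "corrected":
        if epoch_a is None:
            raise ProtocolError("corrected SERCA mode requires epoch a")
        fit_a = _twitch_tau(epoch_a, stim_times)
        out["twitch_tau"] = fit_a.tau
        out["serca_rate"] = 1.0 / fit_a.tau - 1.0 / fit_d.tau
        diag.extra["twitch_rss"] = fit_a.rss
    diag.extra["segments"] = (
        "epoch_d decay" + (" + epoch_a last twitch decay" if mode == "corrected" else "")
    )
    return out, diag


def estimate_pmca(epoch_e) -> tuple[float, EstimateDiagnostics]:
    """PMCA as the OLS slope magnitude of the initial epoch-e decay.

    The fit spans ``PMCA_WINDOW_MS`` from the sample after the post-caffeine
    peak; the signed slope is kept in the diagnostics.
    """
    t, y = epoch_e
    if t[-1] - t[0] < 2000.0:
        raise ProtocolError("epoch e must span >= 2 s")
    pk = int(np.argmax(y))
    mask = (t > t[pk]) & (t <= t[pk] + PMCA_WINDOW_MS)
    if mask.sum() < 5:
        raise ProtocolError("fewer than 5 samples in the PMCA linearization window")
    slope = fit_linear_slope(t[mask], y[mask])
    diag = EstimateDiagnostics(n=int(mask.sum()), extra={"signed_slope": slope})
    return abs(slope), diag


def estimate_ncx(epoch_e, epoch_f) -> tuple[dict, EstimateDiagnostics]:
    """NCX from the decay acceleration on restoring Na/Ca.

    tau_e (slow, PMCA only) from the epoch-e fit, tau_f (fast, NCX + PMCA)
    from the epoch-f fit; k_NCX = 1/tau_f - 1/tau_e.  tau_f >= tau_e is
    physically unexpected and flagged.
    """
    fit_e = _decay_fit(epoch_e[0], epoch_e[1], skip_artifact=False)
    fit_f = _decay_fit(epoch_f[0], epoch_f[1])
    diag = EstimateDiagnostics(
        rss=fit_f.rss, n=fit_f.n_points, extra={"tau_e_rss": fit_e.rss}
    )
    if fit_f.tau >= fit_e.tau:
        diag.warnings.append(
            f"tau_f ({fit_f.tau:.1f} ms) >= tau_e ({fit_e.tau:.1f} ms): "
            "no decay acceleration on Na/Ca restoration"
        )
    return (
        {"tau_e": fit_e.tau, "tau_f": fit_f.tau, "ncx_rate": 1.0 / fit_f.tau - 1.0 / fit_e.tau},
        diag,
    )


def fractional_release(
    cat_amplitude: float, sr_content: float, convention: str = "amp_over_sr"
) -> float:
    """Fractional SR release per twitch.

    ``amp_over_sr`` (default) is the standard physiological definition —
    the fraction of the SR content released per beat; ``sr_over_amp`` is the
    inverse reading.  The convention is always recorded by the pipeline.
    """
    if cat_amplitude <= 0 or sr_content <= 0:
        raise ValueError("both amplitudes must be > 0")
    if convention == "amp_over_sr":
        return cat_amplitude / sr_content
    if convention == "sr_over_amp":
        return sr_content / cat_amplitude
    raise ValueError("convention must be 'amp_over_sr' or 'sr_over_amp'")


@dataclass
class FluxEstimates:
    """Derived leak/content/pump quantities with per-epoch diagnostics."""

    cat_amplitude: float | None = None
    ryr_leak: float | None = None
    sr_content: float | None = None
    serca_tau: float | None = None
    serca_rate: float | None = None
    twitch_tau: float | None = None
    pmca_slope: float | None = None
    ncx_tau_e: float | None = None
    ncx_tau_f: float | None = None
    ncx_rate: float | None = None
    fractional_release: float | None = None
    fractional_release_convention: str = "amp_over_sr"
    serca_mode: str = "literal"
    errors: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    fit_diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            out[k] = v if not isinstance(v, dict) else dict(v)
        return out


def run_flux_pipeline(
    trace: FluxProtocolTrace,
    protocol: ProtocolDefinition,
    serca_mode: str = "literal",
    fractional_convention: str = "amp_over_sr",
) -> FluxEstimates:
    """Execute epochs a-f in order and assemble all flux estimates.

    Per-epoch failures are recorded in ``errors`` and the remaining
    estimates are still produced; only an unusable trace/protocol aborts.
    """
    out = FluxEstimates(serca_mode=serca_mode, fractional_release_convention=fractional_convention)

    try:
        segs = segment_epochs(trace, protocol)
    except ProtocolError:
        # allow a truncated trace: keep whatever epochs are fully covered
        segs = {}
        for e in protocol.epochs:
            if e.end <= trace.time[-1] + trace.dt + 1e-9:
                mask = (trace.time >= e.start - 1e-9) & (trace.time < e.end - 1e-9)
                segs[e.label] = (trace.time[mask], trace.values[mask])
            else:
                out.errors[e.label] = "epoch extends beyond the recorded trace"

    def _attempt(label, fn):
        if label not in segs:
            out.errors.setdefault(label, "epoch missing from trace")
            return None
        try:
            return fn()
        except (ProtocolError, FitDegenerateError, ValueError) as exc:
            out.errors[label] = str(exc)
            return None

    res = _attempt("a", lambda: _cat_amplitude(segs["a"], protocol.stim_times, trace.dt))
    if res is not None:
        out.cat_amplitude, diag = res
        out.fit_diagnostics["a"] = diag.__dict__

    res = _attempt("b", lambda: estimate_ryr_leak(segs["b"], protocol.tetracaine_time))
    if res is not None:
        out.ryr_leak, diag = res
        if diag.warnings:
            out.warnings["b"] = diag.warnings
        out.fit_diagnostics["b"] = diag.__dict__

    caf1 = protocol.caffeine_times[0] if protocol.caffeine_times else None
    res = _attempt("c", lambda: estimate_sr_content(segs["c"], caf1))
    if res is not None:
        out.sr_content, diag = res
        out.fit_diagnostics["c"] = diag.__dict__

    res = _attempt(
        "d", lambda: estimate_serca(segs.get("a"), segs["d"], protocol.stim_times, serca_mode)
    )
    if res is not None:
        vals, diag = res
        out.serca_tau = vals["serca_tau"]
        out.serca_rate = vals.get("serca_rate")
        out.twitch_tau = vals.get("twitch_tau")
        out.fit_diagnostics["d"] = diag.__dict__

    res = _attempt("e", lambda: estimate_pmca(segs["e"]))
    if res is not None:
        out.pmca_slope, diag = res
        out.fit_diagnostics["e"] = diag.__dict__

    def _ncx():
        if "e" not in segs:
            raise ProtocolError("epoch e required for the NCX rate difference")
        return estimate_ncx(segs["e"], segs["f"])

    res = _attempt("f", _ncx)
    if res is not None:
        vals, diag = res
        out.ncx_tau_e, out.ncx_tau_f = vals["tau_e"], vals["tau_f"]
        out.ncx_rate = vals["ncx_rate"]
        if diag.warnings:
            out.warnings["f"] = diag.warnings
        out.fit_diagnostics["f"] = diag.__dict__

    if out.cat_amplitude is not None and out.sr_content is not None:
        try:
            out.fractional_release = fractional_release(
                out.cat_amplitude, out.sr_content, fractional_convention
            )
            if fractional_convention == "amp_over_sr" and out.fractional_release > 1:
                out.warnings.setdefault("fractional_release", []).append(
                    "fractional release > 1; check amplitude/content estimates"
                )
        except ValueError as exc:
            out.errors["fractional_release"] = str(exc)

    return out
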
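"""Reading, writing and F/F0 normalization of confocal line-scan recordings.

A line-scan repeatedly samples one spatial line of a cell, producing a
position x time fluorescence image.  Everything downstream uses the fixed
axis convention established here: axis 0 is the spatial pixel, axis 1 is the
time sample, indices are 0-based and time is in milliseconds from the first
sample.  Physical calibration (pixel pitch in um, line interval in ms) must
always be explicit; it is read from a JSON sidecar or passed as overrides,
never guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "LineScanRecording",
    "NormalizedRecording",
    "Baseline",
    "CalibrationError",
    "BaselineError",
    "read_linescan",
    "write_linescan",
    "estimate_baseline",
    "normalize",
    "write_normalized",
]

MIN_PIXELS = 8
MIN_SAMPLES = 50

# sidecar JSON keys
_CALIB_KEYS = ("pixel_pitch_um", "line_interval_ms", "stim_times_ms")


class CalibrationError(ValueError):
    """Missing or invalid physical calibration / unusable image layout."""


class BaselineError(ValueError):
    """Baseline window invalid or estimated F0 not strictly positive."""


def _validate_grid(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise CalibrationError(
            f"expected a 2-D position x time grid, got {values.ndim}-D data"
        )
    if values.shape[0] < MIN_PIXELS or values.shape[1] < MIN_SAMPLES:
        raise CalibrationError(
            f"grid {values.shape} too small: need >= {MIN_PIXELS} pixels and "
            f">= {MIN_SAMPLES} time samples"
        )
    if not np.all(np.isfinite(values)):
        raise CalibrationError("fluorescence grid contains non-finite values")
    if np.any(values < 0):
        raise CalibrationError("fluorescence intensities must be non-negative")
    return values


@dataclass(frozen=True)
class LineScanRecording:
    """Raw fluorescence line-scan with physical calibration.

    Attributes
    ----------
    values : ndarray, shape (n_pixels, n_samples)
        Non-negative fluorescence intensities.
    pixel_pitch : float
        Spatial sampling along the scan line, um per pixel.
    line_interval : float
        Temporal sampling, ms per line.
    stim_times : tuple of float or None
        Field-stimulation times in ms from the first sample.
    source_id : str
        Free-text provenance label.
    """

    values: np.ndarray
    pixel_pitch: float
    line_interval: float
    stim_times: tuple | None = None
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", _validate_grid(self.values))
        if not (self.pixel_pitch > 0):
            raise CalibrationError("pixel_pitch must be > 0 (um per pixel)")
        if not (self.line_interval > 0):
            raise CalibrationError("line_interval must be > 0 (ms per sample)")
        if self.stim_times is not None:
            st = tuple(float(t) for t in self.stim_times)
            if len(st) == 0:
                st = None
            else:
                if np.any(np.diff(st) <= 0):
                    raise CalibrationError("stim_times must be strictly increasing")
                if st[0] < 0 or st[-1] >= self.duration:
                    raise CalibrationError(
                        "stim_times must fall within the recording duration"
                    )
            object.__setattr__(self, "stim_times", st)

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in ms."""
        return self.n_samples * self.line_interval

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in ms from the first line."""
        return np.arange(self.n_samples) * self.line_interval


@dataclass(frozen=True)
class Baseline:
    """Per-pixel baseline fluorescence F0 and a record of how it was made.

    ``f0`` has shape (n_pixels,) for a constant baseline or
    (n_pixels, n_samples) when a linear photobleach detrend was requested.
    """

    f0: np.ndarray
    method: str

    def __post_init__(self):
        f0 = np.asarray(self.f0, dtype=float)
        if np.any(f0 <= 0) or not np.all(np.isfinite(f0)):
            raise BaselineError("baseline F0 must be finite and strictly positive")
        object.__setattr__(self, "f0", f0)


@dataclass(frozen=True)
class NormalizedRecording:
    """F/F0-normalized line-scan; carries the source calibration unchanged."""

    ratio: np.ndarray
    f0: np.ndarray
    baseline_method: str
    pixel_pitch: float
    line_interval: float
    stim_times: tuple | None = None
    source_id: str = ""

    def __post_init__(self):
        ratio = np.asarray(self.ratio, dtype=float)
        if ratio.ndim != 2:
            raise ValueError("ratio must be a 2-D pixel x time grid")
        if not np.all(np.isfinite(ratio)):
            raise ValueError("ratio must be finite everywhere")
        object.__setattr__(self, "ratio", ratio)

    @property
    def n_pixels(self) -> int:
        return self.ratio.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ratio.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.line_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.line_interval


# ---------------------------------------------------------------------------
# reading / writing


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists() and sidecar != path:
        with open(sidecar) as fh:
            data = json.load(fh)
        return {k: data[k] for k in _CALIB_KEYS if k in data}
    return {}


def _read_grid(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise CalibrationError(
                f"{path.name}: expected a single-plane grayscale image, "
                f"got shape {arr.shape} (multi-channel or stack)"
            )
        return np.asarray(arr, dtype=float)
    # delimited text grid; autodetect comma vs whitespace/tab
    try:
        with open(path) as fh:
            first = fh.readline()
        delim = "," if "," in first else None
        return np.loadtxt(path, delimiter=delim, dtype=float)
    except OSError:
        raise
    except Exception as exc:  # malformed text
        raise CalibrationError(f"could not parse {path} as a 2-D grid: {exc}") from exc


def read_linescan(
    path,
    *,
    pixel_pitch: float | None = None,
    line_interval: float | None = None,
    stim_times=None,
    time_axis: int | None = None,
    source_id: str | None = None,
) -> LineScanRecording:
    """Read a line-scan from a single-plane TIFF or a delimited text grid.

    Calibration is resolved in priority order: explicit keyword overrides,
    then a JSON sidecar (``<stem>.json`` with keys ``pixel_pitch_um``,
    ``line_interval_ms``, ``stim_times_ms``).  Missing calibration raises
    :class:`CalibrationError`.

    Orientation: axis 0 must be position and axis 1 time.  By default the
    longer axis is taken to be time; pass ``time_axis=0`` or ``1`` to force.
    """
    path = Path(path)
    grid = _read_grid(path)
    sidecar = _load_sidecar(path)

    if pixel_pitch is None:
        pixel_pitch = sidecar.get("pixel_pitch_um")
    if line_interval is None:
        line_interval = sidecar.get("line_interval_ms")
    if stim_times is None:
        stim_times = sidecar.get("stim_times_ms")
    if pixel_pitch is None or line_interval is None:
        raise CalibrationError(
            f"{path.name}: pixel_pitch/line_interval not in metadata; supply "
            "overrides or a JSON sidecar with pixel_pitch_um / line_interval_ms"
        )

    if time_axis is None:
        time_axis = 0 if grid.shape[0] > grid.shape[1] else 1
    if time_axis not in (0, 1):
        raise CalibrationError("time_axis must be 0 or 1")
    if time_axis == 0:
        grid = grid.T

    return LineScanRecording(
        values=grid,
        pixel_pitch=float(pixel_pitch),
        line_interval=float(line_interval),
        stim_times=tuple(stim_times) if stim_times is not None else None,
        source_id=source_id if source_id is not None else path.name,
    )


def write_linescan(rec: LineScanRecording, path, *, dtype=None) -> Path:
    """Write the raw grid as a TIFF (with a calibration sidecar JSON).

    Integer ``dtype`` round-trips bit-exactly when the data are integral.
    """
    path = Path(path)
    data = rec.values
    if dtype is not None:
        data = data.astype(dtype)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_pitch_um": rec.pixel_pitch,
        "line_interval_ms": rec.line_interval,
    }
    if rec.stim_times is not None:
        sidecar["stim_times_ms"] = list(rec.stim_times)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# baseline and normalization


def estimate_baseline(
    rec: LineScanRecording,
    window: tuple | None = None,
    percentile: float = 0.10,
    detrend: bool = False,
) -> Baseline:
    """Estimate per-pixel baseline fluorescence F0.

    With an explicit quiescent ``window`` (``(start_ms, end_ms)``, half-open)
    F0 is the per-pixel mean over that window.  Without one, F0 falls back to
    the per-pixel lower ``percentile`` (default 10th percentile) of the whole
    trace — a deliberately simple convention that is slightly biased low in
    the presence of noise (documented; prefer an explicit window when the
    protocol has a pre-stimulus quiescent period).

    ``detrend=True`` additionally fits a per-pixel linear photobleach trend
    to the below-percentile samples and returns a time-varying F0 grid.
    """
    values = rec.values
    dt = rec.line_interval
    if window is not None:
        t0, t1 = float(window[0]), float(window[1])
        i0 = max(0, int(np.ceil(t0 / dt)))
        i1 = min(rec.n_samples, int(np.ceil(t1 / dt)))
        if i1 - i0 < 5:
            raise BaselineError(
                f"baseline window [{t0}, {t1}) ms spans {i1 - i0} samples; need >= 5"
            )
        f0 = values[:, i0:i1].mean(axis=1)
        method = f"window_mean[{t0:g},{t1:g})ms"
    else:
        if not (0 < percentile < 1):
            raise BaselineError("percentile must be in (0, 1)")
        f0 = np.quantile(values, percentile, axis=1)
        method = f"percentile_{percentile:g}"

    if np.any(f0 <= 0):
        raise BaselineError(
            f"{int(np.sum(f0 <= 0))} pixel(s) produced F0 <= 0; "
            "check background subtraction / window choice"
        )

    if detrend:
        # linear trend through the quiescent (below-percentile) samples
        t = rec.times
        thresh = np.quantile(values, max(percentile, 0.25), axis=1)
        f0t = np.empty_like(values)
        for i in range(rec.n_pixels):
            quiet = values[i] <= thresh[i]
            if quiet.sum() < 5:
                f0t[i] = f0[i]
                continue
            coef = np.polyfit(t[quiet], values[i, quiet], 1)
            f0t[i] = np.polyval(coef, t)
        if np.any(f0t <= 0):
            raise BaselineError("linear detrend produced nonpositive F0")
        return Baseline(f0=f0t, method=method + "+linear_detrend")

    return Baseline(f0=f0, method=method)


def normalize(rec: LineScanRecording, baseline) -> NormalizedRecording:
    """Divide the raw grid by per-pixel F0 to give F/F0.

    ``baseline`` may be a :class:`Baseline` or a bare array of shape
    (n_pixels,) or (n_pixels, n_samples).
    """
    if isinstance(baseline, Baseline):
        f0, method = baseline.f0, baseline.method
    else:
        f0 = np.asarray(baseline, dtype=float)
        method = "user_supplied"
    if f0.ndim == 1:
        if f0.shape[0] != rec.n_pixels:
            raise ValueError(
                f"f0 length {f0.shape[0]} does not match pixel axis {rec.n_pixels}"
            )
        denom = f0[:, None]
    elif f0.shape == rec.values.shape:
        denom = f0
    else:
        raise ValueError(f"f0 shape {f0.shape} incompatible with grid {rec.values.shape}")
    if np.any(f0 <= 0):
        raise BaselineError("f0 must be strictly positive")

    return NormalizedRecording(
        ratio=rec.values / denom,
        f0=f0,
        baseline_method=method,
        pixel_pitch=rec.pixel_pitch,
        line_interval=rec.line_interval,
        stim_times=rec.stim_times,
        source_id=rec.source_id,
    )


def write_normalized(norm: NormalizedRecording, path) -> Path:
    """Write F/F0 as 32-bit float TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, norm.ratio.astype(np.float32))
    meta = {
        "pixel_pitch_um": norm.pixel_pitch,
        "line_interval_ms": norm.line_interval,
        "baseline_method": norm.baseline_method,
        "source_id": norm.source_id,
    }
    if norm.stim_times is not None:
        meta["stim_times_ms"] = list(norm.stim_times)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path
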
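import numpy as np
import pytest

from catsigma import LineScanSimConfig, NormalizedRecording, normalize, simulate_linescan


def make_norm(ratio, line_interval=2.0, pixel_pitch=0.397, stim_times=None):
    """Wrap a plain F/F0 array as a NormalizedRecording."""
    ratio = np.asarray(ratio, dtype=float)
    return NormalizedRecording(
        ratio=ratio,
        f0=np.ones(ratio.shape[0]),
        baseline_method="test",
        pixel_pitch=pixel_pitch,
        line_interval=line_interval,
        stim_times=stim_times,
    )


def simulate_norm(**kwargs):
    """Simulated recording normalized by its true baseline."""
    cfg = LineScanSimConfig(**kwargs)
    rec, truth = simulate_linescan(cfg)
    norm = normalize(rec, np.full(cfg.n_pixels, cfg.baseline_f0))
    return norm, truth, cfg


def triangle(n, start, peak_idx, end, height):
    """Triangular pulse on a zero baseline, as a float array of length n."""
    y = np.zeros(n)
    up = np.arange(start, peak_idx + 1)
    y[up] = height * (up - start) / max(peak_idx - start, 1)
    down = np.arange(peak_idx, end + 1)
    y[down] = height * (end - down) / max(end - peak_idx, 1)
    return y


@pytest.fixture
def default_sim():
    return simulate_norm(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
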
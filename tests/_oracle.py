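"""Independent straight-line re-implementation of the sigma statistics.

Plain Python loops and ``math`` only — no code shared with the package —
mirroring the documented measurement definitions step by step.  Used to
verify the vectorized implementation on small grids to 1e-9.
"""

import math

BASELINE_PRE_MS = 50.0
ONSET_FRACTION = 0.10
RECOVERY = 0.66


def _mean(xs):
    return sum(xs) / len(xs)


def _pop_sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def _sample_sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def c4(k):
    return math.sqrt(2.0 / (k - 1)) * math.gamma(k / 2) / math.gamma((k - 1) / 2)


def _boxcar(y, w):
    if w <= 1:
        return list(y)
    h = (w - 1) // 2
    n = len(y)
    out = []
    for j in range(n):
        acc = 0.0
        for o in range(j - h, j + h + 1):
            acc += y[min(max(o, 0), n - 1)]
        out.append(acc / w)
    return out


def _parabola(ym, y0, yp):
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < 1e-30:
        return 0.0
    return min(0.5, max(-0.5, 0.5 * (ym - yp) / denom))


def _argmax(xs):
    best, bi = xs[0], 0
    for i, v in enumerate(xs):
        if v > best:
            best, bi = v, i
    return bi


def extract(ratio, dt, window, min_amp_snr=3.0, smooth_ms=10.0, max_lag_ms=150.0):
    """Per-pixel time-to-peak / decay / amplitude / validity for one frame.

    ``ratio`` is a list of per-pixel lists (pixel-major).  Returns a dict.
    """
    n_total = len(ratio[0])
    t0, t1 = float(window[0]), float(window[1])
    i0 = max(0, math.ceil(t0 / dt - 1e-9))
    i1 = min(n_total, math.ceil(t1 / dt - 1e-9))
    ctx = int(round(BASELINE_PRE_MS / dt))
    ib0 = max(0, i0 - ctx)
    w0 = i0 - ib0
    sub = [row[ib0:i1] for row in ratio]
    n_pix, n = len(sub), i1 - ib0
    t = [(ib0 + j) * dt for j in range(n)]

    w = max(1, int(round(smooth_ms / dt)))
    if w % 2 == 0:
        w += 1

    g = [_mean([sub[p][j] for p in range(n_pix)]) for j in range(n)]
    gs = _boxcar(g, w)
    gpk = w0 + _argmax(gs[w0:])
    gb0 = min(gs[: gpk + 1])
    amp0 = gs[gpk] - gb0

    level = gb0 + ONSET_FRACTION * amp0
    onset_t = t[0]
    for j in range(gpk, 0, -1):
        if gs[j - 1] < level <= gs[j]:
            onset_t = t[j - 1] + (level - gs[j - 1]) / (gs[j] - gs[j - 1]) * dt
            break

    b0 = max(t[0], onset_t - BASELINE_PRE_MS)
    bidx = [j for j in range(n) if b0 <= t[j] < onset_t]
    if not bidx:
        bidx = [0]

    g_base = _mean([g[j] for j in bidx])
    tmpl = [v - g_base for v in gs]
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
    tmpl = [tmpl[j] if lo_s <= j <= hi_s else 0.0 for j in range(n)]

    g_delta = 0.0 if gpk in (0, n - 1) else _parabola(gs[gpk - 1], gs[gpk], gs[gpk + 1])
    g_peak_time = t[gpk] + g_delta * dt
    g_amp = gs[gpk] - g_base

    max_lag = max(1, int(round(max_lag_ms / dt)))

    tp = [float("nan")] * n_pix
    decay = [float("nan")] * n_pix
    amp = [0.0] * n_pix
    valid = [False] * n_pix

    for p in range(n_pix):
        base_p0 = _mean([sub[p][j] for j in bidx])
        yb = [v - base_p0 for v in sub[p]]
        ybs = _boxcar(yb, w)
        if w > 1:
            resid = [yb[j] - ybs[j] for j in range(n)]
            noise = _pop_sd(resid) / math.sqrt(1.0 - 1.0 / w)
        else:
            noise = 0.0

        crow = []
        for lag in range(-max_lag, max_lag + 1):
            acc = 0.0
            for j in range(n):
                jj = j - lag
                if 0 <= jj < n:
                    acc += yb[j] * tmpl[jj]
            crow.append(acc)

        p_arg = _argmax(ybs)
        center = min(max(p_arg - gpk, -max_lag), max_lag)
        cmax = max(crow)
        tol = 1e-9 * max(1.0, abs(cmax))
        best = None
        for li, cv in enumerate(crow):
            if cv >= cmax - tol:
                lag = li - max_lag
                key = (abs(lag - center), lag)
                if best is None or key < best[0]:
                    best = (key, lag)
        lag = best[1]

        p_onset = onset_t + lag * dt
        pb0 = max(t[0], p_onset - BASELINE_PRE_MS)
        pbidx = [j for j in range(n) if pb0 <= t[j] < p_onset]
        base_p = _mean([sub[p][j] for j in pbidx]) if pbidx else base_p0
        shift = base_p0 - base_p
        amp_p = ybs[p_arg] + shift
        amp[p] = amp_p
        if amp_p <= 0 or amp_p < min_amp_snr * noise:
            continue
        valid[p] = True

        if -max_lag < lag < max_lag:
            delta = _parabola(
                crow[lag - 1 + max_lag], crow[lag + max_lag], crow[lag + 1 + max_lag]
            )
        else:
            delta = 0.0
        tp[p] = g_peak_time + (lag + delta) * dt - onset_t

        target = (1.0 - RECOVERY) * amp_p - shift
        for j in range(p_arg + 1, n):
            if ybs[j] <= target:
                if ybs[j] == ybs[j - 1]:
                    t_cross = t[j]
                else:
                    t_cross = t[j - 1] + (ybs[j - 1] - target) / (ybs[j - 1] - ybs[j]) * dt
                if t_cross - t[p_arg] > 0:
                    decay[p] = t_cross - t[p_arg]
                break

    return {
        "time_to_peak": tp,
        "decay": decay,
        "amplitude": amp,
        "valid": valid,
        "onset": onset_t,
        "global_amplitude": g_amp,
    }


def _vals(res, metric):
    key = "time_to_peak" if metric == "rise" else "decay"
    return [
        v for v, ok in zip(res[key], res["valid"]) if ok and not math.isnan(v)
    ]


def spatial_sigma(ratio, dt, window, metric="rise", **kw):
    return _pop_sd(_vals(extract(ratio, dt, window, **kw), metric))


def temporal_sigma(ratio, dt, windows, metric="rise", **kw):
    k = len(windows)
    results = [extract(ratio, dt, win, **kw) for win in windows]
    key = "time_to_peak" if metric == "rise" else "decay"
    n_pix = len(ratio)
    sds = []
    for p in range(n_pix):
        vals = [r[key][p] for r in results]
        if all(r["valid"][p] for r in results) and not any(math.isnan(v) for v in vals):
            sds.append(_sample_sd(vals) / c4(k))
    return _mean(sds)


def structural_sigma(ratio, dt, windows, metric="rise", **kw):
    n_total = len(ratio[0])
    slices = []
    for t0, t1 in windows:
        i0 = max(0, math.ceil(t0 / dt - 1e-9))
        i1 = min(n_total, math.ceil(t1 / dt - 1e-9))
        slices.append((i0, i1))
    lead = min(int(round(BASELINE_PRE_MS / dt)), min(i0 for i0, _ in slices))
    length = slices[0][1] - slices[0][0] + lead
    n_pix = len(ratio)
    mean_frame = []
    for p in range(n_pix):
        row = []
        for j in range(length):
            row.append(_mean([ratio[p][i0 - lead + j] for i0, _ in slices]))
        mean_frame.append(row)
    return _pop_sd(
        _vals(extract(mean_frame, dt, (lead * dt, length * dt), **kw), metric)
    )
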
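import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catsigma import (
    NoTransientError,
    analyze_dyssynchrony,
    extract_local_transients,
    local_amplitude_variability,
    simulate_linescan,
    spatial_sigma,
    structural_sigma,
    synchrony_efficiency,
    temporal_sigma,
)
from catsigma.dyssynchrony import AlignmentError, c4
from catsigma.simulate import LineScanSimConfig
from conftest import make_norm, simulate_norm, triangle
import _oracle


def _two_group_frame(n_pix=32, n=1000, dt=2.0, shift=5, amp=2.0):
    """Half the pixels peak `shift` samples later than the other half."""
    ratio = np.ones((n_pix, n))
    base = triangle(n, 100, 120, 250, amp)
    late = triangle(n, 100 + shift, 120 + shift, 250 + shift, amp)
    ratio[: n_pix // 2] += base
    ratio[n_pix // 2 :] += late
    return make_norm(ratio, line_interval=dt)


class TestExtract:
    def test_identical_pixels_zero_dispersion(self):
        norm, truth, cfg = simulate_norm(
            seed=0, structural_sd=0.0, beat_jitter_sd=0.0, gaussian_sd=0.0,
            amplitude_cv=0.0, n_beats=1,
        )
        m = extract_local_transients(norm, (200.0, 2200.0))
        assert m.n_valid == cfg.n_pixels
        assert np.ptp(m.time_to_peak) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(m.local_amplitude) == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_resolved(self):
        norm = _two_group_frame(shift=5)  # 10 ms apart at 2 ms sampling
        m = extract_local_transients(norm, (0.0, 2000.0))
        early = m.time_to_peak[:16]
        late = m.time_to_peak[16:]
        assert np.all(m.valid_mask)
        assert late.mean() - early.mean() == pytest.approx(10.0, abs=1.0)
        assert spatial_sigma(m) == pytest.approx(5.0, abs=0.5)

    def test_no_transient_raises(self):
        norm = make_norm(np.ones((16, 1000)) + 1e-4)
        with pytest.raises(NoTransientError):
            extract_local_transients(norm, (0.0, 2000.0))

    def test_latency_recovery_rmse(self):
        """Per-pixel time-to-peak RMSE < 2 ms against generator latencies
        (constant template-alignment offset removed) at SNR 10."""
        errs = []
        for seed in range(20):
            norm, truth, cfg = simulate_norm(
                seed=seed, n_beats=1, structural_sd=8.0, beat_jitter_sd=0.0,
                gaussian_sd=0.2,
            )
            m = extract_local_transients(norm, (200.0, 2200.0))
            tp_abs = m.time_to_peak + m.onset_time - 200.0
            err = tp_abs - truth.true_time_to_peak[:, 0]
            errs.append(err[m.valid_mask] - err[m.valid_mask].mean())
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse < 2.0

    def test_snr_mask_excludes_silent_pixels(self):
        norm, _, cfg = simulate_norm(seed=2, n_beats=1)
        ratio = norm.ratio.copy()
        ratio[:4] = 1.0 + np.random.default_rng(0).normal(0, 0.1, ratio[:4].shape)
        silent = make_norm(ratio, line_interval=cfg.line_interval)
        m = extract_local_transients(silent, (200.0, 2200.0))
        assert not m.valid_mask[:4].any()
        assert m.valid_mask[4:].all()


class TestSigmaStatistics:
    def test_equal_halves_give_five_ms(self):
        norm = _two_group_frame(shift=5)
        m = extract_local_transients(norm, (0.0, 2000.0))
        # population SD of {t, t+10} in equal halves is exactly 5
        assert spatial_sigma(m) == pytest.approx(5.0, abs=0.5)

    def test_min_valid_enforced(self):
        norm = _two_group_frame(n_pix=32)
        m = extract_local_transients(norm, (0.0, 2000.0))
        with pytest.raises(ValueError):
            spatial_sigma(m, min_valid=64)

    def test_masked_pixels_never_contribute(self):
        """Invalidated pixels are excluded: corrupting their entries leaves
        every sigma unchanged."""
        norm, _, _ = simulate_norm(seed=3, n_beats=1)
        m = extract_local_transients(norm, (200.0, 2200.0))
        import dataclasses
        mask = m.valid_mask.copy()
        mask[:10] = False
        tp = m.time_to_peak.copy()
        tp[:10] = 1e6
        corrupted = dataclasses.replace(m, valid_mask=mask, time_to_peak=tp)
        clean = dataclasses.replace(m, valid_mask=mask)
        assert spatial_sigma(corrupted) == spatial_sigma(clean)

    def test_temporal_needs_two_beats(self):
        norm, _, _ = simulate_norm(seed=1, n_beats=1)
        with pytest.raises(ValueError):
            temporal_sigma(norm, [(200.0, 2200.0)])

    def test_identical_beats_zero_temporal_sigma(self):
        norm, _, cfg = simulate_norm(
            seed=0, structural_sd=4.0, beat_jitter_sd=0.0, gaussian_sd=0.0,
        )
        wins = [(200.0 + 2000.0 * b, 2200.0 + 2000.0 * b) for b in range(5)]
        assert temporal_sigma(norm, wins) < cfg.line_interval

    def test_jitter_recovered_by_temporal_sigma(self):
        vals = []
        for seed in range(20):
            norm, _, _ = simulate_norm(seed=seed)
            wins = [(200.0 + 2000.0 * b, 2200.0 + 2000.0 * b) for b in range(5)]
            vals.append(temporal_sigma(norm, wins))
        assert np.mean(vals) == pytest.approx(6.0, rel=0.15)

    def test_structural_equals_spatial_without_jitter(self):
        norm, _, _ = simulate_norm(
            seed=5, structural_sd=8.0, beat_jitter_sd=0.0, gaussian_sd=0.0,
            amplitude_cv=0.0,
        )
        wins = [(200.0 + 2000.0 * b, 2200.0 + 2000.0 * b) for b in range(5)]
        st = structural_sigma(norm, wins)
        m = extract_local_transients(norm, wins[0])
        assert st == pytest.approx(spatial_sigma(m), abs=0.1)

    def test_structural_attenuates_jitter(self):
        """With zero structural offsets, frame averaging attenuates jitter:
        structural sigma falls well below single-beat spatial sigma and
        matches the noiseless-field oracle."""
        st_meas, st_oracle, sp = [], [], []
        for seed in range(10):
            norm, truth, cfg = simulate_norm(
                seed=seed, structural_sd=0.0, beat_jitter_sd=6.0,
            )
            wins = [(200.0 + 2000.0 * b, 2200.0 + 2000.0 * b) for b in range(5)]
            st_meas.append(structural_sigma(norm, wins))
            clean = make_norm(truth.noiseless_ratio, line_interval=cfg.line_interval)
            st_oracle.append(structural_sigma(clean, wins))
            m = extract_local_transients(norm, wins[0])
            sp.append(spatial_sigma(m))
        assert np.mean(st_meas) < 0.6 * np.mean(sp)
        assert np.mean(st_meas) == pytest.approx(np.mean(st_oracle), rel=0.15, abs=0.5)

    def test_alignment_error_on_unequal_windows(self):
        norm, _, _ = simulate_norm(seed=1)
        with pytest.raises(AlignmentError):
            structural_sigma(norm, [(200.0, 2200.0), (2200.0, 3200.0)])

    def test_c4_constant(self):
        assert c4(5) == pytest.approx(0.9400, abs=1e-4)


class TestSynchronyEfficiency:
    def test_perfectly_synchronous_is_one(self):
        norm, _, _ = simulate_norm(
            seed=0, structural_sd=0.0, beat_jitter_sd=0.0, gaussian_sd=0.0,
            amplitude_cv=0.0, n_beats=1,
        )
        assert synchrony_efficiency(norm, (200.0, 2200.0)) == pytest.approx(1.0, abs=1e-9)

    def test_non_overlapping_populations_half(self):
        """Two equal-amplitude populations firing at disjoint times: the
        spatial mean peaks at half the local peak."""
        n = 1000
        ratio = np.ones((32, n))
        ratio[:16] += triangle(n, 100, 130, 200, 2.0)
        ratio[16:] += triangle(n, 300, 330, 400, 2.0)
        norm = make_norm(ratio)
        eff = synchrony_efficiency(norm, (0.0, 2000.0), max_lag_ms=600.0)
        assert eff == pytest.approx(0.5, abs=1e-3)

    def test_monotone_in_structural_dispersion(self):
        means = []
        for sd in (0.0, 10.0, 30.0):
            vals = []
            for seed in range(10):
                norm, _, _ = simulate_norm(seed=seed, structural_sd=sd, n_beats=1)
                vals.append(synchrony_efficiency(norm, (200.0, 2200.0)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestAmplitudeVariability:
    def test_uniform_amplitudes_zero_cv(self):
        norm, _, _ = simulate_norm(
            seed=0, structural_sd=0.0, beat_jitter_sd=0.0, gaussian_sd=0.0,
            amplitude_cv=0.0, n_beats=1,
        )
        m = extract_local_transients(norm, (200.0, 2200.0))
        assert local_amplitude_variability(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_level_amplitudes(self):
        n = 1000
        ratio = np.ones((32, n))
        ratio[:16] += triangle(n, 100, 130, 250, 1.0)
        ratio[16:] += triangle(n, 100, 130, 250, 3.0)
        m = extract_local_transients(make_norm(ratio), (0.0, 2000.0))
        assert local_amplitude_variability(m) == pytest.approx(0.5, abs=0.01)

    def test_generator_cv_recovered(self):
        vals = []
        for seed in range(20):
            norm, _, _ = simulate_norm(seed=seed, n_beats=1, amplitude_cv=0.2)
            m = extract_local_transients(norm, (200.0, 2200.0))
            vals.append(local_amplitude_variability(m))
        assert np.mean(vals) == pytest.approx(0.2, rel=0.15)


class TestInvariances:
    @settings(max_examples=10, deadline=None)
    @given(
        shift_samples=st.integers(min_value=0, max_value=200),
        scale=st.floats(min_value=0.25, max_value=4.0),
    )
    def test_sigma_invariant_to_time_shift_and_gain(self, shift_samples, scale):
        """Sigma statistics do not change under a global time shift of the
        recording or a positive gain applied to the raw fluorescence."""
        cfg = LineScanSimConfig(seed=9, n_beats=1)
        rec, _ = simulate_linescan(cfg)
        f0 = np.full(cfg.n_pixels, cfg.baseline_f0)

        from catsigma import normalize
        base_norm = normalize(rec, f0)
        m0 = extract_local_transients(base_norm, (200.0, 2200.0))
        ref = spatial_sigma(m0)

        # gain on raw fluorescence with matching f0 leaves F/F0 unchanged
        from catsigma import LineScanRecording
        scaled = LineScanRecording(rec.values * scale, rec.pixel_pitch,
                                   rec.line_interval, rec.stim_times)
        norm_s = normalize(scaled, f0 * scale)
        m1 = extract_local_transients(norm_s, (200.0, 2200.0))
        assert spatial_sigma(m1) == pytest.approx(ref, rel=1e-9)

        # integer-sample time shift with shifted window
        pad = np.ones((cfg.n_pixels, shift_samples))
        shifted = make_norm(
            np.hstack([pad, base_norm.ratio]), line_interval=cfg.line_interval
        )
        off = shift_samples * cfg.line_interval
        m2 = extract_local_transients(shifted, (200.0 + off, 2200.0 + off))
        assert spatial_sigma(m2) == pytest.approx(ref, rel=1e-9)


class TestOracleEquivalence:
    """The vectorized implementation must agree with an independent
    straight-line re-implementation on small grids to 1e-9."""

    @pytest.mark.parametrize("kwargs", [
        dict(seed=0, n_pixels=8, n_beats=3, structural_sd=8.0, beat_jitter_sd=6.0),
        dict(seed=1, n_pixels=8, n_beats=3, gaussian_sd=0.0, amplitude_cv=0.0),
        dict(seed=2, n_pixels=8, n_beats=2, structural_sd=0.0, gaussian_sd=0.2),
    ])
    def test_all_sigmas_match_oracle(self, kwargs):
        norm, _, cfg = simulate_norm(pacing_interval=1000.0, **kwargs)
        wins = [(200.0 + 1000.0 * b, 1200.0 + 1000.0 * b) for b in range(cfg.n_beats)]
        ratio_lists = [list(map(float, row)) for row in norm.ratio]
        dt = cfg.line_interval

        m = extract_local_transients(norm, wins[0])
        for metric in ("rise", "decay"):
            mine = spatial_sigma(m, metric, min_valid=4)
            oracle = _oracle.spatial_sigma(ratio_lists, dt, wins[0], metric)
            assert mine == pytest.approx(oracle, abs=1e-9)

            mine_t = temporal_sigma(norm, wins, metric, min_valid=4)
            oracle_t = _oracle.temporal_sigma(ratio_lists, dt, wins, metric)
            assert mine_t == pytest.approx(oracle_t, abs=1e-9)

            mine_s = structural_sigma(norm, wins, metric, min_valid=4)
            oracle_s = _oracle.structural_sigma(ratio_lists, dt, wins, metric)
            assert mine_s == pytest.approx(oracle_s, abs=1e-9)


class TestAnalyzeCell:
    def test_full_result_fields(self, default_sim):
        norm, truth, cfg = default_sim
        res = analyze_dyssynchrony(norm)
        d = res.to_dict()
        assert res.n_beats_used == 5
        for key in ("spatial_sigma_rise", "temporal_sigma_rise",
                    "structural_sigma_rise", "synchrony_efficiency",
                    "local_amplitude_cv"):
            assert d[key] is not None and d[key] >= 0
        assert res.synchrony_efficiency <= 1.05
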
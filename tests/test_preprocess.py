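"""Preprocessing: onset rule, spline baseline removal, QRS detection,
segmentation, median template, alignment."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alternans import (BaselineSpec, EcgTracing, Fiducials, PipelineConfig,
                       TwaPattern, align_twaves, detect_qrs, median_template,
                       preprocess_tracing, remove_baseline, segment_twaves,
                       simulate_tracing, t_wave_onset)

FS = 500


class TestOnsetRule:
    @pytest.mark.parametrize("rr,expected", [(700.0, 74.4), (400.0, 66.0)])
    def test_values(self, rr, expected):
        assert t_wave_onset(rr) == pytest.approx(expected, abs=0.05)

    def test_short_rr_limit(self):
        assert t_wave_onset(1e-9) == pytest.approx(40.0, abs=1e-3)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            t_wave_onset(0.0)

    @given(st.floats(min_value=200.0, max_value=2000.0),
           st.floats(min_value=1.0, max_value=500.0))
    @settings(deadline=None)
    def test_strictly_increasing_in_rr(self, rr, delta):
        assert t_wave_onset(rr + delta) > t_wave_onset(rr)


class TestBaselineRemoval:
    def test_exact_at_knots_and_no_op_without_baseline(self, quiescent):
        tracing, truth = quiescent
        out = remove_baseline(tracing, truth.fiducials)
        assert np.allclose(out.samples, tracing.samples, atol=1e-9)

    def test_sinusoid_interpolated_exactly_at_knots(self, template):
        tracing, truth = simulate_tracing(template, TwaPattern(kind="none"),
                                          BaselineSpec(0.1, 0.30))
        cfg = PipelineConfig()
        out = remove_baseline(tracing, truth.fiducials, cfg.knot_offsets_ms)
        offs = np.round(np.asarray(cfg.knot_offsets_ms) / 1000 * FS).astype(int)
        knots = (truth.fiducials.qrs_sample[:, None] + offs).ravel()
        knots = knots[(knots >= 0) & (knots < tracing.length_samples)]
        clean, _ = simulate_tracing(template, TwaPattern(kind="none"))
        assert np.allclose(out.samples[knots], clean.samples[knots], atol=1e-8)

    @pytest.mark.parametrize("freq,tol_uv", [(0.30, 5.0), (1.50, 12.0)])
    def test_residual_in_t_windows_below_tolerance(self, template, freq, tol_uv):
        """Residual wander inside the analysis windows after spline removal
        stays below the documented tolerance: 5 µV at respiratory rates, and
        the T-gap interpolation bound (~8 µV) at 1.5 Hz."""
        tracing, truth = simulate_tracing(template, TwaPattern(kind="none"),
                                          BaselineSpec(0.1, freq))
        out = remove_baseline(tracing, truth.fiducials)
        clean, _ = simulate_tracing(template, TwaPattern(kind="none"))
        resid = out.samples - clean.samples
        mat = segment_twaves(EcgTracing(resid, FS), truth.fiducials)
        assert np.abs(mat.waves).max() < tol_uv

    def test_too_few_beats_rejected(self, quiescent):
        tracing, truth = quiescent
        fid = Fiducials(truth.fiducials.qrs_sample[:2], truth.fiducials.rr_ms[:2])
        with pytest.raises(ValueError, match="at least 3"):
            remove_baseline(tracing, fid)


class TestQrsDetection:
    def test_finds_all_beats_near_truth(self, template):
        tracing, truth = simulate_tracing(template, TwaPattern(kind="none"),
                                          BaselineSpec(0.1, 0.30))
        fid = detect_qrs(tracing)
        assert fid.n_beats == 128
        err_ms = np.abs(fid.qrs_sample - truth.fiducials.qrs_sample) / FS * 1000
        assert err_ms.max() <= 10.0

    def test_translation_equivariance(self, quiescent):
        tracing, _ = quiescent
        shifted = EcgTracing(np.concatenate([np.zeros(100), tracing.samples]), FS)
        a = detect_qrs(tracing)
        b = detect_qrs(shifted)
        assert np.array_equal(b.qrs_sample, a.qrs_sample + 100)

    def test_flatline_rejected(self):
        with pytest.raises(ValueError, match="no beats"):
            detect_qrs(EcgTracing(np.zeros(5000), FS))


class TestSegmentation:
    def test_window_geometry(self, stationary50):
        tracing, truth = stationary50
        mat = segment_twaves(tracing, truth.fiducials)
        assert mat.waves.shape == (128, 150)  # 300 ms at 500 Hz
        # RR=700 ms: onset 74.4 ms -> 37 samples after the fiducial
        assert np.all(mat.start_sample - truth.fiducials.qrs_sample == 37)

    def test_identical_beats_identical_rows(self, quiescent):
        tracing, truth = quiescent
        mat = segment_twaves(tracing, truth.fiducials)
        assert np.array_equal(mat.waves, np.tile(mat.waves[0], (128, 1)))

    def test_truncated_last_beat_dropped(self, quiescent):
        tracing, truth = quiescent
        short = EcgTracing(tracing.samples[:-200], FS)
        mat = segment_twaves(short, truth.fiducials)
        assert mat.n_beats == 127
        assert mat.beat_index[-1] == 126


class TestMedianTemplate:
    def test_identity_and_robustness(self):
        row = np.arange(5.0)
        assert np.array_equal(median_template(np.tile(row, (4, 1))), row)
        stack = np.vstack([np.zeros(5), np.zeros(5), np.ones(5)])
        assert np.array_equal(median_template(stack), np.zeros(5))
        with_outlier = np.vstack([row, row, row + 1000.0])
        assert np.array_equal(median_template(with_outlier), row)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_template(np.empty((0, 5)))


class TestAlignment:
    def test_already_aligned_gives_zero_shifts(self, stationary50):
        tracing, truth = stationary50
        mat = segment_twaves(tracing, truth.fiducials)
        out = align_twaves(tracing, mat)
        assert not np.any(out.shift_samples)
        assert np.array_equal(out.waves, mat.waves)

    def test_recovers_injected_fiducial_jitter(self, stationary50):
        """A window extracted 10 ms late is pulled back by exactly -10 ms."""
        tracing, truth = stationary50
        qrs = truth.fiducials.qrs_sample.copy()
        qrs[5] += 5  # +10 ms
        mat = segment_twaves(tracing, Fiducials.from_samples(qrs, FS))
        out = align_twaves(tracing, mat)
        assert out.shift_samples[5] == -5
        clean = segment_twaves(tracing, truth.fiducials)
        assert np.array_equal(out.waves, clean.waves)

    def test_tie_break_prefers_zero_shift(self):
        # constant tracing: every shift correlates equally -> shift 0 wins
        tracing = EcgTracing(np.ones(4000), FS)
        fid = Fiducials.from_samples(np.arange(4, dtype=int) * 800 + 200, FS)
        mat = segment_twaves(tracing, fid)
        out = align_twaves(tracing, mat)
        assert not np.any(out.shift_samples)

    def test_shifts_bounded(self, template):
        tracing, truth = simulate_tracing(template, TwaPattern(kind="none"),
                                          BaselineSpec(0.1, 1.50))
        mat = segment_twaves(tracing, truth.fiducials)
        out = align_twaves(tracing, mat, align_ms=30.0)
        assert np.abs(out.shift_samples).max() <= 15


class TestFullChain:
    def test_exact_recovery_on_clean_input(self, stationary50, study_cfg):
        """On clean simulator output the preprocessed rows equal the true
        injected T-wave windows sample for sample."""
        tracing, truth = stationary50
        mat, _ = preprocess_tracing(tracing, study_cfg, truth.fiducials)
        direct = segment_twaves(tracing, truth.fiducials)
        assert np.allclose(mat.waves, direct.waves, atol=1e-12)
        assert mat.template is not None and len(mat.template) == 150
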
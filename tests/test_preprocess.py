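import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedgca import preprocess as pp
from seedgca.preprocess import (
    MotionTrace,
    PreprocessConfig,
    TimeSeries,
    bandpass_filter,
    detrend_linear,
    discard_initial,
    extract_mean_series,
    motion_exclusion,
    motion_summary,
    preprocess_voxelwise,
    regress_nuisance,
    smooth_gaussian,
)


class TestDiscardInitial:
    def test_drops_dummy_volumes(self):
        vol = np.random.default_rng(0).standard_normal((4, 4, 2, 205))
        out = discard_initial(vol, 5)
        assert out.shape == (4, 4, 2, 200)
        np.testing.assert_array_equal(out, vol[..., 5:])

    def test_zero_is_identity(self):
        vol = np.zeros((2, 2, 2, 10))
        np.testing.assert_array_equal(discard_initial(vol, 0), vol)

    def test_rejects_discarding_everything(self):
        with pytest.raises(ValueError):
            discard_initial(np.zeros((2, 2, 2, 10)), 10)


class TestMotionSummary:
    def test_constant_trace_is_zero(self):
        trace = MotionTrace(np.ones((5, 3)) * 2.0, np.ones((5, 3)) * -1.0)
        assert motion_summary(trace) == (0.0, 0.0)

    def test_hand_evaluated_steps(self):
        # steps of length 1 and 1 -> mean 1; rotations still
        trans = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        trace = MotionTrace(trans, np.zeros((3, 3)))
        t, r = motion_summary(trace)
        assert t == pytest.approx(1.0)
        assert r == 0.0

    def test_single_euclidean_step(self):
        trace = MotionTrace(np.array([[0, 0, 0], [3, 4, 0]], float), np.zeros((2, 3)))
        assert motion_summary(trace)[0] == pytest.approx(5.0)

    @given(offset=st.floats(-10, 10))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_constant_offset(self, offset):
        rng = np.random.default_rng(3)
        trans = rng.standard_normal((8, 3))
        rot = rng.standard_normal((8, 3))
        base = motion_summary(MotionTrace(trans, rot))
        shifted = motion_summary(MotionTrace(trans + offset, rot + offset))
        assert shifted == pytest.approx(base)


class TestMotionExclusion:
    def test_excludes_beyond_translation_limit(self):
        trans = np.zeros((10, 3))
        trans[4, 1] = 1.6
        decision = motion_exclusion(MotionTrace(trans, np.zeros((10, 3))))
        assert decision.exclude
        assert decision.offending_axis == "y"
        assert decision.volume_index == 4

    def test_retains_still_subject(self):
        assert not motion_exclusion(
            MotionTrace(np.zeros((5, 3)), np.zeros((5, 3)))
        ).exclude

    def test_boundary_is_strict(self):
        trans = np.zeros((5, 3))
        trans[2, 0] = 1.5
        assert not motion_exclusion(MotionTrace(trans, np.zeros((5, 3)))).exclude


class TestExtractMeanSeries:
    def test_single_voxel_mask(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((3, 3, 2, 20))
        mask = np.zeros((3, 3, 2), bool)
        mask[1, 2, 0] = True
        np.testing.assert_allclose(
            extract_mean_series(vol, mask).samples, vol[1, 2, 0]
        )

    def test_two_voxel_average(self):
        vol = np.zeros((2, 1, 1, 5))
        vol[0, 0, 0] = np.arange(5)
        vol[1, 0, 0] = np.arange(5) * 3
        mask = np.ones((2, 1, 1), bool)
        np.testing.assert_allclose(
            extract_mean_series(vol, mask).samples, np.arange(5) * 2.0
        )

    def test_rejects_empty_mask_and_grid_mismatch(self):
        vol = np.zeros((2, 2, 2, 8))
        with pytest.raises(ValueError, match="empty"):
            extract_mean_series(vol, np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="grid"):
            extract_mean_series(vol, np.ones((3, 2, 2), bool))


class TestRegressNuisance:
    def test_series_equal_to_regressor_vanishes(self):
        r = np.sin(np.arange(30))
        resid = regress_nuisance(r.copy(), [r])
        assert np.max(np.abs(resid)) < 1e-10

    def test_orthogonal_series_untouched(self):
        # explicitly orthogonalize a random series against the regressor
        # and the intercept: regression must then return it unchanged
        rng = np.random.default_rng(8)
        reg = rng.standard_normal(40)
        design = np.column_stack([np.ones(40), reg])
        raw = rng.standard_normal(40)
        series = raw - design @ np.linalg.solve(design.T @ design, design.T @ raw)
        resid = regress_nuisance(series, [reg])
        np.testing.assert_allclose(resid, series, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        design = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid = regress_nuisance(y, [x])
        np.testing.assert_allclose(resid, y - design @ beta, atol=1e-12)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(100)
        regs = [rng.standard_normal(100) for _ in range(4)]
        resid = regress_nuisance(y, regs)
        for reg in regs:
            assert abs(resid @ reg) <= 1e-8 * np.linalg.norm(resid) * np.linalg.norm(reg)
        assert abs(resid.sum()) < 1e-8

    def test_collinear_set_warns(self):
        y = np.arange(20.0)
        r = np.ones(20)
        with pytest.warns(UserWarning, match="collinear"):
            regress_nuisance(y, [r, 2 * r])


class TestBandpass:
    TR = 2.0

    def _amplitude(self, freq, t_len=400):
        t = np.arange(t_len) * self.TR
        sig = np.sin(2 * np.pi * freq * t)
        out = bandpass_filter(sig, 0.01, 0.08, self.TR)
        spec = np.abs(np.fft.rfft(out)) * 2 / t_len
        return spec[np.argmin(np.abs(np.fft.rfftfreq(t_len, self.TR) - freq))]

    def test_dc_removed(self):
        out = bandpass_filter(np.full(200, 7.0), 0.01, 0.08, self.TR)
        assert np.max(np.abs(out)) <= 1e-6 * 7.0

    def test_passband_tone_preserved(self):
        assert 0.9 <= self._amplitude(0.04) <= 1.1

    def test_stopband_tone_suppressed(self):
        assert self._amplitude(0.2) <= 0.1

    def test_idempotent_in_band(self):
        rng = np.random.default_rng(2)
        sig = rng.standard_normal(256)
        once = bandpass_filter(sig, 0.01, 0.08, self.TR)
        twice = bandpass_filter(once, 0.01, 0.08, self.TR)
        freqs = np.fft.rfftfreq(256, self.TR)
        band = (freqs >= 0.015) & (freqs <= 0.075)
        a1 = np.abs(np.fft.rfft(once))[band]
        a2 = np.abs(np.fft.rfft(twice))[band]
        assert np.max(np.abs(a1 - a2)) <= 0.01 * np.max(a1)

    def test_rejects_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), 0.01, 0.3, self.TR)

    def test_timeseries_roundtrip_keeps_tr(self):
        ts = TimeSeries(np.random.default_rng(0).standard_normal(64), 2.0)
        out = bandpass_filter(ts, 0.01, 0.08)
        assert isinstance(out, TimeSeries) and out.tr_seconds == 2.0


class TestDetrend:
    def test_removes_exact_line(self):
        t = np.arange(50.0)
        assert np.max(np.abs(detrend_linear(2 * t + 1))) < 1e-10

    def test_hand_case(self):
        np.testing.assert_allclose(
            detrend_linear(np.array([0.0, 1.0, 2.0, 3.0])), np.zeros(4), atol=1e-12
        )

    def test_output_has_no_residual_trend(self):
        rng = np.random.default_rng(4)
        out = detrend_linear(rng.standard_normal(200))
        t = np.arange(200.0)
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-10


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        vol = np.random.default_rng(0).standard_normal((6, 6, 6, 3))
        np.testing.assert_array_equal(smooth_gaussian(vol, 0.0), vol)

    def test_impulse_peak_matches_closed_form(self):
        vol = np.zeros((21, 21, 21, 1))
        vol[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(vol, 8.0, (3.0, 3.0, 3.0))
        sigma = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        expected = (1.0 / (sigma * np.sqrt(2 * np.pi))) ** 3
        assert out[10, 10, 10, 0] == pytest.approx(expected, rel=0.01)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8, 2), 3.5)
        np.testing.assert_allclose(smooth_gaussian(vol, 8.0), vol, atol=1e-8)


class TestPipelineComposition:
    def _inputs(self, t_len=60):
        rng = np.random.default_rng(9)
        grid = (4, 4, 2)
        wm = np.zeros(grid, bool)
        wm[0, 0, 0] = True
        csf = np.zeros(grid, bool)
        csf[3, 3, 1] = True
        brain = np.ones(grid, bool)
        wm_series = rng.standard_normal(t_len + 5)
        vol = np.empty(grid + (t_len + 5,))
        vol[...] = wm_series  # every voxel equals the WM signal
        trace = MotionTrace(
            rng.standard_normal((t_len + 5, 3)) * 0.01,
            rng.standard_normal((t_len + 5, 3)) * 0.01,
        )
        return vol, trace, wm, csf, brain

    def test_wm_signal_removed_from_identical_voxels(self):
        vol, trace, wm, csf, brain = self._inputs()
        cfg = PreprocessConfig()
        cleaned, _ = preprocess_voxelwise(vol, trace, wm, csf, brain, cfg, 2.0)
        assert np.var(cleaned) <= 1e-10 * np.var(vol)

    def test_stage_order_is_filter_then_detrend(self):
        # swapping the last two stages must change the output: witness that
        # the implemented order (regression -> band-pass -> detrend) is real
        rng = np.random.default_rng(11)
        t_len = 64
        sig = rng.standard_normal(t_len) + 0.3 * np.arange(t_len)
        ours = detrend_linear(bandpass_filter(sig, 0.01, 0.08, 2.0))
        swapped = bandpass_filter(detrend_linear(sig), 0.01, 0.08, 2.0)
        assert not np.allclose(ours, swapped)
        vol = np.zeros((1, 1, 1, t_len + 5))
        vol[0, 0, 0, :] = np.concatenate([np.zeros(5), sig])
        wm = csf = np.zeros((1, 1, 1), bool)
        brain = np.ones((1, 1, 1), bool)
        cfg = PreprocessConfig(
            use_motion_regressors=False, use_wm_regressor=False, use_csf_regressor=False
        )
        trace = MotionTrace(np.zeros((t_len + 5, 3)), np.zeros((t_len + 5, 3)))
        cleaned, _ = preprocess_voxelwise(vol, trace, wm, csf, brain, cfg, 2.0)
        demeaned = sig - sig.mean()
        expected = detrend_linear(bandpass_filter(demeaned, 0.01, 0.08, 2.0))
        np.testing.assert_allclose(cleaned[0, 0, 0], expected, atol=1e-8)

    def test_smoke_preserves_grid_and_flags_constant_voxels(self, tiny_cohort):
        sub = tiny_cohort.subjects[0]
        vol = sub.volume.astype(float)
        vol[0, 0, 0, :] = 5.0  # plant a dead voxel
        cfg = PreprocessConfig()
        cleaned, flagged = preprocess_voxelwise(
            vol, sub.motion, tiny_cohort.wm_mask, tiny_cohort.csf_mask,
            tiny_cohort.brain_mask, cfg, 2.0,
        )
        assert cleaned.shape == vol.shape[:3] + (vol.shape[3] - cfg.n_discard,)
        assert flagged[0, 0, 0]
        assert np.all(cleaned[0, 0, 0] == 0)

    def test_deterministic(self, tiny_cohort):
        sub = tiny_cohort.subjects[1]
        cfg = PreprocessConfig()
        args = (
            sub.volume.astype(float), sub.motion, tiny_cohort.wm_mask,
            tiny_cohort.csf_mask, tiny_cohort.brain_mask, cfg, 2.0,
        )
        a, _ = preprocess_voxelwise(*args)
        b, _ = preprocess_voxelwise(*args)
        assert a.tobytes() == b.tobytes()
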
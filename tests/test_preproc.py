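"""BOLD cleaning chain: discarding, FD, Friston-24, spikes, nuisance
regression and the ideal band-pass filter."""

import numpy as np
import pytest

from nvcoupling.images import BoldSeries, MotionTrace
from nvcoupling.preproc import (
    bandpass_filter,
    build_friston24,
    build_nuisance_design,
    build_spike_regressors,
    discard_initial_volumes,
    framewise_displacement,
    preprocess,
    regress_nuisance,
)


def _bold(t=40, shape=(4, 4, 4), seed=0, **kw):
    rng = np.random.default_rng(seed)
    return BoldSeries(data=rng.standard_normal((*shape, t)), tr_s=2.0, **kw)


class TestDiscard:
    def test_210_to_200(self):
        bold = _bold(t=210)
        motion = MotionTrace(np.arange(210 * 6, dtype=float).reshape(210, 6))
        out, mout = discard_initial_volumes(bold, motion, 10)
        assert out.n_timepoints == 200
        assert mout.n_frames == 200
        # synchronous: first remaining frame is original frame 10
        np.testing.assert_array_equal(out.data[..., 0], bold.data[..., 10])
        np.testing.assert_array_equal(mout.params[0], motion.params[10])

    def test_zero_is_identity(self):
        bold = _bold(t=20)
        motion = MotionTrace(np.zeros((20, 6)))
        out, _ = discard_initial_volumes(bold, motion, 0)
        np.testing.assert_array_equal(out.data, bold.data)

    def test_discard_all_rejected(self):
        bold = _bold(t=20)
        motion = MotionTrace(np.zeros((20, 6)))
        with pytest.raises(ValueError):
            discard_initial_volumes(bold, motion, 20)


class TestFramewiseDisplacement:
    def test_constant_motion_zero_fd(self):
        motion = MotionTrace(np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (30, 1)))
        np.testing.assert_allclose(framewise_displacement(motion), 0.0)

    def test_translation_step(self):
        params = np.zeros((10, 6))
        params[5:, 0] = 0.3
        fd = framewise_displacement(MotionTrace(params))
        expected = np.zeros(10)
        expected[5] = 0.3
        np.testing.assert_allclose(fd, expected)

    def test_rotation_contribution_radius_scaled(self):
        # 0.01 rad step at 50 mm radius -> 0.5 mm of FD
        params = np.zeros((5, 6))
        params[2:, 4] = 0.01
        fd = framewise_displacement(MotionTrace(params), head_radius_mm=50.0)
        assert fd[2] == pytest.approx(50.0 * 0.01)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            framewise_displacement(MotionTrace(np.zeros((1, 6))))


class TestFriston24:
    def test_zero_motion_all_zero(self):
        out = build_friston24(MotionTrace(np.zeros((15, 6))))
        assert out.shape == (15, 24)
        np.testing.assert_array_equal(out, 0.0)

    def test_lag_columns_shifted_by_one(self, rng):
        params = rng.standard_normal((25, 6))
        out = build_friston24(MotionTrace(params))
        np.testing.assert_array_equal(out[:, :6], params)
        np.testing.assert_array_equal(out[:, 6:12], params**2)
        np.testing.assert_array_equal(out[0, 12:], 0.0)
        np.testing.assert_array_equal(out[1:, 12:18], params[:-1])
        np.testing.assert_array_equal(out[1:, 18:24], params[:-1] ** 2)


class TestSpikeRegressors:
    def test_no_spikes_zero_columns(self):
        assert build_spike_regressors(np.full(20, 0.2), 0.5).shape == (20, 0)

    def test_indicator_placement(self):
        fd = np.zeros(40)
        fd[[7, 30]] = 0.9
        cols = build_spike_regressors(fd, 0.5)
        assert cols.shape == (40, 2)
        np.testing.assert_array_equal(np.flatnonzero(cols[:, 0]), [7])
        np.testing.assert_array_equal(np.flatnonzero(cols[:, 1]), [30])

    def test_spiked_frames_have_zero_residual(self, rng):
        """A frame carrying its own indicator regressor is fit exactly."""
        t = 60
        params = np.zeros((t, 6))
        params[[7, 30], 0] = 1.0  # transient jumps -> FD > 0.5 at 7, 8, 30, 31
        bold = _bold(t=t, seed=3)
        motion = MotionTrace(params)
        design = build_nuisance_design(bold, motion)
        out = regress_nuisance(bold, design)
        spike_frames = [int(l.split("_")[1]) for l in design.labels if l.startswith("spike")]
        assert spike_frames  # design found spikes
        resid = out.data[out.brain_mask]
        np.testing.assert_allclose(resid[:, spike_frames], 0.0, atol=1e-10)


class TestRegressNuisance:
    def test_design_column_regressed_to_zero(self):
        t = 50
        motion = MotionTrace(np.zeros((t, 6)))
        bold = _bold(t=t)
        design = build_nuisance_design(bold, motion)
        trend = design.matrix[:, design.labels.index("linear_trend")]
        bold.data[0, 0, 0, :] = 3.0 * trend + 1.5
        out = regress_nuisance(bold, design)
        np.testing.assert_allclose(out.data[0, 0, 0], 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        bold = _bold(t=80, seed=1)
        motion = MotionTrace(np.hstack([rng.normal(0, 0.03, (80, 3)), rng.normal(0, 3e-4, (80, 3))]))
        design = build_nuisance_design(bold, motion)
        out = regress_nuisance(bold, design)
        R = out.data[out.brain_mask]
        dots = R @ design.matrix
        scale = np.abs(R).sum() * np.abs(design.matrix).max()
        assert np.abs(dots).max() < 1e-8 * scale

    def test_matches_normal_equations_oracle(self, rng):
        """Vectorised residuals equal a per-voxel normal-equations solve."""
        t = 30
        data = rng.standard_normal((5, 1, 1, t))
        bold = BoldSeries(data=data, tr_s=2.0)
        motion = MotionTrace(np.hstack([rng.normal(0, 0.02, (t, 3)), rng.normal(0, 2e-4, (t, 3))]))
        design = build_nuisance_design(bold, motion)
        out = regress_nuisance(bold, design)
        X = design.matrix
        for v in range(5):
            y = data[v, 0, 0]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(out.data[v, 0, 0], y - X @ beta, atol=1e-10)

    def test_masked_out_voxels_untouched(self, rng):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        bold = _bold(t=40, brain_mask=mask)
        motion = MotionTrace(np.zeros((40, 6)))
        original = bold.data.copy()
        out = regress_nuisance(bold, build_nuisance_design(bold, motion))
        np.testing.assert_array_equal(out.data[~mask], original[~mask])

    def test_wmcsf_means_only_from_their_masks(self):
        brain = np.ones((4, 4, 4), bool)
        wm = np.zeros_like(brain)
        wm[0, 0, 0] = True
        bold = _bold(t=40, brain_mask=brain, wm_mask=wm)
        wm_series = bold.data[0, 0, 0].copy()
        design = build_nuisance_design(bold, MotionTrace(np.zeros((40, 6))))
        col = design.matrix[:, design.labels.index("wm_mean")]
        np.testing.assert_allclose(col, wm_series - wm_series.mean(), atol=1e-12)


class TestBandpass:
    def _sine(self, freq, t=200, tr=2.0):
        time = np.arange(t) * tr
        data = np.sin(2 * np.pi * freq * time)[None, None, None, :]
        return BoldSeries(data=np.tile(data, (2, 1, 1, 1)), tr_s=tr)

    def test_passband_sine_preserved(self):
        bold = self._sine(0.05)
        out = bandpass_filter(bold, 0.01, 0.10)
        in_amp = np.abs(bold.data[0, 0, 0]).max()
        np.testing.assert_allclose(
            out.data[0, 0, 0], bold.data[0, 0, 0], atol=0.01 * in_amp
        )

    def test_stopband_sine_rejected(self):
        bold = self._sine(0.2)
        out = bandpass_filter(bold, 0.01, 0.10)
        assert (out.data**2).sum() < 0.01 * (bold.data**2).sum()

    def test_constant_series_becomes_zero(self):
        bold = BoldSeries(data=np.full((2, 2, 2, 64), 7.0), tr_s=2.0)
        out = bandpass_filter(bold, 0.01, 0.10)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(self._sine(0.05), 0.01, 0.3)

    def test_filter_idempotent(self, rng):
        bold = _bold(t=128, seed=5)
        once = bandpass_filter(bold, 0.01, 0.10)
        twice = bandpass_filter(once, 0.01, 0.10)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


def test_full_chain_runs_and_zero_means(rng):
    bold = _bold(t=80, shape=(5, 5, 5), seed=9)
    motion = MotionTrace(np.hstack([rng.normal(0, 0.02, (80, 3)), rng.normal(0, 2e-4, (80, 3))]))
    out = preprocess(bold, motion, n_discard=5)
    assert out.n_timepoints == 75
    means = out.data[out.brain_mask].mean(axis=-1)
    np.testing.assert_allclose(means, 0.0, atol=1e-10)
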
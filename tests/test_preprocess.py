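"""Temporal preprocessing: discard, filter, nuisance regression, motion."""
import numpy as np
import pytest

from conftest import make_series
from fcdmap import preprocess as pre


class TestDiscard:
    def test_240_minus_10_gives_230(self):
        series = make_series(np.random.default_rng(0).normal(size=(4, 4, 4, 240)))
        out = pre.discard_initial(series, 10)
        assert out.n_volumes == 230

    def test_zero_discard_is_identity(self, random_series):
        out = pre.discard_initial(random_series, 0)
        np.testing.assert_array_equal(out.data, random_series.data)

    def test_too_few_volumes_errors_with_counts(self):
        series = make_series(np.zeros((2, 2, 2, 5)) + np.arange(5))
        with pytest.raises(ValueError, match="5"):
            pre.discard_initial(series, 10)


class TestBandpass:
    def make_tone(self, freq, tr=2.0, n=230):
        t = np.arange(n) * tr
        return make_series(np.broadcast_to(np.sin(2 * np.pi * freq * t), (2, 2, 2, n)).copy(), tr=tr)

    def test_in_band_tone_preserved(self):
        """0.05 Hz sits fully inside the pass band: amplitude within 5%."""
        series = self.make_tone(0.05)
        out = pre.bandpass_detrend(series)
        ratio = out.data[0, 0, 0].std() / series.data[0, 0, 0].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated(self):
        """0.2 Hz is far outside 0.01-0.1 Hz: >= 90% amplitude loss."""
        series = self.make_tone(0.2)
        out = pre.bandpass_detrend(series)
        assert out.data[0, 0, 0].std() <= 0.1 * series.data[0, 0, 0].std()

    def test_constant_series_maps_to_zero(self):
        series = make_series(np.full((2, 2, 2, 64), 7.0))
        out = pre.bandpass_detrend(series)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_output_mean_free(self, random_series):
        out = pre.bandpass_detrend(random_series)
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-5)

    def test_band_above_nyquist_rejected(self, random_series):
        with pytest.raises(ValueError, match="Nyquist"):
            pre.bandpass_detrend(random_series, low=0.01, high=0.3)


class TestFriston24:
    def test_zero_trace_gives_zero_matrix(self):
        out = pre.build_friston24(np.zeros((20, 6)))
        assert out.shape == (20, 24)
        assert np.all(out == 0)

    def test_single_spike_lands_in_expected_cells(self):
        trace = np.zeros((10, 6))
        trace[4, 2] = 0.5  # z-translation at volume 4
        out = pre.build_friston24(trace)
        expected = np.zeros((10, 24))
        expected[4, 2] = 0.5          # p(t)
        expected[5, 8] = 0.5          # p(t-1)
        expected[4, 14] = 0.25        # p(t)^2
        expected[5, 20] = 0.25        # p(t-1)^2
        np.testing.assert_array_equal(out, expected)

    def test_random_trace_shape_and_rank(self, rng):
        out = pre.build_friston24(rng.normal(size=(50, 6)))
        assert out.shape == (50, 24)
        assert np.linalg.matrix_rank(out) <= 24

    def test_wrong_parameter_count_rejected(self):
        with pytest.raises(ValueError, match="6"):
            pre.build_friston24(np.zeros((10, 5)))


class TestNuisanceRegression:
    def test_nuisance_column_itself_becomes_zero(self, rng):
        reg = rng.normal(size=(40, 24))
        data = np.tile(reg[:, 3], (2, 2, 2, 1))
        series = make_series(data)
        out = pre.regress_nuisance(series, pre.NuisanceModel(friston24=reg))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_empty_model_removes_only_the_mean(self, random_series):
        out = pre.regress_nuisance(random_series, pre.NuisanceModel())
        expected = random_series.data - random_series.data.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_orthogonal_voxel_unchanged_up_to_mean(self, rng):
        """A series orthogonalized against the regressors (Gram-Schmidt)
        passes through regression up to mean removal."""
        reg = rng.normal(size=(60, 4))
        x = rng.normal(size=60)
        basis = np.hstack([np.ones((60, 1)), reg - reg.mean(axis=0)])
        q, _ = np.linalg.qr(basis)
        x_orth = x - q @ (q.T @ x)
        series = make_series(np.tile(x_orth, (2, 2, 2, 1)))
        model = pre.NuisanceModel(friston24=None, tissue_signals=reg)
        out = pre.regress_nuisance(series, model)
        np.testing.assert_allclose(out.data[0, 0, 0], x_orth - x_orth.mean(), atol=1e-8)

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        reg = rng.normal(size=(40, 24))
        series = make_series(rng.normal(size=(4, 4, 4, 40)))
        out = pre.regress_nuisance(series, pre.NuisanceModel(friston24=reg))
        resid = out.data.reshape(-1, 40)
        centered = reg - reg.mean(axis=0)
        corr = resid @ centered / 40.0
        assert np.abs(corr).max() < 1e-6

    def test_mismatched_rows_rejected(self, random_series, rng):
        with pytest.raises(ValueError, match="rows"):
            pre.regress_nuisance(
                random_series, pre.NuisanceModel(friston24=rng.normal(size=(10, 24)))
            )


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        out = pre.framewise_displacement(np.zeros((30, 6)))
        assert np.all(out.fd == 0)
        assert out.mean_fd == 0.0
        assert len(out.fd) == 29

    def test_unit_translation_step_gives_fd_1mm(self):
        trace = np.zeros((3, 6))
        trace[1:, 0] = 1.0  # x jumps by 1 mm between volumes 0 and 1
        out = pre.framewise_displacement(trace)
        assert out.fd[0] == pytest.approx(1.0, abs=1e-12)
        assert out.fd[1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("axis", [3, 4, 5])
    def test_small_rotation_closed_form(self, axis):
        """FD ~ R * theta * sqrt(2/5) for a small pure rotation."""
        theta = 1e-3
        trace = np.zeros((2, 6))
        trace[1, axis] = theta
        out = pre.framewise_displacement(trace, head_radius=80.0)
        assert out.fd[0] == pytest.approx(80.0 * theta * np.sqrt(2.0 / 5.0), rel=1e-5)

    def test_translation_offset_invariance(self, rng):
        """A constant translation offset leaves relative transforms (hence
        FD) unchanged for translation-only traces; with rotations present
        the conjugation term is O(theta * offset) and stays negligible at
        realistic rotation sizes."""
        trace = rng.normal(scale=0.1, size=(20, 6))
        trace[:, 3:] = 0.0
        shifted = trace.copy()
        shifted[:, :3] += np.array([5.0, -3.0, 2.0])
        np.testing.assert_allclose(
            pre.framewise_displacement(trace).fd,
            pre.framewise_displacement(shifted).fd,
            atol=1e-12,
        )
        small_rot = rng.normal(scale=0.1, size=(20, 6))
        small_rot[:, 3:] = rng.normal(scale=5e-4, size=(20, 3))
        shifted = small_rot.copy()
        shifted[:, :3] += np.array([5.0, -3.0, 2.0])
        np.testing.assert_allclose(
            pre.framewise_displacement(small_rot).fd,
            pre.framewise_displacement(shifted).fd,
            atol=2e-2,
        )


class TestMotionExclusion:
    def test_zero_trace_passes(self):
        assert pre.motion_exclusion(np.zeros((10, 6))).passed

    def test_translation_over_limit_fails_naming_axis_and_volume(self):
        trace = np.zeros((10, 6))
        trace[7, 1] = 2.1
        result = pre.motion_exclusion(trace)
        assert not result.passed
        assert "y" in result.reason and "volume 7" in result.reason

    def test_just_under_both_limits_passes(self):
        trace = np.zeros((10, 6))
        trace[5, 0] = 1.9
        trace[5, 4] = np.deg2rad(1.9)
        assert pre.motion_exclusion(trace).passed

    def test_exactly_at_limit_fails_strict_inequality(self):
        trace = np.zeros((4, 6))
        trace[2, 2] = 2.0
        assert not pre.motion_exclusion(trace).passed


class TestFullPreprocess:
    def test_order_and_output_shape(self, rng):
        series = make_series(rng.normal(size=(6, 6, 6, 60)) + 100.0)
        motion = rng.normal(scale=0.02, size=(60, 6))
        out, fd = pre.preprocess_subject(series, motion, n_discard=10)
        assert out.n_volumes == 50
        assert len(fd.fd) == 49
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-4)
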
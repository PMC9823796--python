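"""Preprocessing-chain tests: window arithmetic, interpolation semantics,
Savitzky-Golay exactness, resampling oracles and hip-centring invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pose2grf import preprocess as pp
from pose2grf.types import EventPair, KeypointTrial


def make_trial(n_frames=100, fps=25.0, fill=None, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(100, 900, size=(n_frames, 8, 2)) if fill is None else np.full(
        (n_frames, 8, 2), float(fill)
    )
    return KeypointTrial(
        subject_id="s1", movement="running", camera_view="TS", estimator="A",
        fps=fps, coords=coords, presence=np.ones((n_frames, 8), dtype=bool),
    )


def smooth_trial(n_frames=60, fps=25.0, seed=0):
    """A trial with smooth (cubic) joint trajectories, for SG/upsampling tests."""
    t = np.arange(n_frames, dtype=float)
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_frames, 8, 2))
    for j in range(8):
        for ax in range(2):
            c = rng.uniform(-1, 1, size=4)
            coords[:, j, ax] = c[0] + c[1] * t / 10 + c[2] * (t / 10) ** 2 + c[3] * (t / 10) ** 3
    return KeypointTrial(
        subject_id="s1", movement="running", camera_view="TS", estimator="A",
        fps=fps, coords=coords, presence=np.ones((n_frames, 8), dtype=bool),
    )


class TestExtractWindow:
    def test_default_window_arithmetic(self):
        w = pp.extract_window(make_trial(100), EventPair(30, 45))
        assert w.n_frames == 41  # frames 15..55
        assert (w.stance_start, w.stance_stop) == (15, 30)
        assert w.valid_full_window and w.valid_stance

    def test_clipped_lead_in_marked_absent(self):
        w = pp.extract_window(make_trial(100), EventPair(5, 20))
        assert w.n_frames == 41
        assert not w.presence[:10].any()  # frames -10..-1 of the recording
        assert not w.valid_full_window
        assert w.valid_stance

    def test_zero_leads_equal_stance(self):
        w = pp.extract_window(make_trial(100), EventPair(30, 45), lead_in=0, lead_out=0)
        assert w.n_frames == 16
        assert (w.stance_start, w.stance_stop) == (0, 15)

    def test_inverted_events_refused(self):
        with pytest.raises(ValueError):
            EventPair(45, 30)


class TestInterpolateGaps:
    def test_linear_midpoint(self):
        trial = make_trial(3, fill=0.0)
        trial.coords[0, 0, 0], trial.coords[2, 0, 0] = 1.0, 3.0
        trial.presence[1, 0] = False
        w = pp.extract_window(trial, EventPair(0, 2), lead_in=0, lead_out=0)
        w = pp.interpolate_gaps(w)
        assert w.coords[1, 0, 0] == 2.0
        assert w.presence[1, 0]

    def test_boundary_gap_not_interpolated(self):
        trial = make_trial(3, fill=2.0)
        trial.presence[0, 0] = False
        w = pp.extract_window(trial, EventPair(0, 2), lead_in=0, lead_out=0)
        w = pp.interpolate_gaps(w)
        assert not w.presence[0, 0]
        assert not w.valid_full_window

    def test_exact_recovery_on_affine_signals(self, rng):
        # linear interpolation is exact on affine trajectories
        n = 50
        trial = make_trial(n, fill=0.0)
        slope = rng.uniform(-2, 2, size=(8, 2))
        intercept = rng.uniform(0, 10, size=(8, 2))
        t = np.arange(n)[:, None, None]
        trial.coords[:] = intercept + slope * t
        original = trial.coords.copy()
        drop = rng.choice(np.arange(1, n - 1), size=15, replace=False)
        trial.presence[drop, :] = False
        w = pp.extract_window(trial, EventPair(0, n - 1), lead_in=0, lead_out=0)
        w = pp.interpolate_gaps(w)
        np.testing.assert_allclose(w.coords, original, atol=1e-9)
        assert w.valid_full_window


class TestSmooth:
    def test_constant_series_unchanged(self):
        trial = make_trial(20, fill=5.0)
        w = pp.extract_window(trial, EventPair(0, 19), lead_in=0, lead_out=0)
        out = pp.smooth(pp.interpolate_gaps(w))
        np.testing.assert_allclose(out.coords, 5.0, atol=1e-10)

    def test_exact_on_cubics(self):
        # an order-3 filter reproduces cubic polynomials exactly
        trial = smooth_trial(60)
        w = pp.interpolate_gaps(pp.extract_window(trial, EventPair(0, 59), lead_in=0, lead_out=0))
        out = pp.smooth(w)
        np.testing.assert_allclose(out.coords, trial.coords, atol=1e-9)

    def test_equals_sliding_least_squares_oracle(self, rng):
        # direct least-squares cubic fit per centred window
        n = 30
        trial = make_trial(n, seed=4)
        w = pp.interpolate_gaps(pp.extract_window(trial, EventPair(0, n - 1), lead_in=0, lead_out=0))
        out = pp.smooth(w, order=3, window=5)
        y = trial.coords[:, 2, 1]
        for center in range(2, n - 2):
            tt = np.arange(center - 2, center + 3)
            fit = np.polynomial.polynomial.polyfit(tt, y[tt], 3)
            expected = np.polynomial.polynomial.polyval(center, fit)
            assert out.coords[center, 2, 1] == pytest.approx(expected, abs=1e-8)

    def test_short_series_refused(self):
        trial = make_trial(4)
        w = pp.interpolate_gaps(pp.extract_window(trial, EventPair(0, 3), lead_in=0, lead_out=0))
        with pytest.raises(ValueError, match="shorter than window"):
            pp.smooth(w)


class TestUpsample:
    def test_linear_ramp_preserved(self):
        n = 26
        trial = make_trial(n, fill=0.0)
        trial.coords[:] = np.arange(n)[:, None, None]
        w = pp.interpolate_gaps(pp.extract_window(trial, EventPair(0, n - 1), lead_in=0, lead_out=0))
        out = pp.upsample(w, target_fs=200.0)
        assert out.n_frames == (n - 1) * 8 + 1
        expect = np.linspace(0, n - 1, out.n_frames)
        np.testing.assert_allclose(out.coords[:, 0, 0], expect, atol=1e-9)

    def test_grid_arithmetic_41_to_321(self):
        w = pp.interpolate_gaps(pp.extract_window(make_trial(100), EventPair(30, 45)))
        out = pp.upsample(w)
        assert out.n_frames == 321
        assert out.trial.fps == 200.0

    def test_sinusoid_against_analytic_oracle(self):
        n, fps = 100, 25.0
        t = np.arange(n) / fps
        trial = make_trial(n, fill=0.0)
        trial.coords[:] = (100 + 50 * np.sin(2 * np.pi * 2.0 * t))[:, None, None]
        w = pp.interpolate_gaps(pp.extract_window(trial, EventPair(0, n - 1), lead_in=0, lead_out=0))
        out = pp.upsample(w, target_fs=200.0)
        t_new = np.arange(out.n_frames) / 200.0
        analytic = 100 + 50 * np.sin(2 * np.pi * 2.0 * t_new)
        np.testing.assert_allclose(out.coords[:, 0, 0], analytic, rtol=0.01, atol=0.5)

    def test_downsampling_direction_refused(self):
        w = pp.interpolate_gaps(pp.extract_window(make_trial(50), EventPair(10, 30)))
        with pytest.raises(ValueError):
            pp.upsample(w, target_fs=10.0)


class TestHipCenter:
    def test_definition_example(self):
        trial = make_trial(1, fill=0.0)
        trial.coords[0, 2] = [2.0, 0.0]
        trial.coords[0, 3] = [4.0, 0.0]
        trial.coords[0, 6] = [3.0, 5.0]
        wt = pp.WindowedTrial(trial=trial, lead_in=0, lead_out=0, stance_start=0, stance_stop=0)
        out = pp.hip_center(wt)
        assert out.coords[0, 6].tolist() == [0.0, 5.0]
        np.testing.assert_allclose(out.coords[0, [2, 3]].mean(axis=0), [0.0, 0.0], atol=1e-12)

    def test_translation_invariance(self, rng):
        trial = make_trial(30, seed=2)
        shifted = make_trial(30, seed=2)
        shifted.coords += np.array([123.4, -77.0])
        w1 = pp.hip_center(pp.WindowedTrial(trial=trial, lead_in=0, lead_out=0, stance_start=0, stance_stop=29))
        w2 = pp.hip_center(pp.WindowedTrial(trial=shifted, lead_in=0, lead_out=0, stance_start=0, stance_stop=29))
        np.testing.assert_allclose(w1.coords, w2.coords, atol=1e-9)

    def test_transformed_hip_mean_is_origin(self, rng):
        trial = make_trial(40, seed=3)
        out = pp.hip_center(pp.WindowedTrial(trial=trial, lead_in=0, lead_out=0, stance_start=0, stance_stop=39))
        np.testing.assert_allclose(out.coords[:, [2, 3], :].mean(axis=1), 0.0, atol=1e-9)

    def test_absent_hip_refused(self):
        trial = make_trial(10)
        trial.presence[4, 2] = False
        with pytest.raises(ValueError, match="hip"):
            pp.hip_center(pp.WindowedTrial(trial=trial, lead_in=0, lead_out=0, stance_start=0, stance_stop=9))


class TestTimeNormalize:
    def test_identity_on_101_frames(self, rng):
        series = rng.normal(size=(101, 3))
        np.testing.assert_allclose(pp.time_normalize(series), series, atol=1e-12)

    @given(T=st.integers(min_value=2, max_value=400))
    @settings(max_examples=25, deadline=None)
    def test_linear_ramp_any_length(self, T):
        series = np.linspace(0.0, 7.0, T)[:, None]
        out = pp.time_normalize(series)
        np.testing.assert_allclose(out[:, 0], np.linspace(0.0, 7.0, 101), atol=1e-9)

    def test_sinusoid_analytic_resample(self):
        x = np.linspace(0, 1.6, 321)
        series = np.sin(2 * np.pi * 2.0 * x)[:, None]
        out = pp.time_normalize(series)
        analytic = np.sin(2 * np.pi * 2.0 * np.linspace(0, 1.6, 101))
        np.testing.assert_allclose(out[:, 0], analytic, atol=1e-3)

    def test_short_series_refused(self):
        with pytest.raises(ValueError):
            pp.time_normalize(np.array([[1.0, 2.0]]).T[:1])


class TestAssembleAndPipeline:
    def test_pipeline_order_produces_finite_sample(self, one_trial):
        _, kp, force, events = one_trial
        w = pp.interpolate_gaps(pp.extract_window(kp, events))
        s = pp.build_sample(w, force)
        assert s.inputs.shape == (101, 16)
        assert s.targets.shape == (101, 3)

    def test_sensor_translation_invariance_of_samples(self, one_trial):
        # shifting every raw pixel by a constant changes nothing after hip-centring
        from dataclasses import replace

        _, kp, force, events = one_trial
        shifted = replace(kp, coords=kp.coords + np.array([50.0, -20.0]), presence=kp.presence.copy())
        s1 = pp.build_sample(pp.interpolate_gaps(pp.extract_window(kp, events)), force)
        s2 = pp.build_sample(pp.interpolate_gaps(pp.extract_window(shifted, events)), force)
        np.testing.assert_allclose(s1.inputs, s2.inputs, atol=1e-6)

    def test_assemble_shapes_and_ordering(self, study_samples):
        X, Y = pp.assemble_inputs(study_samples)
        assert X.shape == (291, 101, 16)
        assert Y.shape == (291, 101, 3)
        only_a = [s for s in study_samples if s.estimator == "A"]
        Xa, Ya = pp.assemble_inputs(only_a)
        assert Xa.shape == (97, 101, 16)

    def test_assemble_empty_refused(self):
        with pytest.raises(ValueError):
            pp.assemble_inputs([])
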
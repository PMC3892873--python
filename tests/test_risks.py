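"""The eight per-module risk computations and their gating."""
import math

import numpy as np
import pytest

from fallwarn.floor import FloorPlane
from fallwarn.risks import (MODULES, LocalParams, RiskVector, WindowConfig,
                            clip_risk_vector, ground_speed, risk_foot_altitude,
                            risk_head_altitude, risk_jump, risk_lean, risk_run,
                            risk_sway)
from fallwarn.simulate import BehaviorSpec, generate_clip
from fallwarn.skeleton import JointName, N_JOINTS, SkeletonClip

from .conftest import make_frame


def _static_clip(frame, n=40, frame_rate=30.0):
    pos = np.tile(frame.positions, (n, 1, 1))
    return SkeletonClip(pos, frame_rate=frame_rate)


@pytest.fixture
def upright_frame():
    """A standing body over the origin, feet on the floor."""
    return make_frame(
        head=(0, 0.8, 0), shoulder_center=(0, 0.68, 0), spine=(0, 0.55, 0),
        hip_center=(0, 0.42, 0),
        shoulder_left=(-0.1, 0.66, 0), elbow_left=(-0.13, 0.52, 0),
        wrist_left=(-0.14, 0.42, 0), hand_left=(-0.14, 0.38, 0),
        shoulder_right=(0.1, 0.66, 0), elbow_right=(0.13, 0.52, 0),
        wrist_right=(0.14, 0.42, 0), hand_right=(0.14, 0.38, 0),
        hip_left=(-0.07, 0.4, 0), knee_left=(-0.08, 0.22, 0),
        ankle_left=(-0.08, 0.04, 0), foot_left=(-0.08, 0.0, 0),
        hip_right=(0.07, 0.4, 0), knee_right=(0.08, 0.22, 0),
        ankle_right=(0.08, 0.04, 0), foot_right=(0.08, 0.0, 0))


class TestRiskRun:
    def test_stationary_skeleton_zero_risk(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_run(clip, horizontal_plane, 0.009), 0.0)

    def test_vertical_bounce_ignored_by_ground_projection(self, upright_frame,
                                                          horizontal_plane):
        n, v = 60, 0.8
        pos = np.tile(upright_frame.positions, (n, 1, 1))
        t = np.arange(n) / 30.0
        pos[:, :, 0] += (v * t)[:, None]                       # constant drift
        pos[:, :, 1] += 0.1 * np.sin(2 * np.pi * 2 * t)[:, None]  # bounce
        clip = SkeletonClip(pos)
        speed = ground_speed(clip, horizontal_plane)
        # away from the clip edges the projected speed equals the drift speed
        assert np.allclose(speed[5:-5], v, atol=1e-9)

    def test_two_frame_minimum(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame, n=1)
        with pytest.raises(ValueError):
            risk_run(clip, horizontal_plane, 0.009)

    def test_monotone_in_speed(self, horizontal_plane):
        risks = []
        for i in np.linspace(0.1, 1.0, 6):
            clip, _ = generate_clip(BehaviorSpec("rush_running", intensity=float(i),
                                                 seed=4, noise_sd=0.0))
            risks.append(np.mean(risk_run(clip, horizontal_plane, 1.0)))
        assert np.all(np.diff(risks) > 0)


class TestRiskJump:
    def test_constant_height_zero(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_jump(clip, horizontal_plane, 0.017), 0.0)

    def test_two_point_alternation_closed_form(self, upright_frame, horizontal_plane):
        # centroid altitude alternates +/- h around its mean: variance = h^2
        h, alpha = 0.1, 0.017
        n = 40
        pos = np.tile(upright_frame.positions, (n, 1, 1))
        pos[1::2, :, 1] += 2 * h
        clip = SkeletonClip(pos)
        risk = risk_jump(clip, horizontal_plane, alpha,
                         WindowConfig(velocity_smoothing=5, variance_window=n))
        assert risk[-1] == pytest.approx(1 - math.exp(-h * h / alpha), rel=1e-6)

    def test_monotone_in_amplitude(self, horizontal_plane):
        risks = []
        for i in np.linspace(0.2, 1.0, 5):
            clip, _ = generate_clip(BehaviorSpec("high_jumping", intensity=float(i),
                                                 seed=4, noise_sd=0.0))
            risks.append(np.mean(risk_jump(clip, horizontal_plane, 0.01)))
        assert np.all(np.diff(risks) > 0)

    def test_short_clip_uses_full_length(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame, n=10)
        risk = risk_jump(clip, horizontal_plane, 0.017,
                         WindowConfig(variance_window=30))
        assert risk.shape == (10,)


class TestRiskSway:
    def test_centroid_on_foot_line_zero(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_sway(clip, horizontal_plane, 0.008), 0.0,
                           atol=1e-4)

    def test_offset_centroid_reference_value(self, horizontal_plane):
        # feet at (0,0) and (2,0) on the floor; body mass over (1, 1):
        # d = 1 and alpha = 0.008 saturates the sigmoid
        frame = make_frame(positions=np.tile([1.0, 0.5, 1.0], (N_JOINTS, 1)),
                           foot_left=(0.0, 0.0, 0.0), foot_right=(2.0, 0.0, 0.0))
        clip = _static_clip(frame)
        risk = risk_sway(clip, horizontal_plane, 0.008)
        centroid_d = 1.0  # all mass except the feet sits at z = 1
        assert np.allclose(risk, 1 - math.exp(-centroid_d ** 2 / 0.008), atol=0.01)
        assert risk[0] > 0.999

    def test_seated_gate_zeroes_risk(self, horizontal_plane):
        frame = make_frame(positions=np.tile([1.0, 0.5, 1.0], (N_JOINTS, 1)),
                           foot_left=(0.0, 0.0, 0.0), foot_right=(2.0, 0.0, 0.0))
        clip = _static_clip(frame, n=10)
        seated = np.ones(10, dtype=bool)
        assert np.allclose(risk_sway(clip, horizontal_plane, 0.008, seated), 0.0)

    def test_untracked_feet_zero_risk(self, upright_frame, horizontal_plane):
        pos = np.tile(upright_frame.positions, (10, 1, 1))
        pos[:, :, 2] += 1.0
        trk = np.ones((10, N_JOINTS), dtype=bool)
        trk[:, JointName.FOOT_LEFT] = False
        clip = SkeletonClip(pos, trk)
        assert np.allclose(risk_sway(clip, horizontal_plane, 0.008), 0.0)


class TestRiskLean:
    def test_vertical_spine_zero(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_lean(clip, horizontal_plane, 0.115), 0.0)

    def test_horizontal_spine_saturates(self, horizontal_plane):
        frame = make_frame(shoulder_center=(0.3, 0.0, 0.0))  # spine along x
        clip = _static_clip(frame, n=5)
        risk = risk_lean(clip, horizontal_plane, 0.115)
        expected = 1 - math.exp(-((math.pi / 2) ** 2) / 0.115)
        assert np.allclose(risk, expected, rtol=1e-9)
        assert risk[0] > 0.999

    def test_invariant_to_spine_magnitude(self, horizontal_plane):
        a = _static_clip(make_frame(shoulder_center=(0.2, 0.2, 0.0)), n=4)
        b = _static_clip(make_frame(shoulder_center=(2.0, 2.0, 0.0)), n=4)
        assert np.allclose(risk_lean(a, horizontal_plane, 0.115),
                           risk_lean(b, horizontal_plane, 0.115), atol=1e-12)

    def test_zero_spine_vector_flagged_zero(self, horizontal_plane):
        clip = _static_clip(make_frame(), n=4)  # all joints coincide
        assert np.allclose(risk_lean(clip, horizontal_plane, 0.115), 0.0)


class TestRiskAltitude:
    def test_feet_on_floor_zero(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_foot_altitude(clip, horizontal_plane, 0.217),
                           0.0, atol=1e-6)

    def test_elevated_feet_reference_value(self, upright_frame, horizontal_plane):
        pos = np.tile(upright_frame.positions, (6, 1, 1))
        pos[:, :, 1] += 0.6  # standing 0.6 m up
        clip = SkeletonClip(pos)
        risk = risk_foot_altitude(clip, horizontal_plane, 0.217)
        assert np.allclose(risk, 1 - math.exp(-0.36 / 0.217), rtol=1e-9)
        assert risk[0] == pytest.approx(0.810, abs=5e-4)

    def test_seated_on_sofa_gated(self, upright_frame, horizontal_plane):
        pos = np.tile(upright_frame.positions, (6, 1, 1))
        pos[:, :, 1] += 0.4
        clip = SkeletonClip(pos)
        seated = np.ones(6, dtype=bool)
        assert np.allclose(risk_foot_altitude(clip, horizontal_plane, 0.217, seated), 0.0)

    def test_head_altitude_upright_on_floor_near_zero(self, upright_frame,
                                                      horizontal_plane):
        clip = _static_clip(upright_frame)
        assert np.allclose(risk_head_altitude(clip, horizontal_plane, 0.214),
                           0.0, atol=1e-6)

    def test_head_altitude_platform_reference_value(self, upright_frame,
                                                    horizontal_plane):
        from fallwarn.skeleton import body_height
        pos = np.tile(upright_frame.positions, (6, 1, 1))
        H = body_height(upright_frame)
        # raise the body so the head sits exactly H + 0.5 above the floor
        pos[:, :, 1] += (H + 0.5) - 0.8
        clip = SkeletonClip(pos)
        risk = risk_head_altitude(clip, horizontal_plane, 0.214)
        assert np.allclose(risk, 1 - math.exp(-0.25 / 0.214), rtol=1e-9)
        assert risk[0] == pytest.approx(0.689, abs=5e-4)

    def test_crouching_clamps_to_zero(self, upright_frame, horizontal_plane):
        pos = np.tile(upright_frame.positions, (6, 1, 1))
        pos[:, JointName.HEAD, 1] -= 0.3  # head below full body height
        clip = SkeletonClip(pos)
        assert np.allclose(risk_head_altitude(clip, horizontal_plane, 0.214), 0.0)


class TestClipRiskVector:
    def test_motionless_upright_all_near_zero(self, upright_frame, horizontal_plane):
        clip = _static_clip(upright_frame, n=60)
        rv = clip_risk_vector(clip, horizontal_plane, LocalParams.reference_preset())
        assert np.all(rv.p < 0.05)

    def test_constant_module_risk_equals_clip_mean(self, upright_frame,
                                                   horizontal_plane):
        pos = np.tile(upright_frame.positions, (30, 1, 1))
        pos[:, :, 1] += 0.6
        clip = SkeletonClip(pos)
        rv = clip_risk_vector(clip, horizontal_plane, LocalParams.reference_preset())
        idx = MODULES.index("foot_altitude")
        assert rv.p[idx] == pytest.approx(1 - math.exp(-0.36 / 0.217), abs=1e-6)

    def test_high_jumping_dominated_by_jump_module(self, horizontal_plane):
        clip, _ = generate_clip(BehaviorSpec("high_jumping", intensity=0.9, seed=8))
        rv = clip_risk_vector(clip, horizontal_plane, LocalParams.reference_preset())
        assert MODULES[int(np.argmax(rv.p))] == "jump"

    def test_forcing_seated_zeroes_exactly_sway_and_foot(self, horizontal_plane):
        clip, _ = generate_clip(BehaviorSpec("tumbling", intensity=0.8, seed=3,
                                             combined_with="standing_on_furniture"))
        params = LocalParams.reference_preset()
        rv_free = clip_risk_vector(clip, horizontal_plane, params)
        rv_gated = clip_risk_vector(clip, horizontal_plane, params,
                                    seated_mask=np.ones(clip.n_frames, dtype=bool))
        sway_i, foot_i = MODULES.index("sway"), MODULES.index("foot_altitude")
        assert rv_free.p[sway_i] > 0 and rv_free.p[foot_i] > 0
        assert rv_gated.p[sway_i] == 0.0 and rv_gated.p[foot_i] == 0.0
        others = [i for i in range(len(MODULES)) if i not in (sway_i, foot_i)]
        assert np.allclose(rv_free.p[others], rv_gated.p[others], atol=1e-12)

    def test_risks_bounded_and_zero_at_zero_stimulus(self, upright_frame,
                                                     horizontal_plane):
        clip = _static_clip(upright_frame)
        rv = clip_risk_vector(clip, horizontal_plane, LocalParams.reference_preset())
        assert np.all((rv.p >= 0) & (rv.p < 1))

    def test_disabled_modules_carry_zero(self):
        with pytest.raises(ValueError, match="zero risk"):
            RiskVector(np.full(8, 0.5), np.zeros(8, dtype=bool))


def test_window_config_validation():
    with pytest.raises(ValueError):
        WindowConfig(velocity_smoothing=1)
    with pytest.raises(ValueError):
        WindowConfig(variance_window=1)


def test_local_params_positive():
    with pytest.raises(ValueError):
        LocalParams(run=0.0)
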
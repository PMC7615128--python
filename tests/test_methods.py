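"""The four version estimators: sign convention, exact recovery, invariances."""

import math

import numpy as np
import pytest

from glenoidversion.geometry import (
    DegenerateGeometryError,
    OrientationAmbiguityError,
    project_to_frame,
)
from glenoidversion.io import resolve_roles
from glenoidversion.methods import (
    AxialLandmarks,
    CorrectedLandmarks,
    VersionResult,
    corrected_friedman_version,
    corrected_friedman_version_2d,
    corrected_transverse_frame,
    friedman_version,
    line_version_2d,
    two_plane_version,
    vault_version,
)
from glenoidversion.synthetic import (
    PoseTransform,
    SyntheticParams,
    axial_project,
    generate_case,
)


def rotated_rim(version_deg, half_len=10.0):
    """2-D oracle: glenoid line built by rotating (0,1) by `version_deg`
    toward +u, medial reference far out on the +u axis."""
    t = math.radians(version_deg)
    d = np.array([math.sin(t), math.cos(t)])
    return -half_len * d, half_len * d, np.array([100.0, 0.0])


class TestLineVersion2D:
    def test_perpendicular_lines_read_zero(self):
        assert line_version_2d((0, -10), (0, 10), (100, 0)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("v", [10.0, -5.0, 25.0, -17.5])
    def test_rotated_glenoid_line_recovers_angle(self, v):
        a, p, m = rotated_rim(v)
        assert line_version_2d(a, p, m) == pytest.approx(v, abs=1e-9)

    def test_rounded_hand_derived_coordinates(self):
        # 10-mm rim rotated by +10 and -5 degrees, coordinates at 3 decimals
        # (+10: (10 sin10, 10 cos10) = (1.736, 9.848); -5: (0.872, 9.962))
        assert line_version_2d((-1.736, -9.848), (1.736, 9.848), (100, 0)) == pytest.approx(10.0, abs=1e-2)
        assert line_version_2d((0.872, -9.962), (-0.872, 9.962), (100, 0)) == pytest.approx(-5.0, abs=1e-2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            line_version_2d((1, 1), (1, 1), (100, 0))
        with pytest.raises(DegenerateGeometryError):
            line_version_2d((0, -10), (0, 10), (0, 0))  # ref at midpoint

    def test_rigid_motion_and_scale_invariance(self, rng):
        a, p, m = rotated_rim(12.0)
        base = line_version_2d(a, p, m)
        for _ in range(100):
            th = rng.uniform(-np.pi, np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            shift = rng.uniform(-100, 100, 2)
            s = rng.uniform(0.1, 10.0)
            moved = [s * (rot @ q) + shift for q in (a, p, m)]
            assert line_version_2d(*moved) == pytest.approx(base, abs=1e-9)


class TestTwoPlane:
    @pytest.mark.parametrize("v", [0.0, 15.0, -7.0])
    def test_synthetic_truth_recovered(self, v):
        case = generate_case(SyntheticParams(true_version_deg=v))
        lm, _ = resolve_roles(case.landmarks, "two_plane")
        assert two_plane_version(lm).version_deg == pytest.approx(v, abs=1e-9)

    def test_independent_rotation_matrix_oracle(self):
        """The fossa normal of a +15 degree case must equal the neutral lateral
        normal rotated 15 degrees toward posterior, computed independently."""
        v = 15.0
        case = generate_case(SyntheticParams(true_version_deg=v))
        lm, _ = resolve_roles(case.landmarks, "two_plane")
        n = two_plane_version(lm).diagnostics["fossa_normal"]
        t = math.radians(v)
        rot_z = np.array([[math.cos(-t), -math.sin(-t), 0],
                          [math.sin(-t), math.cos(-t), 0], [0, 0, 1]])
        expected = rot_z @ np.array([-1.0, 0.0, 0.0])
        assert np.allclose(n, expected, atol=1e-9)

    def test_orientation_ambiguity_detected(self):
        # fossa plane containing the lateral reference direction: cannot orient
        lm, _ = resolve_roles(generate_case(SyntheticParams()).landmarks, "two_plane")
        bad = type(lm)(
            glenoid_superior=(0, 0, 15), glenoid_anterior=(10, -13, 0),
            glenoid_posterior=(-10, -13, 0),
            glenoid_center=(0, 0, 0), medial_border=(0, 0, 10), inferior_angle=(80, 0, -120),
        )
        with pytest.raises((OrientationAmbiguityError, DegenerateGeometryError)):
            two_plane_version(bad)


class TestAxialMethods:
    @pytest.mark.parametrize("v", [0.0, 10.0, -8.0])
    def test_friedman_and_vault_recover_truth(self, v):
        case = generate_case(SyntheticParams(true_version_deg=v))
        f = friedman_version(axial_project(case, "medial_border"))
        w = vault_version(axial_project(case, "vault_tip"))
        assert f.version_deg == pytest.approx(v, abs=1e-9)
        assert w.version_deg == pytest.approx(v, abs=1e-9)
        assert f.method == "friedman" and w.method == "vault"

    def test_friedman_sensitive_to_pose_tilt(self):
        pose = PoseTransform.from_euler_deg(rx=15.0)
        case = generate_case(SyntheticParams(true_version_deg=10.0, pose=pose))
        f = friedman_version(axial_project(case, "medial_border"))
        assert abs(f.version_deg - 10.0) > 0.5

    def test_posteriorly_displaced_vault_tip_overestimates(self):
        """Shifting the vault tip posteriorly off the transverse axis raises
        the vault reading above Friedman's on the same case (the vault
        method's known tendency to overestimate)."""
        case = generate_case(SyntheticParams(true_version_deg=10.0))
        axial = axial_project(case, "medial_border")
        shifted = AxialLandmarks(
            glenoid_anterior=axial.glenoid_anterior,
            glenoid_posterior=axial.glenoid_posterior,
            medial_reference=np.array([30.0, 5.0]),  # 5 mm posterior
            method_tag="vault",
        )
        v = vault_version(shifted).version_deg
        f = friedman_version(axial).version_deg
        # independent oracle: the extra angle is atan(5/30) on top of truth
        assert v > f
        assert v - f == pytest.approx(math.degrees(math.atan2(5.0, 30.0)), abs=1e-6)


class TestCorrectedFrame:
    def test_hand_computed_example(self):
        f = corrected_transverse_frame((0, 0, 0), (100, 0, 10), (80, 0, -120))
        assert np.allclose(f.axis_u, np.array([100.0, 0, 10]) / np.linalg.norm([100, 0, 10]))
        assert np.allclose(f.axis_v, [0, 1, 0])  # normal of y=0 plane, posterior
        assert abs(np.dot(f.axis_u, f.axis_v)) < 1e-12

    def test_collinear_triple_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            corrected_transverse_frame((0, 0, 0), (50, 0, 0), (100, 0, 0))


class TestCorrectedFriedman:
    @pytest.mark.parametrize("v", [0.0, 12.0, -6.0])
    def test_truth_recovered_under_arbitrary_pose(self, v):
        pose = PoseTransform.from_euler_deg(17.0, -23.0, 41.0, translation=(30, -40, 55))
        case = generate_case(SyntheticParams(true_version_deg=v, pose=pose))
        lm, _ = resolve_roles(case.landmarks, "corrected_friedman")
        assert corrected_friedman_version(lm).version_deg == pytest.approx(v, abs=1e-9)

    def test_projection_path_matches_prepicked_path(self):
        case = generate_case(SyntheticParams(true_version_deg=9.0))
        lm, _ = resolve_roles(case.landmarks, "corrected_friedman")
        auto = corrected_friedman_version(lm)
        frame = auto.diagnostics["frame"]
        picked = corrected_friedman_version_2d(
            project_to_frame(frame, lm.glenoid_anterior),
            project_to_frame(frame, lm.glenoid_posterior),
            project_to_frame(frame, lm.medial_axis_point),
        )
        assert picked.version_deg == pytest.approx(auto.version_deg, abs=1e-12)
        assert picked.method == "corrected_friedman"


class TestSignConventionAndContract:
    @pytest.mark.parametrize("v", [8.0, -8.0])
    def test_retro_positive_ante_negative_all_methods(self, v):
        case = generate_case(SyntheticParams(true_version_deg=v))
        tp, _ = resolve_roles(case.landmarks, "two_plane")
        cf, _ = resolve_roles(case.landmarks, "corrected_friedman")
        values = [
            two_plane_version(tp).version_deg,
            friedman_version(axial_project(case, "medial_border")).version_deg,
            vault_version(axial_project(case, "vault_tip")).version_deg,
            corrected_friedman_version(cf).version_deg,
        ]
        assert all(np.sign(x) == np.sign(v) for x in values)

    def test_version_result_range_enforced(self):
        with pytest.raises(ValueError):
            VersionResult(method="friedman", version_deg=120.0)

    def test_rigid_motion_invariance_of_3d_methods(self, rng):
        case = generate_case(SyntheticParams(true_version_deg=14.0))
        tp0, _ = resolve_roles(case.landmarks, "two_plane")
        cf0, _ = resolve_roles(case.landmarks, "corrected_friedman")
        base_tp = two_plane_version(tp0).version_deg
        base_cf = corrected_friedman_version(cf0).version_deg
        for _ in range(200):
            pose = PoseTransform.from_euler_deg(
                *rng.uniform(-30, 30, 3), translation=rng.uniform(-100, 100, 3))
            moved = generate_case(SyntheticParams(true_version_deg=14.0, pose=pose))
            tp, _ = resolve_roles(moved.landmarks, "two_plane")
            cf, _ = resolve_roles(moved.landmarks, "corrected_friedman")
            assert two_plane_version(tp).version_deg == pytest.approx(base_tp, abs=1e-6)
            assert corrected_friedman_version(cf).version_deg == pytest.approx(base_cf, abs=1e-6)
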
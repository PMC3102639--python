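"""Geometry of the two rotation measurements and the torsion angle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stnum

from spinetorsion import (
    DegenerateBisectorError,
    DegenerateLandmarkError,
    ImplausibleLandmarkError,
    OrientedSegment,
    Point2D,
    canonical_template,
    generate_phantom,
    measure_ho_rotation,
    measure_new_rotation,
    measure_vertebra,
    torsion_angle,
    PhantomParams,
    VertebraLandmarks,
)


def rotate_cw(x, y, theta_deg, cx=0.0, cy=0.0):
    """Independent oracle: clockwise (right-rotation) 2D rotation matrix."""
    t = math.radians(theta_deg)
    dx, dy = x - cx, y - cy
    return (
        cx + dx * math.cos(t) + dy * math.sin(t),
        cy - dx * math.sin(t) + dy * math.cos(t),
    )


class TestNewRotation:
    def test_horizontal_chord_is_zero(self):
        assert measure_new_rotation(Point2D(15, 10), Point2D(-15, 10)) == 0.0

    @pytest.mark.parametrize("theta", [-35.0, -10.0, 0.5, 10.0, 27.3])
    def test_recovers_rigid_rotation(self, theta):
        left = Point2D(*rotate_cw(15, 10, theta))
        right = Point2D(*rotate_cw(-15, 10, theta))
        assert measure_new_rotation(left, right) == pytest.approx(theta, abs=1e-9)

    def test_worked_ten_degree_example(self):
        # left (15,10), right (-15,10) rotated rigidly 10 deg to the right
        left = Point2D(16.508598071852425, 7.243354865118125)
        right = Point2D(-13.035634518513818, 12.452800195126034)
        assert measure_new_rotation(left, right) == pytest.approx(10.0, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateLandmarkError):
            measure_new_rotation(Point2D(15, 10), Point2D(15, 10))

    def test_near_sagittal_chord_raises(self):
        with pytest.raises(ImplausibleLandmarkError):
            measure_new_rotation(Point2D(0, 30), Point2D(0.1, -30))


class TestHoRotation:
    def test_mirror_symmetric_laminae_give_zero(self):
        left = OrientedSegment(Point2D(3, 42), Point2D(16, 28))
        right = OrientedSegment(Point2D(-3, 42), Point2D(-16, 28))
        assert measure_ho_rotation(left, right) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [-25.0, -5.0, 4.2, 15.0, 30.0])
    def test_recovers_rigid_rotation(self, theta):
        pts = [rotate_cw(x, y, theta) for x, y in ((3, 42), (16, 28), (-3, 42), (-16, 28))]
        left = OrientedSegment(Point2D(*pts[0]), Point2D(*pts[1]))
        right = OrientedSegment(Point2D(*pts[2]), Point2D(*pts[3]))
        assert measure_ho_rotation(left, right) == pytest.approx(theta, abs=1e-9)

    def test_antiparallel_directions_raise(self):
        left = OrientedSegment(Point2D(0, 0), Point2D(1, 0))
        right = OrientedSegment(Point2D(0, 5), Point2D(-1, 5))
        with pytest.raises(DegenerateBisectorError):
            measure_ho_rotation(left, right)


class TestTorsionAngle:
    @pytest.mark.parametrize(
        "beta,alpha,expected", [(10.0, 10.0, 0.0), (15.0, 5.0, 10.0), (-5.0, 5.0, -10.0)]
    )
    def test_discrepancy(self, beta, alpha, expected):
        assert torsion_angle(beta, alpha) == expected

    def test_nonfinite_raises(self):
        with pytest.raises(DegenerateLandmarkError):
            torsion_angle(float("nan"), 0.0)


class TestMeasureVertebra:
    def test_symmetric_template_measures_zero(self, template):
        m = measure_vertebra(template)
        assert (m.alpha_deg, m.beta_deg, m.torsion_deg) == (0.0, 0.0, 0.0)

    def test_component_rotations_recovered(self):
        # anterior rotated 14 deg, posterior 8 deg -> (8, 14, 6)
        lm = generate_phantom(PhantomParams(theta_post_deg=8.0, tau_deg=6.0))
        m = measure_vertebra(lm)
        assert m.alpha_deg == pytest.approx(8.0, abs=1e-9)
        assert m.beta_deg == pytest.approx(14.0, abs=1e-9)
        assert m.torsion_deg == pytest.approx(6.0, abs=1e-9)

    def test_error_names_subject(self):
        t = canonical_template()
        lm = VertebraLandmarks(
            subject_id="S9",
            level="T8",
            pedicle_base_left=Point2D(0, 30),
            pedicle_base_right=Point2D(0.01, -30),
            lamina_left=t.lamina_left,
            lamina_right=t.lamina_right,
        )
        with pytest.raises(ImplausibleLandmarkError, match="S9"):
            measure_vertebra(lm)


def _transform_landmarks(lm, fn):
    t = canonical_template(lm.subject_id, lm.level)
    pts = {role: Point2D(*fn(p.x, p.y)) for role, p in lm.points_by_role().items()}
    return VertebraLandmarks.from_points(lm.subject_id, lm.level, pts)


@settings(max_examples=60, derandomize=True)
@given(
    theta=stnum.floats(-25, 25),
    tau=stnum.floats(-12, 12),
    dx=stnum.floats(-100, 100),
    dy=stnum.floats(-100, 100),
    scale=stnum.floats(0.2, 5.0),
    delta=stnum.floats(-15, 15),
)
def test_rigid_motion_and_scale_equivariance(theta, tau, dx, dy, scale, delta):
    """Translation/scale leave all angles alone; global rotation shifts alpha
    and beta by exactly the rotation and leaves the torsion intrinsic."""
    lm = generate_phantom(PhantomParams(theta_post_deg=theta, tau_deg=tau))
    base = measure_vertebra(lm)

    moved = _transform_landmarks(lm, lambda x, y: (x * scale + dx, y * scale + dy))
    m = measure_vertebra(moved)
    assert m.alpha_deg == pytest.approx(base.alpha_deg, abs=1e-9)
    assert m.beta_deg == pytest.approx(base.beta_deg, abs=1e-9)

    rotated = _transform_landmarks(lm, lambda x, y: rotate_cw(x, y, delta))
    m = measure_vertebra(rotated)
    assert m.alpha_deg == pytest.approx(base.alpha_deg + delta, abs=1e-9)
    assert m.beta_deg == pytest.approx(base.beta_deg + delta, abs=1e-9)
    assert m.torsion_deg == pytest.approx(base.torsion_deg, abs=1e-9)


@settings(max_examples=60, derandomize=True)
@given(theta=stnum.floats(-25, 25), tau=stnum.floats(-12, 12))
def test_mirror_antisymmetry(theta, tau):
    """Sagittal reflection with left/right role swap negates all three angles."""
    lm = generate_phantom(PhantomParams(theta_post_deg=theta, tau_deg=tau))
    pts = lm.points_by_role()

    def flip(p):
        return Point2D(-p.x, p.y)

    mirrored = VertebraLandmarks.from_points(
        lm.subject_id,
        lm.level,
        {
            "pedicle_base_left": flip(pts["pedicle_base_right"]),
            "pedicle_base_right": flip(pts["pedicle_base_left"]),
            "lamina_left_post": flip(pts["lamina_right_post"]),
            "lamina_left_ant": flip(pts["lamina_right_ant"]),
            "lamina_right_post": flip(pts["lamina_left_post"]),
            "lamina_right_ant": flip(pts["lamina_left_ant"]),
        },
    )
    base = measure_vertebra(lm)
    m = measure_vertebra(mirrored)
    assert m.alpha_deg == pytest.approx(-base.alpha_deg, abs=1e-9)
    assert m.beta_deg == pytest.approx(-base.beta_deg, abs=1e-9)
    assert m.torsion_deg == pytest.approx(-base.torsion_deg, abs=1e-9)


def test_torsion_identity_holds_under_noise(rng):
    """tau == beta - alpha exactly, even on noisy landmarks."""
    for _ in range(20):
        lm = generate_phantom(
            PhantomParams(
                theta_post_deg=float(rng.uniform(-20, 20)),
                tau_deg=float(rng.uniform(-10, 10)),
                noise_sigma_mm=1.0,
                seed=int(rng.integers(0, 2**31)),
            )
        )
        m = measure_vertebra(lm)
        assert m.torsion_deg == m.beta_deg - m.alpha_deg
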
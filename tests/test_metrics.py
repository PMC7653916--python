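"""Tooth planes, tip/torque angles, measurement and crown transfer."""

import math

import numpy as np
import pytest

from palatesup.frame import DegeneratePlaneError, Plane
from palatesup.metrics import (
    ToothLandmarkSet,
    buccolingual_plane,
    measure_tooth,
    mesiodistal_plane,
    tip_angle,
    tooth_axis,
    torque_angle,
    transfer_crown,
)
from palatesup.phantom import rotation_about
from palatesup.pipeline import build_t1_frame
from palatesup.transforms import RigidTransform

FOP = Plane((0, 0, 0), (0, 0, 1))


def test_mesiodistal_plane_axis_aligned_and_symmetric():
    md = mesiodistal_plane((0, 5, 2), (10, 5, 2), FOP)
    assert np.isclose(abs(np.dot(md.normal, [0, 1, 0])), 1.0)
    assert abs(md.signed_distance(np.array([0.0, 5.0, 0.0]))) < 1e-12
    md_swapped = mesiodistal_plane((10, 5, 2), (0, 5, 2), FOP)
    assert np.isclose(abs(np.dot(md.normal, md_swapped.normal)), 1.0)


def test_mesiodistal_plane_properties(rng):
    for _ in range(10):
        b, c = rng.normal(size=3) * 10, rng.normal(size=3) * 10
        md = mesiodistal_plane(b, c, FOP)
        assert abs(np.dot(md.normal, FOP.normal)) < 1e-12
        assert abs(np.dot(md.normal, c - b)) < 1e-9
        # both points and their projections lie on the plane
        for p in (b, c, b * [1, 1, 0], c * [1, 1, 0]):
            assert abs(md.signed_distance(np.asarray(p, float))) < 1e-9


def test_mesiodistal_plane_degenerate():
    with pytest.raises(DegeneratePlaneError):
        mesiodistal_plane((0, 0, 0), (0, 0, 5), FOP)  # perpendicular to FOP


def test_buccolingual_plane_perpendicular_to_both(rng):
    md = Plane((0, 0, 0), (0, 1, 0))
    bl = buccolingual_plane(md, FOP, through=(1, 2, 3))
    assert np.isclose(abs(np.dot(bl.normal, [1, 0, 0])), 1.0)
    assert abs(bl.signed_distance(np.array([1.0, 2.0, 3.0]))) < 1e-12
    for _ in range(10):
        n = rng.normal(size=3)
        n[2] = 0.1 * n[2]  # keep away from parallel with the FOP normal
        md = Plane(rng.normal(size=3), n)
        bl = buccolingual_plane(md, FOP, through=np.zeros(3))
        assert abs(np.dot(bl.normal, md.normal)) < 1e-9
        assert abs(np.dot(bl.normal, FOP.normal)) < 1e-9


def test_tooth_axis():
    assert np.allclose(tooth_axis((0, 0, 1), (0, 0, 0)), [0, 0, 1])
    assert np.allclose(tooth_axis((0, 0, 0), (0, 0, 1)), [0, 0, -1])
    v = tooth_axis((3, -1, 2), (0, 1, 1))
    assert np.isclose(np.linalg.norm(v), 1.0)
    with pytest.raises(ValueError):
        tooth_axis((1, 1, 1), (1, 1, 1))


def test_upright_axis_zero_angles():
    md = Plane((0, 0, 0), (0, 1, 0))
    bl = buccolingual_plane(md, FOP, through=np.zeros(3))
    assert abs(torque_angle((0, 0, 1), md, FOP)) < 1e-12
    assert abs(tip_angle((0, 0, 1), bl, FOP)) < 1e-12


def test_in_plane_tilt_preserved():
    """An axis tilted within the projection plane keeps its tilt angle."""
    md = Plane((0, 0, 0), (0, 1, 0))  # plane spanned by x and z
    t = math.radians(10.0)
    axis = np.array([math.sin(t), 0.0, math.cos(t)])
    assert np.isclose(
        torque_angle(axis, md, FOP, positive_toward=np.array([1.0, 0, 0])), 10.0
    )
    bl = buccolingual_plane(md, FOP, through=np.zeros(3))  # spanned by y and z
    t2 = math.radians(7.0)
    axis2 = np.array([0.0, math.sin(t2), math.cos(t2)])
    assert np.isclose(
        tip_angle(axis2, bl, FOP, positive_toward=np.array([0, 1.0, 0])), 7.0
    )


def _angle_oracle(axis, plane_normal, fop_normal, tangent):
    """Brute-force reference: acos of the normalized in-plane projection
    against the FOP normal, signed by the tangential component."""
    u = plane_normal / np.linalg.norm(plane_normal)
    p = axis - np.dot(axis, u) * u
    p = p / np.linalg.norm(p)
    if np.dot(p, fop_normal) < 0:
        p = -p
    ang = math.degrees(math.acos(np.clip(np.dot(p, fop_normal), -1, 1)))
    return math.copysign(ang, np.dot(p, tangent)) if ang > 0 else 0.0


def test_angles_match_bruteforce_oracle(rng):
    for _ in range(100):
        n = rng.normal(size=3)
        fop = Plane(rng.normal(size=3), n)
        seg = rng.normal(size=3)
        if np.linalg.norm(np.cross(seg, fop.normal)) < 1e-2:
            continue
        md = mesiodistal_plane(rng.normal(size=3), rng.normal(size=3) + seg, fop)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        if np.linalg.norm(axis - np.dot(axis, md.normal) * md.normal) < 1e-2:
            continue
        ref = rng.normal(size=3)
        got = torque_angle(axis, md, fop, positive_toward=ref)
        t = np.cross(md.normal, fop.normal)
        t /= np.linalg.norm(t)
        if abs(np.dot(t, ref)) >= 1e-6 and np.dot(t, ref) < 0:
            t = -t
        assert np.isclose(got, _angle_oracle(axis, md.normal, fop.normal, t), atol=1e-9)


def test_orthogonal_decomposition_identity(rng):
    """tan^2(torque) + tan^2(tip) = tan^2(total inclination) for pairwise
    orthogonal mesiodistal/buccolingual/occlusal planes."""
    md = Plane((0, 0, 0), (0, 1, 0))
    bl = buccolingual_plane(md, FOP, through=np.zeros(3))
    for _ in range(20):
        axis = rng.normal(size=3)
        axis[2] = abs(axis[2]) + 1.0
        axis /= np.linalg.norm(axis)
        torq = torque_angle(axis, md, FOP)
        tip = tip_angle(axis, bl, FOP)
        total = math.degrees(math.acos(np.clip(axis[2], -1, 1)))
        assert np.isclose(
            math.tan(math.radians(torq)) ** 2 + math.tan(math.radians(tip)) ** 2,
            math.tan(math.radians(total)) ** 2,
            atol=1e-9,
        )


def test_measure_tooth_reproduces_phantom_pose(null_bundle):
    frame, fop = build_t1_frame(null_bundle.t1_landmarks)
    for tooth, lms in null_bundle.tooth_landmark_sets("t1").items():
        m = measure_tooth(lms, frame, fop)
        gt = null_bundle.gt_measurements_t1[tooth]
        assert np.allclose(m.position, gt.position, atol=1e-9)
        assert np.isclose(m.tip, gt.tip, atol=1e-9)
        assert np.isclose(m.torque, gt.torque, atol=1e-9)


def test_measure_invariant_under_rigid_motion(null_bundle, rng):
    """Moving the whole model (landmarks, suture, FOP points) rigidly leaves
    every measured quantity unchanged."""
    from palatesup.mesh import Landmark

    T = rotation_about(rng.normal(size=3), 18.0, center=[5, -3, 2])
    T = RigidTransform(T.rotation, T.translation + np.array([4.0, -6.0, 2.0]))
    frame, fop = build_t1_frame(null_bundle.t1_landmarks)
    moved_lms = [
        Landmark(lm.id, T.apply(lm.position), lm.tooth)
        for lm in null_bundle.t1_landmarks
    ]
    frame2, fop2 = build_t1_frame(moved_lms)
    for tooth, lms in null_bundle.tooth_landmark_sets("t1").items():
        m1 = measure_tooth(lms, frame, fop)
        m2 = measure_tooth(lms.transformed(T), frame2, fop2)
        assert np.allclose(m1.position, m2.position, atol=1e-8)
        assert np.isclose(m1.tip, m2.tip, atol=1e-8)
        assert np.isclose(m1.torque, m2.torque, atol=1e-8)


def test_swap_labels_flips_torque_sign_only(null_bundle):
    """Swapping mesial/distal labels mirrors the mesiodistal plane's
    orientation; the signed torque is unchanged in magnitude."""
    frame, fop = build_t1_frame(null_bundle.t1_landmarks)
    lms = null_bundle.tooth_landmark_sets("t1")["RU6"]
    pts = dict(lms.points)
    pts["B"], pts["C"] = pts["C"], pts["B"]
    swapped = ToothLandmarkSet("RU6", pts)
    m1 = measure_tooth(lms, frame, fop)
    m2 = measure_tooth(swapped, frame, fop)
    assert np.isclose(abs(m1.torque), abs(m2.torque), atol=1e-9)
    assert np.isclose(m1.tip, m2.tip, atol=1e-9)


def test_landmark_set_validation():
    with pytest.raises(ValueError):
        ToothLandmarkSet("RU6", {"A": (0, 0, 0)})  # missing B..E
    with pytest.raises(ValueError):
        ToothLandmarkSet(
            "RU1",
            {"F": (0, 0, 0), "G": (1, 0, 0), "H": (1, 0, 0), "I": (0, 0, 5)},
        )  # G == H


def test_transfer_crown_self_is_exact(null_bundle):
    t2 = null_bundle.t2
    lms = null_bundle.tooth_landmark_sets("t2")["RU6"]
    moved, res = transfer_crown(t2, null_bundle.t2_masks["crown_RU6"], lms, t2)
    for k in lms.points:
        assert np.array_equal(moved.points[k], lms.points[k])
    assert res.rms_residual < 1e-12


def test_transfer_crown_recovers_known_transform(null_bundle):
    T = rotation_about([0.2, 0.7, 0.7], 4.0, center=[0, -20, 0])
    T = RigidTransform(T.rotation, T.translation + np.array([1.0, 2.0, -1.0]))
    t2 = null_bundle.t2
    target = t2.transformed(T)
    lms = null_bundle.tooth_landmark_sets("t2")["LU6"]
    pert = rotation_about([1.0, 0.2, 0.1], 1.0, center=[0, -20, 0])
    init = RigidTransform(
        pert.rotation @ T.rotation,
        pert.rotation @ T.translation + pert.translation + np.array([0.3, -0.2, 0.2]),
    )
    moved, res = transfer_crown(
        t2, null_bundle.t2_masks["crown_LU6"], lms, target, init=init
    )
    for k in lms.points:
        assert np.allclose(moved.points[k], T.apply(lms.points[k]), atol=0.01)
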
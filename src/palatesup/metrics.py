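"""Per-tooth position and orientation (tip / torque) measurement.

Crown landmarks (named after the convention of the measurement protocol):

* first molars (U6): A mesial-buccal cusp, B/C distal/mesial points of the
  occlusal central groove, D/E most occlusal/gingival points of the buccal
  groove (D-E is the tooth axis);
* central incisors (U1): F midpoint of the incisal edge, G/H distal/mesial
  points of the incisal edge, I midpoint of the gingival edge (I-F is the
  tooth axis).

Position is the frame coordinate of the primary landmark (A for molars,
F for incisors).  The mesiodistal plane of a tooth is the plane through the
two mesiodistal landmarks and their FOP projections; the buccolingual plane
is perpendicular to both the mesiodistal plane and the FOP.  Torque is the
signed angle between the tooth axis projected onto the mesiodistal plane
and the FOP normal; tip the same with the buccolingual plane.  (This is the
measurement protocol's literal assignment; conventional orthodontic usage
often swaps the two names — set ``swap_tip_torque`` to relabel.)

Sign conventions, which the protocol leaves open, are fixed here: the
projected axis is oriented to the gingival side of the FOP and its signed
angle taken positive when it leans toward the frame's +x (anterior) for
torque and +z (transverse) for tip; when the in-plane reference direction
is perpendicular to the preferred frame axis the other axis is used.  All
angles lie in (-90, 90) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import CoordinateFrame, DegeneratePlaneError, Plane, project_point
from .mesh import Landmark, RegionMask, TriangleMesh, TOOTH_IDS
from .registration import ICPConfig, RegistrationResult, icp_region
from .transforms import RigidTransform

__all__ = [
    "ToothLandmarkSet",
    "ToothMeasurement",
    "U6_LANDMARKS",
    "U1_LANDMARKS",
    "mesiodistal_plane",
    "buccolingual_plane",
    "tooth_axis",
    "torque_angle",
    "tip_angle",
    "measure_tooth",
    "transfer_crown",
]

U6_LANDMARKS = ("A", "B", "C", "D", "E")
U1_LANDMARKS = ("F", "G", "H", "I")

# Pairs that must not coincide for the constructions to be defined.
_DISTINCT = {"U6": [("B", "C"), ("D", "E")], "U1": [("G", "H"), ("F", "I")]}


@dataclass(frozen=True)
class ToothLandmarkSet:
    """Complete named landmark set of one measurable tooth."""

    tooth: str
    points: dict  # id -> (3,) ndarray

    def __post_init__(self) -> None:
        if self.tooth not in TOOTH_IDS:
            raise ValueError(f"unknown tooth {self.tooth!r}")
        required = U6_LANDMARKS if self.kind == "U6" else U1_LANDMARKS
        pts = {k: np.asarray(v, float).reshape(3) for k, v in self.points.items()}
        missing = [k for k in required if k not in pts]
        if missing:
            raise ValueError(f"{self.tooth}: missing landmarks {missing}")
        for a, b in _DISTINCT[self.kind]:
            if np.linalg.norm(pts[a] - pts[b]) < 1e-9:
                raise ValueError(f"{self.tooth}: landmarks {a} and {b} coincide")
        object.__setattr__(self, "points", pts)

    @property
    def kind(self) -> str:
        return "U6" if self.tooth.endswith("6") else "U1"

    @property
    def primary(self) -> np.ndarray:
        """Position landmark: mesial-buccal cusp (U6) or incisal midpoint (U1)."""
        return self.points["A" if self.kind == "U6" else "F"]

    def as_landmarks(self) -> list[Landmark]:
        return [Landmark(k, v, self.tooth) for k, v in sorted(self.points.items())]

    @classmethod
    def from_landmarks(cls, landmarks, tooth: str) -> "ToothLandmarkSet":
        pts = {lm.id: lm.position for lm in landmarks if lm.tooth == tooth}
        return cls(tooth, pts)

    def transformed(self, T: RigidTransform) -> "ToothLandmarkSet":
        return ToothLandmarkSet(
            self.tooth, {k: T.apply(v) for k, v in self.points.items()}
        )


@dataclass(frozen=True)
class ToothMeasurement:
    tooth: str
    position: np.ndarray  # (x, y, z) in the T1 frame, mm
    tip: float  # degrees
    torque: float  # degrees

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite tooth position")
        object.__setattr__(self, "position", pos)


def mesiodistal_plane(distal: np.ndarray, mesial: np.ndarray, fop: Plane) -> Plane:
    """Plane through the mesiodistal landmark pair and their FOP projections.

    Its normal is horizontal (orthogonal to the FOP normal).  Degenerate when
    the segment is perpendicular to the FOP (the projections coincide).
    """
    distal = np.asarray(distal, float).reshape(3)
    mesial = np.asarray(mesial, float).reshape(3)
    seg = mesial - distal
    normal = np.cross(seg, fop.normal)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(seg), 1e-12):
        raise DegeneratePlaneError("mesiodistal segment is perpendicular to the FOP")
    return Plane(distal, normal)


def buccolingual_plane(md: Plane, fop: Plane, through: np.ndarray) -> Plane:
    """Plane perpendicular to both the mesiodistal plane and the FOP.

    Its normal is the (horizontal) mesiodistal direction; the anchor point is
    supplied by the caller (the tooth-axis midpoint in ``measure_tooth`` —
    the angles do not depend on it).
    """
    normal = np.cross(md.normal, fop.normal)
    if np.linalg.norm(normal) < 1e-9:
        raise DegeneratePlaneError("mesiodistal plane is parallel to the FOP")
    return Plane(np.asarray(through, float), normal)


def tooth_axis(occlusal_end: np.ndarray, gingival_end: np.ndarray) -> np.ndarray:
    """Unit tooth-axis vector oriented gingival -> occlusal."""
    occ = np.asarray(occlusal_end, float).reshape(3)
    gin = np.asarray(gingival_end, float).reshape(3)
    v = occ - gin
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("axis endpoints coincide")
    return v / n


def _signed_projection_angle(
    axis: np.ndarray,
    plane: Plane,
    fop: Plane,
    positive_toward: np.ndarray | None,
    fallback_toward: np.ndarray | None,
) -> float:
    """Signed angle between the axis projected into ``plane`` and the FOP
    normal line, in degrees.

    The projection is re-oriented to the gingival side of the FOP (the angle
    is between undirected lines, kept in (-90, 90]).  The in-plane horizontal
    tangent fixes the sign; it is oriented along ``positive_toward`` (or the
    fallback direction when nearly perpendicular to it).
    """
    a = np.asarray(axis, float).reshape(3)
    u = plane.normal
    n = fop.normal
    proj = a - np.dot(a, u) * u
    norm = np.linalg.norm(proj)
    if norm < 1e-9:
        raise DegeneratePlaneError("tooth axis is perpendicular to the projection plane")
    proj = proj / norm
    if np.dot(proj, n) < 0:
        proj = -proj
    tangent = np.cross(u, n)
    tangent = tangent / np.linalg.norm(tangent)
    if positive_toward is not None:
        s = float(np.dot(tangent, positive_toward))
        if abs(s) < 1e-6 and fallback_toward is not None:
            s = float(np.dot(tangent, fallback_toward))
        if s < 0:
            tangent = -tangent
    return float(np.degrees(np.arctan2(np.dot(proj, tangent), np.dot(proj, n))))


def torque_angle(
    axis: np.ndarray,
    md: Plane,
    fop: Plane,
    positive_toward: np.ndarray | None = None,
    fallback_toward: np.ndarray | None = None,
) -> float:
    """Signed angle between the axis projected onto the mesiodistal plane and
    the FOP normal (degrees)."""
    return _signed_projection_angle(axis, md, fop, positive_toward, fallback_toward)


def tip_angle(
    axis: np.ndarray,
    bl: Plane,
    fop: Plane,
    positive_toward: np.ndarray | None = None,
    fallback_toward: np.ndarray | None = None,
) -> float:
    """Signed angle between the axis projected onto the buccolingual plane and
    the FOP normal (degrees)."""
    return _signed_projection_angle(axis, bl, fop, positive_toward, fallback_toward)


def measure_tooth(
    lms: ToothLandmarkSet,
    frame: CoordinateFrame,
    fop: Plane,
    swap_tip_torque: bool = False,
) -> ToothMeasurement:
    """Position (frame coordinates of the primary landmark) and tip/torque."""
    pts = lms.points
    if lms.kind == "U6":
        distal, mesial = pts["B"], pts["C"]
        axis = tooth_axis(pts["D"], pts["E"])
        mid = (pts["D"] + pts["E"]) / 2.0
    else:
        distal, mesial = pts["G"], pts["H"]
        axis = tooth_axis(pts["F"], pts["I"])
        mid = (pts["F"] + pts["I"]) / 2.0
    md = mesiodistal_plane(distal, mesial, fop)
    bl = buccolingual_plane(md, fop, mid)
    torque = torque_angle(axis, md, fop, frame.x_axis, frame.z_axis)
    tip = tip_angle(axis, bl, fop, frame.z_axis, frame.x_axis)
    if swap_tip_torque:
        tip, torque = torque, tip
    return ToothMeasurement(lms.tooth, frame.to_frame(lms.primary), tip, torque)


def transfer_crown(
    t2: TriangleMesh,
    crown_mask: RegionMask,
    lms: ToothLandmarkSet,
    t2_prime: TriangleMesh,
    cfg: ICPConfig | None = None,
    init: RigidTransform | None = None,
) -> tuple[ToothLandmarkSet, RegistrationResult]:
    """Carry a crown patch with its bonded landmarks onto another aligned copy
    of the same model.

    The crown region of ``t2`` is rigidly registered onto ``t2_prime`` and
    the landmarks are moved by the recovered transform, so both models end up
    measured with the *same* landmark identifications (landmark-picking error
    cancels in the comparison).  When the two models coincide the transfer is
    exactly the identity.
    """
    result = icp_region(t2, t2_prime, crown_mask, init or RigidTransform.identity(), cfg)
    if not result.converged:
        raise RuntimeError(
            f"crown transfer for {lms.tooth} did not converge "
            f"(rms={result.rms_residual:.4g} mm after {result.n_iterations} iterations)"
        )
    return lms.transformed(result.transform), result
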
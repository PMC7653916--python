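"""Rigid (rotation + translation) transforms and landmark-based alignment.

All superimpositions in the pipeline are rigid: digital dental models are
1:1 replicas of the anatomy, so no scaling is ever estimated.  Rotations are
proper (determinant +1); reflections are rejected in the least-squares solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "DegenerateConfigurationError",
    "kabsch",
    "landmark_align",
    "rotation_angle_deg",
]


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration cannot determine a rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` in millimetre coordinates."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return rotation_angle_deg(self.rotation)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def rotation_angle_deg(R: np.ndarray) -> float:
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping ``src`` points onto ``dst`` points.

    Solves ``argmin_{R,t} sum_i |R src_i + t - dst_i|^2`` over proper
    rotations via the SVD of the cross-covariance, with the sign of the
    smallest singular direction flipped when needed so that det(R) = +1.

    Returns the transform and the RMS residual (mm).  If the two point sets
    are bitwise identical the exact identity is returned, so that a null
    alignment stays null to the last bit downstream.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise DegenerateConfigurationError("need at least 3 point pairs")
    if np.array_equal(src, dst):
        return RigidTransform.identity(), 0.0

    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    p = src - c_src
    q = dst - c_dst
    H = p.T @ q
    U, S, Vt = np.linalg.svd(H)
    # Collinear configurations leave the rotation about the line undetermined.
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise DegenerateConfigurationError("point configuration is (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_dst - R @ c_src
    T = RigidTransform(R, t)
    resid = T.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return T, rms


def landmark_align(src_landmarks, dst_landmarks) -> tuple[RigidTransform, float]:
    """Rigid alignment seeded from >=3 paired named landmarks.

    ``src_landmarks`` and ``dst_landmarks`` are iterables of objects with
    ``key`` and ``position`` attributes (see :mod:`palatesup.mesh`); pairs
    are matched by key and the transform maps source positions onto the
    destination ones.  Mirrors the three-landmark coarse pre-alignment used
    to seed surface registration.
    """
    src_map = {lm.key: np.asarray(lm.position, float) for lm in src_landmarks}
    dst_map = {lm.key: np.asarray(lm.position, float) for lm in dst_landmarks}
    common = sorted(set(src_map) & set(dst_map))
    if len(common) < 3:
        raise DegenerateConfigurationError(
            f"need >=3 paired landmarks, found {len(common)}"
        )
    src = np.array([src_map[k] for k in common])
    dst = np.array([dst_map[k] for k in common])
    return kabsch(src, dst)
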
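"""Occlusal-plane coordinate frame for pose-independent tooth measurement.

The frame is built on the pre-treatment (T1) model:

* the functional occlusal plane (FOP) is the orthogonal least-squares plane
  through the cusp tips of the bilateral first/second premolars and first
  molars (the molars' distal-lingual cusps excluded), 14 points by default;
* two points A (anterior) and B (posterior) marked on the midpalatal suture
  are projected onto the FOP as A' and B';
* B' is the origin, B'->A' the x axis (anterior, in the FOP), B'->B the
  y axis (the FOP normal, toward the palate), and z = x cross y completes a
  right-handed frame.  The x-y plane is the sagittal plane through A A' B B'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform

__all__ = [
    "Plane",
    "CoordinateFrame",
    "DegeneratePlaneError",
    "fit_fop",
    "project_point",
    "build_frame",
]


class DegeneratePlaneError(ValueError):
    """Input configuration does not determine a plane or frame."""


@dataclass(frozen=True)
class Plane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, float).reshape(3)
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise DegeneratePlaneError("plane normal has zero length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float)
        return (np.atleast_2d(q) - self.point) @ self.normal if q.ndim > 1 else float(
            np.dot(q - self.point, self.normal)
        )


def fit_fop(cusp_points: np.ndarray, toward: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through cusp points.

    Minimizes the sum of squared orthogonal distances (the plane normal is
    the smallest-variance direction of the centred point cloud).  The normal
    sign is oriented toward ``toward`` when given — in the pipeline this is
    the palatal suture point B, so the normal points to the palatal/gingival
    side and angle signs are reproducible.  Without ``toward`` the sign is
    fixed by making the normal's largest-magnitude component positive.
    """
    pts = np.asarray(cusp_points, float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegeneratePlaneError("need at least 3 cusp points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # Smallest right-singular vector = normal of the orthogonal LS plane.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegeneratePlaneError("cusp points are (near-)collinear")
    normal = vt[2]
    if toward is not None:
        side = float(np.dot(np.asarray(toward, float) - centroid, normal))
        if abs(side) < 1e-12:
            raise DegeneratePlaneError("orientation point lies on the fitted plane")
        if side < 0:
            normal = -normal
    else:
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
    return Plane(centroid, normal)


def fit_plane_residual(points: np.ndarray, plane: Plane) -> float:
    """RMS orthogonal distance of points to a plane (mm)."""
    pts = np.asarray(points, float).reshape(-1, 3)
    d = (pts - plane.point) @ plane.normal
    return float(np.sqrt(np.mean(d**2)))


def project_point(p: np.ndarray, plane: Plane) -> np.ndarray:
    """Orthogonal projection of point(s) onto a plane."""
    p = np.asarray(p, float)
    single = p.ndim == 1
    q = np.atleast_2d(p)
    d = (q - plane.point) @ plane.normal
    out = q - d[:, None] * plane.normal
    return out[0] if single else out


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed orthonormal frame: origin B', axes x (B'A'), y (B'B), z."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, float).reshape(3)
        axes = [np.asarray(a, float).reshape(3) for a in (self.x_axis, self.y_axis, self.z_axis)]
        R = np.stack(axes)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
            raise ValueError("frame is left-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", axes[0])
        object.__setattr__(self, "y_axis", axes[1])
        object.__setattr__(self, "z_axis", axes[2])

    @property
    def rotation(self) -> np.ndarray:
        """World->frame rotation (rows are the axes)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, p: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates (rigid change of basis)."""
        p = np.asarray(p, float)
        single = p.ndim == 1
        q = (np.atleast_2d(p) - self.origin) @ self.rotation.T
        return q[0] if single else q

    def from_frame(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        single = p.ndim == 1
        q = np.atleast_2d(p) @ self.rotation + self.origin
        return q[0] if single else q

    def transformed(self, T: RigidTransform) -> "CoordinateFrame":
        """Frame carried along by a rigid motion of the model."""
        R = T.rotation
        return CoordinateFrame(
            T.apply(self.origin), R @ self.x_axis, R @ self.y_axis, R @ self.z_axis
        )

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
        }


def build_frame(A: np.ndarray, B: np.ndarray, fop: Plane) -> CoordinateFrame:
    """Frame from the suture points and the FOP.

    A is the anterior suture point, B the posterior one; A' and B' are their
    FOP projections.  Degenerate when B lies on the FOP (y undefined) or
    A' == B' (the suture is perpendicular to the FOP).
    """
    A = np.asarray(A, float).reshape(3)
    B = np.asarray(B, float).reshape(3)
    Ap = project_point(A, fop)
    Bp = project_point(B, fop)
    x_dir = Ap - Bp
    if np.linalg.norm(x_dir) < 1e-9:
        raise DegeneratePlaneError("suture projections coincide (A' == B')")
    y_dir = B - Bp
    if np.linalg.norm(y_dir) < 1e-9:
        raise DegeneratePlaneError("posterior suture point lies on the FOP")
    x = x_dir / np.linalg.norm(x_dir)
    y = y_dir / np.linalg.norm(y_dir)  # = +/- FOP normal by construction
    z = np.cross(x, y)
    return CoordinateFrame(Bp, x, y, z)
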
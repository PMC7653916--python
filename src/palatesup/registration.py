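"""Region-restricted rigid best-fit surface registration (trimmed ICP).

Two superimposition modes share one engine:

* ``palate`` — the moving post-treatment model is registered to the
  pre-treatment model by its palatal-vault stable region (the medial
  two-thirds of the third rugae and the vault dorsal to it);
* ``crown`` — a dental-crown patch is registered to a target surface, used
  both for the reference (CBCT-surface) route and for carrying landmarks
  from one aligned copy of a model to another.

The ICP flavour is point-to-surface: sample points from the moving region
are matched to their exact nearest points on the fixed triangle mesh, the
worst correspondences are gated and trimmed, and the rigid update is the
closed-form least-squares (Kabsch) solve.  Registration always starts from
a landmark-seeded coarse alignment; there is no global search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from trimesh import triangles as _tri

from .mesh import RegionMask, TriangleMesh, restrict
from .transforms import RigidTransform, kabsch

__all__ = [
    "ICPConfig",
    "RegistrationResult",
    "SurfaceIndex",
    "DivergenceError",
    "icp_region",
]


class DivergenceError(RuntimeError):
    """ICP lost all correspondences or could not proceed."""


@dataclass(frozen=True)
class ICPConfig:
    """Best-fit configuration.

    max_iter / tol: stop when the relative change of the trimmed RMS falls
    below ``tol`` or after ``max_iter`` iterations.  ``trim_fraction`` of the
    worst gated correspondences is discarded each iteration (robustness to
    soft-tissue edge effects); pairs farther than ``gate_factor`` times the
    current RMS are rejected outright.  Region sampling uses the region's
    vertices plus face barycentres; if that still yields fewer than
    ``min_samples`` points, edge midpoints are added.  ``max_samples`` caps
    the sample count (seeded random subsample) to bound run time.
    """

    max_iter: int = 100
    tol: float = 1e-6
    trim_fraction: float = 0.10
    gate_factor: float = 5.0
    min_samples: int = 500
    max_samples: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.max_iter < 1 or self.tol < 0 or self.gate_factor <= 1:
            raise ValueError("invalid ICP configuration")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    n_correspondences: int
    n_iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class SurfaceIndex:
    """Exact nearest-point queries against a triangle mesh.

    Candidate triangles are found through a KD-tree over triangle centroids
    (k nearest), then the exact closest point on each candidate triangle is
    evaluated and the best kept.  With reasonably uniform triangle sizes the
    candidate set virtually always contains the true nearest triangle.
    """

    def __init__(self, mesh: TriangleMesh, k_candidates: int = 12):
        self._triangles = mesh.triangles
        self._k = int(min(k_candidates, len(self._triangles)))
        self._tree = cKDTree(mesh.face_centroids())
        cr = np.cross(
            self._triangles[:, 1] - self._triangles[:, 0],
            self._triangles[:, 2] - self._triangles[:, 0],
        )
        norms = np.linalg.norm(cr, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.face_normals = cr / norms

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest surface points, distances, face indices) for
        (N, 3) query points."""
        points = np.asarray(points, float).reshape(-1, 3)
        _, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx)
        best_pts = np.empty_like(points)
        best_d2 = np.full(len(points), np.inf)
        best_face = np.zeros(len(points), dtype=np.int64)
        for j in range(idx.shape[1]):
            cand = _tri.closest_point(self._triangles[idx[:, j]], points)
            d2 = np.sum((cand - points) ** 2, axis=1)
            better = d2 < best_d2
            best_pts[better] = cand[better]
            best_d2[better] = d2[better]
            best_face[better] = idx[better, j]
        return best_pts, np.sqrt(best_d2), best_face


def sample_region(mesh: TriangleMesh, region: RegionMask, cfg: ICPConfig) -> np.ndarray:
    """Sample points of the masked region: vertices + face barycentres
    (+ edge midpoints for sparse masks), capped at ``cfg.max_samples``."""
    sub = restrict(mesh, region)
    pts = [sub.vertices, sub.face_centroids()]
    if sum(len(p) for p in pts) < cfg.min_samples:
        t = sub.triangles
        mids = np.concatenate(
            [(t[:, 0] + t[:, 1]) / 2, (t[:, 1] + t[:, 2]) / 2, (t[:, 2] + t[:, 0]) / 2]
        )
        pts.append(mids)
    samples = np.concatenate(pts)
    if len(samples) > cfg.max_samples:
        rng = np.random.default_rng(cfg.seed)
        keep = rng.choice(len(samples), size=cfg.max_samples, replace=False)
        samples = samples[np.sort(keep)]
    return samples


def _planarity_warning(samples: np.ndarray) -> str | None:
    cov = np.cov((samples - samples.mean(axis=0)).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] <= 1e-6 * max(evals[-1], 1e-12):
        return "region is near-planar; in-plane pose may be weakly constrained"
    return None


def _gate_and_trim(dist: np.ndarray, prev_rms: float, cfg: ICPConfig) -> np.ndarray:
    keep = np.ones(len(dist), dtype=bool)
    if np.isfinite(prev_rms) and prev_rms > 0:
        keep &= dist <= cfg.gate_factor * prev_rms
    if not keep.any():
        raise DivergenceError("no correspondences within the gating distance")
    if cfg.trim_fraction > 0:
        n_drop = int(np.floor(cfg.trim_fraction * keep.sum()))
        if n_drop > 0:
            kept_idx = np.flatnonzero(keep)
            order = np.argsort(dist[kept_idx], kind="stable")
            keep[kept_idx[order[-n_drop:]]] = False
    if keep.sum() < 3:
        raise DivergenceError("fewer than 3 correspondences after trimming")
    return keep


def _trimmed_rms(T: RigidTransform, samples, index, prev_rms, cfg) -> float:
    _, dist, _ = index.query(T.apply(samples))
    keep = _gate_and_trim(dist, prev_rms, cfg)
    return float(np.sqrt(np.mean(dist[keep] ** 2)))


def _point_to_plane_step(
    T: RigidTransform,
    moved: np.ndarray,
    targets: np.ndarray,
    normals: np.ndarray,
) -> RigidTransform:
    """Linearized least-squares rigid update minimizing the signed distances
    along the target surface normals (Gauss-Newton step of point-to-plane
    ICP); the incremental rotation is re-orthogonalized exactly."""
    from scipy.spatial.transform import Rotation

    b = -np.einsum("ij,ij->i", moved - targets, normals)
    A = np.hstack([np.cross(moved, normals), normals])
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    R = Rotation.from_rotvec(delta[:3]).as_matrix()
    step = RigidTransform(R, delta[3:])
    return step.compose(T)


def icp_region(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    region: RegionMask,
    init: RigidTransform,
    cfg: ICPConfig | None = None,
) -> RegistrationResult:
    """Trimmed point-to-surface ICP of a region of ``moving`` onto ``fixed``.

    Returns the rigid transform mapping the moving model into the fixed
    model's space.  Each iteration matches the transformed region samples to
    their exact nearest surface points, gates and trims the correspondences,
    and proposes two rigid updates — a linearized point-to-plane step (fast
    tangential convergence on smooth surfaces) and the closed-form
    least-squares fit onto the projections — accepting whichever lowers the
    trimmed RMS; a step that lowers neither terminates the iteration.  The
    objective is therefore non-increasing across accepted iterations.
    Convergence is declared when its relative change drops below
    ``cfg.tol``.  If the initial alignment is already exact (trimmed RMS at
    machine zero) the seed transform is returned unchanged, so null
    registrations stay exactly null.
    """
    cfg = cfg or ICPConfig()
    samples = sample_region(moving, region, cfg)
    index = SurfaceIndex(fixed)
    warnings: list[str] = []
    w = _planarity_warning(samples)
    if w:
        warnings.append(w)

    T = init
    prev_rms = np.inf
    history: list[float] = []
    n_kept = len(samples)
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        p = T.apply(samples)
        targets, dist, faces = index.query(p)
        keep = _gate_and_trim(dist, prev_rms, cfg)
        n_kept = int(keep.sum())
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        if rms <= 1e-12:
            converged = True
            break
        if np.isfinite(prev_rms) and abs(prev_rms - rms) <= cfg.tol * max(prev_rms, 1e-30):
            converged = True
            break

        candidates = [
            _point_to_plane_step(
                T, p[keep], targets[keep], index.face_normals[faces[keep]]
            ),
            kabsch(samples[keep], targets[keep])[0],
        ]
        scored = [(_trimmed_rms(Tc, samples, index, rms, cfg), Tc) for Tc in candidates]
        best_rms, best_T = min(scored, key=lambda s: s[0])
        if best_rms >= rms:
            converged = True  # no rigid update improves the objective
            break
        prev_rms = rms
        T = best_T

    return RegistrationResult(
        transform=T,
        rms_residual=history[-1] if history else 0.0,
        n_correspondences=n_kept,
        n_iterations=n_iter,
        converged=converged,
        rms_history=history,
        warnings=warnings,
    )
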
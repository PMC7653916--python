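"""Mesh and landmark data model, STL I/O and region masks.

Maxillary digital models are triangle surface meshes in millimetres.  STL
carries no attributes, so landmarks live in a plain-text sidecar table and
region masks (palatal vault, per-tooth crowns) in a JSON sidecar keyed by
mask name.  Vertex deduplication on read uses exact coordinate equality —
not tolerance welding — so landmark-to-surface distances stay stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "Landmark",
    "RegionMask",
    "MeshFormatError",
    "EmptyMeshError",
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
    "read_masks",
    "write_masks",
    "restrict",
]

TOOTH_IDS = ("RU6", "LU6", "RU1", "LU1")


class MeshFormatError(ValueError):
    """Malformed STL or sidecar file."""


class EmptyMeshError(ValueError):
    """STL solid or mask contains no geometry."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh (vertices in mm, faces as vertex-index triplets)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.size == 0 or self.faces.size == 0:
            raise EmptyMeshError(f"mesh {self.name!r} is empty")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError(f"mesh {self.name!r} has non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError(f"mesh {self.name!r} has out-of-range face indices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        cr = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length where defined)."""
        t = self.triangles
        fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms

    def transformed(self, T) -> "TriangleMesh":
        return replace(self, vertices=T.apply(self.vertices))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass(frozen=True)
class Landmark:
    """Named 3D point; per-tooth landmarks carry the tooth they belong to."""

    id: str
    position: np.ndarray
    tooth: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"landmark {self.id!r} has non-finite position")
        if self.tooth is not None and self.tooth not in TOOTH_IDS:
            raise ValueError(f"unknown tooth {self.tooth!r} for landmark {self.id!r}")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> str:
        """Unique key within a model (tooth-qualified for crown landmarks)."""
        return self.id if self.tooth is None else f"{self.tooth}:{self.id}"

    def moved_to(self, position: np.ndarray) -> "Landmark":
        return Landmark(self.id, np.asarray(position, float), self.tooth)


@dataclass
class RegionMask:
    """Face-index subset of a named mesh (palatal vault, crown, cusp set)."""

    mesh_ref: str
    kind: str  # palatal_vault | crown | cusp_set
    member_faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        faces = np.unique(np.asarray(self.member_faces, dtype=np.int64))
        if faces.size == 0:
            raise EmptyMeshError(f"mask {self.name or self.kind!r} is empty")
        if faces.min() < 0:
            raise ValueError("mask has negative face indices")
        self.member_faces = faces
        if not self.name:
            self.name = self.kind

    def validate_for(self, mesh: TriangleMesh) -> None:
        if self.member_faces.max() >= mesh.n_faces:
            raise ValueError(
                f"mask {self.name!r} references face "
                f"{int(self.member_faces.max())} but mesh {mesh.name!r} has "
                f"{mesh.n_faces} faces"
            )


# ---------------------------------------------------------------------------
# STL I/O


def _dedup_exact(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def read_stl(path: str | Path, name: str | None = None) -> TriangleMesh:
    """Read an ASCII or binary STL file into a :class:`TriangleMesh`.

    Vertices shared bitwise between facets are merged; face winding is kept
    as stored.
    """
    path = Path(path)
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises various types on bad input
        raise MeshFormatError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise EmptyMeshError(f"STL file {path} contains no facets")
    v, f = _dedup_exact(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    return TriangleMesh(v, f, name=name if name is not None else path.stem)


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write a mesh as STL (``dialect`` = ``ascii`` or ``binary``)."""
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    tm = mesh.to_trimesh()
    if dialect == "ascii":
        data = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(data)
    else:
        data = trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    return path


# ---------------------------------------------------------------------------
# Landmark sidecar table: whitespace-delimited "id tooth x y z", '-' = no tooth.


def write_landmarks(landmarks, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# id tooth x y z"]
    seen: set[str] = set()
    for lm in landmarks:
        if lm.key in seen:
            raise ValueError(f"duplicate landmark {lm.key!r}")
        seen.add(lm.key)
        tooth = lm.tooth if lm.tooth is not None else "-"
        x, y, z = lm.position
        lines.append(f"{lm.id} {tooth} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path: str | Path) -> list[Landmark]:
    path = Path(path)
    out: list[Landmark] = []
    seen: set[str] = set()
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise MeshFormatError(f"{path}:{ln}: expected 'id tooth x y z'")
        lid, tooth = parts[0], parts[1]
        try:
            pos = [float(p) for p in parts[2:5]]
        except ValueError as exc:
            raise MeshFormatError(f"{path}:{ln}: non-numeric coordinate") from exc
        lm = Landmark(lid, pos, None if tooth == "-" else tooth)
        if lm.key in seen:
            raise ValueError(f"{path}:{ln}: duplicate landmark {lm.key!r}")
        seen.add(lm.key)
        out.append(lm)
    return out


# ---------------------------------------------------------------------------
# Region-mask sidecar (JSON)


def write_masks(masks: dict[str, RegionMask], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        name: {
            "mesh_ref": m.mesh_ref,
            "kind": m.kind,
            "faces": m.member_faces.tolist(),
        }
        for name, m in masks.items()
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_masks(path: str | Path) -> dict[str, RegionMask]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MeshFormatError(f"cannot parse mask file {path}: {exc}") from exc
    return {
        name: RegionMask(d["mesh_ref"], d["kind"], np.asarray(d["faces"]), name=name)
        for name, d in payload.items()
    }


# ---------------------------------------------------------------------------


def restrict(mesh: TriangleMesh, mask: RegionMask) -> TriangleMesh:
    """Sub-mesh containing exactly the masked faces and their vertices."""
    mask.validate_for(mesh)
    faces = mesh.faces[mask.member_faces]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TriangleMesh(
        mesh.vertices[used], remap[faces], name=f"{mesh.name}:{mask.name}"
    )
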
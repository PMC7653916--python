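"""Synthetic palate phantom with known ground truth.

Real study inputs (laser-scanned dental casts of treated patients) are not
available, so the pipeline is exercised on a parametric phantom:

* a smooth palatal-vault dome with transverse rugae-like ridges anteriorly,
  carrying the midpalatal suture points (A anterior, B posterior), the
  stable-region mask (medial part of the third rugae plus the vault dorsal
  to it) and auxiliary stable landmarks used to seed registration;
* four measurable crowns — right/left first molars (RU6/LU6) and central
  incisors (RU1/LU1) — as analytic solids whose named landmarks (A-E for
  molars, F-I for incisors) are emitted at exactly known coordinates; the
  crowns are analytic so that landmark positions are exact by construction,
  which scanned anatomy cannot provide;
* 14 functional-occlusal-plane cusp points (premolar and molar cusps, the
  molars' distal-lingual cusps excluded), coplanar in the noiseless phantom;
* a per-tooth rigid "treatment" motion, a rigid global pose difference
  between the two acquisitions, and Gaussian surface noise along vertex
  normals (stable-region noise separately configurable, plus an optional
  smooth soft-tissue drift of the palate to stress the stable-region
  assumption).

The canonical T1 space puts the functional occlusal plane at z = 0 with
+z toward the palate, the midline at y = 0 and +x anterior; the measurement
frame derived from it has +x anterior, +y toward the palate and +z toward
the patient's right.

Ground-truth tooth measurements are computed analytically from the phantom
parameters and landmark coordinates, never from the meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .frame import CoordinateFrame
from .mesh import Landmark, RegionMask, TriangleMesh
from .metrics import ToothLandmarkSet, ToothMeasurement
from .transforms import RigidTransform

__all__ = [
    "ToothPose",
    "PhantomSpec",
    "PhantomBundle",
    "GeometryError",
    "generate_phantom",
    "cohort",
    "rotation_about",
]

_Z = np.array([0.0, 0.0, 1.0])


class GeometryError(RuntimeError):
    """Phantom geometry became inconsistent (e.g. crowns overlap)."""


def rotation_about(axis: np.ndarray, angle_deg: float, center: np.ndarray) -> RigidTransform:
    """Rigid rotation by ``angle_deg`` about a line through ``center``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
    center = np.asarray(center, float)
    return RigidTransform(R, center - R @ center)


@dataclass(frozen=True)
class ToothPose:
    """Pre-treatment pose of one tooth: frame coordinates of its primary
    landmark (mm) plus signed tip and torque angles (degrees)."""

    position: tuple
    tip: float
    torque: float


def _default_tooth_poses() -> dict:
    return {
        "RU6": ToothPose((9.5, -0.3, 23.0), tip=7.0, torque=3.0),
        "LU6": ToothPose((9.5, -0.3, -23.0), tip=-7.0, torque=3.0),
        "RU1": ToothPose((33.0, -0.2, 6.0), tip=8.0, torque=-1.5),
        "LU1": ToothPose((33.0, -0.2, -6.0), tip=8.0, torque=1.5),
    }


def _identity_motions() -> dict:
    return {t: RigidTransform.identity() for t in ("RU6", "LU6", "RU1", "LU1")}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom subject (all lengths mm, angles degrees)."""

    # Palatal dome: full transverse width, anteroposterior length, apex height.
    dome_width: float = 34.0
    dome_length: float = 40.0
    dome_height: float = 12.0
    # Rugae ridges (most posterior ridge first; the stable region starts
    # there) and the median palatine raphe running along the suture.
    rugae_count: int = 3
    rugae_amplitude: float = 1.2
    rugae_spacing: float = 3.0
    rugae_posterior_x: float = 9.0
    raphe_amplitude: float = 0.5
    # Mesh density.
    palate_grid: tuple = (64, 44)
    crown_subdivisions: int = 3
    # Suture points (x positions on the midline; B is the frame origin's source).
    suture_anterior_x: float = 15.0
    suture_posterior_x: float = -12.0
    # Teeth.
    tooth_poses: dict = field(default_factory=_default_tooth_poses)
    # Acquisition/treatment geometry.
    global_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    treatment: dict = field(default_factory=_identity_motions)
    # Surface noise (Gaussian along vertex normals, per scan).
    surface_noise_sd: float = 0.05
    stable_noise_sd: float = 0.0
    soft_tissue_drift_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface_noise_sd < 0 or self.stable_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        nx, ny = self.palate_grid
        if nx < 16 or ny < 12:
            raise ValueError("palate grid too coarse for region sampling")


@dataclass
class PhantomBundle:
    """One phantom subject: both acquisitions plus every ground truth."""

    t1: TriangleMesh
    t1_landmarks: list
    t1_masks: dict
    t2: TriangleMesh
    t2_landmarks: list
    t2_masks: dict
    reference_surface: TriangleMesh  # post-treatment anatomy already in T1 space
    global_pose: RigidTransform
    treatment: dict
    frame: CoordinateFrame  # ground-truth measurement frame of T1
    gt_measurements_t1: dict  # tooth -> ToothMeasurement
    gt_measurements_t2: dict  # tooth -> ToothMeasurement (in the T1 frame)
    spec: PhantomSpec = None

    def tooth_landmark_sets(self, which: str = "t2") -> dict:
        lms = self.t2_landmarks if which == "t2" else self.t1_landmarks
        return {
            tooth: ToothLandmarkSet.from_landmarks(lms, tooth)
            for tooth in self.treatment
        }


# ---------------------------------------------------------------------------
# Geometry helpers


def _frame_to_mesh(p_frame: np.ndarray, xB: float) -> np.ndarray:
    """Frame coordinates (x anterior, y up, z right) -> canonical mesh coords."""
    X, Y, Z = p_frame
    return np.array([xB + X, -Z, Y])


def _orient_tangent(t: np.ndarray, primary: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    s = float(np.dot(t, primary))
    if abs(s) < 1e-6:
        s = float(np.dot(t, fallback))
    return t if s >= 0 else -t


def _axis_from_tip_torque(
    m_s: np.ndarray, x_f: np.ndarray, z_f: np.ndarray, tip: float, torque: float
) -> np.ndarray:
    """Unit vector (pointing gingivally, +z side) whose projections onto the
    tooth's mesiodistal / buccolingual planes make the requested signed
    angles with the occlusal-plane normal."""
    u = np.cross(m_s, _Z)
    u = u / np.linalg.norm(u)  # mesiodistal-plane normal
    t_md = np.cross(u, _Z)
    t_md = _orient_tangent(t_md / np.linalg.norm(t_md), x_f, z_f)
    bl_n = np.cross(u, _Z)
    bl_n = bl_n / np.linalg.norm(bl_n)  # buccolingual-plane normal
    t_bl = np.cross(bl_n, _Z)
    t_bl = _orient_tangent(t_bl / np.linalg.norm(t_bl), z_f, x_f)
    a = math.tan(math.radians(torque)) * t_md + math.tan(math.radians(tip)) * t_bl + _Z
    return a / np.linalg.norm(a)


def _analytic_measurement(
    lms: ToothLandmarkSet, frame: CoordinateFrame, n: np.ndarray
) -> ToothMeasurement:
    """Ground-truth measurement from analytic landmark coordinates.

    Kept local to the generator (plain vector algebra against the T1
    occlusal-plane normal ``n``) so that closure tests against the
    measurement module compare two separately written computations.
    """
    pts = lms.points
    if lms.kind == "U6":
        seg = pts["C"] - pts["B"]
        axis = pts["D"] - pts["E"]
    else:
        seg = pts["H"] - pts["G"]
        axis = pts["F"] - pts["I"]
    u = np.cross(seg, n)
    u = u / np.linalg.norm(u)

    def _angle(plane_normal: np.ndarray, primary: np.ndarray, fallback: np.ndarray) -> float:
        p = axis - np.dot(axis, plane_normal) * plane_normal
        p = p / np.linalg.norm(p)
        if np.dot(p, n) < 0:
            p = -p
        t = np.cross(plane_normal, n)
        t = _orient_tangent(t / np.linalg.norm(t), primary, fallback)
        return math.degrees(math.atan2(float(np.dot(p, t)), float(np.dot(p, n))))

    torque = _angle(u, frame.x_axis, frame.z_axis)
    bl_n = np.cross(u, n)
    bl_n = bl_n / np.linalg.norm(bl_n)
    tip = _angle(bl_n, frame.z_axis, frame.x_axis)
    return ToothMeasurement(lms.tooth, frame.to_frame(lms.primary), tip, torque)


def _palate_mesh(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, callable]:
    """Grid mesh of the palatal dome; returns vertices, faces and the height
    function z(x, y) used to place on-surface landmarks analytically."""
    L, W, H = spec.dome_length, spec.dome_width, spec.dome_height
    x0, x1 = -L / 2, L / 2
    yh = W / 2

    ridge_xs = [
        spec.rugae_posterior_x + i * spec.rugae_spacing for i in range(spec.rugae_count)
    ]

    def height(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        # Anteroposterior profile is asymmetric (the vault falls off faster
        # posteriorly than anteriorly), as in real palates.
        xr_half = np.where(x >= 0, 0.62 * L, 0.45 * L)
        lam = np.clip(1.0 - (x / xr_half) ** 2, 0.0, None) ** 1.6
        dome = H * np.clip(1.0 - (y / yh) ** 2, 0.0, None) ** 1.1 * lam
        z = 2.0 + dome
        # Median palatine raphe: shallow midline ridge along the suture.
        z = z + spec.raphe_amplitude * np.exp(-((y / 1.6) ** 2)) * np.clip(
            1.0 - (x / (L / 2)) ** 2, 0.0, None
        )
        for xr in ridge_xs:
            z = z + spec.rugae_amplitude * np.exp(-(((x - xr) / 1.3) ** 2)) * np.exp(
                -((y / 7.0) ** 2)
            )
        return z

    nx, ny = spec.palate_grid
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(-yh, yh, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Zs = height(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Zs.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return verts, np.asarray(faces, dtype=np.int64), height


def _subdivided_box(nu: int) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    for _ in range(nu):
        box = box.subdivide()
    return np.asarray(box.vertices, float), np.asarray(box.faces, np.int64)


def _molar_crown(center_occ, m_s, e_b, a_up, wu, wv, h, nsub) -> np.ndarray:
    """Vertices of a molar crown: subdivided box with four cusp bumps of
    unequal height on the occlusal face (asymmetry disambiguates the pose)."""
    v, f = _subdivided_box(nsub)
    U = v[:, 0] * wu
    V = v[:, 1] * wv
    Wc = (v[:, 2] + 0.5) * h  # 0 = occlusal base, h = gingival
    occl = v[:, 2] < -0.5 + 1e-9
    cusps = [
        (+wu / 4, +wv / 4, 1.3),  # mesio-buccal
        (-wu / 4, +wv / 4, 1.0),  # disto-buccal
        (+wu / 4, -wv / 4, 0.9),  # mesio-lingual
        (-wu / 4, -wv / 4, 0.6),  # disto-lingual
    ]
    bump = np.zeros(len(v))
    for cu, cv, ch in cusps:
        bump += ch * np.exp(-(((U - cu) / 1.7) ** 2 + ((V - cv) / 1.7) ** 2))
    Wc = np.where(occl, Wc - bump, Wc)
    verts = (
        np.asarray(center_occ)[None, :]
        + U[:, None] * m_s[None, :]
        + V[:, None] * e_b[None, :]
        + Wc[:, None] * a_up[None, :]
    )
    return verts, f


def _incisor_crown(center_occ, m_s, e_b, a_up, wu, wv, h, nsub) -> np.ndarray:
    """Incisor crown: slab pinched to an incisal edge, slightly asymmetric."""
    v, f = _subdivided_box(nsub)
    U = v[:, 0] * wu
    W01 = v[:, 2] + 0.5  # 0 at incisal, 1 at gingival
    pinch = 0.2 + 0.8 * np.clip(W01, 0.0, 1.0) ** 0.8
    V = v[:, 1] * wv * pinch + 0.15 * (1 - W01) * (U / wu)  # slight twist
    Wc = W01 * h
    verts = (
        np.asarray(center_occ)[None, :]
        + U[:, None] * m_s[None, :]
        + V[:, None] * e_b[None, :]
        + Wc[:, None] * a_up[None, :]
    )
    return verts, f


_TOOTH_GEOMETRY = {
    # mesiodistal direction angle (deg, in the occlusal plane, from +x for
    # molars / from +y for incisors) and crown box dimensions (mm).
    "RU6": {"angle": 12.0, "dims": (10.0, 10.5, 7.5)},
    "LU6": {"angle": -12.0, "dims": (10.0, 10.5, 7.5)},
    "RU1": {"angle": 8.0, "dims": (7.0, 2.8, 10.0)},
    "LU1": {"angle": -8.0, "dims": (7.0, 2.8, 10.0)},
}


def _tooth_directions(tooth: str) -> tuple[np.ndarray, np.ndarray]:
    """Mesiodistal (toward mesial) and buccal-outward horizontal unit vectors."""
    ang = math.radians(_TOOTH_GEOMETRY[tooth]["angle"])
    side = +1.0 if tooth.startswith("R") else -1.0
    if tooth.endswith("6"):
        m_s = np.array([math.cos(ang), side * abs(math.sin(ang)), 0.0])
        e_b = np.cross(m_s, _Z)
        if (e_b[1] * -side) < 0:  # buccal = away from the midline
            e_b = -e_b
    else:
        m_s = np.array([abs(math.sin(ang)), side * math.cos(ang), 0.0])
        e_b = np.cross(m_s, _Z)
        if e_b[0] < 0:  # labial = anterior
            e_b = -e_b
    return m_s, e_b / np.linalg.norm(e_b)


def _build_tooth(
    tooth: str, pose: ToothPose, frame: CoordinateFrame, xB: float, nsub: int
) -> tuple[ToothLandmarkSet, np.ndarray, np.ndarray]:
    P = _frame_to_mesh(np.asarray(pose.position, float), xB)
    m_s, e_b = _tooth_directions(tooth)
    a_up = _axis_from_tip_torque(m_s, frame.x_axis, frame.z_axis, pose.tip, pose.torque)
    wu, wv, h = _TOOTH_GEOMETRY[tooth]["dims"]
    if tooth.endswith("6"):
        center_occ = P - (wu / 4) * m_s - (wv / 4) * e_b + 1.3 * _Z
        groove = center_occ + 0.3 * _Z
        pts = {
            "A": P,
            "B": groove - 4.0 * m_s,  # distal point of the central groove
            "C": groove + 4.0 * m_s,  # mesial point
            "E": center_occ + (wv / 2) * e_b + 4.5 * a_up,  # gingival, buccal groove
        }
        pts["D"] = pts["E"] - 5.0 * a_up  # most occlusal point of the buccal groove
        verts, faces = _molar_crown(center_occ, m_s, e_b, a_up, wu, wv, h, nsub)
    else:
        center_occ = P
        pts = {
            "F": P,
            "G": P - 3.5 * m_s,  # distal point of the incisal edge
            "H": P + 3.5 * m_s,  # mesial point
            "I": P + 9.0 * a_up,  # midpoint of the gingival edge
        }
        verts, faces = _incisor_crown(center_occ, m_s, e_b, a_up, wu, wv, h, nsub)
    return ToothLandmarkSet(tooth, pts), verts, faces


# ---------------------------------------------------------------------------


def _combine(parts: list[tuple[np.ndarray, np.ndarray, str]], name: str):
    """Concatenate (vertices, faces, label) parts; return mesh + face ranges."""
    verts, faces, ranges = [], [], {}
    v_off = f_off = 0
    for v, f, label in parts:
        verts.append(v)
        faces.append(f + v_off)
        ranges[label] = np.arange(f_off, f_off + len(f))
        v_off += len(v)
        f_off += len(f)
    mesh = TriangleMesh(np.concatenate(verts), np.concatenate(faces), name=name)
    return mesh, ranges


def _fop_cusp_landmarks() -> list[Landmark]:
    """14 coplanar (z = 0) cusp points: premolar buccal+lingual cusps and the
    molar mesio-buccal, disto-buccal and mesio-lingual cusps, both sides."""
    out = []
    arch = {"U4": (10.0, 17.0), "U5": (3.0, 19.5), "U6": (-5.0, 21.5)}
    for side, s in (("R", -1.0), ("L", 1.0)):
        for tooth in ("U4", "U5"):
            x, y = arch[tooth]
            out.append(Landmark(f"FOP_{side}{tooth}B", (x, s * (y + 2.2), 0.0)))
            out.append(Landmark(f"FOP_{side}{tooth}L", (x, s * (y - 2.2), 0.0)))
        x, y = arch["U6"]
        out.append(Landmark(f"FOP_{side}U6MB", (x + 3.0, s * (y + 2.4), 0.0)))
        out.append(Landmark(f"FOP_{side}U6DB", (x - 3.0, s * (y + 2.4), 0.0)))
        out.append(Landmark(f"FOP_{side}U6ML", (x + 3.0, s * (y - 2.4), 0.0)))
    return out


def _surface_noise(
    mesh: TriangleMesh, stable_faces: np.ndarray, sd: float, stable_sd: float, rng
) -> TriangleMesh:
    if sd == 0.0 and stable_sd == 0.0:
        return mesh
    normals = mesh.vertex_normals()
    stable_verts = np.unique(mesh.faces[stable_faces])
    sds = np.full(mesh.n_vertices, sd)
    sds[stable_verts] = stable_sd
    disp = rng.normal(0.0, 1.0, mesh.n_vertices) * sds
    return replace(mesh, vertices=mesh.vertices + disp[:, None] * normals)


def _soft_tissue_drift(mesh: TriangleMesh, palate_faces: np.ndarray, amp: float, rng):
    """Smooth low-frequency deformation of the palate surface (models the
    soft-tissue variability of the vault mucosa between visits)."""
    if amp == 0.0:
        return mesh
    phase = rng.uniform(0, 2 * np.pi, size=2)
    palate_verts = np.unique(mesh.faces[palate_faces])
    v = mesh.vertices.copy()
    x, y = v[palate_verts, 0], v[palate_verts, 1]
    v[palate_verts, 2] += amp * np.sin(2 * np.pi * x / 45.0 + phase[0]) * np.cos(
        2 * np.pi * y / 50.0 + phase[1]
    )
    return replace(mesh, vertices=v)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build one phantom subject (deterministic for a fixed spec)."""
    rng = np.random.default_rng(spec.seed)
    xB = spec.suture_posterior_x

    # Ground-truth frame of the canonical T1 space.
    frame = CoordinateFrame(
        origin=(xB, 0.0, 0.0),
        x_axis=(1.0, 0.0, 0.0),
        y_axis=(0.0, 0.0, 1.0),
        z_axis=(0.0, -1.0, 0.0),
    )

    pal_v, pal_f, height = _palate_mesh(spec)
    parts = [(pal_v, pal_f, "palate")]
    tooth_lms_t1: dict[str, ToothLandmarkSet] = {}
    for tooth, pose in spec.tooth_poses.items():
        lms, v, f = _build_tooth(tooth, pose, frame, xB, spec.crown_subdivisions)
        tooth_lms_t1[tooth] = lms
        parts.append((v, f, tooth))
    t1_clean, ranges = _combine(parts, "T1")

    # Region masks (face indices are shared by T1 and T2: same topology).
    centroids = t1_clean.face_centroids()[ranges["palate"]]
    vault = ranges["palate"][
        (centroids[:, 0] <= spec.rugae_posterior_x + 0.8)
        & (np.abs(centroids[:, 1]) <= 12.0)
    ]

    def masks_for(mesh_ref: str) -> dict:
        m = {"palatal_vault": RegionMask(mesh_ref, "palatal_vault", vault, "palatal_vault")}
        for tooth in spec.tooth_poses:
            m[f"crown_{tooth}"] = RegionMask(
                mesh_ref, "crown", ranges[tooth], f"crown_{tooth}"
            )
        return m

    # Stable (non-tooth) landmarks, on the analytic dome surface.
    xa, xp = spec.suture_anterior_x, spec.suture_posterior_x
    stable = [
        Landmark("A", (xa, 0.0, float(height(xa, 0.0)))),
        Landmark("B", (xp, 0.0, float(height(xp, 0.0)))),
        Landmark("SL", (-4.0, 8.0, float(height(-4.0, 8.0)))),
        Landmark("SR", (-4.0, -8.0, float(height(-4.0, -8.0)))),
    ]
    t1_landmarks = (
        stable
        + _fop_cusp_landmarks()
        + [lm for lms in tooth_lms_t1.values() for lm in lms.as_landmarks()]
    )

    # Treatment: move each crown (mesh part + landmarks) rigidly; everything
    # still expressed in the T1 space.
    treated = t1_clean.copy()
    tooth_lms_t2: dict[str, ToothLandmarkSet] = {}
    for tooth, motion in spec.treatment.items():
        fidx = ranges[tooth]
        vidx = np.unique(treated.faces[fidx])
        treated.vertices[vidx] = motion.apply(treated.vertices[vidx])
        tooth_lms_t2[tooth] = tooth_lms_t1[tooth].transformed(motion)
    _check_crown_separation(treated, ranges, spec)

    # Independent scan-noise draws: T1 scan, T2 scan, reference (CBCT) surface.
    t1_mesh = _surface_noise(
        t1_clean, vault, spec.surface_noise_sd, spec.stable_noise_sd, rng
    )
    t2_anat = _soft_tissue_drift(
        treated, ranges["palate"], spec.soft_tissue_drift_amp, rng
    )
    t2_scan = _surface_noise(
        t2_anat, vault, spec.surface_noise_sd, spec.stable_noise_sd, rng
    )
    reference = _surface_noise(
        treated, vault, spec.surface_noise_sd, spec.stable_noise_sd, rng
    )
    reference = replace(reference, name="T2_reference")

    # Global acquisition pose: the T2 scan lives in its own space.
    t2_mesh = replace(t2_scan.transformed(spec.global_pose), name="T2")
    t2_landmarks = [
        lm.moved_to(spec.global_pose.apply(lm.position))
        for lm in stable
        + [lm for lms in tooth_lms_t2.values() for lm in lms.as_landmarks()]
    ]

    gt_t1 = {
        tooth: ToothMeasurement(
            tooth, np.asarray(pose.position, float), pose.tip, pose.torque
        )
        for tooth, pose in spec.tooth_poses.items()
    }
    gt_t2 = {
        tooth: _analytic_measurement(lms, frame, _Z)
        for tooth, lms in tooth_lms_t2.items()
    }

    return PhantomBundle(
        t1=t1_mesh,
        t1_landmarks=t1_landmarks,
        t1_masks=masks_for("T1"),
        t2=t2_mesh,
        t2_landmarks=t2_landmarks,
        t2_masks=masks_for("T2"),
        reference_surface=reference,
        global_pose=spec.global_pose,
        treatment=dict(spec.treatment),
        frame=frame,
        gt_measurements_t1=gt_t1,
        gt_measurements_t2=gt_t2,
        spec=spec,
    )


def _check_crown_separation(mesh: TriangleMesh, ranges: dict, spec: PhantomSpec) -> None:
    boxes = {}
    for tooth in spec.tooth_poses:
        vidx = np.unique(mesh.faces[ranges[tooth]])
        pts = mesh.vertices[vidx]
        boxes[tooth] = (pts.min(axis=0), pts.max(axis=0))
    teeth = list(boxes)
    for i, a in enumerate(teeth):
        for b in teeth[i + 1 :]:
            lo = np.maximum(boxes[a][0], boxes[b][0])
            hi = np.minimum(boxes[a][1], boxes[b][1])
            if np.all(hi - lo > 1.5):  # gross interpenetration, not mere contact
                raise GeometryError(f"crowns {a} and {b} overlap after treatment motion")


# ---------------------------------------------------------------------------


def _random_rigid(rng, max_rot_deg: float, max_trans: float, center) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = rotation_about(axis, rng.uniform(0.0, max_rot_deg), center)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_trans)
    return RigidTransform(rot.rotation, rot.translation + t)


def cohort(
    template: PhantomSpec,
    n: int,
    seed: int = 0,
    treatment_max_rot: float = 6.0,
    treatment_max_trans: float = 2.0,
    pose_max_rot: float = 8.0,
    pose_max_trans: float = 4.0,
) -> list[PhantomBundle]:
    """Generate ``n`` independent phantom subjects.

    Each subject jitters the anatomy (dome size, tooth poses), draws random
    per-tooth treatment motions and a random global acquisition pose, then
    runs :func:`generate_phantom`.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n).reshape(n, 2)
    bundles = []
    for i in range(n):
        rng = np.random.default_rng(int(seeds[i, 0]))
        poses = {}
        for tooth, pose in template.tooth_poses.items():
            poses[tooth] = ToothPose(
                tuple(np.asarray(pose.position) + rng.normal(0.0, 0.5, 3)),
                tip=pose.tip + rng.normal(0.0, 2.0),
                torque=pose.torque + rng.normal(0.0, 2.0),
            )
        # Treatment motions rotate about each crown's own neighbourhood so the
        # teeth do not sweep across the arch and collide.
        treatment = {}
        for tooth in poses:
            center = _frame_to_mesh(
                np.asarray(poses[tooth].position), template.suture_posterior_x
            )
            treatment[tooth] = _random_rigid(
                rng, treatment_max_rot, treatment_max_trans, center
            )
        global_pose = _random_rigid(
            rng, pose_max_rot, pose_max_trans, center=np.zeros(3)
        )
        spec = replace(
            template,
            dome_width=template.dome_width * rng.uniform(0.95, 1.05),
            dome_height=template.dome_height * rng.uniform(0.95, 1.05),
            tooth_poses=poses,
            treatment=treatment,
            global_pose=global_pose,
            seed=int(seeds[i, 1]),
        )
        bundles.append(generate_phantom(spec))
    return bundles
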
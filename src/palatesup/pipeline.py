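"""End-to-end orchestration of the two superimposition routes.

Reference route (emulating the CBCT-anchored procedure): the post-treatment
model is brought into the pre-treatment (T1) space either by the phantom's
known acquisition pose (the voxel-based CBCT superimposition treated as a
validated black box) or by registering its dental-crown regions onto a
supplied reference surface that already sits in T1 space.  Its output plays
the role of the "T2" model.

Palatal (MDM) route: the same post-treatment model is registered onto T1 by
the palatal-vault stable region after a landmark-seeded coarse alignment;
its output is the "T2'" model.  Crown patches of the reference-route model,
with their bonded landmarks, are then rigidly transferred onto T2' so both
models are measured with identical landmark identifications.

Validation compares the two routes over a synthetic cohort: signed
deviations (T2' - T2) of tooth position and tip/torque with one-sample
t-tests, and intra-/inter-examiner ICCs from repeated runs with
re-randomized operator (landmark-identification) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frame import CoordinateFrame, Plane, build_frame, fit_fop
from .mesh import RegionMask, TriangleMesh
from .metrics import ToothLandmarkSet, ToothMeasurement, measure_tooth, transfer_crown
from .phantom import PhantomBundle, PhantomSpec, cohort
from .registration import ICPConfig, RegistrationResult, icp_region
from .stats import (
    DeviationRecord,
    build_icc_table,
    build_orientation_table,
    build_position_table,
    signed_deviation,
)
from .transforms import RigidTransform, landmark_align

__all__ = [
    "RouteResult",
    "ValidationConfig",
    "ValidationReport",
    "build_t1_frame",
    "run_reference",
    "run_mdm",
    "run_validation",
]

_STABLE_IDS = ("A", "B", "SL", "SR")


@dataclass
class RouteResult:
    """One superimposition route: the aligned model and its measurements."""

    transform: RigidTransform  # T2 acquisition space -> T1 space
    mesh: TriangleMesh
    landmarks: list
    tooth_landmarks: dict  # tooth -> ToothLandmarkSet (in T1 space)
    measurements: dict  # tooth -> ToothMeasurement
    registrations: dict = field(default_factory=dict)  # stage -> RegistrationResult


def build_t1_frame(t1_landmarks) -> tuple[CoordinateFrame, Plane]:
    """Measurement frame of the T1 model from its landmark set.

    The functional occlusal plane is fitted to the ``FOP_*`` cusp landmarks
    (normal oriented toward the palatal suture point B); the frame itself
    comes from the suture points A (anterior) and B (posterior).
    """
    by_key = {lm.key: lm for lm in t1_landmarks}
    cusps = np.array(
        [lm.position for lm in t1_landmarks if lm.id.startswith("FOP_")]
    )
    if len(cusps) < 3:
        raise ValueError("T1 landmark set has no FOP cusp points")
    B = by_key["B"].position
    fop = fit_fop(cusps, toward=B)
    frame = build_frame(by_key["A"].position, B, fop)
    return frame, fop


def _stable_landmarks(landmarks) -> list:
    return [lm for lm in landmarks if lm.tooth is None and lm.id in _STABLE_IDS]


def _measure_all(
    tooth_landmarks: dict, frame: CoordinateFrame, fop: Plane, swap: bool = False
) -> dict:
    return {
        tooth: measure_tooth(lms, frame, fop, swap_tip_torque=swap)
        for tooth, lms in tooth_landmarks.items()
    }


def run_reference(
    bundle: PhantomBundle,
    mode: str = "ground_truth",
    icp_cfg: ICPConfig | None = None,
    frame_and_fop: tuple | None = None,
) -> RouteResult:
    """Reference (CBCT-anchored) route: T2 brought into T1 space.

    ``mode='ground_truth'`` uses the phantom's known acquisition pose;
    ``mode='crown_icp'`` registers the union of the dental-crown regions onto
    the bundle's reference surface (landmark-seeded, then best-fit).
    """
    frame, fop = frame_and_fop or build_t1_frame(bundle.t1_landmarks)
    registrations: dict[str, RegistrationResult] = {}
    if mode == "ground_truth":
        T_ref = bundle.global_pose.invert()
    elif mode == "crown_icp":
        init, _ = landmark_align(
            _stable_landmarks(bundle.t2_landmarks), _stable_landmarks(bundle.t1_landmarks)
        )
        crown_faces = np.concatenate(
            [m.member_faces for name, m in bundle.t2_masks.items() if m.kind == "crown"]
        )
        crown_union = RegionMask(bundle.t2.name, "crown", crown_faces, "crown_union")
        res = icp_region(bundle.t2, bundle.reference_surface, crown_union, init, icp_cfg)
        registrations["crown_reference"] = res
        T_ref = res.transform
    else:
        raise ValueError(f"unknown reference mode {mode!r}")

    landmarks = [lm.moved_to(T_ref.apply(lm.position)) for lm in bundle.t2_landmarks]
    tooth_lms = {
        tooth: ToothLandmarkSet.from_landmarks(landmarks, tooth)
        for tooth in bundle.treatment
    }
    return RouteResult(
        transform=T_ref,
        mesh=replace(bundle.t2.transformed(T_ref), name="T2_ref"),
        landmarks=landmarks,
        tooth_landmarks=tooth_lms,
        measurements=_measure_all(tooth_lms, frame, fop),
        registrations=registrations,
    )


def run_mdm(
    bundle: PhantomBundle,
    reference: RouteResult,
    icp_cfg: ICPConfig | None = None,
    frame_and_fop: tuple | None = None,
) -> RouteResult:
    """Palatal-vault route: produce T2' and measure it via crown transfer.

    The post-treatment model is registered onto T1 by its palatal-vault
    region (landmark-seeded); crown patches of the reference-route model are
    then registered onto the resulting T2' to carry the landmarks across, so
    landmark identification is shared between the routes.
    """
    frame, fop = frame_and_fop or build_t1_frame(bundle.t1_landmarks)
    init, _ = landmark_align(
        _stable_landmarks(bundle.t2_landmarks), _stable_landmarks(bundle.t1_landmarks)
    )
    pal = icp_region(
        bundle.t2, bundle.t1, bundle.t2_masks["palatal_vault"], init, icp_cfg
    )
    T_pal = pal.transform
    t2_prime = replace(bundle.t2.transformed(T_pal), name="T2_prime")
    registrations = {"palatal_vault": pal}

    # Relative pose between the two aligned copies seeds each crown transfer.
    rel_init = T_pal.compose(reference.transform.invert())
    tooth_lms: dict[str, ToothLandmarkSet] = {}
    for tooth, lms in reference.tooth_landmarks.items():
        moved, res = transfer_crown(
            reference.mesh,
            bundle.t2_masks[f"crown_{tooth}"],
            lms,
            t2_prime,
            cfg=icp_cfg,
            init=rel_init,
        )
        tooth_lms[tooth] = moved
        registrations[f"crown_transfer_{tooth}"] = res

    landmarks = [lm.moved_to(T_pal.apply(lm.position)) for lm in bundle.t2_landmarks]
    return RouteResult(
        transform=T_pal,
        mesh=t2_prime,
        landmarks=landmarks,
        tooth_landmarks=tooth_lms,
        measurements=_measure_all(tooth_lms, frame, fop),
        registrations=registrations,
    )


# ---------------------------------------------------------------------------
# Cohort validation


@dataclass(frozen=True)
class ValidationConfig:
    """Study-shaped validation run: cohort size, noise injections, models."""

    n_subjects: int = 20
    n_reliability_subjects: int = 10
    seed: int = 0
    reference_mode: str = "ground_truth"
    icp: ICPConfig = field(default_factory=ICPConfig)
    # Net MDM-route measurement error injected on the transferred tooth
    # landmarks (mm); gives the deviation distribution a known scale.
    landmark_noise_sd: float = 0.0
    # Operator landmark-identification noise re-drawn per reliability repeat.
    repeat_noise_sd_mdm: float = 0.15
    repeat_noise_sd_reference: float = 0.02
    icc_model: str = "ICC2"
    alpha: float = 0.05
    # Cohort randomization magnitudes (all zero = null study: identity
    # treatment motions and acquisition poses).
    treatment_max_rot: float = 6.0
    treatment_max_trans: float = 2.0
    pose_max_rot: float = 8.0
    pose_max_trans: float = 4.0


@dataclass
class ValidationReport:
    deviations: pd.DataFrame
    position_table: pd.DataFrame
    orientation_table: pd.DataFrame
    icc_table: pd.DataFrame | None
    diagnostics: pd.DataFrame
    config: ValidationConfig

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.deviations.to_csv(outdir / "deviations.csv", index=False)
        self.position_table.to_csv(outdir / "position_deviations.csv", index=False)
        self.orientation_table.to_csv(outdir / "orientation_deviations.csv", index=False)
        if self.icc_table is not None:
            self.icc_table.to_csv(outdir / "reliability_icc.csv", index=False)
        self.diagnostics.to_csv(outdir / "registration_diagnostics.csv", index=False)


def _noisy_landmark_sets(tooth_lms: dict, sd: float, rng) -> dict:
    if sd == 0.0:
        return tooth_lms
    return {
        tooth: ToothLandmarkSet(
            tooth, {k: v + rng.normal(0.0, sd, 3) for k, v in lms.points.items()}
        )
        for tooth, lms in tooth_lms.items()
    }


def _position_frame(measurements: dict, subject: str) -> list:
    return [
        {
            "subject": subject,
            "tooth": tooth,
            "x": m.position[0],
            "y": m.position[1],
            "z": m.position[2],
        }
        for tooth, m in measurements.items()
    ]


def run_validation(
    template: PhantomSpec | None = None, config: ValidationConfig | None = None
) -> ValidationReport:
    """Run both routes over a synthetic cohort and assemble the report."""
    config = config or ValidationConfig()
    template = template or PhantomSpec()
    root = np.random.SeedSequence(config.seed)
    cohort_seed, noise_seed = root.generate_state(2)
    bundles = cohort(
        template,
        config.n_subjects,
        seed=int(cohort_seed),
        treatment_max_rot=config.treatment_max_rot,
        treatment_max_trans=config.treatment_max_trans,
        pose_max_rot=config.pose_max_rot,
        pose_max_trans=config.pose_max_trans,
    )
    rng = np.random.default_rng(int(noise_seed))

    records: list[DeviationRecord] = []
    diagnostics = []
    reliability: dict[str, list] = {
        key: []
        for key in (
            "mdm_s1",
            "mdm_s2",
            "mdm_e2",
            "ref_s1",
            "ref_s2",
            "ref_e2",
        )
    }
    n_rel = min(config.n_reliability_subjects, config.n_subjects)

    for i, bundle in enumerate(bundles):
        subject = f"S{i + 1:03d}"
        frame_and_fop = build_t1_frame(bundle.t1_landmarks)
        ref = run_reference(
            bundle, config.reference_mode, config.icp, frame_and_fop
        )
        mdm = run_mdm(bundle, ref, config.icp, frame_and_fop)

        mdm_lms = _noisy_landmark_sets(mdm.tooth_landmarks, config.landmark_noise_sd, rng)
        mdm_meas = _measure_all(mdm_lms, *frame_and_fop)
        for tooth in bundle.treatment:
            records.append(
                signed_deviation(mdm_meas[tooth], ref.measurements[tooth], subject)
            )
        for stage, res in {**ref.registrations, **mdm.registrations}.items():
            diagnostics.append(
                {
                    "subject": subject,
                    "stage": stage,
                    "rms_residual": res.rms_residual,
                    "n_iterations": res.n_iterations,
                    "n_correspondences": res.n_correspondences,
                    "converged": res.converged,
                    "warnings": "; ".join(res.warnings),
                }
            )

        # Reliability repeats: re-measure with freshly drawn operator noise
        # (three runs: examiner 1 twice, examiner 2 once), per route.
        if i < n_rel:
            for key, route, sd in (
                ("mdm", mdm, config.repeat_noise_sd_mdm),
                ("ref", ref, config.repeat_noise_sd_reference),
            ):
                for run in ("s1", "s2", "e2"):
                    lms = _noisy_landmark_sets(route.tooth_landmarks, sd, rng)
                    meas = _measure_all(lms, *frame_and_fop)
                    reliability[f"{key}_{run}"].extend(
                        _position_frame(meas, subject)
                    )

    icc_table = None
    if n_rel >= 2:
        frames = {k: pd.DataFrame(v) for k, v in reliability.items()}
        mdm_icc = build_icc_table(
            frames["mdm_s1"], frames["mdm_s2"], frames["mdm_e2"],
            model=config.icc_model, prefix="mdm_",
        )
        ref_icc = build_icc_table(
            frames["ref_s1"], frames["ref_s2"], frames["ref_e2"],
            model=config.icc_model, prefix="reference_",
        )
        icc_table = mdm_icc.merge(ref_icc, on="variable")

    return ValidationReport(
        deviations=pd.DataFrame([r.__dict__ for r in records]),
        position_table=build_position_table(records),
        orientation_table=build_orientation_table(records),
        icc_table=icc_table,
        diagnostics=pd.DataFrame(diagnostics),
        config=config,
    )
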
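"""Accuracy and reliability statistics for the superimposition comparison.

Accuracy: per-subject signed deviations (palatal-route minus reference-route,
i.e. T2' - T2) of tooth position (x, y, z and their Euclidean norm) and of
tip/torque, summarized as mean, SD and a two-sided one-sample t-test against
zero.  Reliability: intraclass correlation coefficients between repeated
superimposition runs (two sessions of one examiner = intra-examiner; two
examiners = inter-examiner), computed per tooth-coordinate on frame
coordinates.  The default ICC model is two-way random effects, absolute
agreement, single measurement — ICC(2,1) — configurable to the consistency
model ICC(3,1).  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .metrics import ToothMeasurement

__all__ = [
    "DeviationRecord",
    "TTestResult",
    "ConstantInputError",
    "signed_deviation",
    "one_sample_t",
    "icc",
    "build_position_table",
    "build_orientation_table",
    "build_icc_table",
]

TEETH = ("RU6", "LU6", "RU1", "LU1")
COORDS = ("x", "y", "z")


class ConstantInputError(ValueError):
    """t statistic undefined: all values identical (zero variance)."""


@dataclass(frozen=True)
class DeviationRecord:
    """Signed T2' - T2 differences for one tooth of one subject."""

    subject: str
    tooth: str
    dx: float
    dy: float
    dz: float
    total: float
    dtip: float
    dtorque: float


@dataclass(frozen=True)
class TTestResult:
    label: str
    n: int
    mean: float
    sd: float
    p_value: float


def signed_deviation(
    m2p: ToothMeasurement, m2: ToothMeasurement, subject: str = ""
) -> DeviationRecord:
    """Componentwise T2' - T2; ``total`` is the Euclidean landmark distance."""
    if m2p.tooth != m2.tooth:
        raise ValueError(f"tooth mismatch: {m2p.tooth!r} vs {m2.tooth!r}")
    d = m2p.position - m2.position
    return DeviationRecord(
        subject=subject,
        tooth=m2.tooth,
        dx=float(d[0]),
        dy=float(d[1]),
        dz=float(d[2]),
        total=float(np.linalg.norm(d)),
        dtip=float(m2p.tip - m2.tip),
        dtorque=float(m2p.torque - m2.torque),
    )


def one_sample_t(values, mu0: float = 0.0, label: str = "") -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise ConstantInputError(f"{label or 'sample'}: zero variance, t undefined")
    res = _sps.ttest_1samp(v, popmean=mu0)
    return TTestResult(label, len(v), float(v.mean()), sd, float(res.pvalue))


def icc(ratings: np.ndarray, model: str = "ICC2") -> float:
    """Intraclass correlation of a subjects x raters matrix.

    ``model``: ``ICC2`` = two-way random effects, absolute agreement, single
    measurement (default); ``ICC3`` = two-way mixed effects, consistency,
    single measurement.  Computed from the two-way ANOVA mean-squares
    decomposition (Shrout & Fleiss):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    with MSR/MSC/MSE the between-subject, between-rater and residual mean
    squares.  A warning is emitted when the between-subject variance
    vanishes (the coefficient is then ill-defined); raters in perfect
    agreement yield exactly 1.
    """
    if model not in ("ICC2", "ICC3"):
        raise ValueError(f"unknown ICC model {model!r}")
    mat = np.asarray(ratings, float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("ratings must be (>=2 subjects) x (>=2 raters)")
    if not np.all(np.isfinite(mat)):
        raise ValueError("ratings contain missing/non-finite cells")
    n, k = mat.shape
    if np.allclose(mat.mean(axis=1).var(), 0.0, atol=1e-30):
        warnings.warn("zero between-subject variance: ICC is ill-defined")
    if np.array_equal(mat, np.tile(mat[:, :1], (1, k))):
        return 1.0  # perfect agreement, exactly
    grand = mat.mean()
    ssr = k * float(np.sum((mat.mean(axis=1) - grand) ** 2))
    ssc = n * float(np.sum((mat.mean(axis=0) - grand) ** 2))
    sse = float(np.sum((mat - grand) ** 2)) - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    if model == "ICC2":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    if denom == 0.0:
        return float("nan")
    return (msr - mse) / denom


# ---------------------------------------------------------------------------
# Report tables


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _t_row(values: np.ndarray, label: str) -> dict:
    values = np.asarray(values, float)
    try:
        t = one_sample_t(values, 0.0, label)
        p = t.p_value
    except ConstantInputError:
        p = np.nan  # degenerate (e.g. all-zero null cohort): p undefined
    return {
        "variable": label,
        "n": len(values),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else np.nan,
        "p_value": p,
    }


def build_position_table(records) -> pd.DataFrame:
    """Per-tooth position deviations: rows {tooth}-{x,y,z,total}."""
    df = _records_frame(records)
    rows = []
    for tooth in TEETH:
        sub = df[df.tooth == tooth]
        if sub.empty:
            continue
        for comp, col in (("x", "dx"), ("y", "dy"), ("z", "dz"), ("total", "total")):
            rows.append(_t_row(sub[col].to_numpy(), f"{tooth}-{comp}"))
    return pd.DataFrame(rows)


def build_orientation_table(records) -> pd.DataFrame:
    """Per-tooth orientation deviations: rows {tooth}-{tip,torque}."""
    df = _records_frame(records)
    rows = []
    for tooth in TEETH:
        sub = df[df.tooth == tooth]
        if sub.empty:
            continue
        for comp, col in (("tip", "dtip"), ("torque", "dtorque")):
            rows.append(_t_row(sub[col].to_numpy(), f"{tooth}-{comp}"))
    return pd.DataFrame(rows)


def build_icc_table(
    session1: pd.DataFrame,
    session2: pd.DataFrame,
    examiner2: pd.DataFrame,
    model: str = "ICC2",
    prefix: str = "",
) -> pd.DataFrame:
    """Reliability table: intra-examiner (session 1 vs the repeat session of
    the same examiner) and inter-examiner (examiner 1 vs examiner 2) ICC per
    tooth-coordinate.

    Each input is a tidy frame with columns subject, tooth, x, y, z
    containing one superimposition-plus-measurement run.
    """
    rows = []
    for tooth in TEETH:
        for comp in COORDS:
            cols = {}
            for pair_name, other in (("intra", session2), ("inter", examiner2)):
                a = session1[session1.tooth == tooth].set_index("subject")[comp]
                b = other[other.tooth == tooth].set_index("subject")[comp]
                common = a.index.intersection(b.index)
                mat = np.column_stack([a.loc[common], b.loc[common]])
                cols[pair_name] = icc(mat, model=model)
            rows.append(
                {
                    "variable": f"{tooth}-{comp}",
                    f"{prefix}intra_examiner_icc": cols["intra"],
                    f"{prefix}inter_examiner_icc": cols["inter"],
                }
            )
    return pd.DataFrame(rows)
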
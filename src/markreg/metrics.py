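"""Registration error metrics: parameter RMSE, FRE, and gold-standard RMSE.

Three root-mean-square metrics score a trial registration T against a
reference ("gold standard", GS) transform and against its own landmark
residuals:

* ``rmse1`` — RMS difference of the 6 transform parameters, rotation
  (degrees) and translation (mm) reported separately and never summed,
  since the two have different units.
* ``fre`` — fiducial registration error, the RMS Euclidean residual
  ``sqrt(mean_i ||T(x_i) - y_i||^2)`` of the registered pairs, in mm.
* ``rmse2`` — RMS distance between the trial-transformed moving landmarks
  and the GS-transformed ones ("transformed fiducial" vs "GS fiducial"),
  in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkPairing, LandmarkSet, RigidTransform, apply_transform

__all__ = [
    "GoldStandard",
    "MetricRecord",
    "rmse1",
    "fre",
    "rmse2",
    "records_to_frame",
    "write_records",
]


@dataclass
class GoldStandard:
    """A reference transform and the landmarks it maps ("GS fiducials").

    ``gs_fiducials`` must equal ``apply_transform(transform, moving)`` by
    construction; :meth:`from_moving` builds a consistent instance.
    """

    transform: RigidTransform
    gs_fiducials: LandmarkSet

    @classmethod
    def from_moving(cls, transform: RigidTransform, moving: LandmarkSet) -> "GoldStandard":
        return cls(transform, apply_transform(transform, moving))

    def check_consistency(self, moving: LandmarkSet, atol: float = 1e-9) -> None:
        mapped = self.transform.apply(moving.points)
        if not np.allclose(mapped, self.gs_fiducials.points, atol=atol):
            raise ValueError("gs_fiducials are not the GS-transformed moving landmarks")


@dataclass
class MetricRecord:
    """One (patient, user, trial, N) row of the validation study."""

    patient: str
    user: str
    trial: int
    n_landmarks: int
    rmse1_rot: float
    rmse1_trans: float
    fre: float
    rmse2: float

    def __post_init__(self) -> None:
        for name in ("rmse1_rot", "rmse1_trans", "fre", "rmse2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _wrap_degrees(d: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    return 180.0 - np.mod(180.0 - d, 360.0)


def rmse1(eval_t: RigidTransform, gs_t: RigidTransform) -> tuple[float, float]:
    """RMS difference of transform parameters vs the gold standard.

    Both transforms are parameterized under the package's single convention
    (intrinsic Z-Y-X Euler degrees + mm).  Returns ``(rot, trans)``:
    rotation RMS in degrees (differences wrapped to ±180°) and translation
    RMS in mm, separately.
    """
    diff = eval_t.params - gs_t.params
    rot = float(np.sqrt(np.mean(_wrap_degrees(diff[:3]) ** 2)))
    trans = float(np.sqrt(np.mean(diff[3:] ** 2)))
    return rot, trans


def fre(t: RigidTransform, pairing: LandmarkPairing) -> float:
    """Fiducial registration error: RMS residual of registered pairs (mm)."""
    if pairing.n < 1:
        raise ValueError("FRE needs at least one pair")
    residuals = t.apply(pairing.moving.points) - pairing.fixed.points
    return float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))


def rmse2(t: RigidTransform, moving_landmarks: LandmarkSet, gs: GoldStandard) -> float:
    """RMS distance between trial-transformed and GS fiducials (mm)."""
    if len(moving_landmarks) != len(gs.gs_fiducials):
        raise ValueError("moving landmarks and GS fiducials differ in length")
    if moving_landmarks.labels != gs.gs_fiducials.labels:
        raise ValueError("moving landmarks and GS fiducials labels differ")
    tf = t.apply(moving_landmarks.points)
    d = tf - gs.gs_fiducials.points
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy DataFrame: one row per record."""
    return pd.DataFrame(
        [
            {
                "patient": r.patient,
                "user": r.user,
                "trial": r.trial,
                "n_landmarks": r.n_landmarks,
                "rmse1_rot": r.rmse1_rot,
                "rmse1_trans": r.rmse1_trans,
                "fre": r.fre,
                "rmse2": r.rmse2,
            }
            for r in records
        ]
    )


def write_records(records: list[MetricRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    return path
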
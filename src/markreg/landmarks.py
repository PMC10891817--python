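"""Landmark data model and I/O, rigid fiducial registration, transforms.

The registration solver is the closed-form SVD least-squares solution of the
absolute-orientation problem without scaling (Kabsch/Umeyama): given paired
fixed points :math:`y_i` and moving points :math:`x_i` it returns the rigid
map :math:`T(x) = Rx + t` minimizing :math:`\\sum_i \\lVert T(x_i) - y_i
\\rVert^2` with :math:`R` a proper rotation.  Candidate reflections
(det = -1) are corrected by flipping the smallest singular direction, the
standard fix for noisy near-planar configurations.

Transforms are parameterized as a 6-vector: three intrinsic Z-Y-X Euler
angles in degrees followed by three translations in mm.  The direction
convention is explicit everywhere: ``fit_rigid`` returns moving→fixed, and
``RigidTransform.inverse`` is provided rather than guessing a convention.
"""

from __future__ import annotations

import csv as _csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

from .volume import Volume, _INTERPOLATORS, physical_extent

__all__ = [
    "LandmarkSet",
    "LandmarkPairing",
    "RigidTransform",
    "DegenerateLandmarksError",
    "fit_rigid",
    "apply_transform",
    "transform_params",
    "resample_through_transform",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
]

ROTATION_ATOL = 1e-9


class DegenerateLandmarksError(ValueError):
    """The landmark configuration does not determine a unique rotation."""


@dataclass
class LandmarkSet:
    """Ordered physical-space points (LPS mm) with unique labels."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)
    space: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if not self.labels:
            self.labels = [f"F-{i + 1}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique within a set")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, n: int) -> "LandmarkSet":
        """First ``n`` points (prefix order)."""
        return LandmarkSet(self.points[:n].copy(), list(self.labels[:n]), self.space)


@dataclass
class LandmarkPairing:
    """Index-paired fixed/moving landmarks (i-th ↔ i-th, labels must match)."""

    fixed: LandmarkSet
    moving: LandmarkSet

    def __post_init__(self) -> None:
        if len(self.fixed) != len(self.moving):
            raise ValueError("fixed and moving sets must have equal size")
        if len(self.fixed) < 1:
            raise ValueError("pairing needs at least one pair")
        if self.fixed.labels != self.moving.labels:
            raise ValueError("corresponding landmark labels must match")

    @property
    def n(self) -> int:
        return len(self.fixed)

    def subset(self, n: int) -> "LandmarkPairing":
        return LandmarkPairing(self.fixed.subset(n), self.moving.subset(n))


@dataclass
class RigidTransform:
    """Rotation + translation with a 6-parameter vector view.

    ``params`` is ``(rz, ry, rx, tx, ty, tz)``: intrinsic Z-Y-X Euler angles
    in degrees, translations in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("need a 3x3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "RigidTransform":
        params = np.asarray(params, dtype=float)
        if params.shape != (6,):
            raise ValueError("params must be a 6-vector")
        rot = Rotation.from_euler("ZYX", params[:3], degrees=True).as_matrix()
        return cls(rot, params[3:].copy())

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(matrix[:3, :3], matrix[:3, 3])

    # -- views ------------------------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """6-vector (rz, ry, rx, tx, ty, tz); see :func:`transform_params`."""
        return transform_params(self)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    # -- algebra ----------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.rotation.flatten()))
        t.SetTranslation(tuple(self.translation))
        return t


def transform_params(t: RigidTransform) -> np.ndarray:
    """Extract the 6-parameter vector (rz, ry, rx, tx, ty, tz).

    Angles are intrinsic Z-Y-X Euler in degrees, translations in mm.  Near
    gimbal lock (|pitch| within ~1e-6 deg of 90°) the extraction is not
    unique; a warning is emitted and the canonical branch (rx = 0) is chosen.
    """
    # |sin(pitch)| = |R[2,0]| for the ZYX intrinsic convention
    near_lock = abs(abs(t.rotation[2, 0]) - 1.0) < np.deg2rad(1e-6)
    if near_lock:
        warnings.warn(
            "Euler extraction near gimbal lock; canonical branch chosen",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on the same condition
        ang = Rotation.from_matrix(t.rotation).as_euler("ZYX", degrees=True)
    return np.concatenate([ang, t.translation])


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def fit_rigid(pairing: LandmarkPairing) -> RigidTransform:
    """Closed-form least-squares rigid registration (moving → fixed).

    Minimizes ``sum_i ||R x_i + t - y_i||^2`` over proper rotations R and
    translations t, where x are the moving and y the fixed points.  Raises
    :class:`DegenerateLandmarksError` for n < 3 or (near-)collinear moving
    points, where the rotation is not unique.
    """
    if pairing.n < 3:
        raise DegenerateLandmarksError(
            f"rigid registration needs at least 3 pairs, got {pairing.n}"
        )
    x = pairing.moving.points
    y = pairing.fixed.points
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    xc = x - cx
    yc = y - cy
    # collinearity check on the moving cloud: rank < 2 leaves a free rotation
    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateLandmarksError(
            "moving landmarks are (near-)collinear; rotation is not unique"
        )
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cy - rot @ cx)


def apply_transform(t: RigidTransform, points: LandmarkSet) -> LandmarkSet:
    """Map every landmark ``p ↦ R p + t``; labels are preserved."""
    return LandmarkSet(t.apply(points.points), list(points.labels), points.space)


def resample_through_transform(
    moving: Volume, fixed: Volume, t: RigidTransform, method: str = "LINEAR"
) -> Volume:
    """Resample ``moving`` onto the grid of ``fixed`` through ``t``.

    ``t`` maps moving physical space into fixed physical space; voxels of the
    output (fixed geometry) are looked up at ``t^{-1}(p)`` in the moving
    volume.  An empty physical overlap produces a warning, not a failure
    (a fused overlay may legitimately be partial).
    """
    if method not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation method {method!r}")
    mlo, mhi = physical_extent(moving)
    flo, fhi = physical_extent(fixed)
    corners = np.array(
        [[a, b, c] for a in (flo[0], fhi[0]) for b in (flo[1], fhi[1]) for c in (flo[2], fhi[2])]
    )
    back = t.inverse().apply(corners)
    if np.any(back.max(axis=0) < mlo) or np.any(back.min(axis=0) > mhi):
        warnings.warn(
            "transformed moving volume does not overlap the fixed grid",
            stacklevel=2,
        )
    out = sitk.Resample(
        moving.to_sitk(),
        fixed.to_sitk(),
        t.inverse().to_sitk(),
        _INTERPOLATORS[method],
        0.0,
    )
    v = Volume.from_sitk(out)
    v.modality = moving.modality
    return v


# ---------------------------------------------------------------------------
# Landmark file I/O (FCSV, Slicer markups JSON, plain CSV)
# ---------------------------------------------------------------------------

def _infer_landmark_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".fcsv"):
        return "FCSV"
    if name.endswith(".mrk.json") or name.endswith(".json"):
        return "MARKUPS_JSON"
    if name.endswith(".csv"):
        return "CSV"
    raise ValueError(f"cannot infer landmark format from {path.name!r}")


def read_landmarks(path: str | Path, format: str | None = None) -> LandmarkSet:
    """Read landmarks from FCSV, Slicer markups JSON, or plain CSV.

    FCSV and markups files declare their coordinate system; RAS coordinates
    are converted to LPS (negate x and y) on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    fmt = format or _infer_landmark_format(path)
    if fmt == "FCSV":
        return _read_fcsv(path)
    if fmt == "MARKUPS_JSON":
        return _read_markups_json(path)
    if fmt == "CSV":
        return _read_plain_csv(path)
    raise ValueError(f"unknown landmark format {fmt!r}")


def write_landmarks(lset: LandmarkSet, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or _infer_landmark_format(path)
    if fmt == "FCSV":
        _write_fcsv(lset, path)
    elif fmt == "MARKUPS_JSON":
        _write_markups_json(lset, path)
    elif fmt == "CSV":
        _write_plain_csv(lset, path)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")
    return path


def _read_fcsv(path: Path) -> LandmarkSet:
    ras = True  # Slicer default when unstated
    pts, labels = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            low = line.lower()
            if "coordinatesystem" in low:
                val = line.split("=")[-1].strip()
                ras = val in ("RAS", "0")
            continue
        fields = line.split(",")
        x, y, z = (float(fields[i]) for i in (1, 2, 3))
        label = fields[11] if len(fields) > 11 and fields[11] else f"F-{len(pts) + 1}"
        pts.append((x, y, z))
        labels.append(label)
    pts_arr = np.asarray(pts, dtype=float)
    if ras:
        pts_arr[:, 0] *= -1
        pts_arr[:, 1] *= -1
    return LandmarkSet(pts_arr, labels)


def _write_fcsv(lset: LandmarkSet, path: Path) -> None:
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (p, label) in enumerate(zip(lset.points, lset.labels)):
        x, y, z = (repr(float(c)) for c in p)
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{x},{y},{z},0,0,0,1,1,1,0,{label},,"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_markups_json(path: Path) -> LandmarkSet:
    doc = json.loads(path.read_text())
    markup = doc["markups"][0]
    ras = markup.get("coordinateSystem", "LPS") == "RAS"
    pts, labels = [], []
    for cp in markup["controlPoints"]:
        pts.append(cp["position"])
        labels.append(cp.get("label", f"F-{len(pts)}"))
    pts_arr = np.asarray(pts, dtype=float)
    if ras:
        pts_arr[:, 0] *= -1
        pts_arr[:, 1] *= -1
    return LandmarkSet(pts_arr, labels)


def _write_markups_json(lset: LandmarkSet, path: Path) -> None:
    doc = {
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": [
                    {"label": label, "position": [float(c) for c in p]}
                    for p, label in zip(lset.points, lset.labels)
                ],
            }
        ]
    }
    path.write_text(json.dumps(doc, indent=2))


def _read_plain_csv(path: Path) -> LandmarkSet:
    pts, labels = [], []
    with path.open(newline="") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "x", "y", "z"} <= set(reader.fieldnames):
            raise ValueError("CSV landmarks need header columns label,x,y,z")
        for row in reader:
            labels.append(row["label"])
            pts.append((float(row["x"]), float(row["y"]), float(row["z"])))
    return LandmarkSet(np.asarray(pts, dtype=float), labels)


def _write_plain_csv(lset: LandmarkSet, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for p, label in zip(lset.points, lset.labels):
            writer.writerow([label, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])


# ---------------------------------------------------------------------------
# Transform file I/O
# ---------------------------------------------------------------------------

def write_transform(t: RigidTransform, path: str | Path) -> Path:
    """Write a rigid transform (moving→fixed, LPS frame).

    ``.txt``/``.mat`` files get a commented plain-text 4x4 homogeneous
    matrix; ``.tfm`` files are written through SimpleITK in ITK transform
    format (which cannot carry comments — the direction convention is this
    package's documented moving→fixed).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".tfm":
        sitk.WriteTransform(t.to_sitk(), str(path))
        return path
    header = "rigid transform, direction: moving -> fixed, frame: LPS, row-major 4x4"
    np.savetxt(path, t.matrix, header=header, fmt="%.17g")
    return path


def read_transform(path: str | Path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such transform file: {path}")
    if path.suffix == ".tfm":
        t = sitk.ReadTransform(str(path))
        t = sitk.AffineTransform(t)
        rot = np.asarray(t.GetMatrix()).reshape(3, 3)
        center = np.asarray(t.GetCenter())
        trans = np.asarray(t.GetTranslation())
        # fold the ITK center into a plain (R, t) pair
        return RigidTransform(rot, trans + center - rot @ center)
    return RigidTransform.from_matrix(np.loadtxt(path))
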
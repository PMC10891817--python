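"""Volume data model, I/O, resampling, centering and sagittal mirroring.

All physical coordinates in this package are LPS millimetres (the DICOM/ITK
convention).  NIfTI files store RAS geometry; SimpleITK converts them to LPS
on read and back on write, so everything downstream of the I/O boundary sees
a single frame.

A :class:`Volume` holds its voxels as ``data[i, j, k]`` with ``i`` the x
index, and the index-to-physical map is the affine

    p = origin + direction @ (spacing * index)

where ``direction`` is a 3x3 orthonormal matrix of column axis vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "TimeSeriesVolume",
    "VolumeFormatError",
    "FourDImageError",
    "read_volume",
    "write_volume",
    "read_time_series",
    "write_time_series",
    "resample_volume",
    "center_volume",
    "mirror_volume",
    "physical_coordinates",
    "physical_extent",
]

#: Tolerance for orthonormality of direction matrices.
DIRECTION_ATOL = 1e-9

_INTERPOLATORS = {
    "LINEAR": sitk.sitkLinear,
    "NEAREST": sitk.sitkNearestNeighbor,
    "BSPLINE": sitk.sitkBSpline,
}


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3D scalar image."""


class FourDImageError(VolumeFormatError):
    """A 4D file was passed where a 3D volume was expected.

    Signals that the caller should go through the time-series reader
    (:func:`read_time_series`) instead.
    """


def _check_direction(direction: np.ndarray, atol: float = DIRECTION_ATOL) -> None:
    if direction.shape != (3, 3):
        raise ValueError("direction must be a 3x3 matrix")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=atol):
        raise VolumeFormatError("direction matrix is not orthonormal")
    det = float(np.linalg.det(direction))
    if not (abs(abs(det) - 1.0) <= max(atol, 1e-9)):
        raise VolumeFormatError(f"direction determinant {det} is not ±1")


@dataclass
class Volume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    data:
        Voxel intensities, shape ``(nx, ny, nz)``; arbitrary units.
    spacing:
        Per-axis voxel size in mm, all components > 0.
    origin:
        Physical LPS position (mm) of voxel ``(0, 0, 0)``.
    direction:
        3x3 orthonormal axis matrix (det ±1 on read, +1 after internal ops).
    modality:
        One of ``"CT"``, ``"US"``, ``"OTHER"``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive components")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        _check_direction(self.direction)
        if self.modality not in ("CT", "US", "OTHER"):
            raise ValueError(f"unknown modality {self.modality!r}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (...,3) voxel indices to physical LPS mm."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def physical_center(self) -> np.ndarray:
        """Physical centre of the voxel-centre bounding box."""
        return self.index_to_physical((np.asarray(self.shape) - 1) / 2.0)

    def same_grid(self, other: "Volume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    # -- SimpleITK bridge -------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: str = "OTHER") -> "Volume":
        if img.GetDimension() != 3:
            raise FourDImageError(
                f"expected a 3D image, got {img.GetDimension()}D; "
                "use read_time_series for 4D data"
            )
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            data=data,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            modality=modality,
        )


@dataclass
class TimeSeriesVolume:
    """An ordered set of co-registered frames with cardiac-phase annotations.

    ``phase`` is the per-frame cardiac-phase fraction in [0, 1), or ``None``
    when unknown (the free-running US case: acquisition not synchronized with
    an ECG).  ECG-gated series must carry strictly increasing known phases.
    """

    frames: list[Volume]
    phase: np.ndarray | None = None
    source: str = "FREE_RUNNING"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("time series needs at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if not f.same_grid(ref):
                raise ValueError("all frames must share shape, spacing, origin, direction")
        if self.source not in ("ECG_GATED", "FREE_RUNNING"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if len(self.phase) != len(self.frames):
                raise ValueError("one phase per frame required")
        if self.source == "ECG_GATED":
            if self.phase is None:
                raise ValueError("ECG-gated series must have known phases")
            if np.any(np.diff(self.phase) <= 0):
                raise ValueError("ECG-gated phases must be strictly increasing")
            if np.any((self.phase < 0) | (self.phase >= 1)):
                raise ValueError("phases must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "DICOM_DIR"
    name = path.name.lower()
    if name.endswith((".nrrd", ".nhdr")):
        return "NRRD"
    if name.endswith((".nii", ".nii.gz")):
        return "NIFTI"
    raise VolumeFormatError(f"cannot infer image format from {path.name!r}")


def read_volume(path: str | Path, format: str | None = None, modality: str = "OTHER") -> Volume:
    """Read a 3D scalar image (NRRD, NIfTI, or a DICOM series directory).

    Geometry is taken from the header, never guessed; NIfTI RAS headers are
    converted to the package's LPS convention.  A 4D file raises
    :class:`FourDImageError` so the caller knows to use the time-series
    reader instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    fmt = format or _infer_format(path)
    if fmt == "DICOM_DIR":
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise VolumeFormatError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    elif fmt in ("NRRD", "NIFTI"):
        img = sitk.ReadImage(str(path))
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError("expected a scalar image")
    return Volume.from_sitk(img, modality=modality)


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume to NRRD or NIfTI (format chosen by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(v.to_sitk(), str(path), useCompression=False)
    return path


def write_time_series(
    ts: TimeSeriesVolume, directory: str | Path, stem: str = "frame"
) -> Path:
    """Write frames as individual NRRD files plus a JSON manifest sidecar.

    The manifest lists relative frame paths, per-frame phases (or null) and
    the acquisition source; 4D data is deliberately stored as
    directory-of-3D-files so every frame stays readable by any 3D tool.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, f in enumerate(ts.frames):
        name = f"{stem}_{i:03d}.nrrd"
        write_volume(f, directory / name)
        names.append(name)
    manifest = {
        "frames": names,
        "phase": None if ts.phase is None else [float(p) for p in ts.phase],
        "source": ts.source,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_time_series(manifest_path: str | Path, modality: str = "OTHER") -> TimeSeriesVolume:
    """Read a 4D series from its JSON manifest sidecar."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    meta = json.loads(manifest_path.read_text())
    frames = [read_volume(manifest_path.parent / p, modality=modality) for p in meta["frames"]]
    phase = meta.get("phase")
    return TimeSeriesVolume(
        frames=frames,
        phase=None if phase is None else np.asarray(phase, dtype=float),
        source=meta.get("source", "FREE_RUNNING"),
    )


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------

def resample_volume(
    v: Volume, target_spacing: Sequence[float], method: str = "LINEAR"
) -> Volume:
    """Resample onto a grid with the given spacing (mm).

    The output keeps the input origin and direction; the output shape is
    ``ceil(extent / target_spacing)`` so the input physical extent is fully
    covered.  Out-of-grid samples clamp to the nearest edge voxel so linear
    interpolation can never produce values outside the input [min, max].
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target spacing must be three positive components")
    if v.data.size == 0:
        raise ValueError("cannot resample an empty volume")
    if method not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation method {method!r}")
    new_size = np.ceil(np.asarray(v.shape) * v.spacing / target - 1e-9).astype(int)
    new_size = np.maximum(new_size, 1)
    img = v.to_sitk()
    out = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        _INTERPOLATORS[method],
        tuple(v.origin),
        tuple(target),
        tuple(v.direction.flatten()),
        0.0,
        img.GetPixelID(),
        True,  # nearest-neighbour extrapolation = clamp-to-edge
    )
    return replace(Volume.from_sitk(out, modality=v.modality), modality=v.modality)


def center_volume(v: Volume) -> Volume:
    """Translate the origin so the volume's physical centre sits at (0,0,0).

    Only the origin changes; voxel data, spacing and direction are untouched,
    so all pairwise physical distances between voxel centres are preserved
    and the operation is idempotent.
    """
    return replace(v, origin=v.origin - v.physical_center())


def physical_coordinates(v: Volume) -> np.ndarray:
    """Physical LPS coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in v.shape], indexing="ij"), axis=-1
    ).astype(float)
    return v.origin + (idx * v.spacing) @ v.direction.T


def physical_extent(v: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned physical bounding box (mm) of the voxel centres."""
    last = np.asarray(v.shape, dtype=float) - 1
    corners = np.array(
        [[i * last[0], j * last[1], k * last[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    pts = v.index_to_physical(corners)
    return pts.min(axis=0), pts.max(axis=0)


def mirror_volume(
    v: Volume,
    plane_position: float,
    plane_normal_axis: str = "X",
    method: str = "NEAREST",
) -> Volume:
    """Reflect the volume across the physical plane ``x = plane_position``.

    The reflection is realized by resampling onto the original grid: each
    output voxel takes its intensity from the point mirrored across the
    sagittal plane.  Nearest-neighbour interpolation is the default so that
    the operation is an exact involution when the plane lies on a voxel
    column, and bone intensities survive unchanged for later thresholding.
    """
    if plane_normal_axis != "X":
        raise ValueError("only X (sagittal) mirroring is supported")
    if method not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation method {method!r}")
    lo, hi = physical_extent(v)
    if not (lo[0] <= plane_position <= hi[0]):
        raise ValueError(
            f"mirror plane x={plane_position} outside volume x-extent [{lo[0]}, {hi[0]}]"
        )
    reflect = sitk.AffineTransform(3)
    reflect.SetMatrix((-1.0, 0, 0, 0, 1.0, 0, 0, 0, 1.0))
    reflect.SetCenter((float(plane_position), 0.0, 0.0))
    img = v.to_sitk()
    out = sitk.Resample(
        img,
        img,
        reflect,  # self-inverse: maps output points to their mirror source
        _INTERPOLATORS[method],
        0.0,
        img.GetPixelID(),
        True,
    )
    return replace(Volume.from_sitk(out, modality=v.modality), modality=v.modality)
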
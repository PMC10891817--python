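"""Mirror-based unilateral reconstruction: segment, mirror, register, re-segment.

The orthopaedic pipeline reconstructs a one-sided mandible defect from the
healthy side: threshold-segment the bone, mirror the CT across the
mid-sagittal plane, rigidly register the mirrored dataset onto the original
using landmarks on healthy structures adjacent to the defect, and re-segment
the registered mirrored volume with the *same* thresholds used on the
original (asserted, never re-tuned).  "Local" registration means the fit is
driven only by landmarks near the target region; no image masking is added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .landmarks import (
    LandmarkPairing,
    LandmarkSet,
    RigidTransform,
    fit_rigid,
    resample_through_transform,
)
from .volume import Volume, mirror_volume, physical_coordinates, write_volume

__all__ = [
    "SegmentationMask",
    "ReconstructionResult",
    "threshold_segment",
    "reconstruct_unilateral",
    "mask_overlap_report",
    "write_mask",
    "export_mask_surface",
]

#: 26-neighbourhood connectivity for connected components.
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationMask:
    """A binary mask aligned to a volume's geometry, with its thresholds."""

    mask: np.ndarray
    lower: float
    upper: float
    label: str
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def same_geometry(self, other: "SegmentationMask", atol: float = 1e-9) -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def to_volume(self) -> Volume:
        return Volume(
            data=self.mask.astype(np.uint8),
            spacing=self.spacing,
            origin=self.origin,
            direction=self.direction,
        )


def threshold_segment(
    v: Volume,
    lower: float,
    upper: float,
    largest_component: bool = False,
    label: str = "segment",
) -> SegmentationMask:
    """Binary mask of voxels with ``lower <= intensity <= upper``.

    With ``largest_component`` only the largest 26-connected component is
    kept.  An empty mask produces a warning, not an error.
    """
    if lower > upper:
        raise ValueError("need lower <= upper")
    mask = (v.data >= lower) & (v.data <= upper)
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=_CONNECTIVITY)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    if not mask.any():
        warnings.warn(f"threshold [{lower}, {upper}] selected 0 voxels", stacklevel=2)
    return SegmentationMask(
        mask=mask,
        lower=float(lower),
        upper=float(upper),
        label=label,
        spacing=v.spacing,
        origin=v.origin,
        direction=v.direction,
    )


@dataclass
class ReconstructionResult:
    """Artifacts of the mirror + local-registration reconstruction."""

    mirrored: Volume
    registered_mirrored: Volume
    local_transform: RigidTransform
    reconstructed_mask: SegmentationMask


def reconstruct_unilateral(
    ct: Volume,
    bone_thresholds: tuple[float, float],
    defect_side: str,
    landmarks_original: LandmarkSet,
    landmarks_mirrored: LandmarkSet,
    plane_position: float | None = None,
    resample_method: str = "NEAREST",
) -> ReconstructionResult:
    """Reconstruct the defect side of the jaw from its mirrored healthy side.

    Steps: mirror the CT across the sagittal plane ``x = plane_position``
    (default: the x-coordinate of the volume's bounding-box centre); fit the
    rigid transform from the mirrored-volume landmarks to the original-volume
    landmarks; resample the mirrored volume through it onto the original
    grid; re-segment the registered result with exactly the original bone
    thresholds; restrict the mask to the defect side of the plane.

    ``defect_side`` is ``"LEFT"`` (x > plane, LPS) or ``"RIGHT"``
    (x < plane).  Landmarks must sit on healthy structures adjacent to the
    defect, paired by label.
    """
    if defect_side not in ("LEFT", "RIGHT"):
        raise ValueError("defect_side must be LEFT or RIGHT")
    lower, upper = bone_thresholds
    if plane_position is None:
        plane_position = float(ct.physical_center()[0])
    mirrored = mirror_volume(ct, plane_position)
    pairing = LandmarkPairing(fixed=landmarks_original, moving=landmarks_mirrored)
    local_transform = fit_rigid(pairing)
    registered = resample_through_transform(mirrored, ct, local_transform, resample_method)
    # re-segmentation uses bit-identical thresholds to the original bone mask
    mask = threshold_segment(registered, lower, upper, label="reconstructed")
    xs = physical_coordinates(ct)[..., 0]
    side = xs > plane_position if defect_side == "LEFT" else xs < plane_position
    mask.mask &= side
    return ReconstructionResult(
        mirrored=mirrored,
        registered_mirrored=registered,
        local_transform=local_transform,
        reconstructed_mask=mask,
    )


def _surface_points(mask: SegmentationMask) -> np.ndarray:
    """Physical coordinates of surface voxels (mask minus its 6-erosion)."""
    eroded = ndimage.binary_erosion(mask.mask)  # 6-connected structuring element
    surf = mask.mask & ~eroded
    idx = np.argwhere(surf).astype(float)
    return mask.origin + (idx * mask.spacing) @ mask.direction.T


def mask_overlap_report(
    a: SegmentationMask,
    b: SegmentationMask,
    percentiles: tuple[float, ...] = (50.0, 95.0, 100.0),
) -> dict:
    """Dice coefficient and symmetric surface-distance percentiles (mm).

    Distances are nearest-surface-voxel distances pooled over both
    directions (a→b and b→a).
    """
    if not a.same_geometry(b):
        raise ValueError("masks must share geometry")
    na, nb = a.count, b.count
    inter = int((a.mask & b.mask).sum())
    dice = 2.0 * inter / (na + nb) if (na + nb) else float("nan")
    report: dict = {"dice": float(dice), "surface_distance_percentiles": {}}
    if na and nb:
        pa = _surface_points(a)
        pb = _surface_points(b)
        d_ab = cKDTree(pb).query(pa)[0]
        d_ba = cKDTree(pa).query(pb)[0]
        pooled = np.concatenate([d_ab, d_ba])
        report["surface_distance_percentiles"] = {
            f"p{int(p)}": float(np.percentile(pooled, p)) for p in percentiles
        }
    return report


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Write a mask as a 0/1 label volume (NRRD or NIfTI)."""
    return write_volume(mask.to_volume(), path)


def export_mask_surface(mask: SegmentationMask, path: str | Path, level: float = 0.5) -> Path:
    """Export the mask surface as STL via marching cubes (for downstream
    surgical-planning tools)."""
    from skimage.measure import marching_cubes
    import trimesh

    verts, faces, _, _ = marching_cubes(mask.mask.astype(np.float32), level=level)
    verts = mask.origin + (verts * mask.spacing) @ mask.direction.T
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path
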
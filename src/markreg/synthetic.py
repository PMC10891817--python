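"""Synthetic phantoms with known ground truth for both pipelines.

Three generators cover every input the registration workflows need:

* a 4D cardiac phantom pair — an ECG-gated 10-phase contrast-CT-like series
  rendering a pulsating torus annulus with chamber walls and an outflow
  tract, plus a free-running transesophageal-US-like series of the same
  scene viewed through a known rigid transform, cropped to a cone and
  degraded with speckle;
* an observer model that perturbs ground-truth landmark positions with
  per-coordinate Gaussian localization noise (optionally inflating with the
  landmark index, emulating that later landmarks are harder to place);
* an asymmetric skull/jaw phantom — a U-shaped mandible analogue whose one
  ramus is rigidly displaced and carries a "tumour" defect, with the intact
  pre-defect bone mask stored as ground truth.

The scene is built from additive geometric primitives; everything is
deterministic given the spec seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .landmarks import LandmarkPairing, LandmarkSet, RigidTransform
from .volume import TimeSeriesVolume, Volume

__all__ = [
    "CardiacPhantomSpec",
    "ObserverSpec",
    "JawPhantomSpec",
    "CardiacTruth",
    "JawTruth",
    "make_cardiac_truth",
    "make_cardiac_pair",
    "place_landmarks",
    "make_jaw_phantom",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class CardiacPhantomSpec:
    """Conditions of the synthetic cardiac study.

    Grid spacings default to representative clinical values (CT
    0.47x0.47x1.00 mm, US 0.50x0.50x0.27 mm); the annulus defaults to a
    35 mm mean diameter with 15% pulsation.  ``true_transform`` (the US→CT
    map, i.e. the probe pose) is the synthetic stand-in for an expert
    gold-standard registration.
    """

    annulus_diameter_mean: float = 35.0
    annulus_pulsation_amplitude: float = 0.15
    n_ct_phases: int = 10
    n_us_frames: int = 25
    us_cycle_span: int = 20  # US frames per cardiac cycle
    us_phase_offset: float = 0.0
    ct_spacing: tuple[float, float, float] = (0.47, 0.47, 1.00)
    us_spacing: tuple[float, float, float] = (0.50, 0.50, 0.27)
    ct_shape: tuple[int, int, int] = (112, 112, 60)
    us_shape: tuple[int, int, int] = (96, 96, 160)
    true_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform.from_params([25.0, 10.0, -8.0, 12.0, -8.0, 20.0])
    )
    us_cone_half_angle: float = 35.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ct_phases < 2:
            raise ValueError("need at least 2 CT phases")
        if not (0 < self.annulus_pulsation_amplitude < 1):
            raise ValueError("pulsation amplitude must lie in (0, 1)")
        for sp in (self.ct_spacing, self.us_spacing):
            if any(s <= 0 for s in sp):
                raise ValueError("spacings must be positive")
        if self.n_us_frames < 2 or self.us_cycle_span < 2:
            raise ValueError("US series needs at least 2 frames and 2 frames/cycle")


@dataclass
class ObserverSpec:
    """Landmark localization noise model for one observer.

    Per-coordinate SD of landmark k (0-based prefix index) is
    ``sigma_mm * (1 + index_inflation * k)``; ``bias_mm`` is a constant
    per-observer offset.  Placements are reproducible from the seed.
    """

    sigma_mm: float = 1.0
    index_inflation: float = 0.0
    bias_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_mm < 0 or self.index_inflation < 0:
            raise ValueError("sigma and index_inflation must be >= 0")


@dataclass
class JawPhantomSpec:
    """Conditions of the synthetic jaw/skull phantom."""

    shape: tuple[int, int, int] = (64, 56, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    bone_intensity: float = 1200.0
    soft_intensity: float = 80.0
    tumour_intensity: float = 300.0
    asymmetry_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform.from_params([0.0, 3.0, 0.0, 1.5, 1.0, 0.5])
    )
    defect_extent: float = 10.0  # radius (mm) of the spherical defect; 0 = none
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.defect_extent < 0:
            raise ValueError("defect extent must be >= 0")


# ---------------------------------------------------------------------------
# Cardiac scene
# ---------------------------------------------------------------------------

_LANDMARK_LABELS = [
    *[f"annulus-{i + 1}" for i in range(8)],
    "trigone-L",
    "trigone-R",
    "outflow",
    "apex",
]


def _ring_radius(spec: CardiacPhantomSpec, phase: float) -> float:
    """Annulus centreline radius at a cardiac phase; maximal ("fully open")
    at phase 0, so max-min diameter = amplitude * mean diameter."""
    amp = spec.annulus_pulsation_amplitude
    return 0.5 * spec.annulus_diameter_mean * (1.0 + 0.5 * amp * np.cos(2 * np.pi * phase))


def _scene_landmarks(spec: CardiacPhantomSpec, phase: float) -> np.ndarray:
    r = _ring_radius(spec, phase)
    ring = [
        (r * np.cos(th), r * np.sin(th), 0.0)
        for th in np.deg2rad(np.arange(0, 360, 45))
    ]
    trigones = [
        ((r + 4.0) * np.cos(np.deg2rad(20)), (r + 4.0) * np.sin(np.deg2rad(20)), 2.0),
        ((r + 4.0) * np.cos(np.deg2rad(160)), (r + 4.0) * np.sin(np.deg2rad(160)), 2.0),
    ]
    outflow = [(0.0, -10.0, 20.0)]
    apex = [(0.0, 0.0, -28.0)]
    return np.asarray(ring + trigones + outflow + apex, dtype=float)


def _soft_edge(signed: np.ndarray, width: float = 1.5) -> np.ndarray:
    """Weight in [0, 1] from a signed 'inside-ness' value, smoothed over
    ``width`` mm so the scene is Lipschitz and interpolates consistently
    across grids with different spacings."""
    return np.clip(signed / width + 0.5, 0.0, 1.0)


def _render_scene(points: np.ndarray, spec: CardiacPhantomSpec, phase: float) -> np.ndarray:
    """Scene intensity at physical points (..., 3) in the CT frame.

    Additive geometric primitives composited in priority order with soft
    (~1.5 mm) edges: soft-tissue body, two contrast-filled chambers with
    walls, an outflow tube and the bright pulsating annulus torus.
    """
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    r = _ring_radius(spec, phase)
    out = np.zeros(x.shape, dtype=np.float32)

    def paint(weight: np.ndarray, value: float) -> None:
        nonlocal out
        out = out * (1.0 - weight) + value * weight

    # soft-tissue body (ellipsoid; quadratic form scaled to ~mm units)
    u = (x / 42.0) ** 2 + (y / 42.0) ** 2 + (z / 40.0) ** 2
    paint(_soft_edge((1.0 - u) * 20.0), 40.0)

    # chambers: wall shells then contrast-filled interiors
    for cz, rz, fill in ((14.0, 14.0, 260.0), (-14.0, 16.0, 240.0)):
        u = (x / (r + 8.0)) ** 2 + (y / (r + 8.0)) ** 2 + ((z - cz) / rz) ** 2
        paint(_soft_edge((1.0 - u) * 10.0), 160.0)
        paint(_soft_edge((0.85 - u) * 10.0), fill)

    # outflow tract: vertical tube, smoothly windowed in z
    d_tube = 5.0 - np.sqrt(x**2 + (y + 10.0) ** 2)
    w_tube = _soft_edge(d_tube) * _soft_edge(z - 8.0) * _soft_edge(28.0 - z)
    paint(w_tube, 220.0)

    # valve leaflets: a disc closing the orifice away from the fully open
    # state (phase 0); darker than the contrast fill, so the ROI mean
    # intensity peaks at full opening — the basis of the openness signal
    rho = np.sqrt(x**2 + y**2)
    closure = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    d_leaf = np.minimum(0.9 * r - rho, 2.5 - np.abs(z))
    paint(_soft_edge(d_leaf) * closure, 140.0)

    # annulus: torus in the z=0 plane, the bright target ring
    d_torus = 3.0 - np.sqrt((rho - r) ** 2 + z**2)
    paint(_soft_edge(d_torus), 420.0)
    return out.astype(np.float32)


@dataclass
class CardiacTruth:
    """Ground truth of a cardiac phantom pair.

    ``true_transform`` maps US physical space into CT physical space
    (moving → fixed); per-frame US phases are recorded here even though the
    generated US series itself carries no phase annotation (the consumer is
    not supposed to know them).
    """

    spec: CardiacPhantomSpec
    true_transform: RigidTransform
    ct_phases: np.ndarray
    us_frame_phases: np.ndarray

    def ct_landmarks(self, phase: float) -> LandmarkSet:
        return LandmarkSet(
            _scene_landmarks(self.spec, phase), list(_LANDMARK_LABELS), space="CT"
        )

    def us_landmarks(self, phase: float) -> LandmarkSet:
        pts = self.true_transform.inverse().apply(_scene_landmarks(self.spec, phase))
        return LandmarkSet(pts, list(_LANDMARK_LABELS), space="US")

    def pairing(self, phase: float) -> LandmarkPairing:
        """Fixed = CT landmarks, moving = US landmarks at the given phase."""
        return LandmarkPairing(self.ct_landmarks(phase), self.us_landmarks(phase))


def make_cardiac_truth(spec: CardiacPhantomSpec) -> CardiacTruth:
    """Ground truth (transform, phases, landmarks) without rendering volumes."""
    ct_phases = np.arange(spec.n_ct_phases) / spec.n_ct_phases
    us_phases = np.mod(
        spec.us_phase_offset + np.arange(spec.n_us_frames) / spec.us_cycle_span, 1.0
    )
    return CardiacTruth(spec, spec.true_transform, ct_phases, us_phases)


def _grid_volume(shape, spacing, origin, modality, data) -> Volume:
    return Volume(data=data, spacing=np.asarray(spacing), origin=np.asarray(origin), modality=modality)


def _grid_points(shape, spacing, origin) -> np.ndarray:
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def us_cone_apex(spec: CardiacPhantomSpec, us_center: np.ndarray) -> np.ndarray:
    """Cone apex position in the US frame: 10 mm above the +z face centre."""
    half_z = (spec.us_shape[2] - 1) / 2.0 * spec.us_spacing[2]
    return np.asarray(us_center, dtype=float) + np.array([0.0, 0.0, half_z + 10.0])


def us_cone_mask(
    spec: CardiacPhantomSpec,
    points_us: np.ndarray,
    us_center: np.ndarray,
    margin_mm: float = 0.0,
) -> np.ndarray:
    """Indicator of the US field-of-view cone at US-frame points (..., 3).

    The cone axis points in -z from the apex; a positive ``margin_mm``
    shrinks the cone laterally (useful to stay clear of the crop boundary
    when comparing intensities across grids).
    """
    apex = us_cone_apex(spec, us_center)
    rel = points_us - apex
    axial = -rel[..., 2]
    lateral = np.sqrt(rel[..., 0] ** 2 + rel[..., 1] ** 2)
    tan = np.tan(np.deg2rad(spec.us_cone_half_angle))
    return (axial > margin_mm) & (lateral <= axial * tan - margin_mm)


def make_cardiac_pair(
    spec: CardiacPhantomSpec,
) -> tuple[TimeSeriesVolume, TimeSeriesVolume, CardiacTruth]:
    """Render the ECG-gated CT series and the free-running US series.

    The CT grid is centred on the scene.  The US grid has its own spacing
    and shape; its centre is placed at the pre-image of the scene centre
    under ``true_transform``, so the arbitrary probe orientation lives
    entirely in the transform.  US frames are cropped to a cone whose apex
    sits above the +z face and, when ``noise_sd > 0``, degraded with
    multiplicative Rayleigh speckle, additive noise and a mild blur.
    """
    truth = make_cardiac_truth(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(17,)))

    ct_shape = np.asarray(spec.ct_shape)
    ct_spacing = np.asarray(spec.ct_spacing)
    ct_origin = -(ct_shape - 1) / 2.0 * ct_spacing
    ct_pts = _grid_points(ct_shape, ct_spacing, ct_origin)
    ct_frames = [
        _grid_volume(ct_shape, ct_spacing, ct_origin, "CT", _render_scene(ct_pts, spec, p))
        for p in truth.ct_phases
    ]
    ct = TimeSeriesVolume(ct_frames, phase=truth.ct_phases, source="ECG_GATED")

    us_shape = np.asarray(spec.us_shape)
    us_spacing = np.asarray(spec.us_spacing)
    c_us = spec.true_transform.inverse().apply(np.zeros(3))
    us_origin = c_us - (us_shape - 1) / 2.0 * us_spacing
    us_pts = _grid_points(us_shape, us_spacing, us_origin)
    scene_pts = spec.true_transform.apply(us_pts.reshape(-1, 3)).reshape(us_pts.shape)

    cone = us_cone_mask(spec, us_pts, c_us)

    us_frames = []
    for p in truth.us_frame_phases:
        img = _render_scene(scene_pts, spec, p)
        if spec.noise_sd > 0:
            speckle = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=img.shape)
            img = img * speckle + rng.normal(0.0, spec.noise_sd, size=img.shape)
            img = gaussian_filter(img, sigma=1.0)
        img = np.where(cone, img, 0.0).astype(np.float32)
        us_frames.append(_grid_volume(us_shape, us_spacing, us_origin, "US", img))
    us = TimeSeriesVolume(us_frames, phase=None, source="FREE_RUNNING")
    return ct, us, truth


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

def _user_key(user: int | str) -> int:
    if isinstance(user, int):
        return user
    return zlib.crc32(str(user).encode()) & 0x7FFFFFFF


def place_landmarks(
    truth: LandmarkPairing,
    observer: ObserverSpec,
    n: int,
    trial: int = 0,
    user: int | str = 0,
) -> LandmarkPairing:
    """Simulate one observer placing the first ``n`` landmark pairs.

    Truth positions are taken in prefix order and perturbed independently
    per point and per volume.  The draw is deterministic given
    (observer.seed, user, trial) and prefix-nested across ``n``: asking for
    more landmarks never changes the earlier placements.
    """
    n_max = truth.n
    if n > n_max:
        raise ValueError(f"requested {n} landmarks but truth has only {n_max}")
    ss = np.random.SeedSequence(observer.seed, spawn_key=(_user_key(user), trial))
    rng = np.random.default_rng(ss)
    k = np.arange(n_max)
    sigma = observer.sigma_mm * (1.0 + observer.index_inflation * k)
    noise_fixed = rng.normal(size=(n_max, 3)) * sigma[:, None]
    noise_moving = rng.normal(size=(n_max, 3)) * sigma[:, None]
    bias = np.asarray(observer.bias_mm)
    fixed = LandmarkSet(
        truth.fixed.points[:n] + noise_fixed[:n] + bias,
        list(truth.fixed.labels[:n]),
        truth.fixed.space,
    )
    moving = LandmarkSet(
        truth.moving.points[:n] + noise_moving[:n] + bias,
        list(truth.moving.labels[:n]),
        truth.moving.space,
    )
    return LandmarkPairing(fixed, moving)


# ---------------------------------------------------------------------------
# Jaw phantom
# ---------------------------------------------------------------------------

def _capsule(points: np.ndarray, a: Sequence[float], b: Sequence[float], radius: float) -> np.ndarray:
    """Boolean indicator of a capsule (segment a-b dilated by radius)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.sum((points - closest) ** 2, axis=-1) <= radius**2


def _sphere(points: np.ndarray, c: Sequence[float], radius: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.sum((points - c) ** 2, axis=-1) <= radius**2


_ARC_RADIUS = 32.0


def _mandible_half(points: np.ndarray, side: int) -> np.ndarray:
    """Bone indicator for one side's ramus + condyle in ideal (symmetric)
    coordinates; ``side`` is +1 (left, +x in LPS) or -1 (right)."""
    x0 = side * _ARC_RADIUS
    ramus = _capsule(points, (x0, 0.0, 0.0), (x0, 8.0, 36.0), 6.0)
    condyle = _sphere(points, (x0, 10.0, 40.0), 8.0)
    return ramus | condyle


def _mandible_body(points: np.ndarray) -> np.ndarray:
    """Anterior arc of the mandible body (tube around a semicircle at z=0)."""
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    rho = np.sqrt(x**2 + y**2)
    near_arc = (rho - _ARC_RADIUS) ** 2 + z**2 <= 7.0**2
    return near_arc & (y <= 0)


# Right-side (healthy) anatomical landmark positions, chosen on the ramus
# and condyle so their left-side twins stay clear of the defect region.
_JAW_LANDMARKS_RIGHT = np.array(
    [
        [-32.0, 10.0, 48.0],  # condyle top
        [-30.0, 18.0, 40.0],  # condyle posterior
        [-34.0, 2.0, 40.0],  # condyle anterior
        [-32.0, 0.0, 2.0],  # ramus base
        [-32.0, -2.0, 6.0],  # ramus antero-inferior
        [-32.0, 12.0, 34.0],  # ramus posterior-superior
    ]
)
_JAW_LANDMARK_LABELS = [
    "condyle-top",
    "condyle-post",
    "condyle-ant",
    "ramus-base",
    "ramus-antinf",
    "ramus-postsup",
]
_DEFECT_CENTER_IDEAL = np.array([32.0, 4.0, 18.0])  # mid left ramus


@dataclass
class JawTruth:
    """Ground truth of the jaw phantom."""

    pre_defect_mask: np.ndarray  # intact bone mask, before the defect
    asymmetry_transform: RigidTransform
    landmarks_original: LandmarkSet  # on the phantom's displaced (left) side
    landmarks_mirrored: LandmarkSet  # same points as seen in the mirrored volume
    bone_thresholds: tuple[float, float]
    plane_position: float
    defect_side: str
    defect_center: np.ndarray
    defect_radius: float


def make_jaw_phantom(spec: JawPhantomSpec) -> tuple[Volume, JawTruth]:
    """Render the asymmetric jaw phantom with a recoverable one-sided defect.

    The mandible analogue is a U-shaped body arc plus two rami with
    condyles.  The left (+x) ramus/condyle is displaced by the asymmetry
    transform; a spherical defect region on that side is replaced by tumour
    intensity.  The intact (pre-defect) bone mask and exact landmark
    correspondences between the original and mirrored datasets are stored as
    ground truth.
    """
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    # grid symmetric about x=0 (mid-sagittal); y/z centred on the anatomy
    origin = np.array(
        [
            -(shape[0] - 1) / 2.0 * spacing[0],
            -2.0 - (shape[1] - 1) / 2.0 * spacing[1],
            16.0 - (shape[2] - 1) / 2.0 * spacing[2],
        ]
    )
    pts = _grid_points(shape, spacing, origin)
    d = spec.asymmetry_transform
    pts_ideal_left = d.inverse().apply(pts.reshape(-1, 3)).reshape(pts.shape)

    bone = (
        _mandible_body(pts)
        | _mandible_half(pts, side=-1)  # right side, healthy
        | _mandible_half(pts_ideal_left, side=+1)  # left side, displaced by D
    )
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    soft = (x / 42.0) ** 2 + ((y + 5.0) / 40.0) ** 2 + ((z - 15.0) / 38.0) ** 2 <= 1.0

    img = np.zeros(tuple(shape), dtype=np.float32)
    img[soft] = spec.soft_intensity
    img[bone] = spec.bone_intensity

    pre_defect_mask = bone.copy()
    defect_center = d.apply(_DEFECT_CENTER_IDEAL)
    if spec.defect_extent > 0:
        defect = _sphere(pts, defect_center, spec.defect_extent)
        img[defect & bone] = spec.tumour_intensity

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(23,)))
        img = (img + rng.normal(0.0, spec.noise_sd, size=img.shape)).astype(np.float32)

    ct = Volume(data=img, spacing=spacing, origin=origin, modality="CT")

    mirrored_pts = _JAW_LANDMARKS_RIGHT * np.array([-1.0, 1.0, 1.0])  # ideal left
    original_pts = d.apply(mirrored_pts)  # actual (displaced) left anatomy
    truth = JawTruth(
        pre_defect_mask=pre_defect_mask,
        asymmetry_transform=d,
        landmarks_original=LandmarkSet(original_pts, list(_JAW_LANDMARK_LABELS), "original"),
        landmarks_mirrored=LandmarkSet(mirrored_pts, list(_JAW_LANDMARK_LABELS), "mirrored"),
        bone_thresholds=(0.5 * spec.bone_intensity, 2.0 * spec.bone_intensity),
        plane_position=0.0,
        defect_side="LEFT",
        defect_center=defect_center,
        defect_radius=spec.defect_extent,
    )
    return ct, truth
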
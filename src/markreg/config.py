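"""Run configuration: YAML round-trip with explicit validation.

Every pipeline run writes its fully-resolved configuration next to its
outputs, so a run is reproducible from that file plus its seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .validation import ValidationProtocol

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Settings shared by the cardiac and jaw pipelines.

    ``target_spacing`` and ``interpolation`` default to the reference
    resampling settings (0.342 x 0.342 x 0.37 mm, linear).
    """

    # inputs (any may be None when running on synthetic data)
    ct_manifest: str | None = None
    us_manifest: str | None = None
    ct_volume: str | None = None
    landmarks_fixed: str | None = None
    landmarks_moving: str | None = None
    gs_transform: str | None = None
    # processing
    target_spacing: tuple[float, float, float] = (0.342, 0.342, 0.37)
    interpolation: str = "LINEAR"
    registration_phase: float = 0.9  # end-diastole
    synthetic: bool = False
    synthetic_spec: dict | None = None  # keyword overrides for the phantom spec
    observer_sigma_mm: float = 1.0
    bone_thresholds: tuple[float, float] | None = None
    defect_side: str = "LEFT"
    plane_position: float | None = None
    # protocol & bookkeeping
    protocol: ValidationProtocol = field(default_factory=ValidationProtocol)
    seed: int = 0
    out_dir: str = "markreg_out"

    def __post_init__(self) -> None:
        self.target_spacing = tuple(float(s) for s in self.target_spacing)  # type: ignore[assignment]
        if len(self.target_spacing) != 3 or any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be three positive mm values")
        if self.interpolation not in ("LINEAR", "NEAREST", "BSPLINE"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if not (0.0 <= self.registration_phase < 1.0):
            raise ValueError("registration_phase must lie in [0, 1)")
        if self.defect_side not in ("LEFT", "RIGHT"):
            raise ValueError("defect_side must be LEFT or RIGHT")
        if self.observer_sigma_mm < 0:
            raise ValueError("observer_sigma_mm must be >= 0")
        if isinstance(self.protocol, dict):
            self.protocol = ValidationProtocol(**self.protocol)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bone_thresholds" in raw and raw["bone_thresholds"] is not None:
        raw["bone_thresholds"] = tuple(raw["bone_thresholds"])
    return PipelineConfig(**raw)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    """Write the fully-resolved configuration as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    doc = _plain(asdict(config))
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
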
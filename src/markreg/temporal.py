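"""Temporal registration: cycle selection and CT/US cardiac phase matching.

ECG-gated CT provides volumes at known phase fractions (typically
0.0, 0.1, ..., 0.9 of the cycle).  Free-running 4D US is not synchronized
with the ECG, so a single cardiac cycle is first delimited between two
"fully open" valve states — either interactively (the primary path,
mirroring visual assessment) or automatically from a per-frame openness
signal — and phases are then assumed uniformly spaced within that cycle.
Each CT phase fraction p is matched to US frame

    start_frame + round(p * (end_frame - start_frame))

with round-half-even tie-breaking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume import TimeSeriesVolume, Volume

__all__ = [
    "CycleSelection",
    "PhaseMatch",
    "CycleDetectionError",
    "openness_signal",
    "select_cycle",
    "match_phases",
    "extract_matched_pair",
    "write_matches",
    "read_matches",
]

#: Minimum peak prominence, as a fraction of the signal range, for a local
#: maximum to count as a "fully open" event.
PROMINENCE_FRACTION = 0.25


class CycleDetectionError(ValueError):
    """The openness signal does not delimit a cardiac cycle."""


@dataclass(frozen=True)
class CycleSelection:
    """A single cardiac cycle within a free-running US series."""

    start_frame: int
    end_frame: int
    criterion: str = "fully-open to fully-open"

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError("need 0 <= start_frame < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class PhaseMatch:
    """One gated CT phase matched to its temporally corresponding US frame."""

    ct_phase_index: int
    ct_phase_fraction: float
    us_frame_index: int


def openness_signal(
    us: TimeSeriesVolume,
    roi: tuple[slice, slice, slice] | None = None,
    bright_threshold: float | None = None,
) -> np.ndarray:
    """Per-frame scalar proxy for valve opening inside an ROI box.

    By default the ROI mean intensity; with ``bright_threshold`` the
    fraction of ROI voxels above that intensity, which tracks the size of a
    bright structure (e.g. the annulus ring) far more robustly under
    speckle.  The default ROI is the central half of the grid along each
    axis.  This is the automatic stand-in for visual assessment of leaflet
    motion; interactively supplied frame indices remain the primary path.
    """
    if roi is None:
        shape = us.frames[0].shape
        roi = tuple(slice(n // 4, n - n // 4) for n in shape)  # type: ignore[assignment]
    if bright_threshold is None:
        return np.array([float(f.data[roi].mean()) for f in us.frames])
    return np.array([float((f.data[roi] > bright_threshold).mean()) for f in us.frames])


def _local_maxima(signal: np.ndarray) -> list[int]:
    """Indices of local maxima, endpoints included, plateau-aware.

    A run of equal values higher than both flanks counts as one maximum at
    the run's middle index.
    """
    n = len(signal)
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and signal[j + 1] == signal[i]:
            j += 1
        left_ok = i == 0 or signal[i - 1] < signal[i]
        right_ok = j == n - 1 or signal[j + 1] < signal[j]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            idx.append((i + j) // 2)
        i = j + 1
    return idx


def _cyclic_prominence(signal: np.ndarray, m: int) -> float:
    """Peak prominence treating the signal as one period of a cyclic series.

    The signal is tiled three times and the standard prominence rule
    (height above the higher of the two valley minima toward strictly
    higher terrain) is applied to the middle copy, so peaks adjacent to a
    truncated cycle at either end are not penalized.
    """
    n = len(signal)
    tiled = np.concatenate([signal, signal, signal])
    c = m + n
    v = tiled[c]
    left = tiled[:c][::-1]
    higher = np.nonzero(left > v)[0]
    lmin = left[: higher[0] + 1].min() if len(higher) else left.min()
    right = tiled[c + 1 :]
    higher = np.nonzero(right > v)[0]
    rmin = right[: higher[0] + 1].min() if len(higher) else right.min()
    return float(v - max(lmin, rmin))


def select_cycle(
    us: TimeSeriesVolume,
    openness: np.ndarray | None = None,
    manual: tuple[int, int] | None = None,
) -> CycleSelection:
    """Delimit one cardiac cycle between two "fully open" states.

    ``manual`` start/end indices take precedence (bounds-checked and
    returned verbatim), mirroring interactive visual selection.  Otherwise
    the first two consecutive sufficiently prominent local maxima of the
    openness signal delimit the cycle.
    """
    n = us.n_frames
    if manual is not None:
        start, end = manual
        if not (0 <= start < end < n):
            raise ValueError(f"manual cycle ({start}, {end}) out of range for {n} frames")
        return CycleSelection(start, end, criterion="manual")
    if openness is None:
        openness = openness_signal(us)
    openness = np.asarray(openness, dtype=float)
    if len(openness) != n:
        raise ValueError("need one openness value per frame")
    rng_sig = float(openness.max() - openness.min())
    maxima = _local_maxima(openness)
    if rng_sig > 0:
        maxima = [
            i
            for i in maxima
            if _cyclic_prominence(openness, i) >= PROMINENCE_FRACTION * rng_sig
        ]
    else:
        maxima = []
    if len(maxima) < 2:
        raise CycleDetectionError(
            "fewer than 2 'fully open' maxima in the openness signal; cannot delimit a cycle"
        )
    return CycleSelection(maxima[0], maxima[1])


def match_phases(ct: TimeSeriesVolume, cycle: CycleSelection) -> list[PhaseMatch]:
    """Match each gated CT phase to its US frame within the selected cycle.

    CT phase fraction p maps to ``start + round(p * (end - start))`` with
    round-half-even; the mapping is deterministic and monotone, and the
    cycle endpoints map to themselves (p=0 → start; p=1 would → end).
    """
    if ct.source != "ECG_GATED" or ct.phase is None:
        raise ValueError("CT series must be ECG-gated with known phase fractions")
    span = cycle.end_frame - cycle.start_frame
    matches = []
    for i, p in enumerate(ct.phase):
        us_idx = cycle.start_frame + int(np.round(p * span))
        matches.append(PhaseMatch(i, float(p), us_idx))
    return matches


def extract_matched_pair(
    ct: TimeSeriesVolume,
    us: TimeSeriesVolume,
    matches: list[PhaseMatch],
    phase_fraction: float,
) -> tuple[Volume, Volume]:
    """Return the CT frame at a gated phase and its matched US frame.

    The requested phase must be one of the gated fractions (e.g. 0.9, the
    end-diastolic frame used for spatial registration).
    """
    for m in matches:
        if abs(m.ct_phase_fraction - phase_fraction) <= 1e-9:
            return ct.frames[m.ct_phase_index], us.frames[m.us_frame_index]
    avail = [m.ct_phase_fraction for m in matches]
    raise ValueError(f"phase {phase_fraction} not in gated set {avail}")


def write_matches(matches: list[PhaseMatch], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        {"ct_phase": m.ct_phase_fraction, "ct_index": m.ct_phase_index, "us_index": m.us_frame_index}
        for m in matches
    ]
    path.write_text(json.dumps(records, indent=2))
    return path


def read_matches(path: str | Path) -> list[PhaseMatch]:
    records = json.loads(Path(path).read_text())
    return [PhaseMatch(r["ct_index"], r["ct_phase"], r["us_index"]) for r in records]
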
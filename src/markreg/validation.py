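"""Landmark-count validation: trial sweeps, curves, boxplots, optimal N.

The reproducibility study sweeps the number of landmark pairs N used for the
rigid fit, repeats each configuration over trials and observers, and scores
every fit with the three error metrics against the gold-standard transform.
Within a trial the landmark subsets are prefix-nested: the placement of
landmark k does not change as N grows, so the per-N curves are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkPairing, LandmarkSet, RigidTransform, fit_rigid
from .metrics import GoldStandard, MetricRecord, fre, records_to_frame, rmse1, rmse2
from .synthetic import ObserverSpec, place_landmarks

__all__ = [
    "ValidationProtocol",
    "SweepDataset",
    "ValidationReport",
    "run_sweep",
    "aggregate_curves",
    "select_optimal_n",
    "check_bounds",
    "boxplot_summary",
]


@dataclass
class ValidationProtocol:
    """Study design: N range, trials, observers, chosen N and error bounds.

    Defaults reflect the reference protocol: N swept from 3 to 12 with 10
    trials and two observers, 10 landmarks for the final registration, and
    acceptance bounds of 15 mm on RMSE-type errors and 8 mm on FRE.
    """

    n_min: int = 3
    n_max: int = 12
    trials: int = 10
    users: tuple[str, ...] = ("user1", "user2")
    chosen_n: int = 10
    rmse_bound: float = 15.0
    fre_bound: float = 8.0
    optimal_tolerance: float = 0.05  # relative slack on the rmse2-curve minimum

    def __post_init__(self) -> None:
        if not (3 <= self.n_min <= self.chosen_n <= self.n_max):
            raise ValueError("need 3 <= n_min <= chosen_n <= n_max")
        if self.trials < 1:
            raise ValueError("need at least one trial")
        if self.rmse_bound <= 0 or self.fre_bound <= 0:
            raise ValueError("bounds must be positive")

    @property
    def n_values(self) -> range:
        return range(self.n_min, self.n_max + 1)


@dataclass
class SweepDataset:
    """One synthetic (or recorded) patient: truth landmarks + gold standard.

    ``fixed_truth`` and ``moving_truth`` are the true corresponding landmark
    positions in the fixed and moving volumes (>= n_max of them);
    ``gs_transform`` is the reference moving→fixed map.
    """

    patient: str
    fixed_truth: LandmarkSet
    moving_truth: LandmarkSet
    gs_transform: RigidTransform

    def truth_pairing(self) -> LandmarkPairing:
        return LandmarkPairing(self.fixed_truth, self.moving_truth)


def run_sweep(
    datasets: SweepDataset | list[SweepDataset],
    protocol: ValidationProtocol,
    observers: dict[str, ObserverSpec] | None = None,
    seed: int = 0,
    recorded: dict[tuple[str, str, int], LandmarkPairing] | None = None,
) -> list[MetricRecord]:
    """Run the full (patient x user x trial x N) sweep.

    For each (user, trial) the observer model samples one prefix-nested
    placement of ``n_max`` landmark pairs (or a recorded placement is looked
    up under key ``(patient, user, trial)``); for every N the rigid fit uses
    the first N pairs and all metrics are computed against the gold
    standard.  Fully reproducible from ``seed``.
    """
    if isinstance(datasets, SweepDataset):
        datasets = [datasets]
    if observers is None:
        observers = {u: ObserverSpec(sigma_mm=1.0, seed=seed) for u in protocol.users}
    records: list[MetricRecord] = []
    for pi, ds in enumerate(datasets):
        if len(ds.fixed_truth) < protocol.n_max and recorded is None:
            raise ValueError(
                f"dataset {ds.patient!r} has {len(ds.fixed_truth)} truth landmarks, "
                f"needs n_max = {protocol.n_max}"
            )
        truth = ds.truth_pairing()
        for ui, user in enumerate(protocol.users):
            obs = observers[user]
            # offset the observer seed stream per sweep seed and patient
            obs_eff = ObserverSpec(
                sigma_mm=obs.sigma_mm,
                index_inflation=obs.index_inflation,
                bias_mm=obs.bias_mm,
                seed=int(
                    np.random.SeedSequence(seed, spawn_key=(obs.seed, pi)).generate_state(1)[0]
                    % (2**31)
                ),
            )
            for trial in range(protocol.trials):
                if recorded is not None:
                    placed = recorded[(ds.patient, user, trial)]
                    if placed.n < protocol.n_max:
                        raise ValueError(
                            f"recorded placement {(ds.patient, user, trial)} has "
                            f"{placed.n} pairs, needs {protocol.n_max}"
                        )
                else:
                    placed = place_landmarks(truth, obs_eff, protocol.n_max, trial=trial, user=ui)
                for n in protocol.n_values:
                    sub = placed.subset(n)
                    t = fit_rigid(sub)
                    gs = GoldStandard.from_moving(ds.gs_transform, sub.moving)
                    r_rot, r_trans = rmse1(t, ds.gs_transform)
                    records.append(
                        MetricRecord(
                            patient=ds.patient,
                            user=user,
                            trial=trial,
                            n_landmarks=n,
                            rmse1_rot=r_rot,
                            rmse1_trans=r_trans,
                            fre=fre(t, sub),
                            rmse2=rmse2(t, sub.moving, gs),
                        )
                    )
    return records


_METRICS = ["rmse1_rot", "rmse1_trans", "fre", "rmse2"]


def aggregate_curves(records: list[MetricRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per (patient, user, N), over trials."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    g = df.groupby(["patient", "user", "n_landmarks"])[_METRICS]
    out = g.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def select_optimal_n(curves: pd.DataFrame, protocol: ValidationProtocol) -> int:
    """Smallest N whose pooled mean RMSE2 is within tolerance of the minimum.

    The per-(patient, user) curves are pooled by averaging the RMSE2 means
    per N; the returned N is the smallest whose pooled mean lies within
    ``optimal_tolerance`` (relative) of the curve minimum, ties broken
    toward smaller N.  This makes the narrative "compromise between speed
    and accuracy" computable.
    """
    pooled = curves.groupby("n_landmarks")["rmse2_mean"].mean()
    for n in protocol.n_values:
        if n not in pooled.index:
            raise ValueError(f"curves missing N = {n}")
    lo = float(pooled.min())
    for n in sorted(pooled.index):
        if pooled[n] <= lo * (1.0 + protocol.optimal_tolerance) + 1e-12:
            return int(n)
    return int(pooled.idxmin())  # unreachable; defensive


def check_bounds(
    records: list[MetricRecord], protocol: ValidationProtocol
) -> tuple[bool, list[MetricRecord]]:
    """Check every record at the chosen N against the error bounds.

    Passing means rmse2 <= rmse_bound and fre <= fre_bound for all records
    at ``chosen_n`` (inclusive comparisons).  Returns the verdict and the
    offending records.
    """
    at_n = [r for r in records if r.n_landmarks == protocol.chosen_n]
    if not at_n:
        raise ValueError(f"no records at chosen N = {protocol.chosen_n}")
    offenders = [
        r for r in at_n if r.rmse2 > protocol.rmse_bound or r.fre > protocol.fre_bound
    ]
    return (not offenders), offenders


def boxplot_summary(
    records: list[MetricRecord], chosen_n: int, metrics: tuple[str, ...] = ("fre", "rmse2")
) -> pd.DataFrame:
    """Five-number summaries per (patient, user, metric) at the chosen N.

    Quartiles use linear interpolation of order statistics; values outside
    Q1 - 1.5 IQR or Q3 + 1.5 IQR are listed as outliers.
    """
    df = records_to_frame(records)
    df = df[df.n_landmarks == chosen_n]
    if df.empty:
        raise ValueError(f"no records at N = {chosen_n}")
    rows = []
    for (patient, user), grp in df.groupby(["patient", "user"]):
        for metric in metrics:
            v = grp[metric].to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            outliers = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
            rows.append(
                {
                    "patient": patient,
                    "user": user,
                    "metric": metric,
                    "min": float(v.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(v.max()),
                    "outliers": list(map(float, sorted(outliers))),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Bundled sweep output: records, curves, summaries, decisions."""

    records: list[MetricRecord]
    curves: pd.DataFrame
    boxplot_summaries: pd.DataFrame
    optimal_n: int
    bounds_pass: bool
    offenders: list[MetricRecord] = field(default_factory=list)

    @classmethod
    def from_records(
        cls, records: list[MetricRecord], protocol: ValidationProtocol
    ) -> "ValidationReport":
        curves = aggregate_curves(records)
        ok, offenders = check_bounds(records, protocol)
        return cls(
            records=records,
            curves=curves,
            boxplot_summaries=boxplot_summary(records, protocol.chosen_n),
            optimal_n=select_optimal_n(curves, protocol),
            bounds_pass=ok,
            offenders=offenders,
        )

    def write(self, directory: str | Path) -> Path:
        """Write records CSV, curves CSV and the JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        records_to_frame(self.records).to_csv(directory / "records.csv", index=False)
        self.curves.to_csv(directory / "curves.csv", index=False)
        self.boxplot_summaries.to_csv(directory / "boxplots.csv", index=False)
        summary = {
            "optimal_n": self.optimal_n,
            "bounds_pass": bool(self.bounds_pass),
            "offenders": [
                {
                    "patient": r.patient,
                    "user": r.user,
                    "trial": r.trial,
                    "fre": r.fre,
                    "rmse2": r.rmse2,
                }
                for r in self.offenders
            ],
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2))
        return directory


def plot_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Optional four-panel plot of the metric curves vs N (one line per
    patient/user), mirroring the usual presentation of such studies."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    titles = {
        "rmse1_rot": "RMSE1 rotation (deg)",
        "rmse1_trans": "RMSE1 translation (mm)",
        "fre": "FRE (mm)",
        "rmse2": "RMSE2 (mm)",
    }
    for ax, metric in zip(axes.flat, _METRICS):
        for (patient, user), grp in curves.groupby(["patient", "user"]):
            ax.plot(grp["n_landmarks"], grp[f"{metric}_mean"], marker="o", label=f"{patient}/{user}")
        ax.set_title(titles[metric])
        ax.set_xlabel("number of landmark pairs N")
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
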
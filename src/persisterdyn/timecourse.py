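"""Observed-data containers, trajectories, and the MGMT observation model.

The observable channels of the experiment are (i) total viable cell counts
and (ii) the bulk MGMT expression fold-change measured by qPCR, both at
discrete observation days.  The MGMT readout maps the hidden compartment
sizes (sensitive S, transient TR, resistant R) to a population-average
per-cell expression relative to a pure-sensitive population:

    readout = (S + c_tr * TR + alpha * R) / (S + TR + R)

where ``alpha >= 1`` is the per-cell expression ratio of a resistant cell to
a sensitive cell and ``c_tr`` (default 0: the transient state does not yet
express MGMT) is the relative expression of a TR cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schedules import TreatmentSchedule

__all__ = [
    "ReadoutParams",
    "mgmt_readout",
    "Trajectory",
    "TimeCourseDataset",
    "read_dataset",
    "write_dataset",
    "SchemaError",
]

DATASET_COLUMNS = ["replicate_id", "day", "count", "mgmt_fold"]


class SchemaError(ValueError):
    """A dataset file or frame violates the time-course schema."""


@dataclass(frozen=True)
class ReadoutParams:
    """Parameters of the MGMT observation model.

    alpha:
        Per-cell MGMT expression of a resistant cell relative to a sensitive
        cell (unitless, >= 1).
    c_tr:
        Relative expression of a TR cell, in ``[0, alpha]``; default 0.
    normalize_to_baseline:
        If True, trajectory readouts are divided by their value at the first
        grid point (fold-change vs. day 0 rather than vs. a pure-sensitive
        population).
    mode:
        ``"average"`` (default) — population-average per-cell expression;
        ``"total"`` — average multiplied by the population size.
    """

    alpha: float = 20.0
    c_tr: float = 0.0
    normalize_to_baseline: bool = False
    mode: str = "average"

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")
        if not 0 <= self.c_tr <= self.alpha:
            raise ValueError(f"c_tr must be in [0, alpha], got {self.c_tr}")
        if self.mode not in ("average", "total"):
            raise ValueError(f"unknown readout mode {self.mode!r}")


def mgmt_readout(S, TR, R, p: ReadoutParams):
    """Bulk MGMT expression fold-change of a mixed population.

    Accepts scalars or aligned arrays.  Undefined (raises) for an empty
    population.
    """
    S = np.asarray(S, dtype=float)
    TR = np.asarray(TR, dtype=float)
    R = np.asarray(R, dtype=float)
    total = S + TR + R
    if np.any(total <= 0):
        raise ValueError("mgmt_readout undefined for an empty population")
    value = (S + p.c_tr * TR + p.alpha * R) / total
    if p.mode == "total":
        value = value * total
    if value.ndim == 0:
        return float(value)
    return value


@dataclass
class Trajectory:
    """Dense simulated time course of compartment sizes plus readouts.

    ``TR`` is the total size of the transient compartment (integral of its
    age density); ``ages``/``age_density`` optionally hold snapshots of that
    density (cells per day of age) at each grid point.
    """

    t: np.ndarray
    S: np.ndarray
    TR: np.ndarray
    R: np.ndarray
    mgmt: np.ndarray | None = None
    ages: np.ndarray | None = None
    age_density: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.S + self.TR + self.R

    def with_readout(self, p: ReadoutParams) -> "Trajectory":
        m = mgmt_readout(self.S, self.TR, self.R, p)
        m = np.atleast_1d(np.asarray(m, dtype=float))
        if p.normalize_to_baseline:
            m = m / m[0]
        out = replace(self)
        out.mgmt = m
        return out

    def at(self, days) -> "Trajectory":
        """Sub-sample the trajectory at the requested days (must lie on the
        grid to within 1e-9 d)."""
        days = np.asarray(days, dtype=float)
        idx = np.searchsorted(self.t, days)
        idx = np.clip(idx, 0, len(self.t) - 1)
        for j, d in zip(idx, days):
            lo = max(j - 1, 0)
            k = lo + int(np.argmin(np.abs(self.t[lo : j + 1] - d)))
            if abs(self.t[k] - d) > 1e-9:
                raise ValueError(f"day {d} not on the trajectory grid")
        idx = np.array([int(np.argmin(np.abs(self.t - d))) for d in days])
        return Trajectory(
            t=self.t[idx],
            S=self.S[idx],
            TR=self.TR[idx],
            R=self.R[idx],
            mgmt=None if self.mgmt is None else self.mgmt[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "day": self.t,
                "S": self.S,
                "TR": self.TR,
                "R": self.R,
                "total": self.total,
            }
        )
        df["mgmt"] = self.mgmt if self.mgmt is not None else np.nan
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class TimeCourseDataset:
    """Replicated noisy observations at discrete days.

    ``data`` holds one row per (replicate, day) with a strictly positive
    ``count`` and a positive or missing (NaN) ``mgmt_fold``.
    """

    data: pd.DataFrame
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = validate_frame(self.data)

    @property
    def days(self) -> np.ndarray:
        return np.unique(self.data["day"].to_numpy(dtype=float))

    @property
    def replicates(self) -> list[str]:
        return list(dict.fromkeys(self.data["replicate_id"]))

    @property
    def n_count_obs(self) -> int:
        return int(self.data["count"].notna().sum())

    @property
    def n_mgmt_obs(self) -> int:
        return int(self.data["mgmt_fold"].notna().sum())

    def equals(self, other: "TimeCourseDataset") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        return a.equals(b)


def validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the time-course schema; raises :class:`SchemaError` naming
    the offending rows."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[DATASET_COLUMNS].copy()
    df["replicate_id"] = df["replicate_id"].astype(str)
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(float)
    df["count"] = pd.to_numeric(df["count"], errors="raise").astype(float)
    df["mgmt_fold"] = pd.to_numeric(df["mgmt_fold"], errors="coerce").astype(float)

    bad = df.index[(df["day"] < 0) | ~np.isfinite(df["day"])].tolist()
    if bad:
        raise SchemaError(f"negative or non-finite day at rows {bad}")
    bad = df.index[~(df["count"] > 0)].tolist()
    if bad:
        raise SchemaError(f"counts must be strictly positive; offending rows {bad}")
    present = df["mgmt_fold"].notna()
    bad = df.index[present & ~(df["mgmt_fold"] > 0)].tolist()
    if bad:
        raise SchemaError(f"mgmt_fold must be positive where present; offending rows {bad}")
    for rep, grp in df.groupby("replicate_id", sort=False):
        d = grp["day"].to_numpy()
        if np.any(np.diff(d) <= 0):
            raise SchemaError(f"days must be strictly increasing within replicate {rep!r}")
    return df.reset_index(drop=True)


def write_dataset(dataset: TimeCourseDataset, path) -> None:
    """Write a dataset to CSV (full precision; blank cell = missing MGMT)."""
    path = Path(path)
    # default str() formatting is shortest-round-trip; paired with
    # float_precision="round_trip" on read this makes I/O bit-stable
    dataset.data.to_csv(path, index=False)
    sched_path = path.with_suffix(".schedule.yaml")
    if dataset.schedule.entries:
        dataset.schedule.to_yaml(sched_path)


def read_dataset(path, schedule: TreatmentSchedule | None = None) -> TimeCourseDataset:
    """Read a time-course CSV written by :func:`write_dataset`.

    A sibling ``<name>.schedule.yaml`` is picked up automatically unless a
    schedule is passed explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if schedule is None:
        sched_path = path.with_suffix(".schedule.yaml")
        schedule = (
            TreatmentSchedule.from_yaml(sched_path)
            if sched_path.exists()
            else TreatmentSchedule()
        )
    return TimeCourseDataset(data=df, schedule=schedule, provenance={"path": str(path)})
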
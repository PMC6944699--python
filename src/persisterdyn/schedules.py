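"""Pulsed drug schedules and time-varying exposure functions.

A :class:`TreatmentSchedule` records when each drug is given and how a dose
translates into a unitless exposure ``u(t)`` in ``[0, 1]`` that gates the
drug-effect terms of the population models.  Two conventions are supported:

``window``
    Exposure equals ``effect_level`` for ``window_days`` after each dose and
    0 otherwise.  With redosing every 3 days and a 3-day window — the default
    course — exposure is effectively continuous over the treatment period.
``decay``
    Each dose contributes ``effect_level * exp(-decay_rate * (t - dose))``;
    contributions from past doses add up but the total is capped at
    ``effect_level``.

Doses are timed in days; day 0 is the first dose of the course.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DoseEntry",
    "TreatmentSchedule",
    "drug_exposure",
    "exposure_profile",
    "standard_tmz_schedule",
]


@dataclass(frozen=True)
class DoseEntry:
    """Dosing history for a single drug.

    Parameters
    ----------
    drug_id:
        Name of the drug (e.g. ``"TMZ"``, ``"TSA"``).
    dose_times:
        Strictly increasing dose times in days, all >= 0.
    exposure_mode:
        ``"window"`` or ``"decay"`` (see module docstring).
    window_days:
        Duration of the exposure window after each dose (window mode).
    decay_rate:
        Per-day exponential decay of a dose's exposure (decay mode).
    effect_level:
        Unitless maximal exposure in ``[0, 1]``.
    dose_amount:
        Optional physical dose (e.g. µM); metadata only, never consumed by
        the models.
    """

    drug_id: str
    dose_times: tuple[float, ...]
    exposure_mode: str = "window"
    window_days: float = 3.0
    decay_rate: float = 0.0
    effect_level: float = 1.0
    dose_amount: float | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.dose_times)
        object.__setattr__(self, "dose_times", times)
        if any(t < 0 for t in times):
            raise ValueError(f"{self.drug_id}: dose times must be >= 0, got {times}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.drug_id}: dose times must be strictly increasing")
        if self.exposure_mode not in ("window", "decay"):
            raise ValueError(f"unknown exposure_mode {self.exposure_mode!r}")
        if not 0.0 <= self.effect_level <= 1.0:
            raise ValueError(f"effect_level must be in [0, 1], got {self.effect_level}")
        if self.exposure_mode == "window" and self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if self.exposure_mode == "decay" and self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")

    def exposure(self, t: float) -> float:
        """Instantaneous exposure of this entry at time ``t`` (days)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        if not self.dose_times:
            return 0.0
        if self.exposure_mode == "window":
            for d in self.dose_times:
                if d <= t < d + self.window_days:
                    return self.effect_level
            return 0.0
        total = 0.0
        for d in self.dose_times:
            if d <= t:
                total += np.exp(-self.decay_rate * (t - d))
        return min(self.effect_level * total, self.effect_level)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Pulsed multi-drug dosing history mapped to exposure functions."""

    entries: tuple[DoseEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def drugs(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.drug_id not in seen:
                seen.append(e.drug_id)
        return seen

    def exposure(self, drug_id: str, t: float) -> float:
        """Exposure of ``drug_id`` at ``t``; several entries for the same drug
        combine by maximum (a drug cannot act beyond its own full effect)."""
        vals = [e.exposure(t) for e in self.entries if e.drug_id == drug_id]
        return max(vals) if vals else 0.0

    # --- piecewise structure used by the solvers -------------------------

    def breakpoints(self, drug_id: str | None = None, t0: float = 0.0, t1: float = np.inf) -> np.ndarray:
        """Times in ``(t0, t1)`` where any exposure may be discontinuous."""
        pts: set[float] = set()
        for e in self.entries:
            if drug_id is not None and e.drug_id != drug_id:
                continue
            for d in e.dose_times:
                pts.add(d)
                if e.exposure_mode == "window":
                    pts.add(d + e.window_days)
        return np.array(sorted(p for p in pts if t0 < p < t1))

    def is_piecewise_constant(self, drug_id: str) -> bool:
        return all(e.exposure_mode == "window" for e in self.entries if e.drug_id == drug_id)

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for e in self.entries:
            d = {
                "drug": e.drug_id,
                "dose_times": list(e.dose_times),
                "mode": e.exposure_mode,
                "effect_level": e.effect_level,
            }
            if e.exposure_mode == "window":
                d["window_days"] = e.window_days
            else:
                d["decay_rate"] = e.decay_rate
            if e.dose_amount is not None:
                d["dose_amount"] = e.dose_amount
            out.append(d)
        return {"schedule": out}

    @classmethod
    def from_dict(cls, data: dict) -> "TreatmentSchedule":
        entries = []
        for d in data["schedule"]:
            entries.append(
                DoseEntry(
                    drug_id=d["drug"],
                    dose_times=tuple(d["dose_times"]),
                    exposure_mode=d.get("mode", "window"),
                    window_days=float(d.get("window_days", 3.0)),
                    decay_rate=float(d.get("decay_rate", 0.0)),
                    effect_level=float(d.get("effect_level", 1.0)),
                    dose_amount=d.get("dose_amount"),
                )
            )
        return cls(entries=tuple(entries))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TreatmentSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def drug_exposure(schedule: TreatmentSchedule, drug_id: str, t: float) -> float:
    """Unitless exposure of ``drug_id`` at time ``t`` (days).

    Absent drugs give 0; negative ``t`` is a domain error.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return schedule.exposure(drug_id, t)


def exposure_profile(
    schedule: TreatmentSchedule, drug_id: str, times: Sequence[float]
) -> np.ndarray:
    """Vectorized :func:`drug_exposure` over an array of times."""
    return np.array([drug_exposure(schedule, drug_id, float(t)) for t in times])


def standard_tmz_schedule(
    n_doses: int = 6,
    interval_days: float = 3.0,
    effect_level: float = 1.0,
    start_day: float = 0.0,
    dose_amount: float | None = 50.0,
) -> TreatmentSchedule:
    """The default course: TMZ redosed every 3 days with a 3-day exposure
    window, so exposure is continuous from the first to 3 d past the last
    dose.  Six doses cover a 16-day experiment (doses at days 0..15)."""
    times = tuple(start_day + interval_days * i for i in range(n_doses))
    entry = DoseEntry(
        drug_id="TMZ",
        dose_times=times,
        exposure_mode="window",
        window_days=interval_days,
        effect_level=effect_level,
        dose_amount=dose_amount,
    )
    return TreatmentSchedule(entries=(entry,))
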
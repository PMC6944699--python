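"""Multi-start weighted least-squares estimation and practical identifiability.

Either model is fitted to a :class:`~persisterdyn.timecourse.TimeCourseDataset`
by minimizing

    rss_total = w_count * rss_counts + w_mgmt * rss_mgmt

with count residuals on the log10 scale (the dip/regrowth spans orders of
magnitude) and MGMT residuals on the log2 fold-change scale (qPCR-native).
Replicates enter as independent residual rows.  Starts are drawn by Latin
hypercube over the (log-scaled where flagged) parameter bounds and polished
with a bounded trust-region least-squares routine; the sorted ensemble of
converged fits is the unit of identifiability analysis: the *feasible* subset
collects every fit whose loss is within ``(1 + feasibility_epsilon)`` of the
best, and the spread of a parameter across that subset is its feasible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .adaptive import AdaptiveParams, simulate_adaptive
from .clonal import ClonalParams, simulate_clonal
from .timecourse import ReadoutParams, TimeCourseDataset

__all__ = [
    "FreeParam",
    "FitSpec",
    "FitResult",
    "FitEnsemble",
    "residuals",
    "fit_model",
    "feasible_parameter_range",
]

_PENALTY = 1.0e3
_READOUT_KEYS = ("alpha", "c_tr")


@dataclass(frozen=True)
class FreeParam:
    """A fitted parameter with finite ordered bounds; ``log=True`` searches
    and starts on the log10 scale."""

    name: str
    lower: float
    upper: float
    log: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.log and self.lower <= 0:
            raise ValueError(f"{self.name}: log-scale bounds must be positive")


@dataclass(frozen=True)
class FitSpec:
    """Specification of one fitting run."""

    model_id: str
    free_params: tuple[FreeParam, ...]
    fixed_params: dict = field(default_factory=dict)
    w_count: float = 1.0
    w_mgmt: float = 1.0
    n_starts: int = 20
    seed: int = 0
    feasibility_epsilon: float = 0.05
    delta_a: float = 0.05  # adaptive-solver resolution used during fitting

    def __post_init__(self) -> None:
        if self.model_id not in ("clonal", "adaptive"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        object.__setattr__(self, "free_params", tuple(self.free_params))
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.feasibility_epsilon <= 0:
            raise ValueError("feasibility_epsilon must be > 0")
        if self.w_count < 0 or self.w_mgmt < 0:
            raise ValueError("weights must be >= 0")
        names = [f.name for f in self.free_params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free parameter names")


@dataclass
class FitResult:
    """A single converged start."""

    model_id: str
    params: dict
    rss_total: float
    rss_counts: float
    rss_mgmt: float
    converged: bool
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": dict(self.params),
            "rss_total": self.rss_total,
            "rss_counts": self.rss_counts,
            "rss_mgmt": self.rss_mgmt,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }


@dataclass
class FitEnsemble:
    """Multi-start results sorted by loss; feasibility per the epsilon rule."""

    results: list[FitResult]
    feasibility_epsilon: float = 0.05
    spec: FitSpec | None = None

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def feasible(self) -> list[FitResult]:
        cut = (1.0 + self.feasibility_epsilon) * self.best.rss_total
        return [r for r in self.results if r.rss_total <= cut]


def split_params(model_id: str, params: dict, readout: ReadoutParams):
    """Split a flat parameter dict into model params and readout params."""
    model_d = {k: v for k, v in params.items() if k not in _READOUT_KEYS}
    ro = replace(
        readout,
        alpha=float(params.get("alpha", readout.alpha)),
        c_tr=float(params.get("c_tr", readout.c_tr)),
    )
    if model_id == "clonal":
        return ClonalParams.from_dict(model_d), ro
    return AdaptiveParams.from_dict(model_d), ro


def _predict(model_id, params, readout, dataset, delta_a):
    mp, ro = split_params(model_id, params, readout)
    days = dataset.days
    t_grid = np.unique(np.concatenate(([0.0], days)))
    if model_id == "clonal":
        traj = simulate_clonal(mp, dataset.schedule, t_grid, readout=ro)
    else:
        traj = simulate_adaptive(mp, dataset.schedule, t_grid, delta_a=delta_a, readout=ro)
    total = dict(zip(traj.t, traj.total))
    mgmt = dict(zip(traj.t, traj.mgmt))
    return total, mgmt


def residuals(
    model_id: str,
    params: dict,
    dataset: TimeCourseDataset,
    readout: ReadoutParams,
    w_count: float = 1.0,
    w_mgmt: float = 1.0,
    delta_a: float = 0.05,
) -> np.ndarray:
    """Weighted residual vector: one entry per observed (replicate, day,
    channel).  Count residuals are ``log10(model/observed)`` scaled by
    ``sqrt(w_count)``; MGMT residuals are ``log2(model/observed)`` scaled by
    ``sqrt(w_mgmt)``.  A channel with zero weight contributes no rows; rows
    with missing MGMT contribute no MGMT residual.  Simulation failure at
    ``params`` yields a constant penalty vector (optimizer-safe)."""
    df = dataset.data
    counts = df["count"].to_numpy(dtype=float)
    mgmt_obs = df["mgmt_fold"].to_numpy(dtype=float)
    mgmt_mask = np.isfinite(mgmt_obs)
    n_res = (len(df) if w_count > 0 else 0) + (int(mgmt_mask.sum()) if w_mgmt > 0 else 0)
    try:
        total, mgmt = _predict(model_id, params, readout, dataset, delta_a)
        out = []
        if w_count > 0:
            sw = np.sqrt(w_count)
            for day, c in zip(df["day"], counts):
                m = total[day]
                if not np.isfinite(m) or m <= 0:
                    raise FloatingPointError("non-positive model count")
                out.append(sw * (np.log10(m) - np.log10(c)))
        if w_mgmt > 0:
            sw = np.sqrt(w_mgmt)
            for day, f in zip(df["day"][mgmt_mask], mgmt_obs[mgmt_mask]):
                m = mgmt[day]
                if not np.isfinite(m) or m <= 0:
                    raise FloatingPointError("non-positive model MGMT readout")
                out.append(sw * (np.log2(m) - np.log2(f)))
        return np.asarray(out, dtype=float)
    except (ValueError, RuntimeError, FloatingPointError, OverflowError):
        return np.full(n_res, _PENALTY)


def rss_decomposition(
    model_id, params, dataset, readout, w_count=1.0, w_mgmt=1.0, delta_a=0.05
) -> tuple[float, float, float]:
    """(rss_total, rss_counts, rss_mgmt); the total recombines the channel
    sums with the weights exactly."""
    rc = residuals(model_id, params, dataset, readout, 1.0, 0.0, delta_a)
    rm = residuals(model_id, params, dataset, readout, 0.0, 1.0, delta_a)
    rss_c = float(np.sum(rc**2))
    rss_m = float(np.sum(rm**2))
    return w_count * rss_c + w_mgmt * rss_m, rss_c, rss_m


def _to_internal(values: np.ndarray, free: tuple[FreeParam, ...]) -> np.ndarray:
    return np.array(
        [np.log10(v) if f.log else v for v, f in zip(values, free)], dtype=float
    )


def _from_internal(x: np.ndarray, free: tuple[FreeParam, ...]) -> np.ndarray:
    return np.array(
        [10.0**xi if f.log else xi for xi, f in zip(x, free)], dtype=float
    )


def fit_model(
    dataset: TimeCourseDataset,
    spec: FitSpec,
    readout: ReadoutParams | None = None,
    extra_starts: list[dict] | None = None,
) -> FitEnsemble:
    """Multi-start bounded least squares.  Deterministic under a fixed
    ``spec.seed``; returned parameter sets respect the bounds.

    ``extra_starts`` appends explicit start points (dicts of free-parameter
    values) after the Latin-hypercube pool.
    """
    if readout is None:
        readout = ReadoutParams()
    free = spec.free_params
    if not free:
        raise ValueError("spec must declare at least one free parameter")
    n_obs = (dataset.n_count_obs if spec.w_count > 0 else 0) + (
        dataset.n_mgmt_obs if spec.w_mgmt > 0 else 0
    )
    if n_obs < len(free):
        raise ValueError(
            f"dataset has {n_obs} observations for {len(free)} free parameters"
        )

    lo = _to_internal(np.array([f.lower for f in free]), free)
    hi = _to_internal(np.array([f.upper for f in free]), free)
    sampler = qmc.LatinHypercube(d=len(free), seed=spec.seed)
    starts = qmc.scale(sampler.random(n=spec.n_starts), lo, hi)
    if extra_starts:
        rows = [
            _to_internal(np.array([s[f.name] for f in free]), free)
            for s in extra_starts
        ]
        starts = np.vstack([starts, rows])

    def make_params(x: np.ndarray) -> dict:
        vals = _from_internal(x, free)
        params = dict(spec.fixed_params)
        for f, v in zip(free, vals):
            params[f.name] = float(v)
        return params

    def fun(x: np.ndarray) -> np.ndarray:
        return residuals(
            spec.model_id, make_params(x), dataset, readout,
            spec.w_count, spec.w_mgmt, spec.delta_a,
        )

    results: list[FitResult] = []
    failures: list[str] = []
    eps = 1e-12
    for x0 in starts:
        x0 = np.clip(x0, lo + eps, hi - eps)
        try:
            sol = least_squares(
                fun, x0, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=400 * len(free),
            )
        except Exception as exc:  # noqa: BLE001 - report all failed starts
            failures.append(f"start {x0}: {exc}")
            continue
        params = make_params(sol.x)
        rss_t, rss_c, rss_m = rss_decomposition(
            spec.model_id, params, dataset, readout,
            spec.w_count, spec.w_mgmt, spec.delta_a,
        )
        results.append(
            FitResult(
                model_id=spec.model_id,
                params=params,
                rss_total=rss_t,
                rss_counts=rss_c,
                rss_mgmt=rss_m,
                converged=bool(sol.success),
                n_evaluations=int(sol.nfev),
            )
        )
    if not results:
        raise RuntimeError("all starts failed:\n" + "\n".join(failures))
    results.sort(key=lambda r: r.rss_total)
    return FitEnsemble(
        results=results, feasibility_epsilon=spec.feasibility_epsilon, spec=spec
    )


def feasible_parameter_range(ensemble: FitEnsemble, param_name: str) -> tuple[float, float]:
    """Min/max of a parameter over the feasible subset of the ensemble."""
    if not ensemble.results:
        raise ValueError("empty ensemble")
    if param_name not in ensemble.best.params:
        raise KeyError(f"unknown parameter {param_name!r}")
    vals = [r.params[param_name] for r in ensemble.feasible]
    return float(min(vals)), float(max(vals))
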
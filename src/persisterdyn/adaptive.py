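"""Acquired-resistance model: an age-structured drug-tolerant transient state.

Sensitive cells ``S`` exposed to drug enter a transient, non-proliferating,
death-protected state ``TR`` at rate ``beta * u(t)``; a TR cell of age ``a``
(time since entry) matures and converts irreversibly to the resistant state
``R`` at rate ``gamma(a) = gamma_max * [a >= tau]``.  The resistant population
starts at exactly zero.  The dynamics are

    dS/dt           = rho_S * S - (delta_S + beta) * u(t) * S
    dn/dt + dn/da   = (rho_TR - mu_TR - gamma(a)) * n(t, a)
    n(t, 0)         = beta * u(t) * S(t)
    dR/dt           = rho_R * R - delta_R * u(t) * R + ∫ gamma(a) n(t, a) da

where ``n(t, a)`` is the TR age density (cells per day of age).  By default
TR cells neither divide nor die (``rho_TR = mu_TR = 0``).

The transport equation is solved along characteristics with the time step
equal to the age step (``dt = delta_a``), which advects the age density
exactly; within a step the linear reaction terms are integrated with exact
exponential factors, so pure transfer (all proliferation and death rates
zero) conserves cells to machine precision.

Two independent oracles for the deterministic solver live here as well: a
seeded agent-based stochastic simulator with exact age bookkeeping, and an
Erlang-chain ("linear chain trick") ODE approximation of the maturation
delay.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, asdict, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .schedules import TreatmentSchedule, drug_exposure
from .timecourse import ReadoutParams, Trajectory

__all__ = [
    "AdaptiveParams",
    "AgeDensity",
    "simulate_adaptive",
    "simulate_adaptive_stochastic",
    "erlang_chain_approx",
    "tsa_intervention",
]


@dataclass(frozen=True)
class AdaptiveParams:
    """Kinetic parameters of the adaptive model (rates per day, ages in days).

    ``a_max`` truncates the age domain; the last age bin is absorbing (cells
    past ``a_max`` keep converting at ``gamma_max``).  ``maturation`` selects
    the shape of ``gamma(a)``: a sharp step at ``tau`` (default) or a smooth
    Hill curve with half-maximum at ``tau``.  ``entry_drug_gated=False``
    makes TR entry drug-independent (rate ``beta * S``).
    """

    rho_S: float = 0.4
    delta_S: float = 0.9
    rho_R: float = 0.35
    delta_R: float = 0.05
    beta: float = 0.25
    mu_TR: float = 0.0
    rho_TR: float = 0.0
    tau: float = 6.0
    gamma_max: float = 0.3
    N0: float = 1e5
    a_max: float | None = None
    maturation: str = "step"
    hill_exponent: float = 8.0
    entry_drug_gated: bool = True

    def __post_init__(self) -> None:
        for name in (
            "rho_S", "delta_S", "rho_R", "delta_R", "beta",
            "mu_TR", "rho_TR", "gamma_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.N0 <= 0:
            raise ValueError("N0 must be > 0")
        if self.a_max is not None and self.a_max <= self.tau:
            raise ValueError(f"a_max ({self.a_max}) must exceed tau ({self.tau})")
        if self.maturation not in ("step", "hill"):
            raise ValueError(f"unknown maturation shape {self.maturation!r}")

    def resolved_a_max(self) -> float:
        # absorbing last bin makes a moderate truncation safe
        return self.a_max if self.a_max is not None else self.tau + 10.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AdaptiveParams":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class AgeDensity:
    """TR age density snapshot: cells per day of age on a uniform grid."""

    age_grid: np.ndarray
    density: np.ndarray

    @property
    def total(self) -> float:
        da = self.age_grid[1] - self.age_grid[0] if len(self.age_grid) > 1 else 1.0
        return float(np.sum(self.density) * da)


def _gamma_profile(p: AdaptiveParams, delta_a: float, nb: int) -> np.ndarray:
    centers = (np.arange(nb) + 0.5) * delta_a
    if p.maturation == "step":
        return np.where(centers >= p.tau, p.gamma_max, 0.0)
    if p.tau == 0:
        return np.full(nb, p.gamma_max)
    h = p.hill_exponent
    return p.gamma_max * centers**h / (centers**h + p.tau**h)


@njit(cache=True)
def _adaptive_step_loop(
    n_steps, dt, S0, u, u_entry, u_tsa, gamma, rho_S, delta_S, beta,
    rho_TR, mu_TR, kappa_tsa, rho_R, delta_R, n_bins, rec_steps, rec_density,
):  # pragma: no cover - exercised through simulate_adaptive
    S = S0
    R = 0.0
    n = np.zeros(n_bins)
    S_t = np.empty(n_steps + 1)
    TR_t = np.empty(n_steps + 1)
    R_t = np.empty(n_steps + 1)
    S_t[0] = S
    TR_t[0] = 0.0
    R_t[0] = 0.0
    n_rec = 0
    for i in range(n_steps):
        ui = u[i]
        ue = u_entry[i]
        ut = u_tsa[i]
        # sensitive compartment: exact exponential over the step
        r_S = rho_S - (delta_S * ui + beta * ue)
        x = r_S * dt
        grow_S = np.exp(x)
        if abs(x) > 1e-12:
            phi_S = (grow_S - 1.0) / r_S
        else:
            phi_S = dt * (1.0 + 0.5 * x)
        inflow = beta * ue * S * phi_S
        S = S * grow_S
        # TR age bins: reaction with exact exponentials, then transport shift
        conv = 0.0
        mu_eff = mu_TR + kappa_tsa * ut
        for j in range(n_bins):
            r_b = rho_TR - mu_eff - gamma[j]
            xb = r_b * dt
            decay = np.exp(xb)
            if abs(xb) > 1e-12:
                phi_b = (decay - 1.0) / r_b
            else:
                phi_b = dt * (1.0 + 0.5 * xb)
            conv += gamma[j] * n[j] * phi_b
            n[j] = n[j] * decay
        # shift by one bin (dt == delta_a); last bin is absorbing
        last = n[n_bins - 1]
        for j in range(n_bins - 1, 0, -1):
            n[j] = n[j - 1]
        n[n_bins - 1] += last
        n[0] = inflow
        # resistant compartment; converts get a half-step of growth
        r_R = rho_R - delta_R * ui
        R = R * np.exp(r_R * dt) + conv * np.exp(0.5 * r_R * dt)
        S_t[i + 1] = S
        TR_t[i + 1] = np.sum(n)
        R_t[i + 1] = R
        if n_rec < len(rec_steps) and rec_steps[n_rec] == i + 1:
            for j in range(n_bins):
                rec_density[n_rec, j] = n[j] / dt
            n_rec += 1
    return S_t, TR_t, R_t


def _step_exposures(schedule, drug_id, n_steps, dt):
    mids = (np.arange(n_steps) + 0.5) * dt
    return np.array([drug_exposure(schedule, drug_id, m) for m in mids])


def simulate_adaptive(
    p: AdaptiveParams,
    schedule: TreatmentSchedule,
    t_grid,
    delta_a: float = 0.05,
    readout: ReadoutParams | None = None,
    drug_id: str = "TMZ",
    kappa_tsa: float = 0.0,
    tsa_drug_id: str = "TSA",
    store_age_density: bool = False,
) -> Trajectory:
    """Solve the age-structured model along characteristics (dt = delta_a).

    ``t_grid`` points must be integer multiples of ``delta_a``; the solver
    always starts from day 0 with a pure-sensitive population.  ``kappa_tsa``
    adds a TR-specific death rate gated by the exposure of ``tsa_drug_id``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be strictly increasing and non-negative")
    if kappa_tsa < 0:
        raise ValueError("kappa_tsa must be >= 0")
    dt = float(delta_a)
    steps_f = t_grid / dt
    steps = np.rint(steps_f).astype(int)
    if np.any(np.abs(steps_f - steps) > 1e-6):
        raise ValueError("every t_grid point must be a multiple of delta_a")
    n_steps = int(steps[-1])
    a_max = p.resolved_a_max()
    n_bins = max(int(np.ceil(a_max / dt)), 2)
    gamma = _gamma_profile(p, dt, n_bins)
    u = _step_exposures(schedule, drug_id, n_steps, dt)
    u_entry = u if p.entry_drug_gated else np.ones(n_steps)
    if kappa_tsa > 0:
        u_tsa = _step_exposures(schedule, tsa_drug_id, n_steps, dt)
    else:
        u_tsa = np.zeros(n_steps)
    rec_steps = steps[steps > 0] if store_age_density else np.empty(0, dtype=int)
    rec_density = np.zeros((len(rec_steps), n_bins))
    S_t, TR_t, R_t = _adaptive_step_loop(
        n_steps, dt, p.N0, u, u_entry, u_tsa, gamma,
        p.rho_S, p.delta_S, p.beta, p.rho_TR, p.mu_TR, kappa_tsa,
        p.rho_R, p.delta_R, n_bins, rec_steps, rec_density,
    )
    traj = Trajectory(
        t=t_grid,
        S=S_t[steps],
        TR=TR_t[steps],
        R=R_t[steps],
    )
    if store_age_density:
        ages = (np.arange(n_bins) + 0.5) * dt
        # day-0 snapshot is identically zero (no TR cells initially)
        dens = np.zeros((len(t_grid), n_bins))
        dens[steps > 0] = rec_density
        traj.ages = ages
        traj.age_density = dens
    if readout is not None:
        traj = traj.with_readout(readout)
    return traj


def tsa_intervention(
    p: AdaptiveParams,
    schedule: TreatmentSchedule,
    kappa_tsa: float,
    t_grid,
    delta_a: float = 0.05,
    readout: ReadoutParams | None = None,
    drug_id: str = "TMZ",
    tsa_drug_id: str = "TSA",
) -> Trajectory:
    """Adaptive-model run with a TR-specific kill rate ``kappa_tsa`` (per day
    at full exposure) gated by the TSA entries of the schedule.  With
    ``kappa_tsa = 0`` this is exactly :func:`simulate_adaptive`."""
    if kappa_tsa < 0:
        raise ValueError("kappa_tsa must be >= 0")
    return simulate_adaptive(
        p, schedule, t_grid, delta_a=delta_a, readout=readout,
        drug_id=drug_id, kappa_tsa=kappa_tsa, tsa_drug_id=tsa_drug_id,
    )


# ---------------------------------------------------------------------------
# Oracle 1: Erlang-chain (linear chain trick) approximation of the age delay
# ---------------------------------------------------------------------------

def erlang_chain_approx(
    p: AdaptiveParams,
    schedule: TreatmentSchedule,
    t_grid,
    n_stages: int,
    readout: ReadoutParams | None = None,
    drug_id: str = "TMZ",
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Replace the fixed maturation age ``tau`` by ``n_stages`` sequential
    sub-compartments with per-stage transit rate ``n_stages / tau`` feeding a
    mature pool that converts at ``gamma_max``.

    Total transit time through the chain is Erlang(n_stages, n_stages/tau)
    distributed — mean ``tau`` for every ``n_stages`` — and concentrates on
    the fixed delay as ``n_stages`` grows, so this converges to
    :func:`simulate_adaptive` (step maturation).  Used as an independent
    test oracle, not for fitting.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    t_grid = np.asarray(t_grid, dtype=float)
    k = int(n_stages)
    lam = k / p.tau if p.tau > 0 else None  # None: no delay, straight to mature
    n_chain = k if lam is not None else 0

    def rhs(t, y):
        u = drug_exposure(schedule, drug_id, t)
        ue = u if p.entry_drug_gated else 1.0
        S = y[0]
        R = y[-1]
        dy = np.empty_like(y)
        dy[0] = p.rho_S * S - (p.delta_S * u + p.beta * ue) * S
        inflow = p.beta * ue * S
        g_tr = p.rho_TR - p.mu_TR
        if n_chain:
            dy[1] = inflow - lam * y[1] + g_tr * y[1]
            for j in range(2, n_chain + 1):
                dy[j] = lam * (y[j - 1] - y[j]) + g_tr * y[j]
            mature_in = lam * y[n_chain]
        else:
            mature_in = inflow
        M = y[n_chain + 1]
        dy[n_chain + 1] = mature_in - p.gamma_max * M + g_tr * M
        dy[-1] = p.rho_R * R - p.delta_R * u * R + p.gamma_max * M
        return dy

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    edges = np.concatenate(([0.0], schedule.breakpoints(drug_id, 0.0, t1), [t1]))
    y = np.zeros(n_chain + 3)
    y[0] = p.N0
    out = np.zeros((len(t_grid), n_chain + 3))
    if t_grid[0] == 0.0:
        out[0] = y
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate((t_grid[mask], [b])))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"erlang chain solver failed: {sol.message}")
        if mask.any():
            keep = np.isin(sol.t, t_grid[mask])
            out[mask] = sol.y[:, keep].T
        y = sol.y[:, -1]
    S = out[:, 0]
    TR = out[:, 1 : n_chain + 2].sum(axis=1)
    R = out[:, -1]
    traj = Trajectory(t=t_grid, S=S, TR=TR, R=R)
    if readout is not None:
        traj = traj.with_readout(readout)
    return traj


# ---------------------------------------------------------------------------
# Oracle 2: agent-based stochastic simulation with exact age bookkeeping
# ---------------------------------------------------------------------------

def simulate_adaptive_stochastic(
    p: AdaptiveParams,
    schedule: TreatmentSchedule,
    horizon: float,
    n0: int,
    seed: int,
    t_eval=None,
    drug_id: str = "TMZ",
) -> Trajectory:
    """Exact stochastic realization of the adaptive model.

    S and R are birth/death/entry counting processes with exponential clocks
    (piecewise-constant rates between exposure discontinuities); each TR
    agent carries its exact entry time, dies at hazard ``mu_TR`` and converts
    at hazard ``gamma_max`` once older than ``tau``, so maturation clocks are
    ``entry + tau + Exp(gamma_max)`` in competition with ``entry +
    Exp(mu_TR)``.  Reproducible under a fixed seed; the ensemble mean over
    realizations equals the deterministic mean-field solution.
    """
    if n0 > 10_000:
        raise ValueError("stochastic oracle is for desk scale (n0 <= 1e4)")
    if p.rho_TR > 0:
        raise ValueError("stochastic simulator supports non-proliferating TR only (rho_TR = 0)")
    if p.maturation != "step":
        raise ValueError("stochastic simulator implements step maturation only")
    rng = np.random.default_rng(seed)
    if t_eval is None:
        t_eval = np.arange(0.0, horizon + 1e-9, 1.0)
    t_eval = np.asarray(t_eval, dtype=float)

    S = int(n0)
    TR = 0
    R = 0
    CONVERT, TR_DEATH = 0, 1
    heap: list[tuple[float, int]] = []

    edges = np.concatenate(([0.0], schedule.breakpoints(drug_id, 0.0, horizon), [horizon]))
    edges = np.unique(edges)

    out = np.zeros((len(t_eval), 3))
    eval_i = 0

    def record_upto(t_new):
        nonlocal eval_i
        while eval_i < len(t_eval) and t_eval[eval_i] <= t_new + 1e-12:
            out[eval_i] = (S, TR, R)
            eval_i += 1

    record_upto(0.0)
    t = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        u = drug_exposure(schedule, drug_id, 0.5 * (a + b))
        ue = u if p.entry_drug_gated else 1.0
        while t < b:
            rate_S = S * (p.rho_S + p.delta_S * u + p.beta * ue)
            rate_R = R * (p.rho_R + p.delta_R * u)
            total = rate_S + rate_R
            t_cand = t + rng.exponential(1.0 / total) if total > 0 else np.inf
            t_heap = heap[0][0] if heap else np.inf
            t_next = min(t_cand, t_heap)
            if t_next >= b:
                record_upto(min(b, horizon))
                t = b
                break
            record_upto(t_next - 1e-15)
            t = t_next
            if t_heap <= t_cand:
                _, kind = heapq.heappop(heap)
                TR -= 1
                if kind == CONVERT:
                    R += 1
            else:
                x = rng.uniform(0.0, total)
                if x < rate_S:
                    y = x / S
                    if y < p.rho_S:
                        S += 1
                    elif y < p.rho_S + p.delta_S * u:
                        S -= 1
                    else:
                        S -= 1
                        TR += 1
                        t_conv = (
                            t + p.tau + rng.exponential(1.0 / p.gamma_max)
                            if p.gamma_max > 0
                            else np.inf
                        )
                        t_die = (
                            t + rng.exponential(1.0 / p.mu_TR) if p.mu_TR > 0 else np.inf
                        )
                        if t_conv <= t_die and np.isfinite(t_conv):
                            heapq.heappush(heap, (t_conv, CONVERT))
                        elif np.isfinite(t_die):
                            heapq.heappush(heap, (t_die, TR_DEATH))
                else:
                    if (x - rate_S) / max(R, 1) < p.rho_R:
                        R += 1
                    else:
                        R -= 1
    record_upto(horizon)
    return Trajectory(t=t_eval, S=out[:, 0], TR=out[:, 1], R=out[:, 2])
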
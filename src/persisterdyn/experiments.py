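"""Reproducible in-silico experiments built on the synthetic scenarios.

These drivers package the study-level analyses: solver cross-validation
against the stochastic and Erlang-chain oracles, parameter-recovery
benchmarks, the counts-only vs. counts+MGMT identifiability contrast for the
initial resistant fraction, the clonal-vs-adaptive discrimination power
experiment, and the TR-targeted (TSA) intervention runs.  Each takes a base
seed and derives all randomness from it, so results are exactly
reproducible.  Problem sizes (number of datasets, multi-start pool sizes,
solver resolutions) are fixed here as the package's benchmark conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .adaptive import (
    erlang_chain_approx,
    simulate_adaptive,
    simulate_adaptive_stochastic,
)
from .discrimination import compare_models
from .fitting import FitSpec, FreeParam, feasible_parameter_range, fit_model
from .schedules import DoseEntry, TreatmentSchedule
from .synthetic import (
    DEFAULT_ADAPTIVE_PARAMS,
    DEFAULT_READOUT,
    NoiseModel,
    OBS_DAYS,
    generate_dataset,
    paperlike_scenarios,
)

__all__ = [
    "stochastic_agreement",
    "erlang_convergence",
    "grid_convergence_order",
    "recovery_experiment",
    "identifiability_experiment",
    "discrimination_experiment",
    "intervention_experiment",
    "clonal_free_params",
    "adaptive_free_params",
]

_OBS = np.array(OBS_DAYS)


# ---------------------------------------------------------------------------
# Solver cross-validation
# ---------------------------------------------------------------------------

def stochastic_agreement(
    n_runs: int = 500, n0: int = 2000, seed: int = 0, delta_a: float = 0.01
) -> dict:
    """Mean of seeded stochastic realizations vs. the deterministic solver.

    Returns the per-day z-scores of the deterministic total against the
    Monte-Carlo mean (z = (mean - det) / SE); |z| <= 3 is the agreement
    contract.  Day 0 is deterministic by construction (z = 0).
    """
    sched = paperlike_scenarios()["full_course"].schedule
    p = replace(DEFAULT_ADAPTIVE_PARAMS, N0=float(n0))
    det = simulate_adaptive(p, sched, _OBS, delta_a=delta_a)
    totals = np.empty((n_runs, len(_OBS)))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_runs) % (2**31)
    for i in range(n_runs):
        traj = simulate_adaptive_stochastic(
            p, sched, horizon=float(_OBS[-1]), n0=n0, seed=int(child_seeds[i]), t_eval=_OBS
        )
        totals[i] = traj.total
    mean = totals.mean(axis=0)
    se = totals.std(axis=0, ddof=1) / np.sqrt(n_runs)
    z = np.zeros(len(_OBS))
    nz = se > 0
    z[nz] = (mean[nz] - det.total[nz]) / se[nz]
    return {
        "days": _OBS.tolist(),
        "mc_mean": mean.tolist(),
        "mc_se": se.tolist(),
        "deterministic": det.total.tolist(),
        "z": z.tolist(),
        "max_abs_z": float(np.max(np.abs(z))),
        "n_runs": n_runs,
        "n0": n0,
    }


def erlang_convergence(
    n_stages_list=(4, 16, 64), delta_a: float = 0.01
) -> dict:
    """Discrepancy of the Erlang-chain approximation to the age-structured
    solver as the stage count grows (monotone decrease expected)."""
    sched = paperlike_scenarios()["full_course"].schedule
    p = DEFAULT_ADAPTIVE_PARAMS
    t = _OBS
    ref = simulate_adaptive(p, sched, t, delta_a=delta_a)
    discs = []
    for k in n_stages_list:
        e = erlang_chain_approx(p, sched, t, n_stages=int(k))
        discs.append(float(np.max(np.abs(e.total - ref.total) / ref.total)))
    return {
        "n_stages": list(n_stages_list),
        "discrepancy": discs,
        "monotone": bool(all(b < a for a, b in zip(discs, discs[1:]))),
    }


def grid_convergence_order(steps=(0.2, 0.1, 0.05), ref_step: float = 0.0125) -> dict:
    """Empirical convergence order of the characteristics scheme under age/
    time step refinement, measured on the total population at the
    observation days against a fine-grid reference."""
    sched = paperlike_scenarios()["full_course"].schedule
    p = DEFAULT_ADAPTIVE_PARAMS
    ref = simulate_adaptive(p, sched, _OBS, delta_a=ref_step)
    errs = []
    for h in steps:
        sol = simulate_adaptive(p, sched, _OBS, delta_a=h)
        errs.append(float(np.max(np.abs(sol.total - ref.total) / ref.total)))
    orders = [
        float(np.log(errs[i] / errs[i + 1]) / np.log(steps[i] / steps[i + 1]))
        for i in range(len(errs) - 1)
    ]
    return {"steps": list(steps), "errors": errs, "orders": orders,
            "min_order": float(min(orders))}


# ---------------------------------------------------------------------------
# Fitting experiment designs
# ---------------------------------------------------------------------------

def clonal_free_params(with_mgmt: bool, for_recovery: bool = False) -> tuple[FreeParam, ...]:
    """Free-parameter set and bounds for clonal-model fits.

    The recovery benchmark frees {rho_S, rho_R, delta_S, f_R0, alpha}; the
    identifiability/discrimination design additionally frees delta_R (and
    drops alpha when the MGMT channel is excluded).
    """
    free = [
        FreeParam("rho_S", 0.05, 1.5, log=True),
        FreeParam("rho_R", 0.05, 1.5, log=True),
        FreeParam("delta_S", 0.1, 3.0, log=True),
        FreeParam("f_R0", 1e-4, 0.3, log=True),
    ]
    if not for_recovery:
        free.append(FreeParam("delta_R", 0.005, 0.3, log=True))
    if with_mgmt:
        free.append(FreeParam("alpha", 2.0, 100.0, log=True))
    return tuple(free)


def adaptive_free_params(with_mgmt: bool) -> tuple[FreeParam, ...]:
    """Free-parameter set and bounds for adaptive-model fits: entry rate and
    maturation age (the framework's defining parameters) plus the sensitive
    kinetics, and alpha when the MGMT channel is present."""
    free = [
        FreeParam("rho_S", 0.05, 1.5, log=True),
        FreeParam("delta_S", 0.1, 3.0, log=True),
        FreeParam("beta", 0.02, 1.5, log=True),
        FreeParam("tau", 1.0, 12.0, log=False),
        FreeParam("rho_R", 0.05, 1.5, log=True),
    ]
    if with_mgmt:
        free.append(FreeParam("alpha", 2.0, 100.0, log=True))
    return tuple(free)


def _fixed_from(params, readout) -> dict:
    d = params.to_dict()
    d.pop("a_max", None)
    d.pop("maturation", None)
    d.pop("hill_exponent", None)
    d.pop("entry_drug_gated", None)
    d.pop("K", None)
    d["alpha"] = readout.alpha
    d["c_tr"] = readout.c_tr
    return d


def recovery_experiment(model_id: str, n_datasets: int = 20, seed: int = 0) -> dict:
    """Parameter-recovery benchmark on seeded synthetic datasets.

    Clonal arm: recovers {rho_S, rho_R, delta_S, f_R0, alpha} (50 starts).
    Adaptive arm: recovers {rho_S, delta_S, beta, tau, rho_R, alpha}
    (12 starts).  Reports per-parameter relative errors and their medians.
    """
    scen = paperlike_scenarios()[
        "full_course_clonal" if model_id == "clonal" else "full_course"
    ]
    noise = NoiseModel()
    truth_params = _fixed_from(scen.params, scen.readout)
    if model_id == "clonal":
        free = clonal_free_params(with_mgmt=True, for_recovery=True)
        n_starts = 50
        targets = ("alpha", "f_R0")
    else:
        free = adaptive_free_params(with_mgmt=True)
        n_starts = 12
        targets = ("beta", "tau")
    rel_errors: dict[str, list[float]] = {f.name: [] for f in free}
    for i in range(n_datasets):
        ds, _ = generate_dataset(scen, noise, seed=seed + i)
        spec = FitSpec(
            model_id=model_id,
            free_params=free,
            fixed_params=truth_params,
            n_starts=n_starts,
            seed=seed + 1000 + i,
        )
        ens = fit_model(ds, spec, readout=scen.readout)
        for f in free:
            true_v = truth_params[f.name]
            rel_errors[f.name].append(abs(ens.best.params[f.name] - true_v) / abs(true_v))
    medians = {k: float(np.median(v)) for k, v in rel_errors.items()}
    return {
        "model_id": model_id,
        "n_datasets": n_datasets,
        "targets": list(targets),
        "median_rel_error": medians,
        "rel_errors": {k: list(map(float, v)) for k, v in rel_errors.items()},
    }


def identifiability_experiment(seed: int = 0, n_starts: int = 50) -> dict:
    """The initial-resistant-fraction identifiability contrast.

    One paper-like clonal dataset; counts-only fitting vs. counts+MGMT
    fitting with the same generator, 50 starts each; reports the feasible
    f_R0 range (5 % loss tolerance) and its max/min factor for both arms.
    """
    scen = paperlike_scenarios()["full_course_clonal"]
    ds, truth = generate_dataset(scen, NoiseModel(), seed=seed)
    fixed = _fixed_from(scen.params, scen.readout)
    out = {"true_f_R0": truth["params"]["f_R0"]}
    for label, with_mgmt in (("counts_only", False), ("counts_mgmt", True)):
        spec = FitSpec(
            model_id="clonal",
            free_params=clonal_free_params(with_mgmt=with_mgmt),
            fixed_params=fixed,
            w_mgmt=1.0 if with_mgmt else 0.0,
            n_starts=n_starts,
            seed=seed + 2000,
        )
        ens = fit_model(ds, spec, readout=scen.readout)
        lo, hi = feasible_parameter_range(ens, "f_R0")
        out[label] = {
            "f_R0_min": lo,
            "f_R0_max": hi,
            "range_factor": hi / lo,
            "n_feasible": len(ens.feasible),
            "best_rss": ens.best.rss_total,
        }
    return out


def discrimination_experiment(
    generator: str = "adaptive",
    channels: str = "both",
    n_datasets: int = 20,
    seed: int = 0,
    n_starts: int = 12,
) -> dict:
    """Discrimination power: fit both models to datasets generated from one
    of them and tally the AICc verdicts; with MGMT present also the
    late-window [12, 16] d MGMT misfit ratio (clonal / adaptive)."""
    scen = paperlike_scenarios()[
        "full_course" if generator == "adaptive" else "full_course_clonal"
    ]
    with_mgmt = channels == "both"
    noise = NoiseModel()
    fixed_c = _fixed_from(paperlike_scenarios()["full_course_clonal"].params, DEFAULT_READOUT)
    fixed_a = _fixed_from(DEFAULT_ADAPTIVE_PARAMS, DEFAULT_READOUT)
    verdicts = []
    misfit_ratios = []
    deltas = []
    for i in range(n_datasets):
        ds, _ = generate_dataset(scen, noise, seed=seed + 100 + i)
        w_m = 1.0 if with_mgmt else 0.0
        spec_c = FitSpec(
            "clonal", clonal_free_params(with_mgmt), fixed_c,
            w_mgmt=w_m, n_starts=n_starts, seed=seed + 3000 + i,
        )
        spec_a = FitSpec(
            "adaptive", adaptive_free_params(with_mgmt), fixed_a,
            w_mgmt=w_m, n_starts=n_starts, seed=seed + 4000 + i,
        )
        rep = compare_models(ds, spec_c, spec_a, readout=DEFAULT_READOUT)
        verdicts.append(rep.verdict)
        deltas.append(rep.delta_aicc)
        if with_mgmt:
            c_late = rep.clonal.rss_mgmt_late
            a_late = max(rep.adaptive.rss_mgmt_late, 1e-12)
            misfit_ratios.append(c_late / a_late)
    n = len(verdicts)
    out = {
        "generator": generator,
        "channels": channels,
        "n_datasets": n,
        "verdicts": verdicts,
        "delta_aicc": list(map(float, deltas)),
        "frac_adaptive": verdicts.count("adaptive") / n,
        "frac_clonal": verdicts.count("clonal") / n,
        "frac_indeterminate": verdicts.count("indeterminate") / n,
    }
    if with_mgmt:
        out["median_late_misfit_ratio"] = float(np.median(misfit_ratios))
        out["late_misfit_ratios"] = list(map(float, misfit_ratios))
    return out


def intervention_experiment(
    kappa_tsa: float = 30.0, horizon: float = 30.0, delta_a: float = 0.05
) -> dict:
    """TR-targeted kill (TSA analogue) under sustained TMZ.

    Three arms out to day 30: TMZ alone, TMZ + TR-kill from day 3, and
    TMZ + TR-kill only from day 16 (after most conversion has happened).
    """
    scens = paperlike_scenarios()
    p = DEFAULT_ADAPTIVE_PARAMS
    t = np.array(sorted(set(OBS_DAYS + (21.0, 25.0, horizon))))
    tmz = scens["tmz_only_d30"].schedule
    combo_early = scens["tmz_tsa_combo"].schedule
    tsa_late = DoseEntry(
        drug_id="TSA",
        dose_times=tuple(16.0 + 3.0 * i for i in range(5)),
        exposure_mode="window", window_days=3.0, effect_level=1.0,
    )
    combo_late = TreatmentSchedule(entries=tmz.entries + (tsa_late,))

    control = simulate_adaptive(p, tmz, t, delta_a=delta_a)
    early = simulate_adaptive(p, combo_early, t, delta_a=delta_a, kappa_tsa=kappa_tsa)
    late = simulate_adaptive(p, combo_late, t, delta_a=delta_a, kappa_tsa=kappa_tsa)
    return {
        "kappa_tsa": kappa_tsa,
        "horizon": horizon,
        "control_final_total": float(control.total[-1]),
        "control_final_R": float(control.R[-1]),
        "early_tsa_final_R": float(early.R[-1]),
        "early_tsa_final_total": float(early.total[-1]),
        "late_tsa_final_R": float(late.R[-1]),
        "control_regrows_above_N0": bool(control.total[-1] > p.N0),
        "late_over_control_R": float(late.R[-1] / control.R[-1]),
    }
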
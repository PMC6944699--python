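import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from persisterdyn import (
    AdaptiveParams,
    ClonalParams,
    DEFAULT_ADAPTIVE_PARAMS,
    ReadoutParams,
    TreatmentSchedule,
    erlang_chain_approx,
    simulate_adaptive,
    simulate_adaptive_stochastic,
    simulate_clonal,
    tsa_intervention,
)
from persisterdyn.schedules import DoseEntry

DAYS = np.array([0.0, 4.0, 9.0, 12.0, 16.0])


def test_beta_zero_reduces_to_single_population(tmz_schedule):
    p = replace(DEFAULT_ADAPTIVE_PARAMS, beta=0.0)
    adaptive = simulate_adaptive(p, tmz_schedule, DAYS)
    clonal = simulate_clonal(
        ClonalParams(rho_S=p.rho_S, rho_R=p.rho_R, delta_S=p.delta_S,
                     delta_R=p.delta_R, f_R0=0.0, N0=p.N0),
        tmz_schedule, DAYS,
    )
    assert np.allclose(adaptive.S, clonal.S, rtol=1e-8)
    assert np.all(adaptive.TR == 0) and np.all(adaptive.R == 0)


def test_tr_inflow_matches_quadrature_of_sensitive_trajectory(tmz_schedule):
    """With no conversion or TR death, TR_total(t) = ∫ beta u S ds."""
    p = replace(DEFAULT_ADAPTIVE_PARAMS, gamma_max=0.0, mu_TR=0.0, rho_TR=0.0)
    dt = 0.01
    grid = np.round(np.arange(0.0, 16.0 + dt / 2, dt), 9)
    traj = simulate_adaptive(p, tmz_schedule, grid, delta_a=dt)
    u = np.where(grid < 18.0, 1.0, 0.0)  # standard course: exposure 1 on [0,18)
    integrand = p.beta * u * traj.S
    expected = np.concatenate(([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * dt)))
    for d in (4.0, 9.0, 16.0):
        i = int(round(d / dt))
        assert traj.TR[i] == pytest.approx(expected[i], rel=1e-4)


def test_instantaneous_maturation_limit_matches_two_box_ode(tmz_schedule):
    """tau=0 with a very fast conversion clock collapses TR to an instantaneous
    relay: S -> R directly, solved here by an independent ODE oracle."""
    p = replace(DEFAULT_ADAPTIVE_PARAMS, tau=0.0, gamma_max=1e3, a_max=2.0)

    def rhs(t, y):
        u = 1.0 if t < 18.0 else 0.0
        S, R = y
        return [
            p.rho_S * S - (p.delta_S + p.beta) * u * S,
            p.rho_R * R - p.delta_R * u * R + p.beta * u * S,
        ]

    sol = solve_ivp(rhs, (0, 16.0), [p.N0, 0.0], t_eval=DAYS, rtol=1e-10, atol=1e-8)
    traj = simulate_adaptive(p, tmz_schedule, DAYS, delta_a=0.002)
    total_ref = sol.y.sum(axis=0)
    assert np.allclose(traj.total, total_ref, rtol=1e-2)


def test_pure_transfer_conserves_cells_to_machine_precision(tmz_schedule):
    p = AdaptiveParams(
        rho_S=0.0, delta_S=0.0, rho_R=0.0, delta_R=0.0,
        beta=0.4, gamma_max=0.5, tau=3.0, N0=1e5,
    )
    traj = simulate_adaptive(p, tmz_schedule, DAYS)
    assert np.allclose(traj.total, p.N0, rtol=1e-12, atol=1e-6)


def test_grid_refinement_converges_at_first_order(tmz_schedule):
    ref = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, DAYS, delta_a=0.0125)
    errs = []
    for h in (0.2, 0.1, 0.05):
        sol = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, DAYS, delta_a=h)
        errs.append(np.max(np.abs(sol.total - ref.total) / ref.total))
    orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
    assert min(orders) >= 1.0


def test_age_density_snapshots_integrate_to_tr_total(tmz_schedule):
    traj = simulate_adaptive(
        DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, DAYS, store_age_density=True
    )
    da = traj.ages[1] - traj.ages[0]
    for i in range(len(DAYS)):
        assert traj.age_density[i].sum() * da == pytest.approx(traj.TR[i], abs=1e-6 * max(traj.TR[i], 1.0))
    assert np.all(traj.age_density >= 0)


def test_invalid_age_domain_rejected():
    with pytest.raises(ValueError):
        AdaptiveParams(tau=6.0, a_max=5.0)


class TestErlangChain:
    def test_empty_chain_matches_pde_when_no_entry(self, tmz_schedule):
        p = replace(DEFAULT_ADAPTIVE_PARAMS, beta=0.0)
        e = erlang_chain_approx(p, tmz_schedule, DAYS, n_stages=4)
        a = simulate_adaptive(p, tmz_schedule, DAYS)
        assert np.allclose(e.total, a.total, rtol=1e-6)

    def test_stage_count_convergence_is_monotone(self, tmz_schedule):
        ref = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, DAYS, delta_a=0.01)
        discs = []
        for k in (4, 16, 64):
            e = erlang_chain_approx(DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, DAYS, n_stages=k)
            discs.append(np.max(np.abs(e.total - ref.total) / ref.total))
        assert discs[2] < discs[1] < discs[0]

    def test_single_stage_residence_time_is_exponential_with_mean_tau(self, no_drug):
        """k=1: a pulse entering the chain leaves the delay stage at rate 1/tau,
        so the stage content decays as exp(-t/tau)."""
        p = AdaptiveParams(
            rho_S=0.0, delta_S=0.0, rho_R=0.0, delta_R=0.0, beta=50.0,
            tau=2.0, gamma_max=1e3, N0=1e4, entry_drug_gated=False,
        )
        t = np.array([0.0, 2.0])
        e = erlang_chain_approx(p, no_drug, t, n_stages=1)
        # nearly all cells enter TR immediately (beta >> 1/tau); after one mean
        # residence tau the chain retains ~exp(-1) of them (fast conversion
        # empties the mature pool immediately)
        assert e.TR[1] / p.N0 == pytest.approx(np.exp(-1.0), rel=0.05)


class TestStochastic:
    def test_all_rates_zero_keeps_population_constant(self, tmz_schedule):
        p = AdaptiveParams(rho_S=0, delta_S=0, rho_R=0, delta_R=0, beta=0,
                           gamma_max=0, tau=1.0, N0=500)
        traj = simulate_adaptive_stochastic(p, tmz_schedule, 16.0, n0=500, seed=3)
        assert np.all(traj.total == 500)
        assert np.all(traj.S == 500)

    def test_fixed_seed_reproduces_realization(self, tmz_schedule):
        p = replace(DEFAULT_ADAPTIVE_PARAMS, N0=300.0)
        a = simulate_adaptive_stochastic(p, tmz_schedule, 16.0, n0=300, seed=11, t_eval=DAYS)
        b = simulate_adaptive_stochastic(p, tmz_schedule, 16.0, n0=300, seed=11, t_eval=DAYS)
        assert np.array_equal(a.S, b.S)
        assert np.array_equal(a.TR, b.TR)
        assert np.array_equal(a.R, b.R)

    def test_integer_counts(self, tmz_schedule):
        p = replace(DEFAULT_ADAPTIVE_PARAMS, N0=200.0)
        traj = simulate_adaptive_stochastic(p, tmz_schedule, 9.0, n0=200, seed=5, t_eval=DAYS[:3])
        for arr in (traj.S, traj.TR, traj.R):
            assert np.array_equal(arr, np.round(arr))

    def test_ensemble_mean_tracks_deterministic_solution(self, tmz_schedule):
        """Small-scale mean-field agreement check (the full 500-run contract
        runs in the acceptance suite)."""
        p = replace(DEFAULT_ADAPTIVE_PARAMS, N0=1000.0)
        det = simulate_adaptive(p, tmz_schedule, DAYS, delta_a=0.01)
        totals = np.array([
            simulate_adaptive_stochastic(p, tmz_schedule, 16.0, n0=1000, seed=100 + i, t_eval=DAYS).total
            for i in range(60)
        ])
        se = totals.std(axis=0, ddof=1) / np.sqrt(len(totals))
        z = np.abs(totals.mean(axis=0)[1:] - det.total[1:]) / se[1:]
        assert np.max(z) < 4.0

    def test_desk_scale_guard(self, tmz_schedule):
        with pytest.raises(ValueError):
            simulate_adaptive_stochastic(
                DEFAULT_ADAPTIVE_PARAMS, tmz_schedule, 16.0, n0=100000, seed=0
            )


class TestTsaIntervention:
    def test_null_intervention_is_bitwise_identical(self, scenarios):
        sched = scenarios["tmz_tsa_combo"].schedule
        t = np.arange(0.0, 30.5, 0.5)
        a = tsa_intervention(DEFAULT_ADAPTIVE_PARAMS, sched, 0.0, t)
        b = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, sched, t)
        assert np.array_equal(a.S, b.S)
        assert np.array_equal(a.TR, b.TR)
        assert np.array_equal(a.R, b.R)

    def test_early_tr_kill_prevents_resistance(self, scenarios):
        sched = scenarios["tmz_tsa_combo"].schedule
        control_sched = scenarios["tmz_only_d30"].schedule
        t = np.array([0.0, 16.0, 30.0])
        treated = tsa_intervention(DEFAULT_ADAPTIVE_PARAMS, sched, 30.0, t)
        control = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, control_sched, t)
        assert treated.R[-1] < 1.0
        assert control.total[-1] > DEFAULT_ADAPTIVE_PARAMS.N0

    def test_late_tr_kill_barely_changes_outcome(self, scenarios):
        control_sched = scenarios["tmz_only_d30"].schedule
        tsa_late = DoseEntry("TSA", tuple(16.0 + 3 * i for i in range(5)), window_days=3.0)
        late_sched = TreatmentSchedule(control_sched.entries + (tsa_late,))
        t = np.array([0.0, 16.0, 30.0])
        late = tsa_intervention(DEFAULT_ADAPTIVE_PARAMS, late_sched, 30.0, t)
        control = simulate_adaptive(DEFAULT_ADAPTIVE_PARAMS, control_sched, t)
        assert late.R[-1] == pytest.approx(control.R[-1], rel=0.05)


def test_washout_readout_rises_while_transient_pool_drains(scenarios):
    """No back-conversion: after exposure ends the readout keeps rising toward
    alpha for as long as the maturing TR pool (rather than the regrowing
    sensitive remnant) dominates the deviation from alpha."""
    scen = scenarios["washout"]
    t = np.arange(18.0, 28.5, 0.5)
    traj = simulate_adaptive(
        scen.params, scen.schedule, t, readout=ReadoutParams(alpha=20.0)
    )
    assert np.all(np.diff(traj.mgmt) >= -1e-9)
    assert traj.mgmt[-1] > 19.5  # resistance persists near the alpha plateau
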
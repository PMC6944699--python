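import numpy as np
import pandas as pd
import pytest

from persisterdyn import (
    ClonalParams,
    DEFAULT_READOUT,
    FitSpec,
    FreeParam,
    NoiseModel,
    ReadoutParams,
    ScenarioConfig,
    TimeCourseDataset,
    TreatmentSchedule,
    feasible_parameter_range,
    fit_model,
    generate_dataset,
    residuals,
    simulate_clonal,
)
from persisterdyn.fitting import rss_decomposition


@pytest.fixture(scope="module")
def noisefree_clonal(scenarios, noisefree):
    ds, truth = generate_dataset(scenarios["full_course_clonal"], noisefree, seed=0)
    return ds, truth


def _true_params(truth):
    d = dict(truth["params"])
    d.pop("K", None)
    d["alpha"] = truth["readout"]["alpha"]
    d["c_tr"] = truth["readout"]["c_tr"]
    return d


class TestResiduals:
    def test_noise_free_data_from_true_params_gives_zero(self, noisefree_clonal):
        ds, truth = noisefree_clonal
        r = residuals("clonal", _true_params(truth), ds, DEFAULT_READOUT)
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_tenfold_count_offset_gives_unit_log10_residuals(self, noisefree_clonal):
        ds, truth = noisefree_clonal
        shifted = TimeCourseDataset(
            data=ds.data.assign(count=ds.data["count"] / 10.0),
            schedule=ds.schedule,
        )
        r = residuals("clonal", _true_params(truth), shifted, DEFAULT_READOUT, w_mgmt=0.0)
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_missing_mgmt_rows_contribute_no_residual(self, noisefree_clonal):
        ds, truth = noisefree_clonal
        df = ds.data.copy()
        df.loc[df["day"] <= 4.0, "mgmt_fold"] = np.nan
        masked = TimeCourseDataset(data=df, schedule=ds.schedule)
        r_all = residuals("clonal", _true_params(truth), ds, DEFAULT_READOUT)
        r_masked = residuals("clonal", _true_params(truth), masked, DEFAULT_READOUT)
        assert len(r_masked) == len(r_all) - 2

    def test_simulation_failure_yields_penalty_vector(self, noisefree_clonal):
        ds, truth = noisefree_clonal
        bad = dict(_true_params(truth), delta_R=5.0)  # violates delta_R <= delta_S
        r = residuals("clonal", bad, ds, DEFAULT_READOUT)
        assert len(r) == ds.n_count_obs + ds.n_mgmt_obs
        assert np.all(r == 1e3)

    def test_loss_matches_independent_implementation(self, scenarios, noisefree_clonal):
        """Double-coded objective: an independently written loss over random
        parameter draws must match the residual-vector route."""
        ds, truth = noisefree_clonal
        rng = np.random.default_rng(42)
        for _ in range(5):
            params = _true_params(truth)
            params["rho_S"] = rng.uniform(0.1, 0.8)
            params["rho_R"] = rng.uniform(0.1, 0.8)
            params["delta_S"] = rng.uniform(0.5, 2.0)
            params["f_R0"] = 10 ** rng.uniform(-4, -0.7)
            params["alpha"] = rng.uniform(2, 50)
            rss, _, _ = rss_decomposition("clonal", params, ds, DEFAULT_READOUT)
            # independent route: simulate, interpolate, accumulate squares
            mp = ClonalParams(**{k: params[k] for k in
                                 ("rho_S", "rho_R", "delta_S", "delta_R", "f_R0", "N0")})
            ro = ReadoutParams(alpha=params["alpha"], c_tr=params["c_tr"])
            days = np.unique(ds.data["day"])
            traj = simulate_clonal(mp, ds.schedule, days, readout=ro)
            tot = dict(zip(traj.t, traj.total))
            mg = dict(zip(traj.t, traj.mgmt))
            expected = 0.0
            for _, row in ds.data.iterrows():
                expected += (np.log10(tot[row["day"]]) - np.log10(row["count"])) ** 2
                if np.isfinite(row["mgmt_fold"]):
                    expected += (np.log2(mg[row["day"]]) - np.log2(row["mgmt_fold"])) ** 2
            assert rss == pytest.approx(expected, rel=1e-12)


class TestFitModel:
    def test_one_parameter_exponential_growth_is_identifiable(self, no_drug, noisefree):
        scen = ScenarioConfig(
            name="growth", schedule=no_drug, model_id="clonal",
            params=ClonalParams(rho_S=0.45, rho_R=0.05, delta_S=0.0, delta_R=0.0,
                                f_R0=0.0, N0=1e5),
        )
        ds, truth = generate_dataset(scen, noisefree, seed=0)
        spec = FitSpec(
            model_id="clonal",
            free_params=(FreeParam("rho_S", 0.05, 1.5),),
            fixed_params=_true_params(truth),
            n_starts=8,
            seed=0,
        )
        ens = fit_model(ds, spec, readout=DEFAULT_READOUT)
        assert ens.best.params["rho_S"] == pytest.approx(0.45, rel=1e-6)
        lo, hi = feasible_parameter_range(ens, "rho_S")
        assert hi / lo == pytest.approx(1.0, abs=1e-6)

    def test_multi_start_is_deterministic_under_seed(self, clonal_dataset):
        ds, truth = clonal_dataset
        spec = FitSpec(
            model_id="clonal",
            free_params=(
                FreeParam("rho_S", 0.05, 1.5),
                FreeParam("f_R0", 1e-4, 0.3),
            ),
            fixed_params=_true_params(truth),
            n_starts=6,
            seed=7,
        )
        e1 = fit_model(ds, spec, readout=DEFAULT_READOUT)
        e2 = fit_model(ds, spec, readout=DEFAULT_READOUT)
        assert [r.params for r in e1.results] == [r.params for r in e2.results]
        assert [r.rss_total for r in e1.results] == [r.rss_total for r in e2.results]

    def test_bounds_respected_and_results_sorted(self, clonal_dataset):
        ds, truth = clonal_dataset
        free = (
            FreeParam("rho_S", 0.2, 0.6),
            FreeParam("delta_S", 0.5, 2.0),
        )
        spec = FitSpec("clonal", free, _true_params(truth), n_starts=5, seed=1)
        ens = fit_model(ds, spec, readout=DEFAULT_READOUT)
        rss = [r.rss_total for r in ens.results]
        assert rss == sorted(rss)
        for r in ens.results:
            for f in free:
                assert f.lower <= r.params[f.name] <= f.upper

    def test_rss_decomposition_reassembles_total(self, clonal_dataset):
        ds, truth = clonal_dataset
        spec = FitSpec(
            "clonal",
            (FreeParam("rho_S", 0.05, 1.5), FreeParam("f_R0", 1e-4, 0.3)),
            _true_params(truth),
            w_count=2.0, w_mgmt=0.5, n_starts=3, seed=0,
        )
        ens = fit_model(ds, spec, readout=DEFAULT_READOUT)
        for r in ens.results:
            assert r.rss_total == pytest.approx(
                2.0 * r.rss_counts + 0.5 * r.rss_mgmt, rel=1e-12
            )

    def test_feasible_set_monotone_in_epsilon(self, clonal_dataset):
        ds, truth = clonal_dataset
        base = FitSpec(
            "clonal",
            (FreeParam("rho_S", 0.05, 1.5), FreeParam("f_R0", 1e-4, 0.3)),
            _true_params(truth), n_starts=8, seed=0,
        )
        ens = fit_model(ds, base, readout=DEFAULT_READOUT)
        from persisterdyn import FitEnsemble

        sizes = []
        for eps in (0.01, 0.05, 0.5, 5.0):
            e = FitEnsemble(ens.results, feasibility_epsilon=eps)
            sizes.append(len(e.feasible))
            assert e.feasible[0] is e.best
        assert sizes == sorted(sizes)

    def test_freeing_a_parameter_never_worsens_the_objective(self, clonal_dataset):
        """Best loss with {rho_S} free, then with {rho_S, f_R0} free where the
        restricted optimum is added to the start pool."""
        ds, truth = clonal_dataset
        fixed = _true_params(truth)
        spec1 = FitSpec("clonal", (FreeParam("rho_S", 0.05, 1.5),), fixed,
                        n_starts=6, seed=3)
        e1 = fit_model(ds, spec1, readout=DEFAULT_READOUT)
        spec2 = FitSpec(
            "clonal",
            (FreeParam("rho_S", 0.05, 1.5), FreeParam("f_R0", 1e-4, 0.3)),
            fixed, n_starts=6, seed=3,
        )
        start = {"rho_S": e1.best.params["rho_S"], "f_R0": fixed["f_R0"]}
        e2 = fit_model(ds, spec2, readout=DEFAULT_READOUT, extra_starts=[start])
        assert e2.best.rss_total <= e1.best.rss_total + 1e-9

    def test_underdetermined_dataset_rejected(self, noisefree_clonal):
        ds, truth = noisefree_clonal
        tiny = TimeCourseDataset(
            data=ds.data.iloc[:2].assign(mgmt_fold=np.nan), schedule=ds.schedule
        )
        free = tuple(
            FreeParam(n, 0.05, 1.5) for n in ("rho_S", "rho_R", "delta_S")
        ) + (FreeParam("f_R0", 1e-4, 0.3), FreeParam("alpha", 2, 100))
        with pytest.raises(ValueError, match="observations"):
            fit_model(
                tiny, FitSpec("clonal", free, _true_params(truth), n_starts=2, seed=0)
            )

    def test_unknown_parameter_range_rejected(self, clonal_dataset):
        ds, truth = clonal_dataset
        spec = FitSpec("clonal", (FreeParam("rho_S", 0.05, 1.5),),
                       _true_params(truth), n_starts=2, seed=0)
        ens = fit_model(ds, spec, readout=DEFAULT_READOUT)
        with pytest.raises(KeyError):
            feasible_parameter_range(ens, "nonexistent")
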
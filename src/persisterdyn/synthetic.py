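"""Synthetic time-course generator emulating the pulsed-TMZ experiment.

Every downstream stage (fitting, identifiability, discrimination) is
exercised on datasets with the statistical structure of the in-vitro design:
total viable counts and bulk MGMT fold-change observed at days
{0, 4, 9, 12, 16} under 50 µM TMZ redosed every 3 days, in 3 biological
replicates.  Count noise is multiplicative lognormal (scale-free across the
three-decade dip/regrowth, mean-preserving, CV 0.15 by default); MGMT noise
is additive Gaussian on the log2 fold-change scale (qPCR-native, SD 0.25
log2 units by default).  Counts below a detection floor are reported at the
floor, mirroring "not detectable" outcomes.

The named scenarios package the experimental arms: the full 16-day course,
the day-3/day-6 early-stop arms, the wash-out arm, and the TMZ+TSA
combination in which the transient compartment is selectively killed.  The
default true parameters live here, in one place, and are chosen so the
adaptive model reproduces the qualitative timeline: a strong early decline
in S, a transient-dominated mid-phase, MGMT onset around day 9 rising to a
plateau by day 16, and regrowth driven by the resistant population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adaptive import AdaptiveParams, simulate_adaptive
from .clonal import ClonalParams, simulate_clonal
from .schedules import DoseEntry, TreatmentSchedule, standard_tmz_schedule
from .timecourse import ReadoutParams, TimeCourseDataset, Trajectory

__all__ = [
    "NoiseModel",
    "ScenarioConfig",
    "generate_dataset",
    "paperlike_scenarios",
    "simulate_scenario",
    "DEFAULT_ADAPTIVE_PARAMS",
    "DEFAULT_CLONAL_PARAMS",
    "DEFAULT_READOUT",
    "OBS_DAYS",
]

# Observation grid of the transcriptome/count sampling design.
OBS_DAYS = (0.0, 4.0, 9.0, 12.0, 16.0)

# Documented default "ground truth" parameter sets (rates per day, sizes in
# cells).  N0 is arbitrary (absolute cells per dish are not part of the
# design) and the models are linear in it.
DEFAULT_ADAPTIVE_PARAMS = AdaptiveParams(
    rho_S=0.4, delta_S=0.9, rho_R=0.35, delta_R=0.05,
    beta=0.25, tau=6.0, gamma_max=0.3, mu_TR=0.0, rho_TR=0.0, N0=1e5,
)
DEFAULT_CLONAL_PARAMS = ClonalParams(
    rho_S=0.4, rho_R=0.35, delta_S=0.9, delta_R=0.05, f_R0=0.01, N0=1e5,
)
DEFAULT_READOUT = ReadoutParams(alpha=20.0, c_tr=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise structure of the synthetic experiment."""

    count_cv: float = 0.15
    mgmt_sd_log2: float = 0.25
    n_replicates: int = 3
    detection_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.count_cv < 0 or self.mgmt_sd_log2 < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named experimental arm with its schedule and true parameters."""

    name: str
    schedule: TreatmentSchedule
    obs_days: tuple[float, ...] = OBS_DAYS
    horizon: float = 16.0
    model_id: str = "adaptive"
    params: AdaptiveParams | ClonalParams = field(default_factory=lambda: DEFAULT_ADAPTIVE_PARAMS)
    readout: ReadoutParams = field(default_factory=lambda: DEFAULT_READOUT)
    kappa_tsa: float = 0.0
    delta_a: float = 0.05

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.obs_days)
        object.__setattr__(self, "obs_days", days)
        if any(d < 0 or d > self.horizon for d in days):
            raise ValueError("obs_days must lie within [0, horizon]")
        if self.model_id not in ("clonal", "adaptive"):
            raise ValueError(f"unknown model_id {self.model_id!r}")


def simulate_scenario(scenario: ScenarioConfig, t_grid=None) -> Trajectory:
    """Noise-free trajectory of a scenario on ``t_grid`` (default: a dense
    daily-resolution grid over the horizon)."""
    if t_grid is None:
        t_grid = np.round(np.arange(0.0, scenario.horizon + 1e-9, 0.25), 6)
    t_grid = np.asarray(t_grid, dtype=float)
    if scenario.model_id == "clonal":
        return simulate_clonal(
            scenario.params, scenario.schedule, t_grid, readout=scenario.readout
        )
    return simulate_adaptive(
        scenario.params,
        scenario.schedule,
        t_grid,
        delta_a=scenario.delta_a,
        readout=scenario.readout,
        kappa_tsa=scenario.kappa_tsa,
    )


def generate_dataset(
    scenario: ScenarioConfig, noise: NoiseModel, seed: int
) -> tuple[TimeCourseDataset, dict]:
    """Generate a replicated noisy dataset plus its ground-truth record.

    The ground-truth record (scenario, parameters, noise config, seed, and
    the noise-free curves) suffices to regenerate the dataset bit-exactly.
    """
    days = np.array(sorted(set(scenario.obs_days)), dtype=float)
    t_grid = np.unique(np.concatenate(([0.0], days)))
    traj = simulate_scenario(scenario, t_grid)
    traj_at = traj.at(days)
    true_total = traj_at.total
    true_mgmt = traj_at.mgmt

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise.count_cv**2)))
    rows = []
    for r in range(noise.n_replicates):
        rep = f"rep{r + 1}"
        z_count = rng.standard_normal(len(days))
        z_mgmt = rng.standard_normal(len(days))
        counts = true_total * np.exp(sigma * z_count - 0.5 * sigma**2)
        counts = np.maximum(counts, noise.detection_floor)
        folds = true_mgmt * 2.0 ** (noise.mgmt_sd_log2 * z_mgmt)
        for d, c, f in zip(days, counts, folds):
            rows.append((rep, d, c, f))
    df = pd.DataFrame(rows, columns=["replicate_id", "day", "count", "mgmt_fold"])
    truth = {
        "scenario": scenario.name,
        "model_id": scenario.model_id,
        "params": scenario.params.to_dict(),
        "readout": {"alpha": scenario.readout.alpha, "c_tr": scenario.readout.c_tr},
        "kappa_tsa": scenario.kappa_tsa,
        "noise": {
            "count_cv": noise.count_cv,
            "mgmt_sd_log2": noise.mgmt_sd_log2,
            "n_replicates": noise.n_replicates,
            "detection_floor": noise.detection_floor,
        },
        "seed": int(seed),
        "obs_days": days.tolist(),
        "true_total": true_total.tolist(),
        "true_mgmt": true_mgmt.tolist(),
    }
    dataset = TimeCourseDataset(
        data=df, schedule=scenario.schedule, provenance={"generator": truth}
    )
    return dataset, truth


def _tmz_course(last_dose_day: float, start: float = 0.0) -> TreatmentSchedule:
    n = int(np.floor((last_dose_day - start) / 3.0)) + 1
    return standard_tmz_schedule(n_doses=n, start_day=start)


def paperlike_scenarios() -> dict[str, ScenarioConfig]:
    """The named experimental arms with the documented default parameters.

    ``full_course``      TMZ every 3 d through day 16 (adaptive truth).
    ``full_course_clonal`` same design generated from the clonal truth.
    ``early_stop_d3``    single dose: 3 days of exposure, then drug-free.
    ``early_stop_d6``    two doses: 6 days of exposure, then drug-free.
    ``washout``          full course, then drug-free out to day 100.
    ``tmz_tsa_combo``    TMZ from day 0 plus TR-specific TSA kill from day 3,
                         both sustained to day 30.
    ``tmz_only_d30``     sustained-TMZ control for the combination arm.
    """
    tmz16 = _tmz_course(15.0)
    tmz30 = _tmz_course(27.0)
    tsa_from_d3 = DoseEntry(
        drug_id="TSA",
        dose_times=tuple(3.0 + 3.0 * i for i in range(9)),
        exposure_mode="window",
        window_days=3.0,
        effect_level=1.0,
        dose_amount=0.25,
    )
    combo = TreatmentSchedule(entries=tmz30.entries + (tsa_from_d3,))
    washout_days = OBS_DAYS + (30.0, 60.0, 100.0)
    scenarios = {
        "full_course": ScenarioConfig(
            name="full_course", schedule=tmz16, model_id="adaptive",
            params=DEFAULT_ADAPTIVE_PARAMS,
        ),
        "full_course_clonal": ScenarioConfig(
            name="full_course_clonal", schedule=tmz16, model_id="clonal",
            params=DEFAULT_CLONAL_PARAMS,
        ),
        "early_stop_d3": ScenarioConfig(
            name="early_stop_d3", schedule=_tmz_course(0.0), model_id="adaptive",
            params=DEFAULT_ADAPTIVE_PARAMS,
        ),
        "early_stop_d6": ScenarioConfig(
            name="early_stop_d6", schedule=_tmz_course(3.0), model_id="adaptive",
            params=DEFAULT_ADAPTIVE_PARAMS,
        ),
        "washout": ScenarioConfig(
            name="washout", schedule=tmz16, obs_days=washout_days, horizon=100.0,
            model_id="adaptive", params=DEFAULT_ADAPTIVE_PARAMS,
        ),
        "tmz_tsa_combo": ScenarioConfig(
            name="tmz_tsa_combo", schedule=combo, horizon=30.0,
            obs_days=OBS_DAYS + (21.0, 30.0), model_id="adaptive",
            params=DEFAULT_ADAPTIVE_PARAMS, kappa_tsa=30.0,
        ),
        "tmz_only_d30": ScenarioConfig(
            name="tmz_only_d30", schedule=tmz30, horizon=30.0,
            obs_days=OBS_DAYS + (21.0, 30.0), model_id="adaptive",
            params=DEFAULT_ADAPTIVE_PARAMS,
        ),
    }
    return scenarios
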
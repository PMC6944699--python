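# Methods

## Models

Two frameworks for the acquisition of temozolomide resistance in a
proliferating glioma cell population under pulsed drug exposure are
implemented as population-balance models with a shared observation channel.

**Clonal selection** (`persisterdyn.clonal`).  Sensitive (S) and resistant
(R) subpopulations with net per-day proliferation rates `rho_S`, `rho_R` and
drug-induced death rates `delta_S u(t)`, `delta_R u(t)`; the resistant
fraction `f_R0` pre-exists at time 0.  Baseline death is merged into the net
`rho` terms (untreated cultures only tell us net growth); the drug acts as a
separate additive death term gated by the unitless exposure `u(t)`.  Growth
is exponential by default — a 16-day passaged culture is not assumed to
saturate — with an optional logistic factor `1 − N/K`.

**Adaptive acquisition** (`persisterdyn.adaptive`).  R starts at zero.
Under exposure, S cells enter a transient state TR at rate `beta·u(t)`; TR
is structured by age `a` (time since entry), does not proliferate and does
not die by default (`rho_TR = mu_TR = 0`, matching the observed
death-protected, arrested phenotype; both are free knobs, e.g. to encode
the "slow growth" reading of the transient state), and converts irreversibly
to R at rate `gamma(a) = gamma_max·[a >= tau]`.  The step maturation profile
is the sharpest reading of an age-gated transition; a smooth Hill-shaped
`gamma(a)` (half-maximum at `tau`, exponent 8) is available where a sharp
threshold is implausible.  TR entry is drug-gated by default (the transient
population appears only under treatment); `entry_drug_gated=False` gives the
drug-independent variant.

**Exposure model** (`persisterdyn.schedules`).  Doses map to a unitless
exposure in [0, 1].  Default: window mode with window = inter-dose interval
(3 d) and effect 1.0, so the standard every-3-days course is effectively
continuous exposure — the package deliberately does not model TMZ
pharmacokinetics, and physical doses (µM) are carried as metadata only.  A
decay mode (per-dose exponential with accumulation capped at the effect
level) exists for schedules with real gaps.

**MGMT observation model** (`persisterdyn.timecourse`).  The bulk qPCR
fold-change is modelled as the population-average per-cell expression
relative to a pure sensitive population: `(S + c_tr·TR + alpha·R)/(S + TR +
R)` with `alpha >= 1` the resistant-to-sensitive per-cell ratio and `c_tr =
0` by default (single-cell evidence places MGMT onset at conversion, not
entry).  A `total` mode (average × population size) is available behind a
flag for bulk-extract interpretations, and `normalize_to_baseline` re-bases
trajectory readouts to their day-0 value.  A consequence of `c_tr = 0` that
matters downstream: while MGMT-silent TR cells dominate the bulk, the
readout *dips below 1* — a signature the clonal model cannot produce.

## Numerics

The clonal system under piecewise-constant exposure and exponential growth
is linear and is evaluated in closed form via the cumulative exposure
integral (machine-accurate, microseconds per call — this is what makes the
multi-start fitting experiments cheap).  The logistic / decay-exposure cases
use LSODA restarted at every exposure discontinuity, with an internal 100×
safety factor on the requested tolerances so the advertised `rtol` is
conservative.

The age-structured system is solved by the method of characteristics with
time step equal to the age step (`delta_a`, default 0.05 d): transport is an
exact one-bin shift (no numerical diffusion), and within each step the
linear reaction terms use exact exponential factors, with the conversion
flux integrated as `gamma·n·(e^{r dt}−1)/r`.  Pure transfer therefore
conserves cells to machine precision, and the scheme is first-order in
`delta_a` through the age-binning of the maturation threshold (measured
empirical order ≈ 1.1–1.2).  The age domain is truncated at `a_max`
(default `tau + 10` d) with an absorbing terminal bin that keeps converting
at `gamma_max`.  The inner loop is JIT-compiled (numba); a full 16-day
trajectory costs ~1 ms.

Two independent oracles cross-validate this solver:

* an agent-based stochastic simulator (exponential event clocks for
  division/death/entry; each TR agent carries its exact entry time, with
  conversion at `entry + tau + Exp(gamma_max)` competing against death at
  `Exp(mu_TR)`), whose ensemble mean equals the mean-field solution for this
  linear model — it is restricted to `rho_TR = 0` because a dividing TR
  agent's age inheritance is not defined by the mean-field equations alone;
* an Erlang-chain reduction of the fixed delay (`n_stages` sub-compartments
  at rate `n_stages/tau`), which converges monotonically to the
  characteristics solution as stages are added.

## Fitting, identifiability, discrimination

Residuals are per observed (replicate, day, channel): log10 for counts (the
dip/regrowth spans orders of magnitude), log2 for MGMT fold-change
(qPCR-native); channel weights default 1:1 and replicates enter as
independent rows.  Starts are Latin-hypercube draws over the bounds (log10
scale where flagged), polished with scipy's bounded trust-region
least-squares; everything is deterministic under the spec seed.  Parameter
sets that violate model invariants simply return a flat penalty vector, so
the optimizer treats them as infeasible.  The *feasible ensemble* — all
polished fits within `(1 + epsilon)` of the best loss, `epsilon = 0.05` by
default — expresses practical identifiability: the feasible range of a
parameter is its min/max over that set.  Model comparison uses AICc on the
total weighted RSS with `n` = residual count and `k` = free-parameter
count; |ΔAICc| ≥ 10 is decisive, anything less is reported indeterminate.

## Synthetic data and benchmark conditions

The generator (`persisterdyn.synthetic`) emulates the experimental design:
observations at days {0, 4, 9, 12, 16}, 3 biological replicates,
mean-preserving lognormal count noise (CV 0.15), additive Gaussian noise on
log2 MGMT fold-change (SD 0.25), and a 100-cell detection floor for
"not detectable" outcomes.  Default true parameters (documented constants in
one place): adaptive `rho_S=0.4`, `delta_S=0.9`, `beta=0.25`, `tau=6`,
`gamma_max=0.3`, `rho_R=0.35`, `delta_R=0.05`, `alpha=20`; clonal shares the
rates with `f_R0=0.01`.  They were chosen so the simulated course reproduces
the qualitative timeline — strong early kill, a transient-dominated
mid-phase, MGMT onset near day 9 rising to a plateau by day 16, regrowth
past the starting density — and `N0 = 1e5` is an arbitrary scale (the
models are linear in it).  What the generator does *not* emulate: replicate-
to-replicate kinetic heterogeneity (all replicates share one latent
trajectory), time-correlated measurement error, counting error at the
detection floor, and drug-effect ramp-up (exposure steps to 1 at the first
dose, so modelled death flux peaks immediately rather than near day 3).
Passing recovery/discrimination benchmarks therefore speak to the method
under well-specified noise, not to robustness against model misspecification.

Named scenarios package the experimental arms (full course, day-3/day-6
early stops, wash-out to day 100, TMZ+TSA combination with a TR-specific
kill rate `kappa_tsa`, and the matching TMZ-only control).

Benchmark problem sizes, fixed as the package's standard conditions: 500
stochastic runs at `n0 = 2000` for the Monte-Carlo agreement check
(deterministic reference at `delta_a = 0.01`); 20 seeded datasets per
recovery and discrimination arm; 50 multi-start fits for clonal ensembles
and 12 for adaptive ensembles (the clonal closed form is ~100× cheaper per
evaluation).

## Findings worth flagging

Two behaviors of the in-silico study differ from what the corresponding
wet-lab argument might suggest, and both are properties of the problem, not
bugs:

* **Counts alone nearly identify `f_R0` under these benchmark conditions.**
  With 3 replicates at 15% CV and sampling through the regrowth phase, the
  resistant trajectory is pinned on the days it dominates, so the 5%-loss
  feasible ensemble collapses onto a single optimum (measured range factor
  ≈ 1; the profile of the loss spans only ~1.5× in `f_R0`).  A broad
  feasible spread of the initial resistant fraction — the hallmark of
  count-only non-identifiability — requires looser feasibility, sparser or
  noisier counts, or saturating growth; adding the MGMT channel pins `f_R0`
  regardless.  `feasibility_epsilon` is configurable for exploring this.
* **The clonal model's MGMT failure localizes early, not late.**  Against
  adaptive-generated data the clonal fit is rejected decisively (ΔAICc ≈
  +100), but its residual mass sits in days 4–9, where the bulk readout
  dips below baseline under TR dilution; at the late plateau both models
  fit the *mean* MGMT equally well.  A late-window failure signature would
  require replicate variability (a second-moment feature) rather than a
  mean-curve misfit, which an RSS criterion does not measure.

## Limitations

No pharmacokinetics or dose–response calibration (exposure is unitless); no
spatial structure, microenvironment or immune interaction; no genotype
tracking within R; no Bayesian posteriors or profile-likelihood intervals
(the ensemble-range device is deliberate); the stochastic oracle excludes
TR proliferation; age-dependent MGMT expression within TR is not modelled
(`c_tr` is a scalar).
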
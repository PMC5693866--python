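# Methods

## The model

The circuit is the classic LacI/TetR toggle switch: two operons in mutual
transcriptional repression, read out through mKate2 (RFP, fused to *lacI*)
and mEGFP (GFP, fused to *tetR*).  External aTc sequesters TetR and external
IPTG sequesters LacI, so each inducer weakens one repression arm.  The model
is built from eight pseudo-reactions — transcription of each mRNA,
translation, and first-order degradation/dilution of each mRNA and protein —
with transcription regulated by a nested pair of decreasing Hill functions:

    f_L(TetR, aTc)  = k_m0_L + k_m_L · h⁻( TetR · h⁻(aTc,  θ_aTc,  η_aTc),  θ_TetR, η_TetR )
    f_T(LacI, IPTG) = k_m0_T + k_m_T · h⁻( LacI · h⁻(IPTG, θ_IPTG, η_IPTG), θ_LacI, η_LacI )

with h⁻(x, θ, η) = 1/(1 + (x/θ)^η).  The inner Hill factor models
sequestration: the *free* repressor is the total pool scaled down by its
inducer.  Deterministically this yields four ODEs (two mRNAs, two proteins);
stochastically, a continuous-time Markov chain whose propensities equal the
deterministic rate laws.  Protein "a.u." are identified one-to-one with
fluorescence units, and the CTMC treats rounded a.u. as molecule counts; no
system-size factor is introduced because the calibration data constrain only
fluorescence.

Internal inducer levels are additional states governed by a membrane-exchange
model with two variants:

* **symmetric** — internal aTc is slaved algebraically to the external level,
  internal IPTG relaxes with a single rate `k_IPTG` (default 2.75e-2 min⁻¹).
* **asymmetric** (reference) — both inducers relax first-order toward the
  external level, with a different rate for import (external above internal)
  and export.  Defaults: aTc in 1.62e-1 / out 2.0e-2 min⁻¹, IPTG in
  2.75e-2 / out 1.11e-1 min⁻¹.

The strongly unequal aTc rates represent apparent intracellular retention of
the drug (tight TetR binding / adsorption); the slow IPTG import reflects the
permease deletion in the host strain.  The magnitude *assignment* across the
four asymmetric rates was fixed by requiring the model to reproduce the
system's documented forcing phenomenology (single effective attractor on the
LacI-dominant side for the 120/30 protocol, near the basin boundary for
180/30, monotone drift of the attractor with the duty ratio); with the aTc
and IPTG rate pairs swapped, the 120/30 attractor lands in the TetR-dominant
corner, which contradicts the observed post-release fates.

All rates are per minute.  The default parameter set
(`togglectl/data/default_params.yaml`) is the fitted reference
parameterisation of this circuit; under basal inputs (aTc 20 ng/mL, IPTG
0.25 mM) it is bistable with stable points near (LacI, TetR) ≈ (2576, 73)
and (56, 1073) a.u. and a saddle near (526, 287) a.u.

## Deterministic analysis

`integrate` solves the six-state system with LSODA (default rtol 1e-6,
atol 1e-9), restarting at every schedule breakpoint so input discontinuities
are never smoothed over.

Phase-plane objects live in the (LacI, TetR) plane of the reduced system:
mRNA at quasi-steady state (mRNA turnover, t½ ≈ 5 min, is much faster than
protein dilution, t½ ≈ 42 min) and internal inducers at their
input-determined level.  Because each reduced component is affine in its own
variable, each nullcline is an explicit curve (e.g. LacI =
k_p_L·f_L(TetR, aTc)/(g_m_L·g_p_L) parameterised by TetR); nullclines and
nullcline intersections are therefore computed in closed form with a dense
1-D sign-change scan plus Brent polishing rather than by 2-D bracketing.
`find_equilibria` instead multi-starts a Newton-type solver (scipy `hybr`) in
log10 coordinates from a log-spaced grid (default 49 starts plus 5 seeded
jittered extras spanning [1e-2, 10 × the fully-induced level]), deduplicates
roots at 1e-3 relative distance, and the two routes are cross-checked against
each other in the test suite.  Stability is always classified on the full
4×4 mRNA/protein Jacobian (eigenvalues with real part < −1e-9 min⁻¹ on every
mode ⇒ stable); the quasi-steady-state reduction is used only to *locate*
roots, never to classify them.

`separatrix` traces the basin boundary as the stable manifold of the reduced
saddle: backward-time integration from ±ε offsets along the stable
eigenvector, stopped at a bounding box of 20× the fully-induced level.

`time_averaged_field` handles periodic forcing.  The internal-inducer
subsystem is autonomous and piecewise-linear, so its periodic orbit is found
by iterating the exact per-segment exponential map until the start-of-period
state changes by < 1e-6 in relative sup norm (at least 5, at most 50
periods).  The reduced protein field is then averaged over one period along
that orbit (default 240 time samples); averaging commutes with the affine
self-terms, so null points again reduce to a scalar fixed-point equation
solved by scan + Brent.  This averaged field is the quantitative version of
the slow-circuit/fast-forcing argument: commitment dynamics take hours while
the forcing period is 2.5–3.5 h or less, so cells track the average rather
than the instantaneous field, and the averaged field's unique null point acts
as an effective global attractor.

## Stochastic simulation

`simulate_ssa` implements the first-reaction variant of the Gillespie
algorithm: one exponential candidate time per reaction channel, the earliest
fires.  Internal inducers are *not* CTMC species; they advance
deterministically between events via the exact exponential relaxation of the
exchange model.  Propensities are frozen between events and recomputed after
every event and at every input change; a candidate jump that would cross a
schedule breakpoint (or sampling stop) is rejected and the clock advanced to
the boundary, which is exact for the frozen-propensity process by
memorylessness.  Holding propensities constant between events is an
approximation for the continuously-drifting inducer levels, but event gaps at
the fitted copy numbers are ≲ 0.03 min while inducer relaxation times are
tens of minutes, so the within-gap propensity drift is negligible.
Populations use independent per-cell streams spawned deterministically from a
master seed (`numpy` SeedSequence).

## Feedback control

Two independent SISO controllers act at each measurement instant (default
cadence Δt = 5 min, zero-order hold between measurements): the aTc channel
regulates LacI-RFP, the IPTG channel regulates TetR-GFP.  Bounds are
0–50 ng/mL aTc and 0–0.5 mM IPTG; basal inputs (20 ng/mL, 0.25 mM) are the
PI operating point.  Targets default to the saddle coordinates under basal
inputs, the natural "undecided" set-point.  Measurements feed raw plant
states; an optional hook can inject observation noise.

The PI law is u = u0 + K_P·e + K_I·I with I the trapezoidal error integral
on the measurement grid, accumulated only after t_d = 120 min (start-up
errors are unavoidable while the state is still being driven toward the
target; integrating them causes windup and overshoot, hence the window).
The integral contribution is exactly zero for t ≤ t_d.

**Gain units.**  The proportional gains (3.3e-2 for aTc, 1.65e-2 for IPTG)
are dimensionless per a.u.  The integral gains are published as 1.32e-4 and
4.6e-4 "s⁻¹"; applied to a minute-scale integral a literal reading requires
a ×60 conversion.  Empirically that conversion destabilises the loop: from a
10 % perturbation off the saddle the closed loop grows into a full-range
limit cycle (time-averaged relative LacI error ≈ 0.8, excursions to within
7 % of each attractor in log space) — behaviour inconsistent with the
documented closed-loop runs, which hold the cell near the target.  Applied
per-minute, the same numbers hold the loop tightly (relative error ≈ 0.11)
and robustly across exchange-rate assumptions.  The package therefore
adopts the published *numeric* values on the per-minute integral — the most
plausible reading is that the original controller accumulated its integral
on the acquisition-grid timestep — and provides `per_second()` for anyone
wanting the literal conversion.

The bang-bang law applies the maximal inducer concentration when the
controlled protein is below target and the minimal one otherwise, with
equality taking the minimal branch.

Fate labelling after a run: a protein state is assigned to its nearest
stable equilibrium in log10 space ("rfp" when that equilibrium is
LacI-dominant), and called *committed* when the relative log-space distance
is below 0.1.  Log space is used because the two attractors differ by
orders of magnitude in each coordinate.

## Calibration

`objective_msrd` is the mean squared relative deviation between
deterministic model traces and cell-averaged fluorescence, the grand mean
over experiments × channels × time points (so duplicating an experiment
changes nothing).  Initial states are pre-equilibrated: the stable
equilibrium of each experiment's first input condition (nearest to the first
data point in log space if several), matching the recovery period cells get
before a run.  ODE failures return a finite penalty (1e6) so the optimizer
can continue.

Optimisation uses CMA-ES — implemented in `togglectl.optimize` as the
standard (μ/μ_w, λ) strategy with rank-one + rank-μ covariance updates and
cumulative step-size adaptation — in log10-parameter space with box bounds
(rates span orders of magnitude; positivity is automatic).  Out-of-box
candidates are evaluated at their projection with a quadratic penalty.
Restarts split the evaluation budget; restart 0 starts at the box centre,
later ones at seeded uniform draws.  CMA-ES hyperparameters follow the
standard recommendations (λ = 4 + ⌊3 ln n⌋ etc.) and are recorded in the
convergence log.  The inducer-exchange parameters are deliberately excluded
from the fitted vector (they were hand-adjusted in the reference
parameterisation); pass a modified `ExchangeParams` to refit scenarios.

`recovery_report` gives per-parameter relative errors plus a practical
identifiability flag: a parameter is *sloppy* when perturbing its fitted
value by ±50 % changes the MSRD by less than 0.01 (i.e. below a 10 % rms
prediction shift), in which case its recovery error is reported but carries
no information.

## Synthetic data

The generator emulates the calibration experiments: step changes between
saturating media (1 mM IPTG / 100 ng/mL aTc reservoirs) applied to n = 9
cells, fluorescence sampled every 5 min, with a 60-min pre-equilibration
phase under the first medium.  Cell-to-cell heterogeneity multiplies the
production rates (k_m0 excluded by default; k_m and k_p jittered) by
independent log-normal factors with median 1 and CV 0.1; measurement noise
is log-normal with CV 0.05.  Neither CV is documented for the real system;
these values visibly spread a simulated population the way the imaged fields
of view do while keeping the averaged traces smooth.  Log-normal is chosen
for positivity and because expression variation is multiplicative.

What the generator does *not* emulate: imaging artefacts, segmentation and
tracking errors, cell filamentation or growth arrest (and the exclusion
rules they trigger), mother-machine geometry, or division/partitioning
noise.  Passing recovery tests therefore demonstrate correctness of the
fitting machinery under the model's own noise assumptions, not robustness to
real microscopy pathologies.

## Problem sizes and numerical defaults

The shipped experiments and the acceptance script use: 16-cell stochastic
populations (the in-silico population size of the reference study); forcing
runs of 6–7 periods before release with ~10 h of post-release relaxation
(commitment takes 3–4 h); 500-run ensembles for stochastic/deterministic
consistency checks; 200×200 grids for averaged fields; and a 1200-evaluation
CMA-ES budget for the three-parameter recovery demonstration (a full
18-parameter fit needs a budget two orders of magnitude larger and
informative data in both switching directions).  Integration tolerances,
dedup/stability thresholds and the periodic-orbit convergence criterion are
as quoted above.

## Known limitations

* No bifurcation continuation; equilibrium structure is analysed pointwise
  in input space.
* The CTMC treats fluorescence a.u. as molecule counts; absolute noise
  magnitudes are therefore only as meaningful as that identification.
* Time-varying propensities are handled by freeze-and-recompute, not by
  exact time-inhomogeneous sampling.
* The symmetric exchange variant's `k_IPTG` and the heterogeneity/noise CVs
  are package choices (documented above), not fitted quantities.
* Controlling several cells at once is out of scope: the closed loop drives
  one cell; population experiments are open-loop (followers or forcing).
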
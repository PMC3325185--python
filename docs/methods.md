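# Methods

## Scope and model overview

`invadosim` models the turnover of the membrane-anchored protease
MT1-MMP at a single invadopodium and the extracellular-matrix (ECM)
degradation it drives, together with the TIMP-2/proMMP-2 biochemistry
that modulates it. The chain runs:

1. **FRAP phenomenology.** Fluorescence recovery after photobleaching
   of MT1-MMP at an invadopodium (lateral diffusion negligible) is a
   double exponential: fast time constant 26.0 s (amplitude 40.7% of
   the pre-bleach level), slow 259 s (17.5%), non-recovering level
   41.8%. Blocking the lysosomal delivery pathway (bafilomycin A1)
   abolishes the slow phase, leaving a single 49.0 s exponential.
2. **Two-pool turnover model.** Two surface pools explain the two
   phases: pool D (constant insertion flux `C_D`, first-order
   internalization `k_D = 1/26.0 s^-1`) and pool X (insertion limited
   by a finite number of docking sites of capacity `M_S`, constant
   internalization at steady state, recovery rate `k_X = 1/259 s^-1`).
   Bafilomycin is `k_X = 0`.
3. **Reaction network.** Surface MT1-MMP (M14) dimerizes, binds the
   inhibitor TIMP-2 (T2), the M14·T2 receptor binds proMMP-2 (M2)
   forming the quadruple complex M14·M14·T2·M2; a TIMP-2-free M14 in
   the same complex processes the proM2 and releases active MMP-2,
   which degrades ECM and is itself inactivated by T2. Any TIMP-2-free
   M14 also degrades ECM directly. All membrane species are inserted
   and internalized per their pool kinetics.
4. **Simulation and intervention.** The network is integrated
   well-mixed (fixed-step RK4) or on a 3D voxel grid
   (reaction-diffusion), and interventions divide the turnover rates
   and/or the MT1-MMP supply by a reduction factor, reading out the
   ECM half-degradation time τ_h and the degradation efficacy 1/τ_h
   normalized to control.

## Normalization of FRAP traces

Intensity is percent of the pre-bleach level. The three printed
quantities 40.7 + 17.5 + 41.8 sum to 100, so the generated control
curve starts at 0% and plateaus at 58.2%. The experimental narrative
(a drop to ~30% and recovery to ~65%) is not algebraically consistent
with that decomposition; the published normalization of the semi-log
analysis is unstated, and the package follows the printed
decomposition. Synthetic traces add homoscedastic Gaussian noise
(default sd 2% of pre-bleach — the smallest structure sufficient for
parameter-recovery testing; no noise model is published) on a 0–330 s
grid sampled every 3 s, with per-replicate streams spawned
deterministically from a master seed.

## Exponential-mixture fitting

`F(t) = P − Σ amp_i exp(−t/τ_i)` is fit by bounded trust-region least
squares (τ ∈ [0.5, 5000] s in log parameterization, amps ∈ [0, 150]%)
from 8 log-spaced multi-starts plus a seed from classical semi-log
curve peeling; the lowest-RSS solution wins. Exponential mixtures are
ill-conditioned, hence: (i) two-component fits with τ ratio < 2 are
collapsed to one component (identifiability guard); (ii) component
counts are compared by small-sample-corrected AIC on Gaussian
residuals; (iii) a constant trace returns a zero-amplitude fit rather
than raising. Curve peeling estimates the plateau by maximizing the
linearity (1 − R² of the log-residual tail) — minimizing absolute SSE
instead would reward overshooting the plateau into a flat tail.

A caveat quantified during development: with 20 replicates at sd 2%
over a 330 s window, the slow constant's maximum-likelihood estimate
has a heavy-tailed ~25% sampling spread (the RSS profile is nearly
flat between ~200 and ~450 s for unlucky noise draws). Reported
recovery numbers in `scripts/acceptance.py` are therefore medians over
21 independent repetitions of the same 20-trace experiment.

## Two-pool fluorescent-species dynamics

After the bleach the *total* pool occupancies are at steady state;
only the fluorescent (unbleached) fraction evolves. With docking-site
occupancy by bleached molecules at steady state the fluorescent system
is linear:

    dM_D/dt = C_D − k_D·M_D                  (pool D)
    dM_X/dt = k_X·(M_X∞ − M_X),  M_X∞ = M_S − C_X/k_X   (pool X)

giving the double exponential with time constants 1/k_D and 1/k_X.
This is the simplest algebraic form consistent with (a) the two-pool
scheme, (b) the 26.0/259 s decomposition, (c) bafilomycin ≡ k_X = 0
removing only the slow phase, and (d) the 2.31/min = 60/26.0
internalization rate. The derivative function is isolated so an
alternative published form can replace it in one place. Two known
tensions are resolved as follows: the docking-site limit is placed in
pool X (the scheme's reading) even though one text passage attaches
`M_S` to pool D; and the bafilomycin shift of the fast constant
(26.0 → 49.0 s, mechanism unknown) is not reproduced — the
reconstruction keeps the control fast constant, with a per-condition
`k_d_override` available for overlays.

`params_from_fit` maps a fit onto turnover parameters with
`M_S = 2 × (pool-X plateau)` (docking headroom 2, i.e. the steady
state occupies half the sites; any headroom > 1 reproduces the same
fluorescence curve, so this is a labelling convention, not a fit).

## Reaction-network generation

Species are generated, not hand-typed. A membrane complex is an
unordered multiset of up to `max_m14` M14 monomers (default 2 —
dimers; every multimer named in the source behaviours, including the
dimer-of-trimers M14·T2·M2·M14·T2·M2, contains two M14 monomers, and
caps of 3–4 are supported and tested), each monomer's catalytic site
free, T2-bound, T2·M2-bound, or ECM-engaged, the whole complex in pool
X or D. Canonical dotted names are order-invariant
(`M14_D.M14_D.T2.M2`). Reaction emission follows the binding rules
(dimerization, T2 binding, M2 binding, activation by a TIMP-2-free
neighbour, ECM engagement/proteolysis by T2-free M14 — channel
`k_fn11p` — and by active M2 — channel `k_fn2p` — M2 inactivation,
insertion, internalization of *every* membrane species) with
statistical multiplicity factors (number of equivalent sites).

Bookkeeping choices that make conservation exact by construction:
insertion draws monomers from an explicit vesicular reservoir species
(`M14_ves`, sized to outlast the run); internalized complexes are
inert per-species sinks; ECM engaged by an internalizing complex is
released intact. Every emitted reaction is checked against the four
monomer ledgers (M14, T2, M2, fn) at generation time, and simulations
re-check the ledgers along trajectories (tolerance 1e-6 relative;
observed drift is at round-off, ~1e-14).

Pool-X internalization is first-order per species with rate constant
`k_intX = 1/259 s^-1`: at steady state this equals the constant-flux
description, and the post-bleach fluorescent recovery rate is exactly
`k_intX`, which keeps the network consistent with the FRAP slow
constant. Pool X and pool D species degrade ECM with the same
catalytic constants.

## Well-mixed integration and readouts

The network compiles to flux arrays (mass action; a constant-flux law
for pool-D insertion; a `max(M_S − load, 0)` law for docking-limited
pool-X insertion) and a sparse stoichiometry matrix. The contract
integrator is fixed-step RK4 (default dt 0.05 s, output every 1 s)
with an optional step-halving convergence check (accepting a run when
halving dt changes final ECM remaining by < 1e-4 relative) and an
instability guard that reports the offending dt. `solve_ivp` (LSODA,
rtol 1e-8) serves as the independent cross-integrator oracle and as
the fast path for parameter sweeps; RK4 and LSODA agree to < 1e-4 on
the control scenario's ECM curve.

Membrane amounts are expressed as concentrations in the reaction
volume (single documented surface-to-volume convention), so all
species share µM units. Readouts: `ecm_remaining` = 1 − degraded/total
fn; `tau_half` = first, linearly interpolated crossing of 50% (an
infinity sentinel when never reached); `degradation_rate` = summed
flux through the `k_fn11p`/`k_fn2p` channels (µM/s);
`inactivated_mt1` = M14 monomers in membrane complexes whose every
catalytic site is T2-occupied.

## Rate-table calibration

The published supplementary rate table is not reproduced in the main
text, so the package ships a provenance-tagged "calibrated-default"
table (`invadosim.calibration`): FRAP-anchored turnover rates are
fixed (`k_D = 1/26.0`, `k_intX = 1/259 s^-1`), the docking capacity is
tied to the FRAP amplitude ratio (pool X : pool D steady states =
17.5 : 40.7), and eleven remaining constants (binding on/off rates,
activation, proteolysis, supply flux) plus the initial ECM amount are
optimized by bounded Nelder–Mead over log10 values against the
headline behaviours: complete ECM degradation (≤ 1% remaining) at
600 s in the control scenario at 180 nM TIMP-2; the TIMP-2 sweep's
peak MMP-2–ECM complex a strict maximum at 180 nM; factor-10
efficacies of 29.4% (turnover), 17.7% (concentration) and 2.30%
(both); and a blocked-transport stall surrogate (turnover switched off
around the equilibrated surface, TIMP-2 in the volume excess of the
reference spatial geometry: some early degradation, then no
appreciable progress between 500 and 2000 s). A published table is a
drop-in replacement (`RateTable.from_yaml`), which would turn these
calibration constraints into genuine reproduction tests.

The calibrated regime is mechanistically interpretable: TIMP-2 capture
of a surface protease takes tens of seconds — comparable to the 26 s
pool-D dwell time — so under control turnover most molecules degrade
ECM for most of their residence, and the finite TIMP-2 pool is slowly
titrated away by internalization of T2-bound protease. Slowing
turnover (longer dwell, same surface level) lets occupancy accumulate;
lowering supply slows both degradation and TIMP-2 removal. Reducing
both compounds the two effects super-multiplicatively, which is the
synergy the intervention analysis quantifies.

## Interventions and synergy

`apply_reduction` with factor f ≥ 1: *turnover* divides `k_D, k_intX,
k_insX, C_D` by f (steady-state surface levels provably unchanged;
tested by TIMP-2-free equilibration runs); *conc* divides the
vesicular supply handles `C_D` and `M_S` by f (surface re-equilibrates
at 1/f, rates untouched); *both* composes the two (so `C_D` scales by
1/f²). Efficacy is τ_h(control)/τ_h(case); a run that never crosses
50% gets efficacy 0 and a flag. The synergy index
`efficacy(both) / (efficacy(turnover)·efficacy(conc))` uses a
multiplicative (Bliss-style) null — the source describes the joint
effect only qualitatively ("nonlinearly large"), so the index
definition is this package's own, and values < 1 flag
super-multiplicative inhibition.

## Spatial model

Cubic voxels (default 1 µm; geometry fully configurable since the
published compartment sizes are supplement-only); the invadopodium
membrane patch is centred on the z = 0 face; the ECM substrate fills
the adjacent voxel layer(s); soluble species (T2, M2, active M2 and
its T2 complex) diffuse at 20 µm²/s (aqueous-protein order,
calibrated-default) with no-flux boundaries (closed chamber, so the
soluble ledgers stay testable). Diffusion is an explicit
forward-time central-space Laplacian evaluated inside the RK4 stage
derivatives (no operator splitting); the stability bound
dt < h²/(2·n_dim·D_max) is enforced, axes of extent 1 contributing no
diffusion. Insertion fluxes act only in membrane voxels and the
docking-site limit applies per voxel. With zero diffusion, uniform
fields and a full-face patch the spatial model reproduces the
well-mixed trajectory voxel-for-voxel to round-off — the module's
primary correctness oracle.

Default test grids are small (tens to hundreds of voxels) and runs are
minutes-long at most; these problem sizes are the package's chosen
desk scale, and the geometry/diffusion knobs accept larger scenarios.

## Numerical and degenerate-input policy

- RK4 states are clipped at 0 after each output step; a state more
  negative than round-off, or non-finite, aborts with dt advice.
- `tau_half` returns 0 if the trace starts at the threshold and the
  infinity sentinel if it never crosses.
- Sweeps and sensitivity scans record per-point failures and continue.
- The constant-insertion law gates on reservoir availability, so an
  exhausted reservoir stops insertion instead of going negative.
- Seeded generation is bit-reproducible; all pipeline randomness flows
  through manifest-recorded seeds.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis
assumes: exponential-mixture kinetics, additive homoscedastic Gaussian
noise, independent replicates on a fixed grid. It does not emulate the
imaging process (bleach-spot geometry, photophysics, continuous
bleaching of the surrounding region), correlated or multiplicative
noise, replicate-to-replicate kinetic heterogeneity, or baseline
drift. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to real
imaging artefacts. Likewise, the calibrated-default rate table makes
the simulation criteria self-consistency checks of the calibration,
not independent reproductions of the published simulations.

## Known limitations

- The exact published reaction list and rate values (supplementary
  table) are not available to this package; the generated network is a
  rule-based reconstruction with a calibrated-default parameterization.
- The calibration satisfies the control completion time, the turnover
  and joint efficacies, the TIMP-2 optimum and the stall behaviour
  simultaneously, but the concentration-mode efficacy at factor 10
  calibrates to ~0.14 rather than 0.177: in this network the
  concentration reduction is nearly self-similar (degradation and
  TIMP-2 removal both scale with supply, so τ_h scales almost
  proportionally), and the two sub-linearity mechanisms available
  (long-lived active MMP-2 accumulating over the longer horizon;
  enzyme-side ECM-engagement saturation) also inflate the turnover and
  joint efficacies. The acceptance test for that quantity documents
  the residual rather than widening its tolerance.
- Complexes are unordered multisets, so for caps > 2 chain topology is
  not distinguished.
- The bafilomycin fast-constant shift (26 → 49 s) is phenomenological
  and unmodelled.
- Stochastic (particle-level) kinetics and moving-boundary protrusion
  growth are out of scope.
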
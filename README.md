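# invadosim

Kinetic modelling of MT1-MMP turnover and extracellular-matrix (ECM)
degradation at invadopodia — the actin-rich membrane protrusions
through which invasive cancer cells focus proteolysis.

MT1-MMP, the membrane-anchored matrix metalloproteinase that drives
invadopodial ECM degradation, is continuously delivered to and removed
from the invadopodium surface by vesicle transport. This package is
for quantitative cell biologists and modellers who want to (i) extract
turnover rates from FRAP (fluorescence recovery after photobleaching)
experiments, (ii) reconstruct those recoveries mechanistically, and
(iii) ask, in silico, how much the turnover itself — as opposed to the
protease's catalytic activity or expression level — contributes to ECM
degradation, including screening combined interventions.

## The models

**FRAP decomposition.** A recovery curve is fit as an exponential
mixture `F(t) = P − Σᵢ ampᵢ·e^(−t/τᵢ)` (bounded trust-region least
squares with multi-start and semi-log curve-peeling seeds; component
count chosen by small-sample-corrected AIC). The control condition at
an invadopodium gives τ_fast = 26.0 s (amplitude 40.7% of pre-bleach),
τ_slow = 259 s (17.5%), non-recovering level 41.8%; blocking lysosomal
delivery (bafilomycin A1) leaves a single 49.0 s exponential.

**Two-pool turnover model.** Two surface pools carry the two phases —
pool D: constant insertion flux C_D, density-dependent internalization
k_D = 1/26.0 s⁻¹ (= 2.31 min⁻¹); pool X: insertion limited by a finite
number of docking sites (capacity M_S), recovery rate k_X = 1/259 s⁻¹.
The fluorescent-species dynamics are linear,

    dM_D/dt = C_D − k_D·M_D,      dM_X/dt = k_X·(M_X∞ − M_X),

and bafilomycin is k_X = 0.

**Reaction network and simulation.** Surface MT1-MMP (M14) dimerizes,
binds its inhibitor TIMP-2 (T2), recruits proMMP-2 (M2) into the
quadruple complex M14·M14·T2·M2 whose TIMP-2-free subunit releases
active MMP-2; both TIMP-2-free MT1-MMP and active MMP-2 degrade an
immobile fibronectin-like substrate (channels `k_fn11p`, `k_fn2p`),
and every membrane species is inserted/internalized by its pool's
kinetics. The species/reaction set is generated from binding rules
(not hand-typed) with per-reaction monomer-ledger checks, integrated
by fixed-step RK4 well-mixed or as a 3D voxel reaction-diffusion
model, and read out as ECM remaining, the half-degradation time τ_h,
degradation rate, and the inactivated (fully TIMP-2-occupied) MT1-MMP
pool. Interventions divide turnover rates and/or MT1-MMP supply by a
reduction factor; degradation efficacy is 1/τ_h normalized to control.

## Worked example

```python
import numpy as np
from invadosim import synthetic, frap, turnover

# 20 noisy control traces, fit the replicate mean
traces = synthetic.generate_dataset(
    20, ["control"], synthetic.NoiseSpec(sd=2.0, seed=42))
fit = frap.fit_exponential_mixture(synthetic.mean_trace(traces), 2)
print([round(t, 1) for t in fit.taus], [round(a, 1) for a in fit.amps])

params = turnover.params_from_fit(fit)
print(round(params.k_D * 60, 2), "per min")
```

prints

```
[26.2, 224.3] [40.2, 17.2]
2.29 per min
```

— the fitted fast/slow time constants (s) and amplitudes (% of
pre-bleach) recovered from the noisy synthetic data (truth 26.0/259 s,
40.7/17.5%; the slow constant is weakly identified by a single 330 s
window — see docs/methods.md), and the pool-D internalization rate in
min⁻¹. The degradation model runs the same way from the shell:

```bash
invadosim simulate -o run1/         # control scenario, 180 nM TIMP-2
invadosim intervene --factors 1,10 --t-end 750 -o efficacy.csv
```

The first command prints
`{"tau_half_s": 243.81..., "final_ecm_remaining": 0.0035...}` — the
control ECM half-degradation time (s) and the intact fraction left at
700 s. The second prints the per-(mode, factor) table: at reduction
factor 10 the degradation efficacies (1/τ_h relative to control) are
0.273 (turnover), 0.142 (concentration) and 0.025 (both), with synergy
index 0.645 — the joint reduction is super-multiplicative, the model's
central intervention result.

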
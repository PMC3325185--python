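"""Reduction-factor experiments: turnover rate, MT1-MMP level, and both.

* ``turnover`` — divide every turnover rate constant (k_D, k_intX,
  k_insX) and the constant pool-D flux C_D by the factor.  The
  steady-state surface amounts (C_D/k_D and M_S k_insX/(k_insX+k_intX))
  are unchanged: the surface protease level is held constant while
  molecules dwell longer, so TIMP-2 occupancy accumulates.
* ``conc`` — divide the vesicular supply (C_D and the docking capacity
  M_S) by the factor, leaving turnover rates untouched: the surface
  re-equilibrates at 1/factor of the control level.
* ``both`` — both transformations.

Degradation efficacy is 1/tau_h normalized to the control run; the
synergy index compares the joint reduction against the multiplicative
(Bliss-style) null built from the single-mode efficacies — an index
below 1 means super-multiplicative (synergistic) inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Sequence

import pandas as pd

from .network import RateTable, ReactionNetwork
from .wellmixed import (
    SimConfig,
    SimResult,
    TAU_HALF_SENTINEL,
    degradation_rate,
    inactivated_mt1,
    integrate,
    reference_solution,
    tau_half,
)

__all__ = [
    "MODES",
    "InterventionOutcome",
    "apply_reduction",
    "efficacy_curve",
    "synergy_index",
    "outcomes_to_frame",
]

MODES = ("turnover", "conc", "both")
TURNOVER_RATE_NAMES = ("k_D", "k_intX", "k_insX", "C_D")
CONC_RATE_NAMES = ("C_D", "M_S")


@dataclass(frozen=True)
class InterventionOutcome:
    """Result of one (mode, factor) run."""

    mode: str
    factor: float
    tau_half_s: float  # inf sentinel when the 50% crossing never happens
    efficacy: float  # tau_h(control) / tau_h(case); 0 for the sentinel
    degradation_rate_uM_per_s: float  # at the half-degradation timepoint
    inactivated_mt1_uM: float  # at the half-degradation timepoint
    no_crossing: bool = False


def apply_reduction(rates: RateTable, mode: str, factor: float) -> RateTable:
    """Transform a rate table by a reduction factor >= 1 (1 = identity)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if factor < 1:
        raise ValueError(
            "factor must be >= 1 (state an increase explicitly rather than "
            "passing a fractional reduction)"
        )
    if factor == 1:
        return rates
    out = rates
    if mode in ("turnover", "both"):
        # rates slow down; C_D co-scales so steady-state surface amounts
        # (C_D/k_D and M_S k_insX/(k_insX+k_intX)) are unchanged
        out = out.scaled(TURNOVER_RATE_NAMES, 1.0 / factor)
    if mode in ("conc", "both"):
        # vesicular supply and docking capacity shrink; in "both" this
        # composes with the turnover transformation (C_D ends up 1/f^2)
        out = out.scaled(CONC_RATE_NAMES, 1.0 / factor)
    return out


def _run(
    network: ReactionNetwork, config: SimConfig, method: str
) -> SimResult:
    if method == "reference":
        return reference_solution(network, config)
    return integrate(network, config)


def efficacy_curve(
    network: ReactionNetwork,
    config: SimConfig,
    modes: Sequence[str] = MODES,
    factors: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 20.0),
    method: str = "reference",
    horizon_scale: float = 3.0,
) -> list[InterventionOutcome]:
    """Run the well-mixed model per (mode, factor) and normalize 1/tau_h.

    ``factors`` must include 1 (the control anchor).  The simulated
    horizon grows with the factor (``horizon_scale * factor * t_end``)
    so slow runs still reach their 50% crossing; runs that never cross
    get efficacy 0 and the ``no_crossing`` flag.
    """
    factors = sorted(set(float(f) for f in factors))
    if 1.0 not in factors:
        raise ValueError("factors must include 1 (control anchor)")
    for m in modes:
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")

    control = _run(network, config, method)
    tau_control = tau_half(control)
    if not math.isfinite(tau_control):
        raise ValueError("control run never reaches 50% ECM degradation; cannot normalize")

    outcomes: list[InterventionOutcome] = []
    for mode in modes:
        for factor in factors:
            if factor == 1.0:
                res, tau = control, tau_control
            else:
                horizon = config.t_end_s * max(1.0, horizon_scale * factor)
                cfg = SimConfig(
                    **{
                        **config.__dict__,
                        "t_end_s": horizon,
                        "output_every_s": max(config.output_every_s, horizon / 4000.0),
                        "turnover_factor": factor if mode in ("turnover", "both") else 1.0,
                        "conc_factor": factor if mode in ("conc", "both") else 1.0,
                    }
                )
                res = _run(network, cfg, method)
                tau = tau_half(res)
            if math.isfinite(tau):
                t_probe = min(tau, res.times[-1])
                outcomes.append(
                    InterventionOutcome(
                        mode,
                        factor,
                        tau,
                        tau_control / tau if tau > 0 else math.inf,
                        degradation_rate(res, t_probe),
                        inactivated_mt1(res, t_probe),
                    )
                )
            else:
                outcomes.append(
                    InterventionOutcome(
                        mode, factor, TAU_HALF_SENTINEL, 0.0,
                        degradation_rate(res, res.times[-1]),
                        inactivated_mt1(res, res.times[-1]),
                        no_crossing=True,
                    )
                )
    return outcomes


def synergy_index(outcomes: Sequence[InterventionOutcome]) -> float:
    """efficacy(both) / (efficacy(turnover) * efficacy(conc)) at one factor.

    Values below 1 flag super-multiplicative (synergistic) inhibition
    relative to a Bliss-style multiplicative null.  Returns NaN when any
    single-mode efficacy is 0 (sentinel).
    """
    by_mode = {o.mode: o for o in outcomes}
    missing = set(MODES) - set(by_mode)
    if missing:
        raise ValueError(f"need outcomes for all of {MODES}; missing {sorted(missing)}")
    factors = {o.factor for o in outcomes}
    if len(factors) != 1:
        raise ValueError(f"outcomes must share one factor, got {sorted(factors)}")
    e_t, e_c, e_b = (by_mode[m].efficacy for m in MODES)
    if e_t == 0 or e_c == 0:
        return math.nan
    return e_b / (e_t * e_c)


def outcomes_to_frame(outcomes: Sequence[InterventionOutcome]) -> pd.DataFrame:
    df = pd.DataFrame([o.__dict__ for o in outcomes])
    # per-factor synergy where all three modes are present
    syn = {}
    for factor, grp in df.groupby("factor"):
        if set(grp["mode"]) >= set(MODES):
            sub = [o for o in outcomes if o.factor == factor]
            sub = [next(o for o in sub if o.mode == m) for m in MODES]
            syn[factor] = synergy_index(sub)
    df["synergy_index"] = df["factor"].map(syn)
    return df
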
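"""Well-mixed RK4 engine, scalar readouts, sweeps and sensitivities."""

import math

import numpy as np
import pytest

from invadosim import network as nw
from invadosim import wellmixed as wm


def tiny_network(reactions, extra_species=(), rates=None):
    """Minimal hand-built network around the fn / fn_deg pair."""
    species = [
        nw.SpeciesDef("fn", {"fn": 1}, "ecm"),
        nw.SpeciesDef("fn_deg", {"fn": 1}, "ecm", {"degraded": True}),
        *extra_species,
    ]
    return nw.ReactionNetwork(
        tuple(species),
        tuple(reactions),
        nw.BindingRules.none(),
        rates if rates is not None else nw.default_rate_table(),
        2,
    )


@pytest.fixture(scope="module")
def decay_network():
    k = math.log(2.0) / 100.0  # half-life exactly 100 s
    rxn = nw.ReactionDef(
        "r0001", (("fn", 1),), (("fn_deg", 1),), "k_fn11p", k
    )
    return tiny_network([rxn])


def short_cfg(**kw):
    base = dict(t_end_s=60.0, dt_s=0.05, output_every_s=1.0)
    base.update(kw)
    return wm.SimConfig(**base)


class TestIntegrate:
    def test_empty_reaction_set_keeps_state_constant(self):
        net = tiny_network([])
        cfg = short_cfg()
        res = wm.integrate(net, cfg, initial=np.array([1.5, 0.0]))
        assert np.all(res.concentrations == res.concentrations[0])

    def test_first_order_decay_matches_closed_form(self, decay_network):
        cfg = wm.SimConfig(t_end_s=400.0, dt_s=0.1, output_every_s=1.0)
        res = wm.integrate(decay_network, cfg, initial=np.array([1.0, 0.0]))
        k = math.log(2.0) / 100.0
        expected = np.exp(-k * res.times)
        assert np.abs(res.ecm_remaining - expected).max() < 1e-6

    def test_step_halving_convergence_contract(self, decay_network):
        cfg = wm.SimConfig(t_end_s=200.0, dt_s=0.5, output_every_s=10.0)
        res = wm.integrate(
            decay_network, cfg, initial=np.array([1.0, 0.0]), check_convergence=True
        )
        assert res.ecm_remaining[-1] == pytest.approx(
            math.exp(-math.log(2.0) * 2.0), rel=1e-6
        )

    def test_instability_raises_with_dt_advice(self):
        # a fast reaction at a large step drives the state negative
        rxn = nw.ReactionDef("r0001", (("fn", 1),), (("fn_deg", 1),), "k_fn11p", 5.0)
        net = tiny_network([rxn])
        cfg = wm.SimConfig(t_end_s=10.0, dt_s=2.0, output_every_s=2.0)
        with pytest.raises(ValueError, match="dt_s"):
            wm.integrate(net, cfg, initial=np.array([1.0, 0.0]))

    def test_negative_initial_rejected(self, decay_network):
        with pytest.raises(ValueError):
            wm.integrate(decay_network, short_cfg(), initial=np.array([-1.0, 0.0]))

    def test_default_scenario_conserves_monomer_ledgers(self, default_network):
        res = wm.integrate(default_network, short_cfg(t_end_s=120.0))
        totals = res.ledger_totals()
        drift = np.abs(totals - totals[0]).max(axis=0)
        scale = np.maximum(np.abs(totals[0]), 1e-12)
        assert np.all(drift / scale < 1e-6)

    def test_concentrations_stay_non_negative(self, default_network):
        res = wm.integrate(default_network, short_cfg(t_end_s=120.0))
        assert res.concentrations.min() >= 0.0

    def test_rk4_matches_stiff_reference_integrator(self, default_network):
        cfg = short_cfg(t_end_s=150.0)
        rk4 = wm.integrate(default_network, cfg)
        ref = wm.reference_solution(default_network, cfg)
        assert np.abs(rk4.ecm_remaining - ref.ecm_remaining).max() < 1e-4


class TestTauHalf:
    def test_exponential_half_life(self, decay_network):
        cfg = wm.SimConfig(t_end_s=300.0, dt_s=0.1, output_every_s=1.0)
        res = wm.integrate(decay_network, cfg, initial=np.array([1.0, 0.0]))
        assert wm.tau_half(res) == pytest.approx(100.0, rel=1e-5)

    def test_sentinel_when_no_crossing(self, decay_network):
        cfg = wm.SimConfig(t_end_s=30.0, dt_s=0.1, output_every_s=1.0)
        res = wm.integrate(decay_network, cfg, initial=np.array([1.0, 0.0]))
        assert wm.tau_half(res) == math.inf

    def test_zero_when_starting_at_threshold(self, decay_network):
        res = wm.integrate(
            decay_network, short_cfg(), initial=np.array([0.5, 0.5])
        )
        assert wm.tau_half(res) == 0.0


class TestReadouts:
    def test_zero_degradation_constants_give_zero_rate(self, default_network):
        rates = default_network.rates.with_values(k_fn11p=0.0, k_fn2p=0.0)
        net = default_network.with_rates(rates)
        res = wm.integrate(net, short_cfg())
        assert np.all(res.degradation_rate_series == 0.0)
        assert res.ecm_remaining[-1] == pytest.approx(1.0)

    def test_single_channel_rate_equals_k_times_complex(self, decay_network):
        cfg = short_cfg()
        res = wm.integrate(decay_network, cfg, initial=np.array([1.0, 0.0]))
        k = math.log(2.0) / 100.0
        np.testing.assert_allclose(
            res.degradation_rate_series, k * res.conc("fn"), rtol=1e-12
        )

    def test_rate_integral_equals_degraded_amount(self, default_network):
        res = wm.integrate(default_network, short_cfg(t_end_s=150.0))
        integral = np.trapezoid(res.degradation_rate_series, res.times)
        degraded = res.fn_total_initial * (1.0 - res.ecm_remaining[-1])
        # tolerance set by trapezoid quadrature on the 1 s output grid
        assert integral == pytest.approx(degraded, rel=5e-3)

    def test_inactivated_mt1_zero_without_timp2(self, default_network):
        res = wm.integrate(
            default_network, short_cfg(timp2_initial_nM=0.0, t_end_s=60.0)
        )
        assert np.all(res.inactivated_mt1_series == 0.0)

    def test_inactivated_mt1_counts_fully_occupied_monomers(self, default_network):
        idx = default_network.species_index()
        c0 = np.zeros(len(default_network.species))
        c0[idx["M14_D.T2"]] = 0.3  # 1 monomer, fully occupied
        c0[idx["M14_D.T2.M14_D.T2"]] = 0.1  # 2 monomers, fully occupied
        c0[idx["M14_D.M14_D.T2"]] = 0.2  # has a free site: not inactivated
        res = wm.integrate(
            default_network, wm.SimConfig(t_end_s=1.0, dt_s=0.005, output_every_s=1.0),
            initial=c0,
        )
        assert wm.inactivated_mt1(res, 0.0) == pytest.approx(0.3 + 2 * 0.1)

    def test_out_of_range_time_rejected(self, default_network):
        res = wm.integrate(default_network, short_cfg())
        with pytest.raises(ValueError):
            wm.degradation_rate(res, 1e5)


@pytest.fixture(scope="module")
def sweep(default_network):
    return wm.timp2_sweep(
        default_network, [0.0, 60.0, 120.0, 180.0, 240.0, 360.0, 540.0],
        t_end_s=650.0,
    )


class TestSweep:
    def test_no_timp2_means_no_mmp2_ecm_complex(self, sweep):
        row = sweep[sweep.timp2_nM == 0.0].iloc[0]
        assert row.peak_m2_ecm_uM == 0.0

    def test_mt1_ecm_maximal_without_timp2_and_decreasing(self, sweep):
        vals = sweep.peak_m14_ecm_uM.to_numpy()
        assert vals.argmax() == 0
        assert np.all(np.diff(vals) <= 1e-12)

    def test_mmp2_ecm_readout_is_unimodal(self, sweep):
        vals = sweep.peak_m2_ecm_uM.to_numpy()
        peak = vals.argmax()
        assert np.all(np.diff(vals[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(vals[peak:]) <= 1e-15)

    def test_empty_grid_rejected(self, default_network):
        with pytest.raises(ValueError):
            wm.timp2_sweep(default_network, [])


class TestSensitivity:
    def test_zero_flux_parameter_has_zero_sensitivity(self, default_network):
        # without proMMP-2 there is no flux through the MMP-2 proteolysis channel
        cfg = short_cfg(t_end_s=500.0, m2_initial_uM=0.0)
        df = wm.sensitivity_scan(
            default_network, cfg, ["k_fn2p", "k_fn11p"], perturbation=0.2
        )
        row = df[df.parameter == "k_fn2p"].iloc[0]
        assert row.sensitivity == pytest.approx(0.0, abs=1e-6)

    def test_monotone_parameter_gives_opposite_signed_shifts(self, default_network):
        cfg = short_cfg(t_end_s=900.0)
        df = wm.sensitivity_scan(default_network, cfg, ["k_fn11p"], perturbation=0.3)
        row = df.iloc[0]
        assert row.rel_dtau_up * row.rel_dtau_down < 0
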
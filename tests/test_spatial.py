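"""3D reaction-diffusion engine: oracles, conservation, stability."""

import math

import numpy as np
import pytest

from invadosim import network as nw
from invadosim import spatial as sp
from invadosim import wellmixed as wm

ZERO_DIFFUSION = {k: 0.0 for k in ["T2", "M2", "M2_act", "M2_act.T2"]}


def cfg(**kw):
    base = dict(t_end_s=40.0, dt_s=0.008, output_every_s=5.0)
    base.update(kw)
    return wm.SimConfig(**base)


class TestBuildGrid:
    def test_patch_larger_than_face_rejected(self, default_network):
        spec = sp.GridSpec(shape=(2, 2, 2), patch_shape=(3, 3))
        with pytest.raises(ValueError):
            sp.build_grid(spec, default_network)

    def test_membrane_confined_to_one_face(self, default_network):
        grid = sp.build_grid(sp.GridSpec(shape=(4, 4, 3), patch_shape=(2, 2)),
                             default_network)
        assert grid.membrane_mask[:, :, 1:].sum() == 0
        assert grid.membrane_mask[:, :, 0].sum() == 4

    def test_initial_fn_total_is_per_voxel_times_layer_count(self, default_network):
        spec = sp.GridSpec(shape=(3, 3, 4), patch_shape=(2, 2), ecm_layers=2)
        grid = sp.build_grid(spec, default_network)
        compiled = wm.compile_network(default_network)
        state = sp._initial_fields(compiled, grid, cfg(fn_initial_uM=1.5))
        fn_idx = default_network.species_index()["fn"]
        assert state[fn_idx].sum() == pytest.approx(1.5 * 3 * 3 * 2)

    def test_immobile_species_cannot_be_given_diffusion(self, default_network):
        spec = sp.GridSpec(diffusion={"M14_D": 5.0})
        with pytest.raises(ValueError):
            sp.build_grid(spec, default_network)


class TestWellMixedEquivalence:
    def test_single_voxel_grid_collapses_to_well_mixed(self, default_network):
        run_cfg = cfg(t_end_s=60.0, dt_s=0.02)
        grid = sp.build_grid(
            sp.GridSpec(shape=(1, 1, 1), patch_shape=None, ecm_layers=1),
            default_network,
        )
        res = sp.run_spatiotemporal(grid, default_network, run_cfg)
        mixed = wm.integrate(default_network, run_cfg)
        assert np.abs(res.ecm_remaining - mixed.ecm_remaining).max() < 1e-6

    def test_zero_diffusion_uniform_fields_match_well_mixed_per_voxel(
        self, default_network
    ):
        run_cfg = cfg(t_end_s=60.0, dt_s=0.02)
        grid = sp.build_grid(
            sp.GridSpec(shape=(3, 3, 1), patch_shape=None, ecm_layers=1,
                        diffusion=ZERO_DIFFUSION),
            default_network,
        )
        res = sp.run_spatiotemporal(
            grid, default_network, run_cfg, snapshot_every_s=60.0
        )
        mixed = wm.integrate(default_network, run_cfg)
        assert np.abs(res.ecm_remaining - mixed.ecm_remaining).max() < 1e-6
        # every voxel individually matches the well-mixed end state
        final = res.snapshots[-1]
        for i, sid in enumerate(res.species_ids):
            np.testing.assert_allclose(
                final[i], mixed.concentrations[-1, i], rtol=1e-6, atol=1e-12
            )


class TestDiffusionOperator:
    def test_diffusion_alone_conserves_mass_and_flattens(self, default_network):
        # no reactions: drop them but keep the species set
        bare = nw.ReactionNetwork(
            default_network.species, (), default_network.rules,
            default_network.rates, default_network.max_m14,
        )
        grid = sp.build_grid(sp.GridSpec(shape=(4, 3, 3)), bare)
        compiled = wm.compile_network(bare)
        state = sp._initial_fields(compiled, grid, cfg())
        t2 = bare.species_index()["T2"]
        state[t2] = 0.0
        state[t2][0, 0, 0] = 1.0  # point source
        res = sp.run_spatiotemporal(
            grid, bare, cfg(t_end_s=2.0, dt_s=0.005, output_every_s=0.5),
            initial=state, snapshot_every_s=2.0,
        )
        field = res.snapshots[-1][t2]
        assert field.sum() == pytest.approx(1.0, rel=1e-12)  # no-flux boundaries
        assert field.std() < 0.25 * 1.0 / 36  # spreading towards uniformity

    def test_mirrored_patch_gives_mirrored_fields(self, default_network):
        spec = sp.GridSpec(shape=(4, 3, 2), patch_shape=(2, 3), ecm_layers=1)
        grid = sp.build_grid(spec, default_network)
        # off-centre patch and its mirror image along x
        mask = np.zeros(spec.shape, dtype=bool)
        mask[0:2, :, 0] = True
        g1 = sp.SpatialGrid(spec.shape, 1.0, mask, grid.ecm_mask, grid.diffusion)
        g2 = sp.SpatialGrid(
            spec.shape, 1.0, mask[::-1].copy(), grid.ecm_mask, grid.diffusion
        )
        run_cfg = cfg(t_end_s=10.0, output_every_s=10.0)
        r1 = sp.run_spatiotemporal(g1, default_network, run_cfg, snapshot_every_s=10.0)
        r2 = sp.run_spatiotemporal(g2, default_network, run_cfg, snapshot_every_s=10.0)
        np.testing.assert_allclose(
            r1.snapshots[-1], r2.snapshots[-1][:, ::-1], rtol=1e-10, atol=1e-15
        )

    def test_stability_bound_enforced(self, default_network):
        grid = sp.build_grid(sp.GridSpec(shape=(3, 3, 3)), default_network)
        bad = wm.SimConfig(t_end_s=1.0, dt_s=10 * grid.max_stable_dt())
        with pytest.raises(ValueError, match="stability"):
            sp.run_spatiotemporal(grid, default_network, bad)


class TestConservationAndTau:
    def test_ledgers_conserved_with_diffusion(self, default_network):
        grid = sp.build_grid(sp.GridSpec(shape=(3, 3, 3)), default_network)
        res = sp.run_spatiotemporal(grid, default_network, cfg(t_end_s=20.0))
        drift = np.abs(res.ledger_totals - res.ledger_totals[0]).max(axis=0)
        scale = np.maximum(np.abs(res.ledger_totals[0]), 1e-12)
        assert np.all(drift / scale < 1e-6)

    def test_spatial_tau_half_matches_well_mixed_in_uniform_limit(
        self, default_network
    ):
        run_cfg = cfg(t_end_s=400.0, dt_s=0.05, output_every_s=2.0)
        grid = sp.build_grid(
            sp.GridSpec(shape=(2, 2, 1), patch_shape=None, ecm_layers=1,
                        diffusion=ZERO_DIFFUSION),
            default_network,
        )
        res = sp.run_spatiotemporal(grid, default_network, run_cfg)
        mixed = wm.integrate(default_network, run_cfg)
        t_spatial = sp.spatial_tau_half(res)
        t_mixed = wm.tau_half(mixed)
        if math.isinf(t_mixed):
            assert math.isinf(t_spatial)
        else:
            assert t_spatial == pytest.approx(t_mixed, rel=1e-6)

    def test_sentinel_when_no_crossing(self, default_network):
        grid = sp.build_grid(sp.GridSpec(shape=(2, 2, 2)), default_network)
        rates = default_network.rates.with_values(k_fn11p=0.0, k_fn2p=0.0)
        net = default_network.with_rates(rates)
        res = sp.run_spatiotemporal(grid, net, cfg(t_end_s=10.0))
        assert sp.spatial_tau_half(res) == math.inf


def test_snapshot_hdf5_round_trip(tmp_path, default_network):
    import h5py

    grid = sp.build_grid(sp.GridSpec(shape=(2, 2, 2)), default_network)
    res = sp.run_spatiotemporal(
        grid, default_network, cfg(t_end_s=2.0, output_every_s=1.0),
        snapshot_every_s=1.0,
    )
    path = tmp_path / "fields.h5"
    sp.save_snapshots_h5(res, path)
    with h5py.File(path) as fh:
        assert fh["fields"].shape[1] == len(default_network.species)
        assert fh.attrs["voxel_size_um"] == 1.0


class TestGridRefinement:
    def test_global_ecm_converges_under_voxel_halving(self, default_network):
        # the volumetric pathway (active MMP-2 diffusing into a fixed-depth
        # ECM layer) has a well-defined continuum limit; contact proteolysis
        # by membrane enzyme is pinned to the boundary layer by the model's
        # compartment convention and is switched off here
        rates = default_network.rates.with_values(C_D=0.0, k_insX=0.0)
        net = default_network.with_rates(rates)

        def run(shape, voxel, ecm_layers, dt):
            spec = sp.GridSpec(
                shape=shape, voxel_size_um=voxel, patch_shape=None,
                ecm_layers=ecm_layers,
                diffusion={"T2": 2.0, "M2": 2.0, "M2_act": 2.0, "M2_act.T2": 2.0},
            )
            grid = sp.build_grid(spec, net)
            cfg = wm.SimConfig(
                dt_s=dt, t_end_s=30.0, output_every_s=10.0,
                preequilibrate_surface=False,
                extra_initial={"M2_act": 0.3},
            )
            return sp.run_spatiotemporal(grid, net, cfg)

        # same physical domain (2x2x2 um) and same 1 um ECM layer
        coarse = run((2, 2, 2), 1.0, 1, 0.02)
        fine = run((4, 4, 4), 0.5, 2, 0.005)
        assert coarse.ecm_remaining[-1] == pytest.approx(
            fine.ecm_remaining[-1], rel=0.01
        )
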
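"""3D compartmental reaction-diffusion version of the model.

The extracellular space is divided into cubic voxels.  Membrane species
live on an invadopodium patch on one boundary face (z = 0) and do not
diffuse; soluble species (TIMP-2, proMMP-2, active MMP-2 and its
complexes) diffuse with an explicit forward-time central-space
discrete Laplacian under no-flux (closed-chamber) boundaries; the ECM
substrate is an immobile field in the voxel layers adjacent to the
membrane.  Reactions run per voxel with the same compiled network as
the well-mixed engine, inside the same fixed-step RK4 loop, so a
uniform zero-diffusion configuration with a full-face membrane patch
reproduces the well-mixed solution voxel-by-voxel — the module's
primary correctness oracle.

The explicit scheme requires dt < h^2 / (2 n_dim D_max); the stability
bound is enforced and reported when violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Mapping

import numpy as np

from .network import ReactionNetwork, SP_FN, SP_M2, SP_M2A, SP_M2A_T2, SP_T2
from .wellmixed import (
    CompiledNetwork,
    SimConfig,
    compile_network,
    default_initial_concentrations,
)

__all__ = [
    "GridSpec",
    "SpatialGrid",
    "SpatialResult",
    "build_grid",
    "run_spatiotemporal",
    "spatial_tau_half",
    "save_snapshots_h5",
]

#: aqueous-protein diffusion, calibrated-default (um^2/s)
DEFAULT_DIFFUSION_UM2_S = 20.0

#: membrane quantities (initial pools, insertion fluxes, docking capacity)
#: are defined as concentrations in a boundary layer of this reference
#: thickness; other voxel sizes rescale them to keep the areal density
#: of surface protease invariant under grid refinement
REFERENCE_MEMBRANE_THICKNESS_UM = 1.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry request for :func:`build_grid`.

    ``patch_shape`` is the (nx, ny) extent of the invadopodium membrane
    patch centred on the z = 0 face; ``ecm_layers`` is the number of
    voxel layers adjacent to that face holding the immobile ECM
    substrate.  ``diffusion`` overrides per-species coefficients
    (um^2/s); species not listed get the soluble default if they are
    extracellular and 0 otherwise.
    """

    shape: tuple[int, int, int] = (4, 4, 4)
    voxel_size_um: float = 1.0
    patch_shape: tuple[int, int] | None = (2, 2)
    ecm_layers: int = 1
    diffusion: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.ecm_layers < 0 or self.ecm_layers > self.shape[2]:
            raise ValueError("ecm_layers must be within the grid depth")


@dataclass(frozen=True)
class SpatialGrid:
    """Realized grid: membrane mask, ECM mask and diffusion map."""

    shape: tuple[int, int, int]
    voxel_size_um: float
    membrane_mask: np.ndarray  # (nx, ny, nz) bool, confined to z = 0
    ecm_mask: np.ndarray  # (nx, ny, nz) bool
    diffusion: dict[str, float]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def max_stable_dt(self) -> float:
        """Explicit-scheme bound dt < h^2 / (2 n_dim D_max).

        Axes of extent 1 contribute no diffusion; a single-voxel grid
        has no bound at all.
        """
        d_max = max(self.diffusion.values(), default=0.0)
        n_dim = sum(1 for n in self.shape if n > 1)
        if d_max == 0 or n_dim == 0:
            return math.inf
        return self.voxel_size_um**2 / (2.0 * n_dim * d_max)


def build_grid(spec: GridSpec, network: ReactionNetwork) -> SpatialGrid:
    """Construct the voxel grid for a network.

    The membrane patch sits centred on the z = 0 face; a ``patch_shape``
    of None covers the whole face.  Soluble extracellular species get
    the default diffusion coefficient unless overridden; membrane,
    internalized, vesicular and ECM-bound species are immobile.
    """
    nx, ny, nz = spec.shape
    patch = spec.patch_shape or (nx, ny)
    if patch[0] > nx or patch[1] > ny:
        raise ValueError(f"membrane patch {patch} larger than the {nx}x{ny} face")
    membrane = np.zeros(spec.shape, dtype=bool)
    x0 = (nx - patch[0]) // 2
    y0 = (ny - patch[1]) // 2
    membrane[x0 : x0 + patch[0], y0 : y0 + patch[1], 0] = True
    ecm = np.zeros(spec.shape, dtype=bool)
    ecm[:, :, : spec.ecm_layers] = True

    mobile_default = {SP_T2, SP_M2, SP_M2A, SP_M2A_T2}
    diffusion: dict[str, float] = {}
    for sp in network.species:
        if sp.id in spec.diffusion:
            d = float(spec.diffusion[sp.id])
        elif sp.id in mobile_default:
            d = DEFAULT_DIFFUSION_UM2_S
        else:
            d = 0.0
        if d < 0:
            raise ValueError(f"diffusion for {sp.id} must be >= 0")
        if d > 0 and (sp.is_membrane or sp.compartment in ("internalized", "vesicular")):
            raise ValueError(f"membrane/internalized species {sp.id} cannot diffuse")
        diffusion[sp.id] = d
    return SpatialGrid(spec.shape, spec.voxel_size_um, membrane, ecm, diffusion)


@dataclass
class SpatialResult:
    """Global readout series plus optional field snapshots."""

    times: np.ndarray
    ecm_remaining: np.ndarray  # volume-integrated intact fraction
    ledger_totals: np.ndarray  # (n_times, 4) M14/T2/M2/fn monomer totals
    snapshot_times: np.ndarray
    snapshots: np.ndarray | None  # (n_snap, n_species, nx, ny, nz)
    species_ids: list[str]
    grid: SpatialGrid

    def final_field(self, species_id: str) -> np.ndarray:
        if self.snapshots is None:
            raise ValueError("run was configured without snapshots")
        return self.snapshots[-1, self.species_ids.index(species_id)]


def _laplacian_inplace(c: np.ndarray, out: np.ndarray) -> None:
    """Discrete 6-neighbour Laplacian with no-flux (reflecting) boundaries."""
    out[...] = -6.0 * c
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, 1)
        hi[axis] = slice(-1, None)
        shifted_f = np.concatenate([c[tuple(lo)], c], axis=axis)
        shifted_b = np.concatenate([c, c[tuple(hi)]], axis=axis)
        sl_f = [slice(None)] * 3
        sl_f[axis] = slice(0, c.shape[axis])
        sl_b = [slice(None)] * 3
        sl_b[axis] = slice(1, None)
        out += shifted_f[tuple(sl_f)] + shifted_b[tuple(sl_b)]


def _initial_fields(
    compiled: CompiledNetwork,
    grid: SpatialGrid,
    config: SimConfig,
) -> np.ndarray:
    """Uniform soluble fields, ECM layer, membrane pools on the patch.

    The well-mixed initial amounts are placed so that voxel
    concentrations are uniform for soluble species; membrane and
    reservoir amounts are confined to the patch at the same per-voxel
    concentration the well-mixed model uses (membrane quantities are
    per-voxel concentrations of the boundary compartment).
    """
    network = compiled.network
    c0_mixed = default_initial_concentrations(network, config)
    n_sp = len(network.species)
    state = np.zeros((n_sp,) + grid.shape)
    idx = network.species_index()
    membrane_like = {
        i
        for i, sp in enumerate(network.species)
        if sp.is_membrane or sp.compartment in ("internalized", "vesicular")
    }
    mem_scale = REFERENCE_MEMBRANE_THICKNESS_UM / grid.voxel_size_um
    fn_i = idx[SP_FN]
    for i in range(n_sp):
        if i == fn_i:
            state[i][grid.ecm_mask] = c0_mixed[i]
        elif i in membrane_like:
            state[i][grid.membrane_mask] = c0_mixed[i] * mem_scale
        else:
            state[i] += c0_mixed[i]
    return state


def run_spatiotemporal(
    grid: SpatialGrid,
    network: ReactionNetwork,
    config: SimConfig,
    initial: np.ndarray | None = None,
    snapshot_every_s: float | None = None,
) -> SpatialResult:
    """Reaction-diffusion integration (RK4 with in-step explicit diffusion).

    Raises when ``config.dt_s`` violates the diffusion stability bound,
    reporting the maximal admissible step.  Turnover insertion fluxes
    act only in membrane voxels; the docking-site limit applies per
    voxel.
    """
    from .wellmixed import _intervened_network  # shared intervention plumbing

    network = _intervened_network(network, config)
    compiled = compile_network(network)
    dt_max = grid.max_stable_dt()
    if config.dt_s >= dt_max:
        raise ValueError(
            f"dt_s={config.dt_s} violates the explicit-diffusion stability "
            f"bound; use dt_s < {dt_max:.6g} s"
        )
    state = (
        np.array(initial, dtype=float)
        if initial is not None
        else _initial_fields(compiled, grid, config)
    )
    n_sp = len(network.species)
    if state.shape != (n_sp,) + grid.shape:
        raise ValueError("initial state has wrong shape")

    ids = network.species_ids
    d_over_h2 = np.array([grid.diffusion[i] for i in ids]) / grid.voxel_size_um**2
    mobile = np.nonzero(d_over_h2 > 0)[0]
    membrane_flat = grid.membrane_mask.ravel()
    nvox = grid.n_voxels

    r1, r2 = compiled.r1, compiled.r2
    mem_scale = REFERENCE_MEMBRANE_THICKNESS_UM / grid.voxel_size_um
    keff = compiled.keff.copy()
    keff[compiled.const_mask] *= mem_scale  # insertion flux per membrane voxel
    ma = compiled.mass_action
    const_mask = compiled.const_mask
    sites_mask = compiled.sites_mask
    stoich = compiled.stoich
    x_load = compiled.x_load
    m_s = compiled.m_s * mem_scale  # docking capacity per membrane voxel
    n_rx = keff.size
    lap = np.empty(grid.shape)

    def rhs(y_flat: np.ndarray) -> np.ndarray:
        c = y_flat  # (n_sp, nvox)
        f = np.zeros((n_rx, nvox))
        f[ma] = keff[ma, None]
        has_r1 = ma & (r1 >= 0)
        f[has_r1] *= c[r1[has_r1]]
        has_r2 = ma & (r2 >= 0)
        f[has_r2] *= c[r2[has_r2]]
        if const_mask.any():
            f[const_mask] = (
                keff[const_mask, None]
                * (c[r1[const_mask]] > 0)
                * membrane_flat[None, :]
            )
        if sites_mask.any():
            free_sites = np.clip(m_s - x_load @ c, 0.0, None)
            f[sites_mask] = (
                keff[sites_mask, None]
                * free_sites[None, :]
                * (c[r1[sites_mask]] > 0)
                * membrane_flat[None, :]
            )
        dy = stoich @ f
        for i in mobile:
            _laplacian_inplace(c[i].reshape(grid.shape), lap)
            dy[i] += d_over_h2[i] * lap.ravel()
        return dy

    out_every = config.output_every_s
    n_out = int(round(config.t_end_s / out_every))
    out_times = np.arange(n_out + 1) * out_every
    snap_times = (
        np.arange(0, config.t_end_s + 1e-9, snapshot_every_s)
        if snapshot_every_s
        else np.array([0.0, config.t_end_s])
    )
    want_snaps = snapshot_every_s is not None

    y = state.reshape(n_sp, nvox)
    fn0_total = float((state * compiled.ledger[3][:, None, None, None]).sum())
    deg_i = network.species_index()["fn_deg"]
    ecm_series = np.empty(out_times.size)
    ledger_series = np.empty((out_times.size, 4))
    snaps = [] if want_snaps else None
    snap_idx = 0

    t_now = 0.0
    for i, t_target in enumerate(out_times):
        span = t_target - t_now
        if span > 0:
            n_sub = max(1, int(math.ceil(span / config.dt_s - 1e-12)))
            h = span / n_sub
            for _ in range(n_sub):
                k1 = rhs(y)
                k2 = rhs(y + 0.5 * h * k1)
                k3 = rhs(y + 0.5 * h * k2)
                k4 = rhs(y + h * k3)
                y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(y)):
                raise ValueError(
                    f"non-finite field near t={t_target:.3g}s; reduce dt_s"
                )
            np.clip(y, 0.0, None, out=y)
            t_now = t_target
        ecm_series[i] = 1.0 - y[deg_i].sum() / max(fn0_total, 1e-300)
        ledger_series[i] = compiled.ledger @ y.sum(axis=1)
        if want_snaps and snap_idx < snap_times.size and t_target >= snap_times[snap_idx] - 1e-9:
            snaps.append(y.reshape((n_sp,) + grid.shape).copy())
            snap_idx += 1
    return SpatialResult(
        times=out_times,
        ecm_remaining=ecm_series,
        ledger_totals=ledger_series,
        snapshot_times=snap_times[: len(snaps)] if want_snaps else np.array([]),
        snapshots=np.array(snaps) if want_snaps else None,
        species_ids=ids,
        grid=grid,
    )


def spatial_tau_half(result: SpatialResult, threshold: float = 0.5) -> float:
    """Half-degradation time of the volume-integrated ECM (inf sentinel)."""
    rem = result.ecm_remaining
    t = result.times
    below = np.nonzero(rem <= threshold)[0]
    if below.size == 0:
        return math.inf
    i = int(below[0])
    if i == 0:
        return 0.0
    frac = (rem[i - 1] - threshold) / (rem[i - 1] - rem[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def save_snapshots_h5(result: SpatialResult, path) -> None:
    """Write field snapshots as HDF5 (datasets: species x t x x x y x z)."""
    import h5py

    if result.snapshots is None:
        raise ValueError("run was configured without snapshots")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times_s", data=result.snapshot_times)
        fh.create_dataset("fields", data=result.snapshots)
        fh.attrs["species_ids"] = [s.encode() for s in result.species_ids]
        fh.attrs["voxel_size_um"] = result.grid.voxel_size_um
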
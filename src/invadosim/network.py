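"""Rule-based MT1-MMP / TIMP-2 / proMMP-2 reaction network with ECM proteolysis.

Molecules (field shorthand): M14 = MT1-MMP (membrane protease), T2 =
TIMP-2 (inhibitor), M2 = proMMP-2 / MMP-2 (soluble gelatinase), fn =
fibronectin-like immobile ECM substrate.

A membrane complex is a multimer of M14 monomers (up to ``max_m14``),
each monomer's catalytic site in one of four states: free (``0``),
TIMP-2-bound (``T``), TIMP-2·proMMP-2-bound (``TM``), or engaged with
ECM (``F``).  Complexes live in surface pool X (docking-site-limited
insertion, constant internalization) or pool D (constant insertion,
first-order internalization).  The generator enumerates every complex
reachable under the binding rules and emits the full mass-action
reaction set:

* M14 oligomerization (within a pool);
* T2 binding/unbinding at free catalytic sites;
* proMMP-2 binding to complex-bound T2, completing the quadruple
  complex M14.M14.T2.M2;
* proMMP-2 activation: a TIMP-2-free M14 in the same complex processes
  the bound proM2, releasing active MMP-2;
* inactivation of active MMP-2 by T2;
* ECM engagement and proteolysis by any TIMP-2-free M14 (channel
  ``k_fn11p``) and by active MMP-2 (channel ``k_fn2p``);
* insertion and internalization of every membrane species (TIMP-2-bound
  or not), with internalized complexes as inert sinks and insertion
  drawing on an explicit vesicular reservoir so that all four monomer
  ledgers (M14, T2, M2, fn) are conserved by construction.

Rate constants carry a provenance tag (``supplementary`` when taken
from a published table, ``calibrated-default`` for the shipped set
produced by :mod:`invadosim.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_FREE",
    "STATE_T2",
    "STATE_T2M2",
    "STATE_FN",
    "BindingRules",
    "SpeciesDef",
    "ReactionDef",
    "RateTable",
    "ReactionNetwork",
    "default_rate_table",
    "enumerate_species",
    "generate_reactions",
    "build_network",
    "export_network",
    "import_network_tsv",
    "reachable_species",
]

STATE_FREE = "0"
STATE_T2 = "T"
STATE_T2M2 = "TM"
STATE_FN = "F"
_STATE_RANK = {STATE_FREE: 0, STATE_T2: 1, STATE_T2M2: 2, STATE_FN: 3}
_STATE_NAME_PART = {STATE_FREE: "", STATE_T2: ".T2", STATE_T2M2: ".T2.M2", STATE_FN: ".fn"}

POOLS = ("X", "D")

# soluble / ECM / reservoir species ids
SP_T2 = "T2"
SP_M2 = "M2"
SP_M2A = "M2_act"
SP_M2A_T2 = "M2_act.T2"
SP_M2A_FN = "M2_act.fn"
SP_FN = "fn"
SP_FN_DEG = "fn_deg"
SP_VES = "M14_ves"


@dataclass(frozen=True)
class BindingRules:
    """Which elementary binding processes are enabled."""

    dimerization: bool = True
    t2_binding: bool = True
    m2_binding: bool = True
    fn_by_m14: bool = True
    fn_by_m2: bool = True
    activation: bool = True
    m2_inactivation: bool = True

    @classmethod
    def none(cls) -> "BindingRules":
        return cls(False, False, False, False, False, False, False)


@dataclass(frozen=True)
class SpeciesDef:
    """One molecular species.

    ``id`` is the canonical dotted name (order-invariant for complexes,
    e.g. ``M14_D.M14_D.T2.M2``); ``composition`` counts monomers;
    ``flags`` carries ``M2_active`` and ``T2_occupied_sites``;
    ``states`` is the canonical tuple of per-monomer catalytic-site
    states for membrane/internalized complexes (empty otherwise).
    """

    id: str
    composition: Mapping[str, int]
    compartment: str  # membrane_poolX | membrane_poolD | extracellular | internalized | ecm | vesicular
    flags: Mapping[str, object] = field(default_factory=dict)
    states: tuple[str, ...] = ()
    pool: str | None = None

    @property
    def n_m14(self) -> int:
        return int(self.composition.get("M14", 0))

    @property
    def n_free_sites(self) -> int:
        return sum(1 for s in self.states if s == STATE_FREE)

    @property
    def n_t2m2(self) -> int:
        return sum(1 for s in self.states if s == STATE_T2M2)

    @property
    def n_fn_bound(self) -> int:
        return sum(1 for s in self.states if s == STATE_FN)

    @property
    def is_membrane(self) -> bool:
        return self.compartment in ("membrane_poolX", "membrane_poolD")

    @property
    def fully_inhibited(self) -> bool:
        """True when every M14 catalytic site is T2-occupied."""
        return self.is_membrane and self.n_m14 > 0 and all(
            s in (STATE_T2, STATE_T2M2) for s in self.states
        )


@dataclass(frozen=True)
class ReactionDef:
    """One (uni-directional) reaction.

    ``rate_law`` is ``mass_action`` (flux = k * multiplicity * product of
    reactant concentrations), ``constant`` (flux = k while the reactant
    reservoir lasts), or ``free_sites`` (flux = k * max(M_S - pool-X
    M14 load, 0), the docking-site-limited insertion).  ``multiplicity``
    is the statistical factor (e.g. number of equivalent free sites on a
    complex).  ``reversible`` marks members of an emitted forward /
    reverse pair.
    """

    rid: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_name: str
    rate_value: float
    reversible: bool = False
    rate_law: str = "mass_action"
    multiplicity: float = 1.0


class RateTable:
    """name -> (value, provenance) map for every rate constant."""

    def __init__(self, entries: Mapping[str, tuple[float, str]]):
        self._entries = {k: (float(v), str(p)) for k, (v, p) in entries.items()}
        for name, (value, _) in self._entries.items():
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(sorted(self._entries))

    def value(self, name: str) -> float:
        if name not in self._entries:
            raise KeyError(f"unresolved rate constant: {name!r}")
        return self._entries[name][0]

    def provenance(self, name: str) -> str:
        return self._entries[name][1]

    def with_values(self, **updates: float) -> "RateTable":
        entries = dict(self._entries)
        for name, value in updates.items():
            prov = entries[name][1] if name in entries else "calibrated-default"
            entries[name] = (float(value), prov)
        return RateTable(entries)

    def scaled(self, names: Iterable[str], factor: float) -> "RateTable":
        return self.with_values(**{n: self.value(n) * factor for n in names})

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, (v, _) in sorted(self._entries.items())}

    def __eq__(self, other) -> bool:
        return isinstance(other, RateTable) and self._entries == other._entries

    def to_yaml(self, path) -> None:
        payload = {
            name: {"value": v, "provenance": p}
            for name, (v, p) in sorted(self._entries.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RateTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = {}
        for name, item in raw.items():
            if isinstance(item, Mapping):
                entries[name] = (float(item["value"]), item.get("provenance", "user"))
            else:
                entries[name] = (float(item), "user")
        return cls(entries)


# FRAP-anchored turnover rates: 1/26.0 and 1/259 s^-1 (fast pool D
# internalization; slow pool X kinetics).  All binding/catalytic values
# are the calibrated defaults produced by invadosim.calibration (the
# published supplementary table is a drop-in replacement via
# RateTable.from_yaml).
_CALIBRATED_DEFAULTS: dict[str, float] = {
    "k_dim_on": 100.0,                  # 1/(uM s) M14 oligomerization (2D, fast)
    "k_dim_off": 0.01,                  # 1/s
    "k_t2_on": 1.55,      # 1/(uM s) T2 -> free M14 site
    "k_t2_off": 1.3294703062047476e-05,                  # 1/s (tight inhibition)
    "k_m2_on": 1.0064172348478373,       # 1/(uM s) proM2 -> complex-bound T2
    "k_m2_off": 0.01,                   # 1/s
    "k_act": 0.0063,      # 1/s proM2 processing by a T2-free neighbour
    "k_mi_on": 0.013182588092554707,    # 1/(uM s) T2 inactivating active M2
    "k_mi_off": 1e-4,                   # 1/s
    "k_fn11_on": 0.1,                   # 1/(uM s) T2-free M14 engaging ECM
    "k_fn11_off": 0.0029338207653432746,  # 1/s
    "k_fn11p": 2.82314539818032,                     # 1/s ECM proteolysis by M14
    "k_fn2_on": 1.0,                    # 1/(uM s) active M2 engaging ECM
    "k_fn2_off": 0.01,                  # 1/s
    "k_fn2p": 1.3702900919465957,       # 1/s ECM proteolysis by active M2
    "k_D": 1.0 / 26.0,                  # 1/s pool-D internalization (FRAP fast constant)
    "k_intX": 1.0 / 259.0,              # 1/s pool-X internalization (FRAP slow constant)
    "k_insX": 0.02,                     # 1/s per free docking site, pool-X insertion
    "C_D": 0.0011660163176149473,       # uM/s constant insertion flux into pool D
    "M_S": 0.015551788126234286,        # uM docking-site capacity of pool X
}
_FRAP_ANCHORED = {"k_D", "k_intX"}


def default_rate_table() -> RateTable:
    return RateTable(
        {
            name: (value, "supplementary" if name in _FRAP_ANCHORED else "calibrated-default")
            for name, value in _CALIBRATED_DEFAULTS.items()
        }
    )


# ---------------------------------------------------------------------------
# species enumeration


def _canonical_states(states: Sequence[str]) -> tuple[str, ...]:
    return tuple(sorted(states, key=_STATE_RANK.__getitem__))


def _membrane_species(states: Sequence[str], pool: str) -> SpeciesDef:
    states = _canonical_states(states)
    comp = {
        "M14": len(states),
        "T2": sum(1 for s in states if s in (STATE_T2, STATE_T2M2)),
        "M2": sum(1 for s in states if s == STATE_T2M2),
        "fn": sum(1 for s in states if s == STATE_FN),
    }
    sid = ".".join(f"M14_{pool}{_STATE_NAME_PART[s]}" for s in states)
    return SpeciesDef(
        id=sid,
        composition=comp,
        compartment=f"membrane_pool{pool}",
        flags={"M2_active": False, "T2_occupied_sites": comp["T2"]},
        states=states,
        pool=pool,
    )


def _internalized_species(mem: SpeciesDef) -> SpeciesDef:
    # fn is released intact on internalization, so the internalized
    # counterpart never carries fn
    states = _canonical_states(tuple(STATE_FREE if s == STATE_FN else s for s in mem.states))
    base = _membrane_species(states, mem.pool)
    return SpeciesDef(
        id="int." + base.id,
        composition=dict(base.composition),
        compartment="internalized",
        flags={"M2_active": False, "T2_occupied_sites": base.composition["T2"]},
        states=states,
        pool=mem.pool,
    )


def _soluble_fixtures(rules: BindingRules) -> list[SpeciesDef]:
    species = [
        SpeciesDef(SP_T2, {"T2": 1}, "extracellular", {"M2_active": False, "T2_occupied_sites": 0}),
        SpeciesDef(SP_M2, {"M2": 1}, "extracellular", {"M2_active": False, "T2_occupied_sites": 0}),
        SpeciesDef(SP_FN, {"fn": 1}, "ecm", {"M2_active": False, "T2_occupied_sites": 0}),
        SpeciesDef(SP_FN_DEG, {"fn": 1}, "ecm", {"M2_active": False, "T2_occupied_sites": 0, "degraded": True}),
        SpeciesDef(SP_VES, {"M14": 1}, "vesicular", {"M2_active": False, "T2_occupied_sites": 0}),
    ]
    activation_possible = (
        rules.activation and rules.dimerization and rules.t2_binding and rules.m2_binding
    )
    if activation_possible:
        species.append(
            SpeciesDef(SP_M2A, {"M2": 1}, "extracellular", {"M2_active": True, "T2_occupied_sites": 0})
        )
        if rules.m2_inactivation:
            species.append(
                SpeciesDef(
                    SP_M2A_T2, {"M2": 1, "T2": 1}, "extracellular",
                    {"M2_active": True, "T2_occupied_sites": 1},
                )
            )
        if rules.fn_by_m2:
            species.append(
                SpeciesDef(
                    SP_M2A_FN, {"M2": 1, "fn": 1}, "ecm",
                    {"M2_active": True, "T2_occupied_sites": 0},
                )
            )
    return species


def enumerate_species(
    rules: BindingRules = BindingRules(), max_m14: int = 2
) -> list[SpeciesDef]:
    """All species reachable under the binding rules.

    Membrane complexes carry up to ``max_m14`` MT1-MMP monomers, with
    pool-X and pool-D variants of each; output is canonically ordered
    and duplicate-free.
    """
    if max_m14 < 2:
        raise ValueError("max_m14 must be >= 2 (dimerization is required for activation)")
    monomer_states = [STATE_FREE]
    if rules.t2_binding:
        monomer_states.append(STATE_T2)
        if rules.m2_binding:
            monomer_states.append(STATE_T2M2)
    if rules.fn_by_m14:
        monomer_states.append(STATE_FN)

    max_len = max_m14 if rules.dimerization else 1
    membrane: list[SpeciesDef] = []
    for pool in POOLS:
        for n in range(1, max_len + 1):
            for combo in itertools.combinations_with_replacement(
                sorted(monomer_states, key=_STATE_RANK.__getitem__), n
            ):
                membrane.append(_membrane_species(combo, pool))
    internalized = [_internalized_species(m) for m in membrane]
    # fn release on internalization maps several membrane species onto the
    # same internalized id; dedupe
    seen: dict[str, SpeciesDef] = {}
    for sp in internalized:
        seen.setdefault(sp.id, sp)
    species = _soluble_fixtures(rules) + membrane + list(seen.values())
    species.sort(key=lambda s: (s.compartment, s.n_m14, s.id))
    ids = [s.id for s in species]
    if len(ids) != len(set(ids)):
        raise AssertionError("duplicate canonical species ids")
    return species


# ---------------------------------------------------------------------------
# reaction generation


def _replace_state(sp: SpeciesDef, old: str, new: str) -> tuple[str, ...]:
    states = list(sp.states)
    states.remove(old)
    if new:
        states.append(new)
    return _canonical_states(states)


class _Emitter:
    def __init__(self, by_id: Mapping[str, SpeciesDef], rates: RateTable):
        self.by_id = by_id
        self.rates = rates
        self.reactions: list[ReactionDef] = []
        self._n = 0

    def emit(
        self,
        reactants: Sequence[tuple[str, int]],
        products: Sequence[tuple[str, int]],
        rate_name: str,
        *,
        reversible: bool = False,
        rate_law: str = "mass_action",
        multiplicity: float = 1.0,
    ) -> None:
        value = self.rates.value(rate_name)
        for sid, _ in list(reactants) + list(products):
            if sid not in self.by_id:
                raise KeyError(f"reaction references unknown species {sid!r}")
        self._n += 1
        rxn = ReactionDef(
            rid=f"r{self._n:04d}",
            reactants=tuple(reactants),
            products=tuple(products),
            rate_name=rate_name,
            rate_value=value,
            reversible=reversible,
            rate_law=rate_law,
            multiplicity=float(multiplicity),
        )
        _check_mass_balance(rxn, self.by_id)
        self.reactions.append(rxn)


def _check_mass_balance(rxn: ReactionDef, by_id: Mapping[str, SpeciesDef]) -> None:
    """Every reaction conserves M14, T2, M2 and fn monomer counts."""
    for monomer in ("M14", "T2", "M2", "fn"):
        net = 0
        for sid, stoich in rxn.reactants:
            net -= stoich * by_id[sid].composition.get(monomer, 0)
        for sid, stoich in rxn.products:
            net += stoich * by_id[sid].composition.get(monomer, 0)
        if net != 0:
            raise AssertionError(
                f"reaction {rxn.rid} ({rxn.rate_name}) violates {monomer} mass balance"
            )


def generate_reactions(
    species: Sequence[SpeciesDef],
    rates: RateTable,
    rules: BindingRules = BindingRules(),
    max_m14: int = 2,
) -> list[ReactionDef]:
    """Emit the full mass-action reaction set for the enumerated species."""
    by_id = {s.id: s for s in species}
    have = by_id.__contains__
    em = _Emitter(by_id, rates)
    membrane = [s for s in species if s.is_membrane]
    mem_key = {(_canonical_states(s.states), s.pool): s.id for s in membrane}

    def mem_id(states: Sequence[str], pool: str) -> str:
        return mem_key[(_canonical_states(states), pool)]

    # --- oligomerization ---------------------------------------------------
    if rules.dimerization:
        for pool in POOLS:
            pool_sp = [s for s in membrane if s.pool == pool]
            pairs = itertools.combinations_with_replacement(
                sorted(pool_sp, key=lambda s: s.id), 2
            )
            for a, b in pairs:
                if a.n_m14 + b.n_m14 > max_m14:
                    continue
                joined = mem_id(a.states + b.states, pool)
                if a.id == b.id:
                    reactants = ((a.id, 2),)
                else:
                    reactants = ((a.id, 1), (b.id, 1))
                em.emit(reactants, ((joined, 1),), "k_dim_on", reversible=True)
                em.emit(((joined, 1),), reactants, "k_dim_off", reversible=True)

    for sp in membrane:
        # --- T2 binding ----------------------------------------------------
        if rules.t2_binding and sp.n_free_sites > 0:
            tgt = mem_id(_replace_state(sp, STATE_FREE, STATE_T2), sp.pool)
            em.emit(
                ((sp.id, 1), (SP_T2, 1)), ((tgt, 1),), "k_t2_on",
                reversible=True, multiplicity=sp.n_free_sites,
            )
        if rules.t2_binding and STATE_T2 in sp.states:
            tgt = mem_id(_replace_state(sp, STATE_T2, STATE_FREE), sp.pool)
            em.emit(
                ((sp.id, 1),), ((tgt, 1), (SP_T2, 1)), "k_t2_off",
                reversible=True, multiplicity=sp.states.count(STATE_T2),
            )
        # --- proM2 binding to complex-bound T2 ------------------------------
        if rules.m2_binding and STATE_T2 in sp.states:
            tgt = mem_id(_replace_state(sp, STATE_T2, STATE_T2M2), sp.pool)
            em.emit(
                ((sp.id, 1), (SP_M2, 1)), ((tgt, 1),), "k_m2_on",
                reversible=True, multiplicity=sp.states.count(STATE_T2),
            )
        if rules.m2_binding and STATE_T2M2 in sp.states:
            tgt = mem_id(_replace_state(sp, STATE_T2M2, STATE_T2), sp.pool)
            em.emit(
                ((sp.id, 1),), ((tgt, 1), (SP_M2, 1)), "k_m2_off",
                reversible=True, multiplicity=sp.n_t2m2,
            )
        # --- activation: TM processed by a T2-free M14 in the same complex --
        if (
            rules.activation
            and sp.n_t2m2 > 0
            and sp.n_free_sites > 0
            and have(SP_M2A)
        ):
            tgt = mem_id(_replace_state(sp, STATE_T2M2, STATE_T2), sp.pool)
            em.emit(
                ((sp.id, 1),), ((tgt, 1), (SP_M2A, 1)), "k_act",
                multiplicity=sp.n_t2m2,
            )
        # --- ECM engagement and proteolysis by T2-free M14 ------------------
        if rules.fn_by_m14 and sp.n_free_sites > 0:
            tgt = mem_id(_replace_state(sp, STATE_FREE, STATE_FN), sp.pool)
            em.emit(
                ((sp.id, 1), (SP_FN, 1)), ((tgt, 1),), "k_fn11_on",
                reversible=True, multiplicity=sp.n_free_sites,
            )
        if rules.fn_by_m14 and STATE_FN in sp.states:
            back = mem_id(_replace_state(sp, STATE_FN, STATE_FREE), sp.pool)
            em.emit(
                ((sp.id, 1),), ((back, 1), (SP_FN, 1)), "k_fn11_off",
                reversible=True, multiplicity=sp.n_fn_bound,
            )
            em.emit(
                ((sp.id, 1),), ((back, 1), (SP_FN_DEG, 1)), "k_fn11p",
                multiplicity=sp.n_fn_bound,
            )
        # --- internalization (all membrane species; bound fn released) -----
        int_id = "int." + mem_id(
            tuple(STATE_FREE if s == STATE_FN else s for s in sp.states), sp.pool
        )
        products: list[tuple[str, int]] = [(int_id, 1)]
        if sp.n_fn_bound:
            products.append((SP_FN, sp.n_fn_bound))
        rate_name = "k_D" if sp.pool == "D" else "k_intX"
        em.emit(((sp.id, 1),), tuple(products), rate_name)

    # --- insertion ---------------------------------------------------------
    em.emit(((SP_VES, 1),), ((mem_id((STATE_FREE,), "D"), 1),), "C_D", rate_law="constant")
    em.emit(
        ((SP_VES, 1),), ((mem_id((STATE_FREE,), "X"), 1),), "k_insX",
        rate_law="free_sites",
    )

    # --- soluble MMP-2 chemistry -------------------------------------------
    if have(SP_M2A):
        if rules.m2_inactivation and have(SP_M2A_T2):
            em.emit(((SP_M2A, 1), (SP_T2, 1)), ((SP_M2A_T2, 1),), "k_mi_on", reversible=True)
            em.emit(((SP_M2A_T2, 1),), ((SP_M2A, 1), (SP_T2, 1)), "k_mi_off", reversible=True)
        if rules.fn_by_m2 and have(SP_M2A_FN):
            em.emit(((SP_M2A, 1), (SP_FN, 1)), ((SP_M2A_FN, 1),), "k_fn2_on", reversible=True)
            em.emit(((SP_M2A_FN, 1),), ((SP_M2A, 1), (SP_FN, 1)), "k_fn2_off", reversible=True)
            em.emit(((SP_M2A_FN, 1),), ((SP_M2A, 1), (SP_FN_DEG, 1)), "k_fn2p")
    return em.reactions


@dataclass(frozen=True)
class ReactionNetwork:
    """Enumerated species + generated reactions, ready to compile."""

    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    rules: BindingRules
    rates: RateTable
    max_m14: int

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def with_rates(self, rates: RateTable) -> "ReactionNetwork":
        """Regenerate the network with a new rate table (same structure)."""
        return build_network(rules=self.rules, max_m14=self.max_m14, rates=rates)

    def monomer_ledger_matrix(self) -> np.ndarray:
        """(4, n_species) counts of M14 / T2 / M2 / fn per species."""
        mono = ("M14", "T2", "M2", "fn")
        out = np.zeros((4, len(self.species)))
        for j, sp in enumerate(self.species):
            for i, m in enumerate(mono):
                out[i, j] = sp.composition.get(m, 0)
        return out


def build_network(
    rules: BindingRules = BindingRules(),
    max_m14: int = 2,
    rates: RateTable | None = None,
) -> ReactionNetwork:
    rates = rates if rates is not None else default_rate_table()
    species = enumerate_species(rules, max_m14)
    reactions = generate_reactions(species, rates, rules, max_m14)
    return ReactionNetwork(tuple(species), tuple(reactions), rules, rates, max_m14)


# ---------------------------------------------------------------------------
# reachability


def reachable_species(
    network: ReactionNetwork, initial_nonzero: Iterable[str]
) -> set[str]:
    """Fixed-point closure: species producible from the initial set.

    A reaction fires once all its reactants are reachable; its products
    then become reachable.  Used e.g. to show that with no TIMP-2 the
    quadruple complex (and hence active MMP-2) is unreachable.
    """
    reach = set(initial_nonzero)
    unknown = reach - set(network.species_ids)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    changed = True
    while changed:
        changed = False
        for rxn in network.reactions:
            if all(sid in reach for sid, _ in rxn.reactants):
                for sid, _ in rxn.products:
                    if sid not in reach:
                        reach.add(sid)
                        changed = True
    return reach


# ---------------------------------------------------------------------------
# export / import


_TSV_HEADER = "reaction_id\treactants\tproducts\trate_name\trate_value\treversible\trate_law\tmultiplicity"


def _side_to_str(side: Sequence[tuple[str, int]]) -> str:
    return " + ".join(f"{n} {sid}" if n != 1 else sid for sid, n in side)


def _side_from_str(text: str) -> tuple[tuple[str, int], ...]:
    out = []
    for term in text.split(" + "):
        parts = term.split(" ")
        if len(parts) == 2:
            out.append((parts[1], int(parts[0])))
        else:
            out.append((parts[0], 1))
    return tuple(out)


def export_network(network: ReactionNetwork, path, format: str = "tsv") -> None:
    """Write a human-auditable reaction list (TSV) or a minimal SBML L3 file."""
    if format == "tsv":
        lines = [
            f"# species\t{len(network.species)}",
            f"# reactions\t{len(network.reactions)}",
            f"# max_m14\t{network.max_m14}",
            _TSV_HEADER,
        ]
        for rxn in network.reactions:
            lines.append(
                "\t".join(
                    [
                        rxn.rid,
                        _side_to_str(rxn.reactants),
                        _side_to_str(rxn.products),
                        rxn.rate_name,
                        repr(rxn.rate_value),
                        str(rxn.reversible).lower(),
                        rxn.rate_law,
                        repr(rxn.multiplicity),
                    ]
                )
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "sbml":
        _export_sbml(network, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def import_network_tsv(
    path, rules: BindingRules = BindingRules(), rates: RateTable | None = None
) -> ReactionNetwork:
    """Read a TSV reaction list back; checks header counts against content."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    meta = {}
    body = []
    for ln in lines:
        if ln.startswith("# "):
            key, val = ln[2:].split("\t")
            meta[key] = int(val)
        elif ln != _TSV_HEADER:
            body.append(ln)
    reactions = []
    for ln in body:
        rid, reac, prod, name, value, rev, law, mult = ln.split("\t")
        reactions.append(
            ReactionDef(
                rid,
                _side_from_str(reac),
                _side_from_str(prod),
                name,
                float(value),
                rev == "true",
                law,
                float(mult),
            )
        )
    if "reactions" in meta and meta["reactions"] != len(reactions):
        raise ValueError("reaction count header does not match file content")
    max_m14 = meta.get("max_m14", 2)
    rates = rates if rates is not None else default_rate_table()
    species = enumerate_species(rules, max_m14)
    net = ReactionNetwork(tuple(species), tuple(reactions), rules, rates, max_m14)
    if "species" in meta and meta["species"] != len(net.species):
        raise ValueError("species count header does not match enumerated species")
    return net


def _export_sbml(network: ReactionNetwork, path) -> None:
    """Minimal SBML Level 3 Version 2 core document (structural, not schema-validated)."""
    from xml.etree import ElementTree as ET

    ns = "http://www.sbml.org/sbml/level3/version2/core"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{ns}}}model", {"id": "invadosim_network"})
    comps = ET.SubElement(model, f"{{{ns}}}listOfCompartments")
    for comp in sorted({s.compartment for s in network.species}):
        ET.SubElement(
            comps, f"{{{ns}}}compartment", {"id": comp, "constant": "true"}
        )
    sps = ET.SubElement(model, f"{{{ns}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(
            sps,
            f"{{{ns}}}species",
            {
                "id": _sbml_id(sp.id),
                "name": sp.id,
                "compartment": sp.compartment,
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    params = ET.SubElement(model, f"{{{ns}}}listOfParameters")
    for name in network.rates:
        ET.SubElement(
            params,
            f"{{{ns}}}parameter",
            {"id": name, "value": repr(network.rates.value(name)), "constant": "true"},
        )
    rxns = ET.SubElement(model, f"{{{ns}}}listOfReactions")
    for rxn in network.reactions:
        el = ET.SubElement(
            rxns, f"{{{ns}}}reaction", {"id": rxn.rid, "reversible": "false"}
        )
        lor = ET.SubElement(el, f"{{{ns}}}listOfReactants")
        for sid, stoich in rxn.reactants:
            ET.SubElement(
                lor,
                f"{{{ns}}}speciesReference",
                {"species": _sbml_id(sid), "stoichiometry": str(stoich), "constant": "true"},
            )
        lop = ET.SubElement(el, f"{{{ns}}}listOfProducts")
        for sid, stoich in rxn.products:
            ET.SubElement(
                lop,
                f"{{{ns}}}speciesReference",
                {"species": _sbml_id(sid), "stoichiometry": str(stoich), "constant": "true"},
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def _sbml_id(sid: str) -> str:
    return "s_" + sid.replace(".", "_").replace(":", "_")
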
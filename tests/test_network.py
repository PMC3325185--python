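"""Rule-based species enumeration and reaction generation."""

import itertools

import pytest

from invadosim import network as nw


def brute_force_membrane_count(max_m14: int, monomer_states: int = 4) -> int:
    """Independent oracle: count distinct membrane complexes per pool.

    A complex is an unordered multiset of 1..max_m14 monomers, each in
    one of ``monomer_states`` catalytic-site states.
    """
    total = 0
    for n in range(1, max_m14 + 1):
        total += sum(
            1 for _ in itertools.combinations_with_replacement(range(monomer_states), n)
        )
    return total


def brute_force_internalized_count(max_m14: int) -> int:
    """Internalized complexes never carry fn: 3 states per monomer."""
    return brute_force_membrane_count(max_m14, monomer_states=3)


class TestEnumeration:
    @pytest.mark.parametrize("max_m14", [2, 3])
    def test_species_count_matches_brute_force_oracle(self, max_m14):
        species = nw.enumerate_species(max_m14=max_m14)
        n_membrane = sum(1 for s in species if s.is_membrane)
        n_internal = sum(1 for s in species if s.compartment == "internalized")
        assert n_membrane == 2 * brute_force_membrane_count(max_m14)
        assert n_internal == 2 * brute_force_internalized_count(max_m14)
        # solubles: T2, M2, M2_act, M2_act.T2, M2_act.fn, fn, fn_deg, M14_ves
        assert len(species) == n_membrane + n_internal + 8

    def test_characteristic_multimers_present(self, default_network):
        ids = set(default_network.species_ids)
        assert "M14_D.M14_D.T2.M2" in ids
        assert "M14_D.T2.M2.M14_D.T2.M2" in ids

    def test_all_bindings_disabled_leaves_monomeric_membrane_set(self):
        species = nw.enumerate_species(nw.BindingRules.none(), max_m14=2)
        membrane = sorted(s.id for s in species if s.is_membrane)
        assert membrane == ["M14_D", "M14_X"]

    def test_canonical_naming_is_order_invariant(self):
        a = nw._membrane_species((nw.STATE_T2M2, nw.STATE_FREE), "D")
        b = nw._membrane_species((nw.STATE_FREE, nw.STATE_T2M2), "D")
        assert a.id == b.id == "M14_D.M14_D.T2.M2"

    def test_max_m14_below_two_rejected(self):
        with pytest.raises(ValueError):
            nw.enumerate_species(max_m14=1)

    def test_composition_counts(self, default_network):
        sp = {s.id: s for s in default_network.species}["M14_D.T2.M2.M14_D.T2.M2"]
        assert dict(sp.composition) == {"M14": 2, "T2": 2, "M2": 2, "fn": 0}
        assert sp.flags["T2_occupied_sites"] == 2


class TestReactionGeneration:
    def test_every_reaction_conserves_monomer_ledgers(self, default_network):
        # independent recomputation from species compositions
        comp = {s.id: s.composition for s in default_network.species}
        for rxn in default_network.reactions:
            for monomer in ("M14", "T2", "M2", "fn"):
                net_change = sum(
                    n * comp[sid].get(monomer, 0) for sid, n in rxn.products
                ) - sum(n * comp[sid].get(monomer, 0) for sid, n in rxn.reactants)
                assert net_change == 0, (rxn.rid, monomer)

    def test_generation_is_deterministic(self):
        a = nw.build_network()
        b = nw.build_network()
        assert a.species == b.species
        assert a.reactions == b.reactions

    def test_activation_pathway_exists(self, default_network):
        reach = nw.reachable_species(
            default_network, ["M14_ves", "T2", "M2", "fn"]
        )
        # proM2 -> quadruple complex -> active M2 -> inactivated M2.T2
        assert "M14_D.M14_D.T2.M2" in reach
        assert "M2_act" in reach
        assert "M2_act.T2" in reach

    def test_zero_timp2_makes_activation_unreachable(self, default_network):
        reach = nw.reachable_species(default_network, ["M14_ves", "M2", "fn"])
        assert "M2_act" not in reach
        assert not any("T2" in sid for sid in reach)

    def test_disabling_dimerization_removes_activation(self):
        rules = nw.BindingRules(dimerization=False)
        net = nw.build_network(rules=rules)
        assert not any(r.rate_name == "k_act" for r in net.reactions)
        assert "M2_act" not in set(net.species_ids)

    def test_every_membrane_species_internalizes(self, default_network):
        internalizing = {
            rxn.reactants[0][0]
            for rxn in default_network.reactions
            if rxn.rate_name in ("k_D", "k_intX")
        }
        membrane = {s.id for s in default_network.species if s.is_membrane}
        assert internalizing == membrane

    def test_unresolved_rate_name_is_reported(self):
        rates = nw.RateTable(
            {name: (1.0, "test") for name in nw.default_rate_table() if name != "k_act"}
        )
        species = nw.enumerate_species(max_m14=2)
        with pytest.raises(KeyError, match="k_act"):
            nw.generate_reactions(species, rates)


class TestRateTable:
    def test_provenance_tags(self):
        rates = nw.default_rate_table()
        assert rates.provenance("k_D") == "supplementary"
        assert rates.provenance("k_act") == "calibrated-default"

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            nw.RateTable({"k": (-1.0, "x")})

    def test_yaml_round_trip(self, tmp_path):
        rates = nw.default_rate_table()
        path = tmp_path / "rates.yaml"
        rates.to_yaml(path)
        assert nw.RateTable.from_yaml(path) == rates

    def test_scaled_returns_new_table(self):
        rates = nw.default_rate_table()
        scaled = rates.scaled(["k_D"], 0.1)
        assert scaled.value("k_D") == pytest.approx(rates.value("k_D") / 10)
        assert rates.value("k_D") == pytest.approx(1.0 / 26.0)


class TestExport:
    def test_tsv_round_trip_is_identical(self, tmp_path, default_network):
        path = tmp_path / "network.tsv"
        nw.export_network(default_network, path)
        back = nw.import_network_tsv(path)
        assert back.reactions == default_network.reactions
        assert back.species == default_network.species

    def test_tsv_header_counts_match_content(self, tmp_path, default_network):
        path = tmp_path / "network.tsv"
        nw.export_network(default_network, path)
        lines = path.read_text().splitlines()
        meta = dict(ln[2:].split("\t") for ln in lines if ln.startswith("# "))
        assert int(meta["species"]) == len(default_network.species)
        assert int(meta["reactions"]) == len(default_network.reactions)

    def test_sbml_export_is_well_formed_and_complete(self, tmp_path, default_network):
        from xml.etree import ElementTree as ET

        path = tmp_path / "network.sbml.xml"
        nw.export_network(default_network, path, format="sbml")
        root = ET.parse(path).getroot()
        ns = "{http://www.sbml.org/sbml/level3/version2/core}"
        model = root.find(f"{ns}model")
        species = model.find(f"{ns}listOfSpecies")
        reactions = model.find(f"{ns}listOfReactions")
        assert len(species) == len(default_network.species)
        assert len(reactions) == len(default_network.reactions)
        declared = {el.get("id") for el in species}
        for rxn in reactions:
            for ref in rxn.iter(f"{ns}speciesReference"):
                assert ref.get("species") in declared

    def test_unknown_format_rejected(self, tmp_path, default_network):
        with pytest.raises(ValueError):
            nw.export_network(default_network, tmp_path / "x", format="biopax")
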
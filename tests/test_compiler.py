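"""Compiler: gate expansion templates, wiring rules, counting, SBML."""

import io

import pytest

from domaincode.circuits import build_exponentiation_netlist, build_sqrt4_netlist
from domaincode.compiler import (
    Netlist, compile_netlist, crn_from_reactions, expand_gate,
)
from domaincode.errors import CompileError
from domaincode.gates import (
    GateModule, make_amplifier, make_fanout_gate, make_mapping_module,
    make_reporter,
)
from domaincode.sbml import read_sbml, write_sbml
from domaincode.strands import KineticParams, conservation_violations


def _stage_netlist(gates, inputs, unit=1.0e4, shared=frozenset(), outputs=()):
    return Netlist("t", gates, inputs, unit, KineticParams(unit_conc_1X=unit),
                   shared_wires=shared, output_wires=outputs)


class TestMappingExpansion:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_reaction_count_is_matched_prefixes(self, n):
        m = make_mapping_module(n, (0,) * (2 ** n),
                                [f"x{j}" for j in range(n)], "y")
        rxns = expand_gate(m)
        # each of the 2^n duplexes reacts once per consumed input
        assert len(rxns) == n * 2 ** n

    def test_one_input_matched_and_mismatched(self):
        m = make_mapping_module(1, (1, 0), ("a",), "y", gate_id="G")
        rxns = expand_gate(m)
        assert len(rxns) == 2
        for rxn in rxns:
            sig = [s for s in rxn.reactants if not s.is_complex][0]
            duplex = [s for s in rxn.reactants if s.is_complex][0]
            # the consumed strand's logic value equals the duplex match code
            match = [k for k in duplex.strand_counts() if k[0] == "mt"][0][2]
            assert sig.structure[1][3] == match[0]
            # matched reaction releases output + waste; nothing else emitted
            assert len(rxn.products) == 2

    def test_two_input_sequential_order(self):
        m = make_mapping_module(2, (0, 1, 1, 1), ("a", "b"), "y", gate_id="G")
        rxns = expand_gate(m)
        first = [r for r in rxns if any(
            s.structure[1][:2] == ("sig", "a") for s in r.reactants
            if not s.is_complex)]
        # step 1 consumes the first input and yields only the intermediate
        assert all(len(r.products) == 1 for r in first)
        second = [r for r in rxns if r not in first]
        assert all(len(r.products) == 2 for r in second)
        assert len(first) == len(second) == 4

    def test_rates_are_k_bind(self):
        m = make_mapping_module(1, (0, 1), ("a",), "y")
        p = KineticParams()
        assert {r.rate for r in expand_gate(m, p)} == {p.k_bind}


class TestAuxExpansion:
    def test_amplifier_initial_species_count(self):
        crn = crn_from_reactions(expand_gate(make_amplifier("B")))
        # Amp0, Amp1, H0, H1 initially present
        assert crn.count_initial_species() == 4

    def test_amplifier_fuel_at_twice_duplex_conc(self):
        crn = crn_from_reactions(
            expand_gate(make_amplifier("B", gate_id="A"), unit_conc=100.0))
        by_name = {sp.name: sp for sp in crn.species}
        assert by_name["A.Amp0"].init_conc == pytest.approx(100.0)
        assert by_name["A.H0"].init_conc == pytest.approx(200.0)

    def test_fanout_fuel_scales_with_path_duplexes(self):
        crn = crn_from_reactions(expand_gate(
            make_fanout_gate("A", 2, gate_id="F"), unit_conc=100.0))
        by_name = {sp.name: sp for sp in crn.species}
        # default fuel_mult=1: fuel equals the path total = twice one duplex
        assert by_name["F.H0"].init_conc == pytest.approx(200.0)
        crn3 = crn_from_reactions(expand_gate(
            make_fanout_gate("A", 3, gate_id="F"), unit_conc=100.0))
        assert {sp.name: sp for sp in crn3.species}["F.H1"].init_conc == \
            pytest.approx(300.0)

    def test_fanout_catalytic_loop_regenerates_input(self):
        rxns = expand_gate(make_fanout_gate("A", 2, gate_id="F"))
        regen = [r for r in rxns
                 if any(s.role == "fuel" for s in r.reactants)
                 and any(s.structure == ("single", ("sig", "A", v, v))
                         for s in r.products for v in (0, 1))]
        assert len(regen) == 4  # one recovery reaction per branch duplex

    def test_reporter_releases_fluorescence(self):
        rxns = expand_gate(make_reporter("Z", gate_id="R"))
        assert len(rxns) == 2
        for rxn in rxns:
            assert any(s.role == "fluorescence" for s in rxn.products)


class TestWiringRules:
    def test_doubly_consumed_wire_without_fanout_is_an_error(self):
        nl = _stage_netlist([
            make_mapping_module(1, (0, 1), ("A",), "Y1", gate_id="G1"),
            make_mapping_module(1, (0, 1), ("A",), "Y2", gate_id="G2"),
        ], {"A": 1})
        with pytest.raises(CompileError, match="fan-out"):
            compile_netlist(nl)

    def test_fanout_or_shared_declaration_fixes_it(self):
        gates = [
            make_fanout_gate("A", 2, out_wires=("A1", "A2"), gate_id="F"),
            make_mapping_module(1, (0, 1), ("A1",), "Y1", gate_id="G1"),
            make_mapping_module(1, (0, 1), ("A2",), "Y2", gate_id="G2"),
        ]
        compile_netlist(_stage_netlist(gates, {"A": 1}))  # no error
        shared = _stage_netlist([
            make_mapping_module(1, (0, 1), ("A",), "Y1", gate_id="G1"),
            make_mapping_module(1, (0, 1), ("A",), "Y2", gate_id="G2"),
        ], {"A": 1}, shared=frozenset({"A"}))
        compile_netlist(shared)  # declared shared: allowed

    def test_unwired_input_is_an_error(self):
        nl = _stage_netlist(
            [make_mapping_module(1, (0, 1), ("A",), "Y", gate_id="G")], {})
        with pytest.raises(CompileError, match="not driven"):
            compile_netlist(nl)

    def test_multiply_driven_wire_is_an_error(self):
        nl = _stage_netlist([
            make_mapping_module(1, (0, 1), ("A",), "Y", gate_id="G1"),
            make_mapping_module(1, (1, 0), ("B",), "Y", gate_id="G2"),
        ], {"A": 0, "B": 0})
        with pytest.raises(CompileError, match="driven by several"):
            compile_netlist(nl)

    def test_empty_netlist_compiles_empty(self):
        crn = compile_netlist(Netlist("empty"))
        assert crn.species == [] and crn.reactions == []
        assert crn.count_initial_species() == 0


class TestDeterminismAndConservation:
    def test_compilation_is_deterministic(self):
        a = compile_netlist(build_sqrt4_netlist(9))
        b = compile_netlist(build_sqrt4_netlist(9))
        assert [sp.name for sp in a.species] == [sp.name for sp in b.species]
        assert [r.label for r in a.reactions] == [r.label for r in b.reactions]
        assert a.species_table().to_csv() == b.species_table().to_csv()

    def test_every_reaction_conserves_strands(self):
        for netlist in (build_sqrt4_netlist(5), build_exponentiation_netlist(3)):
            crn = compile_netlist(netlist)
            assert conservation_violations(crn.reactions) == []

    def test_two_step_mode_also_conserves(self):
        crn = compile_netlist(build_sqrt4_netlist(5), mode="two-step")
        assert conservation_violations(crn.reactions) == []
        assert len(crn.reactions) == 3 * len(
            compile_netlist(build_sqrt4_netlist(5)).reactions)


class TestCounting:
    def test_exponentiation_module_inventory(self):
        nl = build_exponentiation_netlist(0)
        modules = [g for g in nl.gates if isinstance(g, GateModule)]
        assert sum(1 for m in modules if m.n == 1) == 3
        assert sum(1 for m in modules if m.n == 3) == 8
        assert all(len(m.duplexes) == 2 ** m.n for m in modules)

    def test_component_strand_selectors(self):
        crn = compile_netlist(build_sqrt4_netlist(0))
        core = crn.count_component_strands("core")
        full = crn.count_component_strands("full")
        assert core == 64
        assert full > core
        fanout_only = crn.count_component_strands({"fanout"})
        assert fanout_only == 20  # two fan-out-two gates at 10 strands each
        with pytest.raises(CompileError, match="selector"):
            crn.count_component_strands("bogus")

    def test_involved_species_subset_of_initial(self):
        crn = compile_netlist(build_exponentiation_netlist(6))
        total = crn.count_initial_species()
        involved = crn.count_initial_species(involved_only=True)
        assert involved <= total
        assert involved == 71 and total == 139


class TestSbml:
    def test_amplifier_round_trip(self):
        crn = crn_from_reactions(expand_gate(make_amplifier("B")))
        parsed = read_sbml(io.BytesIO(write_sbml(crn).encode()))
        assert len(parsed["species"]) == len(crn.species)
        assert len(parsed["reactions"]) == len(crn.reactions)
        initial = [s for s in parsed["species"]
                   if s["initial_concentration"] > 0]
        assert len(initial) == 4

    def test_exponentiation_document_round_trips(self):
        crn = compile_netlist(build_exponentiation_netlist(1))
        parsed = read_sbml(io.BytesIO(write_sbml(crn).encode()))
        assert len(parsed["species"]) == len(crn.species)
        rates = sorted({r["rate"] for r in parsed["reactions"]})
        assert rates == [pytest.approx(3.0e-4)]

    def test_empty_model_is_valid(self):
        crn = compile_netlist(Netlist("empty"))
        parsed = read_sbml(io.BytesIO(write_sbml(crn).encode()))
        assert parsed["species"] == [] and parsed["reactions"] == []
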
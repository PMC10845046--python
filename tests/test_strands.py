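"""Strand model: coded variants, canonical species identity, conservation."""

import itertools

import numpy as np
import pytest

from domaincode.compiler import Reaction
from domaincode.errors import DomainCodeError
from domaincode.strands import (
    Domain, KineticParams, Species, canonical_name, complex_species,
    conservation_vectors, conservation_violations, make_signal_strand,
    single_species,
)


class TestSignalStrand:
    def test_four_variants_per_wire(self):
        variants = {make_signal_strand("w", l, r) for l in (0, 1)
                    for r in (0, 1)}
        assert len(variants) == 4
        assert {s.name for s in variants} == {"w.A0", "w.A1", "w.A2", "w.A3"}

    @pytest.mark.parametrize("left,right,variant,logic", [
        (0, 0, 0, 0),   # A0 carries logic 0
        (0, 1, 1, 1),
        (1, 0, 2, 0),
        (1, 1, 3, 1),   # A3 carries logic 1
    ])
    def test_logic_value_is_right_code(self, left, right, variant, logic):
        s = make_signal_strand("w", left, right)
        assert s.variant == variant
        assert s.logic_value == logic

    def test_seven_domain_layout(self):
        domains = make_signal_strand("w", 0, 1).domains()
        assert len(domains) == 7
        kinds = [d.kind for d in domains]
        assert kinds == ["flank", "code", "flank", "toehold", "flank",
                         "code", "flank"]
        assert domains[1].code_bit == 0 and domains[5].code_bit == 1

    @pytest.mark.parametrize("bad", [-1, 2, "1"])
    def test_rejects_non_bit_codes(self, bad):
        with pytest.raises(DomainCodeError):
            make_signal_strand("w", bad, 0)


class TestDomain:
    def test_code_bit_iff_code_kind(self):
        with pytest.raises(DomainCodeError):
            Domain("d", "flank", code_bit=1)
        with pytest.raises(DomainCodeError):
            Domain("d", "code")
        Domain("d", "code", code_bit=0)  # fine

    def test_positive_length(self):
        with pytest.raises(DomainCodeError):
            Domain("d", "flank", length_nt=0)


class TestSpeciesIdentity:
    def test_equal_species_under_construction_order(self):
        k1, k2 = ("sig", "w", 0, 1), ("mt", "g", (0,), 1)
        a = complex_species([k1, k2], "first", "gate", 1.0)
        b = complex_species([k2, k1], "second", "gate", 1.0)
        assert a == b
        assert hash(a) == hash(b)
        assert canonical_name(a) == canonical_name(b)

    def test_repeated_construction_is_stable(self):
        s = make_signal_strand("X0", 0, 0)
        names = {canonical_name(single_species(s.key, s.name, "input"))
                 for _ in range(5)}
        assert len(names) == 1

    def test_code_pairs_have_distinct_canonical_names(self):
        # Exhaustive over all four (left, right) code pairs: duplexes that
        # differ in one code bit must never collide.
        names = set()
        for l, r in itertools.product((0, 1), repeat=2):
            sp = complex_species(
                [("mt", "g", (l,), r), make_signal_strand("y", r, r).key],
                f"d{l}{r}", "gate", 1.0)
            names.add(canonical_name(sp))
        assert len(names) == 4

    def test_roles_validated(self):
        with pytest.raises(DomainCodeError):
            single_species(("sig", "w", 0, 0), "x", "nonsense")
        with pytest.raises(DomainCodeError):
            complex_species([("sig", "w", 0, 0)], "x", "intermediate",
                            init_conc=5.0)
        with pytest.raises(DomainCodeError):
            single_species(("sig", "w", 0, 0), "x", "input", init_conc=-1.0)


class TestConservation:
    def test_single_displacement_balances(self):
        A = single_species(("sig", "A", 0, 0), "A", "input", 1.0)
        G = complex_species([("mt", "g", (0,), 1), ("sig", "O", 1, 1)],
                            "G", "gate", 1.0)
        O = single_species(("sig", "O", 1, 1), "O", "output")
        W = complex_species([("mt", "g", (0,), 1), ("sig", "A", 0, 0)],
                            "W", "waste")
        rxn = Reaction((A, G), (O, W), 3e-4)
        assert conservation_violations([rxn]) == []
        matrix, strands = conservation_vectors([A, G, O, W], [rxn])
        assert matrix.shape == (3, 4)
        # each strand appears exactly twice across this species set
        assert list(matrix.sum(axis=1)) == [2, 2, 2]

    def test_unbalanced_reaction_detected(self):
        A = single_species(("sig", "A", 0, 0), "A", "input", 1.0)
        O = single_species(("sig", "O", 1, 1), "O", "output")
        bad = Reaction((A,), (O,), 1.0)
        violations = conservation_violations([bad])
        assert len(violations) == 1

    def test_empty_set_gives_empty_matrix(self):
        matrix, strands = conservation_vectors([], [])
        assert matrix.shape == (0, 0)
        assert strands == []


class TestKineticParams:
    def test_defaults_are_the_dsd_rates(self):
        p = KineticParams()
        assert p.k_bind == pytest.approx(3.0e-4)
        assert p.k_unbind == pytest.approx(0.1126)
        assert p.unit_conc_1X == pytest.approx(1.0e4)

    @pytest.mark.parametrize("kwargs", [
        {"k_bind": 0.0}, {"k_unbind": -1.0}, {"unit_conc_1X": 0.0},
    ])
    def test_strict_positivity(self, kwargs):
        with pytest.raises(DomainCodeError):
            KineticParams(**kwargs)
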
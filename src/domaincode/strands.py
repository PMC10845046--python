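"""Strand-level data model for domain-coded DSD circuits.

A logic signal is a single DNA strand of seven domains::

    flank - code - flank - T - flank - code - flank

The central toehold ``T`` splits the strand into two halves.  The coded
domain on the left carries the *upstream-match* bit (it hybridises with the
gate that consumes the strand); the coded domain on the right carries the
*logic value* of the signal.  The four code combinations (0,0), (0,1),
(1,0), (1,1) give the four per-wire strand variants A0..A3.  Logic is
therefore carried structurally, not by concentration, which is what makes a
single-track NOT gate sound.

Every complex (gate duplex, partially-triggered intermediate, waste) is a
multiset of *elementary strands*.  Elementary strands are identified by
small hashable key tuples; species equality and naming are derived from the
canonical structure built out of those keys, never from display names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DomainCodeError

Bit = int

TOEHOLD_NAME = "T"

#: Domain kinds.  ``code`` domains carry a bit; ``fluor`` appears only in
#: reporter species.
DOMAIN_KINDS = ("toehold", "flank", "code", "fluor")

#: Strand-key tags (first element of every elementary-strand key).
SIG, MAP_TMPL, FAN_TMPL, AMP_TMPL, REP_TMPL, FUEL, FLUOR = (
    "sig", "mt", "ft", "at", "rt", "fuel", "fl",
)


def _check_bit(value: int, what: str = "code") -> int:
    if value not in (0, 1):
        raise DomainCodeError(f"{what} must be 0 or 1, got {value!r}")
    return value


@dataclass(frozen=True)
class Domain:
    """An abstract contiguous stretch of bases treated as one unit."""

    name: str
    kind: str
    code_bit: Optional[int] = None
    length_nt: int = 15

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise DomainCodeError(f"unknown domain kind {self.kind!r}")
        if (self.code_bit is not None) != (self.kind == "code"):
            raise DomainCodeError(
                f"domain {self.name!r}: code_bit is present iff kind='code'"
            )
        if self.code_bit is not None:
            _check_bit(self.code_bit)
        if self.length_nt <= 0:
            raise DomainCodeError(f"domain {self.name!r}: length must be positive")


def toehold(length_nt: int = 6) -> Domain:
    return Domain(TOEHOLD_NAME, "toehold", None, length_nt)


def code_domain(bit: int, length_nt: int = 15) -> Domain:
    return Domain(f"C{_check_bit(bit)}", "code", bit, length_nt)


def flank(wire_id: str, slot: str, length_nt: int = 15) -> Domain:
    # Flanks are wire-specific so signals on different wires cannot
    # cross-react; slots a..d are the four flank positions of the
    # seven-domain layout.
    return Domain(f"{wire_id}.{slot}", "flank", None, length_nt)


def fluor_domain(wire_id: str, bit: int, length_nt: int = 15) -> Domain:
    return Domain(f"FL.{wire_id}.{_check_bit(bit)}", "fluor", None, length_nt)


@dataclass(frozen=True)
class SignalStrand:
    """A seven-domain coded signal strand on one wire."""

    wire_id: str
    left_code: Bit
    right_code: Bit

    def __post_init__(self) -> None:
        _check_bit(self.left_code, "left_code")
        _check_bit(self.right_code, "right_code")

    @property
    def logic_value(self) -> Bit:
        """The logic value of the strand is its right code."""
        return self.right_code

    @property
    def variant(self) -> int:
        """0..3, the A0..A3 variant index (left code is the high bit)."""
        return 2 * self.left_code + self.right_code

    @property
    def name(self) -> str:
        return f"{self.wire_id}.A{self.variant}"

    @property
    def key(self) -> tuple:
        return (SIG, self.wire_id, self.left_code, self.right_code)

    def domains(self, long_len: int = 15, toehold_len: int = 6) -> tuple[Domain, ...]:
        w = self.wire_id
        return (
            flank(w, "a", long_len),
            code_domain(self.left_code, long_len),
            flank(w, "b", long_len),
            toehold(toehold_len),
            flank(w, "c", long_len),
            code_domain(self.right_code, long_len),
            flank(w, "d", long_len),
        )


def make_signal_strand(wire_id: str, left_code: int, right_code: int) -> SignalStrand:
    """The unique seven-domain strand for ``(wire, left, right)``."""
    return SignalStrand(str(wire_id), _check_bit(left_code, "left_code"),
                        _check_bit(right_code, "right_code"))


def signal_key(wire_id: str, logic_value: int) -> tuple:
    """Key of the canonical circuit-level signal species for a logic value.

    The compiler represents the signal of logic value ``v`` on a wire by the
    (v, v) variant (A0 for logic 0, A3 for logic 1), so each wire carries at
    most two distinct strand species.
    """
    v = _check_bit(logic_value, "logic value")
    return (SIG, str(wire_id), v, v)


# ---------------------------------------------------------------------------
# Species


ROLES = (
    "input", "gate", "fuel", "intermediate", "output", "waste", "fluorescence",
)


@dataclass(eq=False)
class Species:
    """A chemical species: a free strand or a strand complex.

    ``structure`` is the canonical form used for identity:

    * ``("single", strand_key)`` for a free elementary strand;
    * ``("cx", ((strand_key, count), ...), state)`` for a complex, with the
      strand multiset sorted, plus a short state tag (empty for resolved
      complexes, ``"enc"`` for the toehold-bound encounter complexes of the
      two-step kinetic mode).

    Two Species with the same structure are the same species regardless of
    how or in which order they were constructed.
    """

    structure: tuple
    name: str
    role: str
    init_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DomainCodeError(f"unknown species role {self.role!r}")
        if self.init_conc < 0:
            raise DomainCodeError(f"{self.name}: init_conc must be >= 0")
        if self.role in ("intermediate", "waste") and self.init_conc != 0:
            raise DomainCodeError(f"{self.name}: {self.role} species start at 0 nM")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and self.structure == other.structure

    def __hash__(self) -> int:
        return hash(self.structure)

    @property
    def is_complex(self) -> bool:
        return self.structure[0] == "cx"

    def strand_counts(self) -> dict[tuple, int]:
        """Decompose into elementary strands (key -> copy number)."""
        tag = self.structure[0]
        if tag == "single":
            return {self.structure[1]: 1}
        if tag == "cx":
            return {k: c for k, c in self.structure[1]}
        raise DomainCodeError(f"species {self.name!r} cannot be decomposed")


def single_species(key: tuple, name: str, role: str, init_conc: float = 0.0) -> Species:
    return Species(("single", key), name, role, init_conc)


def complex_species(strands: Iterable[tuple], name: str, role: str,
                    init_conc: float = 0.0, state: str = "") -> Species:
    counts: dict[tuple, int] = {}
    for k in strands:
        counts[k] = counts.get(k, 0) + 1
    canon = tuple(sorted(counts.items()))
    return Species(("cx", canon, state), name, role, init_conc)


def _serialize_key(key: tuple) -> str:
    return "/".join(str(part) for part in key)


def canonical_name(species: Species) -> str:
    """Deterministic, injective name derived from the canonical structure."""
    tag = species.structure[0]
    if tag == "single":
        return "s:" + _serialize_key(species.structure[1])
    if tag == "cx":
        _, counts, state = species.structure
        body = "+".join(f"{c}x{_serialize_key(k)}" for k, c in counts)
        return f"c:[{body}]" + (f"!{state}" if state else "")
    raise DomainCodeError(f"species {species.name!r} has malformed structure")


# ---------------------------------------------------------------------------
# Kinetic parameters


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and the circuit concentration unit.

    Defaults are the DSD binding/unbinding rates and the 1X unit used by the
    simulated circuits (concentrations in nM, time in s throughout).
    ``k_resolve`` is the branch-migration resolution rate used only by the
    optional two-step kinetic mode.
    """

    k_bind: float = 3.0e-4      # nM^-1 s^-1
    k_unbind: float = 0.1126    # s^-1
    unit_conc_1X: float = 1.0e4  # nM
    k_resolve: float = 1.0      # s^-1, two-step mode only

    def __post_init__(self) -> None:
        for fld in ("k_bind", "k_unbind", "unit_conc_1X", "k_resolve"):
            if getattr(self, fld) <= 0:
                raise DomainCodeError(f"KineticParams.{fld} must be > 0")


# ---------------------------------------------------------------------------
# Conservation accounting


def conservation_vectors(
    species: Sequence[Species],
    reactions: Sequence = (),
) -> tuple[np.ndarray, list[tuple]]:
    """Per-elementary-strand composition matrix.

    Returns ``(matrix, strands)`` where ``matrix[i, j]`` is the copy number
    of elementary strand ``strands[i]`` in ``species[j]``.  Every physical
    reaction must conserve each row of this matrix (strands are neither
    created nor destroyed by strand displacement); use
    :func:`conservation_violations` to check a reaction set.
    """
    strand_set: set[tuple] = set()
    decomposed = []
    for sp in species:
        counts = sp.strand_counts()
        decomposed.append(counts)
        strand_set.update(counts)
    strands = sorted(strand_set)
    index = {k: i for i, k in enumerate(strands)}
    matrix = np.zeros((len(strands), len(species)), dtype=int)
    for j, counts in enumerate(decomposed):
        for k, c in counts.items():
            matrix[index[k], j] = c
    for rxn in reactions:
        _ = _reaction_imbalance(rxn)  # raises on undecomposable species
    return matrix, strands


def _reaction_imbalance(rxn) -> dict[tuple, int]:
    net: dict[tuple, int] = {}
    for sp in rxn.reactants:
        for k, c in sp.strand_counts().items():
            net[k] = net.get(k, 0) - c
    for sp in rxn.products:
        for k, c in sp.strand_counts().items():
            net[k] = net.get(k, 0) + c
    return {k: v for k, v in net.items() if v != 0}


def conservation_violations(reactions: Sequence) -> list[tuple]:
    """Reactions that fail to conserve some elementary-strand count.

    Returns a list of ``(reaction, {strand_key: net_change})`` tuples; an
    empty list means every reaction is balanced.
    """
    bad = []
    for rxn in reactions:
        imbalance = _reaction_imbalance(rxn)
        if imbalance:
            bad.append((rxn, imbalance))
    return bad
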
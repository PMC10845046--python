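"""Gate constructors: mapping modules, fan-out gates, amplifiers, reporters.

An *n-input mapping module* is the universal logic element of the domain
coding strategy: it holds one gate duplex per input combination, and the
coded output domain ``k_i`` of each duplex IS the corresponding truth-table
entry.  A module of arity n therefore realises all ``2^(2^n)`` Boolean
functions purely by re-coding -- negation costs nothing, unlike dual-rail
designs where NOT doubles the component count.

The three auxiliary families keep multi-gate circuits well-supplied:

* fan-out gates copy one signal to m downstream wires, catalytically
  (fuel strands H0/H1 regenerate the input);
* amplifiers restore a decayed signal up to the gate-duplex concentration,
  also catalytically;
* reporters irreversibly convert an output strand into one of two
  fluorescence species (Y_x1 for logic 0, Y_x2 for logic 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import CompileError, DomainCodeError
from .strands import (
    AMP_TMPL, FAN_TMPL, FLUOR, FUEL, MAP_TMPL, REP_TMPL,
    _check_bit, signal_key,
)

Bits = tuple[int, ...]


def _as_bits(values: Iterable[int], what: str) -> Bits:
    out = tuple(int(v) for v in values)
    for v in out:
        _check_bit(v, what)
    return out


def combo_index(match_codes: Sequence[int]) -> int:
    """Truth-table row index of an input combination.

    ``match_codes[j]`` is the bit on the j-th input wire (consumption
    order, X0 first); the highest-indexed input is the most significant
    bit, so row 0 is all-zeros and row 2^n - 1 is all-ones.
    """
    return sum(b << j for j, b in enumerate(match_codes))


@dataclass(frozen=True)
class GateDuplex:
    """One double strand of a gate.

    ``match_codes`` is the input-combination row this duplex accepts (in
    consumption order); ``out_code`` is the logic value of the strand it
    releases on ``out_wire``.  ``branch`` distinguishes the m parallel
    duplexes of a fan-out path.
    """

    family: str           # mapping | fanout | amplifier | reporter
    gate_id: str
    match_codes: Bits
    out_code: int
    out_wire: str
    label: str
    branch: int = 0

    @property
    def bottom_key(self) -> tuple:
        if self.family == "mapping":
            return (MAP_TMPL, self.gate_id, self.match_codes, self.out_code)
        if self.family == "fanout":
            return (FAN_TMPL, self.gate_id, self.match_codes[0], self.branch)
        if self.family == "amplifier":
            return (AMP_TMPL, self.gate_id, self.match_codes[0])
        if self.family == "reporter":
            return (REP_TMPL, self.gate_id, self.match_codes[0])
        raise DomainCodeError(f"unknown duplex family {self.family!r}")

    @property
    def top_key(self) -> tuple:
        if self.family == "reporter":
            return (FLUOR, self.out_wire, self.out_code)
        return signal_key(self.out_wire, self.out_code)


@dataclass
class GateModule:
    """An n-input, one-output mapping module (2^n coded duplexes)."""

    gate_id: str
    n: int
    in_wires: tuple[str, ...]
    out_wire: str
    k_codes: Bits
    duplexes: tuple[GateDuplex, ...] = field(default_factory=tuple)
    conc: Optional[float] = None  # duplex concentration; None -> circuit unit

    family = "mapping"

    @property
    def consumed_wires(self) -> tuple[str, ...]:
        return self.in_wires

    @property
    def driven_wires(self) -> tuple[str, ...]:
        return (self.out_wire,)


@dataclass
class AuxGate:
    """A fan-out gate, amplifier or reporter on one wire."""

    family: str
    gate_id: str
    in_wire: str
    out_wires: tuple[str, ...]
    duplexes: tuple[GateDuplex, ...]
    fan_m: Optional[int] = None
    fuel_mult: float = 1.0
    conc: Optional[float] = None

    @property
    def has_fuels(self) -> bool:
        return self.family in ("fanout", "amplifier")

    @property
    def consumed_wires(self) -> tuple[str, ...]:
        return (self.in_wire,)

    @property
    def driven_wires(self) -> tuple[str, ...]:
        return self.out_wires

    def fuel_key(self, logic_value: int) -> tuple:
        return (FUEL, self.gate_id, _check_bit(logic_value))

    def path_duplexes(self, logic_value: int) -> tuple[GateDuplex, ...]:
        return tuple(d for d in self.duplexes if d.match_codes[0] == logic_value)


# ---------------------------------------------------------------------------
# Mapping modules


def make_mapping_module(
    n: int,
    k_codes: Sequence[int],
    in_wires: Sequence[str],
    out_wire: str,
    gate_id: Optional[str] = None,
    conc: Optional[float] = None,
) -> GateModule:
    """Build the n-input mapping module coded ``k_codes``.

    ``k_codes[i]`` is the output logic value for input combination ``i``
    (row order as in :func:`combo_index`), so the coding vector is the
    module's truth table.
    """
    if n < 1:
        raise CompileError(f"mapping module arity must be >= 1, got {n}")
    k = _as_bits(k_codes, "k code")
    if len(k) != 2 ** n:
        raise CompileError(
            f"mapping module of arity {n} needs {2 ** n} k codes, got {len(k)}"
        )
    wires = tuple(str(w) for w in in_wires)
    if len(wires) != n:
        raise CompileError(f"expected {n} input wires, got {len(wires)}")
    if len(set(wires) | {out_wire}) != n + 1:
        raise CompileError("module wires must be distinct")
    gid = gate_id or f"M.{out_wire}"
    duplexes = []
    for i in range(2 ** n):
        match = tuple((i >> j) & 1 for j in range(n))
        duplexes.append(GateDuplex(
            family="mapping", gate_id=gid, match_codes=match,
            out_code=k[i], out_wire=str(out_wire), label=f"D{i + 1}",
        ))
    return GateModule(gate_id=gid, n=n, in_wires=wires, out_wire=str(out_wire),
                      k_codes=k, duplexes=tuple(duplexes), conc=conc)


def module_function(module: GateModule) -> Bits:
    """Truth table computed from the module's duplexes.

    ``f(x) = k_codes[combo_index(x)]``; by construction this is the inverse
    of :func:`codes_for_function`.
    """
    table = [None] * (2 ** module.n)
    for d in module.duplexes:
        table[combo_index(d.match_codes)] = d.out_code
    if any(v is None for v in table):
        raise CompileError(f"module {module.gate_id} is missing duplexes")
    return tuple(table)


def codes_for_function(truth_table: Sequence[int]) -> Bits:
    """Coding vector realising a truth table (bijective inverse of
    :func:`module_function`)."""
    table = _as_bits(truth_table, "truth-table entry")
    size = len(table)
    if size < 2 or size & (size - 1):
        raise CompileError(f"truth-table length must be a power of two, got {size}")
    return table


def enumerate_realizable_functions(n: int, cap: int = 4) -> tuple[int, frozenset[Bits]]:
    """All Boolean functions realisable by an n-input mapping module.

    Exhaustively codes all ``2^(2^n)`` duplex codings, derives each truth
    table through :func:`module_function`, and returns ``(count, tables)``.
    Every table is realised by exactly one coding, so the count equals the
    Cartesian-product mapping count ``|A|^(|A|^n)`` with ``|A| = 2``.
    """
    if n < 1:
        raise CompileError("arity must be >= 1")
    if n > cap:
        raise CompileError(f"arity {n} exceeds enumeration cap {cap}")
    wires = tuple(f"x{j}" for j in range(n))
    tables = set()
    for coding in itertools.product((0, 1), repeat=2 ** n):
        module = make_mapping_module(n, coding, wires, "y")
        tables.add(module_function(module))
    return len(tables), frozenset(tables)


#: Named codings accepted in netlist configs.  Keys are (name, arity).
ONE_INPUT_NAMES = {(0, 0): "SET0", (1, 1): "SET1", (0, 1): "YES", (1, 0): "NOT"}

NAMED_FUNCTIONS: dict[str, tuple[int, Bits]] = {
    "SET0": (1, (0, 0)),
    "SET1": (1, (1, 1)),
    "YES": (1, (0, 1)),
    "NOT": (1, (1, 0)),
    "OR": (2, (0, 1, 1, 1)),
    "AND": (2, (0, 0, 0, 1)),
    "NOR": (2, (1, 0, 0, 0)),
    "NAND": (2, (1, 1, 1, 0)),
    "XOR": (2, (0, 1, 1, 0)),
    "XNOR": (2, (1, 0, 0, 1)),
    "OR3": (3, (0, 1, 1, 1, 1, 1, 1, 1)),
    "AND3": (3, (0, 0, 0, 0, 0, 0, 0, 1)),
}


def function_name(table: Sequence[int]) -> Optional[str]:
    """Conventional name of a truth table, if it has one."""
    t = tuple(table)
    for name, (_, coding) in NAMED_FUNCTIONS.items():
        if coding == t:
            return name
    return None


# ---------------------------------------------------------------------------
# Auxiliary gates


def make_fanout_gate(
    wire: str,
    m: int = 2,
    out_wires: Optional[Sequence[str]] = None,
    gate_id: Optional[str] = None,
    conc: Optional[float] = None,
    fuel_mult: float = 1.0,
) -> AuxGate:
    """Catalytic fan-out of one signal onto ``m`` downstream wires.

    For each logic value v there are m duplexes (one per copy) and one fuel
    strand H_v; the input strand triggers every duplex of its logic path,
    releasing the m coded copies, and the fuel recovers the input from the
    intermediate, so the input acts as a catalyst.  Fuel concentration is
    ``fuel_mult`` times the total concentration of the path's duplexes
    (``fuel_mult=1`` is the stoichiometric two-fold excess over a single
    duplex at m=2).
    """
    if m < 2:
        raise CompileError("fan-out needs m >= 2 (use a YES module for m = 1)")
    outs = tuple(out_wires) if out_wires is not None else tuple(
        f"{wire}.o{i + 1}" for i in range(m))
    if len(outs) != m or len(set(outs)) != m:
        raise CompileError(f"fan-out of {wire} needs {m} distinct output wires")
    gid = gate_id or f"FO.{wire}"
    duplexes = []
    for v in (0, 1):
        for i, ow in enumerate(outs):
            duplexes.append(GateDuplex(
                family="fanout", gate_id=gid, match_codes=(v,), out_code=v,
                out_wire=str(ow), label=f"F{v * m + i + 1:02d}", branch=i,
            ))
    return AuxGate(family="fanout", gate_id=gid, in_wire=str(wire),
                   out_wires=outs, duplexes=tuple(duplexes), fan_m=m,
                   fuel_mult=fuel_mult, conc=conc)


def make_amplifier(
    wire: str,
    out_wire: Optional[str] = None,
    gate_id: Optional[str] = None,
    conc: Optional[float] = None,
    fuel_mult: float = 2.0,
) -> AuxGate:
    """Catalytic amplifier restoring a signal to the duplex concentration.

    Amp0/H0 serve logic 0 and Amp1/H1 serve logic 1; only the path matching
    the incoming logic value reacts.  The fuel is supplied at twice the
    duplex concentration by default.
    """
    ow = str(out_wire) if out_wire is not None else f"{wire}.amp"
    gid = gate_id or f"AMP.{wire}"
    duplexes = tuple(
        GateDuplex(family="amplifier", gate_id=gid, match_codes=(v,),
                   out_code=v, out_wire=ow, label=f"Amp{v}")
        for v in (0, 1)
    )
    return AuxGate(family="amplifier", gate_id=gid, in_wire=str(wire),
                   out_wires=(ow,), duplexes=duplexes, fuel_mult=fuel_mult,
                   conc=conc)


def make_reporter(
    wire: str,
    gate_id: Optional[str] = None,
    conc: Optional[float] = None,
) -> AuxGate:
    """Fluorescence reporter: Rep0 converts logic-0 strands into Y_x1,
    Rep1 converts logic-1 strands into Y_x2; both irreversibly."""
    gid = gate_id or f"REP.{wire}"
    duplexes = tuple(
        GateDuplex(family="reporter", gate_id=gid, match_codes=(v,),
                   out_code=v, out_wire=str(wire), label=f"Rep{v}")
        for v in (0, 1)
    )
    return AuxGate(family="reporter", gate_id=gid, in_wire=str(wire),
                   out_wires=(), duplexes=duplexes, fan_m=None,
                   fuel_mult=0.0, conc=conc)


def fluorescence_name(wire: str, logic_value: int) -> str:
    """Display name of a fluorescence species: Y_<wire>_1 reports logic 0,
    Y_<wire>_2 reports logic 1."""
    return f"Y_{wire}_{_check_bit(logic_value) + 1}"
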
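"""Prebuilt circuits: the 4-bit square root and the 2^x exponentiation.

Both are classic benchmarks for strand-displacement logic.  The square-root
circuit computes ``Y1Y0 = floor(sqrt(X3X2X1X0))`` with just two mapping
modules (a two-input module for Y1, which reduces to OR(X3, X2), and a
four-input module for Y0) plus fan-out-two gates on the shared inputs.  The
exponentiation circuit is a 3-to-8 decoder: three NOT modules and eight
three-input AND modules produce the one-hot word Y7..Y0 = binary(2^x),
with a fan-out-two on each input, an amplifier restoring every output rail
and a reporter pair reading each rail out as fluorescence.

Each builder takes the input word and returns a ready-to-compile
:class:`~domaincode.compiler.Netlist`; ``verify_truth_table`` runs one
simulation per input row and compares the decoded words against the truth
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import pandas as pd

from .compiler import Netlist, compile_netlist
from .errors import CompileError, DecodingError, DomainCodeError
from .gates import (
    make_amplifier, make_fanout_gate, make_mapping_module, make_reporter,
)
from .kinetics import decode_word, settle_time, simulate
from .strands import KineticParams

#: Circuit concentration units used by the simulated circuits.
SQRT4_UNIT_CONC = 1.0e4     # nM (1X)
EXP_UNIT_CONC = 1.0e3       # nM


@dataclass
class TruthTable:
    """A complete n_in -> n_out Boolean function, rows keyed by input word."""

    n_in: int
    n_out: int
    rows: dict[int, int]

    def __post_init__(self) -> None:
        if set(self.rows) != set(range(2 ** self.n_in)):
            raise DomainCodeError("truth table must cover every input word")
        for x, y in self.rows.items():
            if not 0 <= y < 2 ** self.n_out:
                raise DomainCodeError(
                    f"row {x}: output {y} does not fit in {self.n_out} bits")

    def output_word(self, x: int) -> int:
        return self.rows[x]

    def output_bits(self, x: int) -> tuple[int, ...]:
        """Output bits MSB first."""
        y = self.rows[x]
        return tuple((y >> (self.n_out - 1 - i)) & 1 for i in range(self.n_out))

    def word_str(self, x: int) -> str:
        return format(self.rows[x], f"0{self.n_out}b")

    def column(self, bit: int) -> tuple[int, ...]:
        """Single-output truth table of output bit ``bit`` (row order)."""
        return tuple((self.rows[x] >> bit) & 1 for x in range(2 ** self.n_in))


def sqrt4_table() -> TruthTable:
    """Y1Y0 = floor(sqrt(x)) for the four-bit input x."""
    return TruthTable(4, 2, {x: math.isqrt(x) for x in range(16)})


def exponentiation_table() -> TruthTable:
    """Y7..Y0 = binary (one-hot) representation of 2^x for x = X2X1X0."""
    return TruthTable(3, 8, {x: 1 << x for x in range(8)})


def _input_bits(x: int, n: int) -> dict[str, int]:
    if not 0 <= x < 2 ** n:
        raise CompileError(f"input word {x} does not fit in {n} bits")
    return {f"X{i}": (x >> i) & 1 for i in range(n)}


def _apply_flip(k_codes: tuple[int, ...], gate_id: str,
                flip: Optional[tuple[str, int]]) -> tuple[int, ...]:
    """Fault injection: flip one k bit of one module."""
    if flip is None or flip[0] != gate_id:
        return k_codes
    idx = flip[1]
    if not 0 <= idx < len(k_codes):
        raise CompileError(f"flip index {idx} out of range for {gate_id}")
    return tuple(b ^ 1 if i == idx else b for i, b in enumerate(k_codes))


def build_sqrt4_netlist(
    x: int,
    unit_conc: float = SQRT4_UNIT_CONC,
    params: Optional[KineticParams] = None,
    flip: Optional[tuple[str, int]] = None,
) -> Netlist:
    """Four-bit square-root circuit for input word ``x``.

    X3 and X2 feed both modules and go through fan-out-two gates; X1 and X0
    feed only the four-input module.  Amplifier + reporter stages on Y1 and
    Y0 read the result out; the decoded word is Y1Y0.
    """
    params = params or KineticParams(unit_conc_1X=unit_conc)
    table = sqrt4_table()
    k_y0 = _apply_flip(table.column(0), "M.Y0", flip)
    # Y1 of floor-sqrt depends only on (X3, X2) and reduces to OR: the
    # result is >= 2 exactly when x >= 4.  Row order (x3 x2) = 00,01,10,11
    # with X1 = X0 = 0 (Y1 is constant over them).
    k_y1 = _apply_flip(tuple(
        (table.rows[((idx >> 1) << 3) | ((idx & 1) << 2)] >> 1) & 1
        for idx in range(4)
    ), "M.Y1", flip)
    gates = [
        make_fanout_gate("X3", 2, out_wires=("X3a", "X3b"), gate_id="FO.X3"),
        make_fanout_gate("X2", 2, out_wires=("X2a", "X2b"), gate_id="FO.X2"),
        make_mapping_module(2, k_y1, ("X2a", "X3a"), "Y1", gate_id="M.Y1"),
        make_mapping_module(4, k_y0, ("X0", "X1", "X2b", "X3b"), "Y0",
                            gate_id="M.Y0"),
        make_amplifier("Y1", out_wire="Z1", gate_id="AMP.Y1"),
        make_amplifier("Y0", out_wire="Z0", gate_id="AMP.Y0"),
        make_reporter("Z1", gate_id="REP.Z1"),
        make_reporter("Z0", gate_id="REP.Z0"),
    ]
    return Netlist(
        name=f"sqrt4_x{x}", gates=gates, input_assignment=_input_bits(x, 4),
        unit_conc=unit_conc, params=params, output_wires=("Z1", "Z0"),
    )


def build_exponentiation_netlist(
    x: int,
    unit_conc: float = EXP_UNIT_CONC,
    params: Optional[KineticParams] = None,
    flip: Optional[tuple[str, int]] = None,
) -> Netlist:
    """2^x exponentiation circuit (3-to-8 decoder) for input word ``x``.

    Each input X_i passes a fan-out-two gate (one copy to its NOT module,
    one copy shared by the four AND modules using the positive literal);
    each NOT output is shared by the four AND modules using the negative
    literal.  The shared literal rails divide among their consumers, which
    is why every output rail carries an amplifier before its reporter.
    Fan-out fuels are at twice the total of the fan-out duplexes.
    """
    params = params or KineticParams(unit_conc_1X=unit_conc)
    gates = []
    shared = set()
    for i in range(3):
        gates.append(make_fanout_gate(
            f"X{i}", 2, out_wires=(f"X{i}a", f"X{i}b"), gate_id=f"FO.X{i}",
            fuel_mult=2.0))
        not_k = _apply_flip((1, 0), f"NOT.X{i}", flip)
        gates.append(make_mapping_module(
            1, not_k, (f"X{i}a",), f"N{i}", gate_id=f"NOT.X{i}"))
        shared.update({f"X{i}b", f"N{i}"})
    for j in range(8):
        lits = tuple(f"X{i}b" if (j >> i) & 1 else f"N{i}" for i in range(3))
        and_k = _apply_flip((0, 0, 0, 0, 0, 0, 0, 1), f"AND.Y{j}", flip)
        gates.append(make_mapping_module(
            3, and_k, lits, f"Y{j}", gate_id=f"AND.Y{j}"))
        gates.append(make_amplifier(f"Y{j}", out_wire=f"Z{j}",
                                    gate_id=f"AMP.Y{j}"))
        gates.append(make_reporter(f"Z{j}", gate_id=f"REP.Z{j}"))
    return Netlist(
        name=f"exponentiation_x{x}", gates=gates,
        input_assignment=_input_bits(x, 3), unit_conc=unit_conc,
        params=params, shared_wires=frozenset(shared),
        output_wires=tuple(f"Z{j}" for j in range(7, -1, -1)),
    )


def build_module_stage(
    k_codes,
    input_bits,
    unit_conc: float = SQRT4_UNIT_CONC,
    params: Optional[KineticParams] = None,
) -> Netlist:
    """A single mapping module followed by an amplifier and a reporter.

    ``input_bits[j]`` drives input wire A{j} (A0 is consumed first).  This
    is the single-gate test stage of the one- and two-input module
    simulations.
    """
    k = tuple(k_codes)
    n = len(k).bit_length() - 1
    if 2 ** n != len(k):
        raise CompileError("k_codes length must be a power of two")
    bits = tuple(input_bits)
    if len(bits) != n:
        raise CompileError(f"expected {n} input bits, got {len(bits)}")
    params = params or KineticParams(unit_conc_1X=unit_conc)
    wires = tuple(f"A{j}" for j in range(n))
    gates = [
        make_mapping_module(n, k, wires, "Y", gate_id="M.Y"),
        make_amplifier("Y", out_wire="Z", gate_id="AMP.Y"),
        make_reporter("Z", gate_id="REP.Z"),
    ]
    return Netlist(
        name=f"stage_{''.join(map(str, k))}", gates=gates,
        input_assignment={w: b for w, b in zip(wires, bits)},
        unit_conc=unit_conc, params=params, output_wires=("Z",),
    )


def verify_truth_table(
    netlist_factory: Callable[[int], Netlist],
    table: TruthTable,
    t_end: float,
    epsilon: float = 0.05,
    ratio_threshold: float = 10.0,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    mode: str = "one-step",
) -> pd.DataFrame:
    """Simulate every input row and compare decoded words to the table.

    Returns a per-row report with the decoded word, pass/fail flag, settle
    time and worst plateau separation; decoding ambiguities mark the row
    failed with the diagnostic in ``note``.
    """
    records = []
    for x in range(2 ** table.n_in):
        netlist = netlist_factory(x)
        crn = compile_netlist(netlist, mode=mode)
        traj = simulate(crn, t_end, rtol=rtol, atol=atol)
        report = settle_time(traj, epsilon=epsilon)
        expected = table.word_str(x)
        decoded, ok, note = None, False, ""
        try:
            outcome = decode_word(traj, netlist.output_wires,
                                  ratio_threshold=ratio_threshold)
            decoded = outcome.word
            ok = decoded == expected
            if not ok:
                note = "decoded word differs from truth table"
        except DecodingError as exc:
            note = str(exc)
        records.append({
            "input": x,
            "input_word": format(x, f"0{table.n_in}b"),
            "expected_word": expected,
            "decoded_word": decoded,
            "ok": ok,
            "settle_s": report.settle_time,
            "note": note,
        })
    return pd.DataFrame.from_records(records)
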
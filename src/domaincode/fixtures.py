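"""Seeded random fixtures: mapping modules and small layered netlists.

Property tests need circuits that were not hand-picked; this module builds
deterministic families from a seed — random k-codings of modules with
arity 1..3, and random two-level netlists (two first-layer modules feeding
a second-layer module, with a fan-out-two on the shared middle input and an
amplifier/reporter tail) whose defining truth table is computed
independently of the chemistry, so a compile+simulate+decode loop can be
checked against it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable

from .circuits import TruthTable
from .compiler import Netlist
from .gates import (
    GateModule, make_amplifier, make_fanout_gate, make_mapping_module,
    make_reporter,
)
from .strands import KineticParams


@dataclass
class RandomModule:
    module: GateModule
    table: tuple[int, ...]


@dataclass
class RandomCircuit:
    """A two-level random circuit plus its composed truth table."""

    name: str
    table: TruthTable
    factory: Callable[[int], Netlist]
    codings: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]


def _random_coding(rng: random.Random, n: int) -> tuple[int, ...]:
    return tuple(rng.randrange(2) for _ in range(2 ** n))


def random_modules(seed: int, count: int = 10) -> list[RandomModule]:
    """Deterministic family of random mapping modules, arity 1..3."""
    rng = random.Random(seed)
    out = []
    for i in range(count):
        n = rng.choice((1, 2, 3))
        coding = _random_coding(rng, n)
        wires = tuple(f"w{i}.{j}" for j in range(n))
        module = make_mapping_module(n, coding, wires, f"w{i}.out",
                                     gate_id=f"RM{i}")
        out.append(RandomModule(module=module, table=coding))
    return out


def _compose(f1, f2, f3, x: int) -> int:
    """g(x0,x1,x2) = f3(f1(x0, x1), f2(x1, x2)), low input bit first."""
    x0, x1, x2 = x & 1, (x >> 1) & 1, (x >> 2) & 1
    m1 = f1[x0 + 2 * x1]
    m2 = f2[x1 + 2 * x2]
    return f3[m1 + 2 * m2]


def random_circuits(seed: int, count: int = 3,
                    unit_conc: float = 1.0e4) -> list[RandomCircuit]:
    """Deterministic family of two-level netlists with known truth tables."""
    rng = random.Random(seed)
    out = []
    for i in range(count):
        f1 = _random_coding(rng, 2)
        f2 = _random_coding(rng, 2)
        f3 = _random_coding(rng, 2)
        table = TruthTable(3, 1, {x: _compose(f1, f2, f3, x)
                                  for x in range(8)})
        name = f"rand2level_{seed}_{i}"

        def factory(x: int, f1=f1, f2=f2, f3=f3, name=name) -> Netlist:
            gates = [
                make_fanout_gate("I1", 2, out_wires=("I1a", "I1b"),
                                 gate_id="FO.I1"),
                make_mapping_module(2, f1, ("I0", "I1a"), "M1",
                                    gate_id="L1.M1"),
                make_mapping_module(2, f2, ("I1b", "I2"), "M2",
                                    gate_id="L1.M2"),
                make_mapping_module(2, f3, ("M1", "M2"), "Y",
                                    gate_id="L2.M3"),
                make_amplifier("Y", out_wire="Z", gate_id="AMP.Y"),
                make_reporter("Z", gate_id="REP.Z"),
            ]
            assignment = {f"I{j}": (x >> j) & 1 for j in range(3)}
            return Netlist(
                name=f"{name}_x{x}", gates=gates,
                input_assignment=assignment, unit_conc=unit_conc,
                params=KineticParams(unit_conc_1X=unit_conc),
                output_wires=("Z",),
            )

        out.append(RandomCircuit(name=name, table=table, factory=factory,
                                 codings=(f1, f2, f3)))
    return out


def generate_fixtures(seed: int, n_modules: int = 10,
                      n_circuits: int = 3) -> dict:
    """Everything the property tests consume, reproducible from the seed."""
    return {
        "modules": random_modules(seed, n_modules),
        "circuits": random_circuits(seed, n_circuits),
    }
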
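"""Netlist configuration files (YAML or JSON).

Schema::

    name: my_circuit
    unit_conc: 10000            # the circuit's 1X, in nM
    params: {k_bind: 3.0e-4, k_unbind: 0.1126}
    inputs: {X0: 1, X1: 0}      # bit per input wire
    shared_wires: [lit0]        # wires deliberately feeding several gates
    outputs: [Z]                # reporter wires, MSB first
    gates:
      - {type: mapping, id: G1, inputs: [X0, X1], output: Y, function: OR}
      - {type: mapping, id: G2, inputs: [Y], output: W, k_codes: [1, 0]}
      - {type: fanout, id: F1, input: X0, outputs: [a, b]}
      - {type: amplifier, id: A1, input: Y, output: Z}
      - {type: reporter, id: R1, input: Z}

Mapping gates take either an explicit ``k_codes`` row vector or a named
``function`` (SET0/SET1/YES/NOT, OR/AND/..., OR3/AND3).  Optional per-gate
keys: ``conc`` (nM) and ``fuel_mult``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml

from .compiler import Netlist
from .errors import CompileError, ConfigError
from .gates import (
    NAMED_FUNCTIONS, make_amplifier, make_fanout_gate, make_mapping_module,
    make_reporter,
)
from .strands import KineticParams


def _mapping_gate(entry: dict):
    inputs = entry.get("inputs")
    output = entry.get("output")
    if not inputs or output is None:
        raise ConfigError(f"mapping gate {entry.get('id')!r} needs inputs/output")
    if "k_codes" in entry:
        k = tuple(entry["k_codes"])
        n = len(inputs)
    elif "function" in entry:
        fname = str(entry["function"]).upper()
        if fname not in NAMED_FUNCTIONS:
            raise ConfigError(f"unknown function name {entry['function']!r}")
        n, k = NAMED_FUNCTIONS[fname]
        if n != len(inputs):
            raise ConfigError(
                f"function {fname} has arity {n}, gate lists {len(inputs)} inputs")
    else:
        raise ConfigError(
            f"mapping gate {entry.get('id')!r} needs k_codes or function")
    return make_mapping_module(n, k, inputs, output, gate_id=entry.get("id"),
                               conc=entry.get("conc"))


def _build_gate(entry: dict):
    kind = entry.get("type")
    if kind == "mapping":
        return _mapping_gate(entry)
    if kind == "fanout":
        outs = entry.get("outputs")
        m = entry.get("m", len(outs) if outs else None)
        if m is None:
            raise ConfigError(f"fanout {entry.get('id')!r} needs outputs or m")
        return make_fanout_gate(entry["input"], m, out_wires=outs,
                                gate_id=entry.get("id"),
                                conc=entry.get("conc"),
                                fuel_mult=entry.get("fuel_mult", 1.0))
    if kind == "amplifier":
        return make_amplifier(entry["input"], out_wire=entry.get("output"),
                              gate_id=entry.get("id"), conc=entry.get("conc"),
                              fuel_mult=entry.get("fuel_mult", 2.0))
    if kind == "reporter":
        return make_reporter(entry["input"], gate_id=entry.get("id"),
                             conc=entry.get("conc"))
    raise ConfigError(f"unknown gate type {kind!r}")


def load_netlist(path, input_word: Optional[str] = None) -> Netlist:
    """Load a netlist config; ``input_word`` (MSB first over sorted input
    wires) overrides the file's ``inputs`` section."""
    p = Path(path)
    try:
        text = p.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read netlist config {path}: {exc}") from exc
    try:
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse netlist config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"netlist config {path} must be a mapping")

    try:
        params = KineticParams(**data.get("params", {}))
    except TypeError as exc:
        raise ConfigError(f"bad params block: {exc}") from exc

    try:
        gates = [_build_gate(entry) for entry in data.get("gates", [])]
    except CompileError as exc:
        raise ConfigError(str(exc)) from exc
    except KeyError as exc:
        raise ConfigError(f"gate entry missing key {exc}") from exc

    inputs = {str(w): int(b) for w, b in (data.get("inputs") or {}).items()}
    if input_word is not None:
        wires = sorted(inputs)
        if len(input_word) != len(wires) or set(input_word) - set("01"):
            raise ConfigError(
                f"input word {input_word!r} does not match input wires {wires}")
        # MSB first over the sorted wire names (X2 X1 X0 style).
        inputs = {w: int(b) for w, b in zip(reversed(wires), input_word)}

    return Netlist(
        name=str(data.get("name", p.stem)),
        gates=gates,
        input_assignment=inputs,
        unit_conc=float(data.get("unit_conc", params.unit_conc_1X)),
        params=params,
        shared_wires=frozenset(data.get("shared_wires", ())),
        output_wires=tuple(data.get("outputs", ())),
    )
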
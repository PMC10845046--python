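"""Netlist -> chemical reaction network compiler.

A :class:`Netlist` wires mapping modules, fan-out gates, amplifiers and
reporters together and assigns one input strand per input wire.  Compilation
expands every gate into its reaction template under mass-action kinetics:

* an n-input mapping-module duplex consumes its inputs sequentially (X0
  first); each matched step is one irreversible toehold-mediated
  displacement, the last step releases the coded output strand plus a fully
  hybridised waste duplex;
* fan-out and amplifier duplexes release their output while capturing the
  input, and the fuel strand recovers the input from the intermediate, so
  the input acts catalytically;
* reporter duplexes irreversibly convert an output strand into a
  fluorescence species.

Mismatched strand/duplex encounters (left duplex code != right input code)
are unproductive and are omitted from the network: their toehold bind/unbind
nets to zero flux.  The optional ``two-step`` mode makes matched encounters
explicit (bind at k_bind, unbind at k_unbind, irreversible resolution at
k_resolve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import CompileError, DomainCodeError
from .gates import AuxGate, GateDuplex, GateModule, fluorescence_name
from .strands import (
    FLUOR, KineticParams, Species, canonical_name, complex_species,
    conservation_violations, make_signal_strand, signal_key, single_species,
)

Gate = Union[GateModule, AuxGate]

MODES = ("one-step", "two-step")

_ROLE_RANK = {role: i for i, role in enumerate(
    ("input", "gate", "fuel", "output", "intermediate", "waste", "fluorescence"))}

#: Sentinel owner for circuit input strands in the component accounting.
INPUT_OWNER = "__input__"

_FAMILIES = ("mapping", "fanout", "amplifier", "reporter")

_STAGE_PRESETS = {
    # Computational core: the stages the circuit-size strand-count
    # argument covers.
    "core": ("inputs", "mapping", "fanout"),
    "full": ("inputs",) + _FAMILIES,
}


@dataclass
class Reaction:
    """An elementary mass-action reaction.

    ``rate`` is in nM^-1 s^-1 for bimolecular and s^-1 for unimolecular
    reactions.  Reversible steps are represented as paired irreversible
    reactions, so ``reversible`` is informational.
    """

    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate: float
    reversible: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2 or not 1 <= len(self.products) <= 3:
            raise CompileError(f"reaction {self.label!r}: bad arity")
        if self.rate <= 0:
            raise CompileError(f"reaction {self.label!r}: rate must be > 0")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lhs = " + ".join(s.name for s in self.reactants)
        rhs = " + ".join(s.name for s in self.products)
        return f"<{lhs} -> {rhs} @ {self.rate:g}>"


@dataclass
class Netlist:
    """A wired composition of gates plus one input assignment.

    Wires are implicit (the union of gate ports).  Each wire may have at
    most one driver; a wire consumed by more than one downstream gate must
    be a fan-out output or be listed in ``shared_wires`` (an explicit
    declaration that the divided signal level is acceptable, e.g. because an
    amplifier downstream restores it).  ``output_wires`` are the reporter
    input wires in word order (MSB first), used for decoding.
    """

    name: str
    gates: list = field(default_factory=list)
    input_assignment: dict = field(default_factory=dict)
    unit_conc: float = 1.0e4
    params: KineticParams = field(default_factory=KineticParams)
    shared_wires: frozenset = frozenset()
    output_wires: tuple = ()

    def drivers(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.gates:
            for w in g.driven_wires:
                out.setdefault(w, []).append(g.gate_id)
        return out

    def consumers(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.gates:
            for w in g.consumed_wires:
                out.setdefault(w, []).append(g.gate_id)
        return out

    def validate(self) -> None:
        ids = [g.gate_id for g in self.gates]
        if len(ids) != len(set(ids)):
            raise CompileError(f"netlist {self.name!r}: duplicate gate ids")
        for w, b in self.input_assignment.items():
            if b not in (0, 1):
                raise CompileError(f"input {w!r}: assignment must be a bit")
        drivers = self.drivers()
        for w, gids in drivers.items():
            if len(gids) > 1:
                raise CompileError(f"wire {w!r} driven by several gates: {gids}")
            if w in self.input_assignment:
                raise CompileError(f"input wire {w!r} must not be gate-driven")
        fanout_outputs = {
            w for g in self.gates if getattr(g, "family", "") == "fanout"
            for w in g.driven_wires
        }
        for w, gids in self.consumers().items():
            if w not in drivers and w not in self.input_assignment:
                raise CompileError(f"gate input wire {w!r} is not driven")
            if len(gids) > 1 and w not in fanout_outputs \
                    and w not in self.shared_wires:
                raise CompileError(
                    f"wire {w!r} is consumed by {len(gids)} gates but is not "
                    "driven through a fan-out gate (add one, or declare the "
                    "wire shared)"
                )


# ---------------------------------------------------------------------------
# Expansion machinery


class _Builder:
    """Species registry + reaction emitter used during compilation."""

    def __init__(self, params: KineticParams, unit_conc: float, mode: str,
                 input_wires: Iterable[str] = ()):
        if mode not in MODES:
            raise CompileError(f"unknown kinetic mode {mode!r}")
        self.params = params
        self.unit_conc = unit_conc
        self.mode = mode
        self.input_wires = set(input_wires)
        self.registry: dict[tuple, Species] = {}
        self.owner: dict[tuple, str] = {}
        self.reactions: list[Reaction] = []
        self.provenance: dict[str, list[Reaction]] = {}

    def intern(self, sp: Species) -> Species:
        return self.registry.setdefault(sp.structure, sp)

    def signal(self, wire: str, value: int) -> Species:
        role = "input" if wire in self.input_wires else "output"
        strand = make_signal_strand(wire, value, value)
        return self.intern(single_species(strand.key, strand.name, role))

    def add_input(self, wire: str, value: int, conc: float) -> Species:
        strand = make_signal_strand(wire, value, value)
        sp = self.intern(single_species(strand.key, strand.name, "input", conc))
        self.owner.setdefault(sp.structure, INPUT_OWNER)
        return sp

    def own(self, gate_id: str, sp: Species) -> Species:
        self.owner.setdefault(sp.structure, gate_id)
        return sp

    def displacement(self, gate_id: str, reactants: tuple[Species, Species],
                     products: tuple[Species, ...], label: str) -> None:
        """Emit one matched toehold-mediated displacement."""
        rxns = self.provenance.setdefault(gate_id, [])
        if self.mode == "one-step":
            rxn = Reaction(reactants, products, self.params.k_bind, label=label)
            self.reactions.append(rxn)
            rxns.append(rxn)
            return
        strands = [k for sp in reactants for k, c in sp.strand_counts().items()
                   for _ in range(c)]
        enc = self.intern(complex_species(
            strands, f"{label}.enc", "intermediate", state="enc"))
        steps = (
            Reaction(reactants, (enc,), self.params.k_bind, reversible=True,
                     label=f"{label}.bind"),
            Reaction((enc,), reactants, self.params.k_unbind, reversible=True,
                     label=f"{label}.unbind"),
            Reaction((enc,), products, self.params.k_resolve,
                     label=f"{label}.resolve"),
        )
        self.reactions.extend(steps)
        rxns.extend(steps)

    # -- gate templates ----------------------------------------------------

    def expand(self, gate: Gate) -> None:
        family = getattr(gate, "family", None)
        if family == "mapping":
            self._expand_mapping(gate)
        elif family == "fanout":
            self._expand_fanout(gate)
        elif family == "amplifier":
            self._expand_amplifier(gate)
        elif family == "reporter":
            self._expand_reporter(gate)
        else:
            raise CompileError(f"cannot expand gate of family {family!r}")

    def _duplex_species(self, gate: Gate, d: GateDuplex, conc: float) -> Species:
        sp = self.intern(complex_species(
            [d.bottom_key, d.top_key], f"{gate.gate_id}.{d.label}", "gate", conc))
        return self.own(gate.gate_id, sp)

    def _expand_mapping(self, gate: GateModule) -> None:
        conc = gate.conc if gate.conc is not None else self.unit_conc
        for d in gate.duplexes:
            prev = self._duplex_species(gate, d, conc)
            consumed: list[tuple] = []
            base = f"{gate.gate_id}.{d.label}"
            for j, wire in enumerate(gate.in_wires):
                sig = self.signal(wire, d.match_codes[j])
                consumed.append(sig.structure[1])
                if j < gate.n - 1:
                    nxt = self.intern(complex_species(
                        [d.bottom_key, d.top_key, *consumed],
                        f"{base}.I{j + 1}", "intermediate"))
                    self.displacement(gate.gate_id, (prev, sig), (nxt,),
                                      f"{base}.step{j + 1}")
                    prev = nxt
                else:
                    out = self.signal(d.out_wire, d.out_code)
                    waste = self.intern(complex_species(
                        [d.bottom_key, *consumed], f"{base}.W", "waste"))
                    self.displacement(gate.gate_id, (prev, sig), (out, waste),
                                      f"{base}.step{j + 1}")

    def _catalytic_paths(self, gate: AuxGate, intermediate_tag: str) -> None:
        conc = gate.conc if gate.conc is not None else self.unit_conc
        for v in (0, 1):
            path = gate.path_duplexes(v)
            fuel = self.own(gate.gate_id, self.intern(single_species(
                gate.fuel_key(v), f"{gate.gate_id}.H{v}", "fuel",
                gate.fuel_mult * len(path) * conc)))
            insig = self.signal(gate.in_wire, v)
            for d in path:
                duplex = self._duplex_species(gate, d, conc)
                outsig = self.signal(d.out_wire, v)
                base = f"{gate.gate_id}.{d.label}"
                inter = self.intern(complex_species(
                    [d.bottom_key, insig.structure[1]],
                    f"{base}.{intermediate_tag}", "intermediate"))
                self.displacement(gate.gate_id, (insig, duplex),
                                  (outsig, inter), f"{base}.release")
                waste = self.intern(complex_species(
                    [d.bottom_key, gate.fuel_key(v)], f"{base}.W", "waste"))
                self.displacement(gate.gate_id, (inter, fuel), (insig, waste),
                                  f"{base}.recover")

    def _expand_fanout(self, gate: AuxGate) -> None:
        # The input triggers each branch duplex of its logic path, releasing
        # one coded copy per branch; the fuel recovers the input from the
        # sp8-style intermediate.
        self._catalytic_paths(gate, "sp8")

    def _expand_amplifier(self, gate: AuxGate) -> None:
        self._catalytic_paths(gate, "sp7")

    def _expand_reporter(self, gate: AuxGate) -> None:
        conc = gate.conc if gate.conc is not None else self.unit_conc
        for d in gate.duplexes:
            v = d.match_codes[0]
            duplex = self._duplex_species(gate, d, conc)
            insig = self.signal(gate.in_wire, v)
            fluor = self.intern(single_species(
                (FLUOR, gate.in_wire, v), fluorescence_name(gate.in_wire, v),
                "fluorescence"))
            base = f"{gate.gate_id}.{d.label}"
            waste = self.intern(complex_species(
                [d.bottom_key, insig.structure[1]], f"{base}.W", "waste"))
            self.displacement(gate.gate_id, (insig, duplex), (fluor, waste),
                              f"{base}.report")


# ---------------------------------------------------------------------------
# CRN


@dataclass
class CRN:
    """A compiled reaction network with initial concentrations (nM)."""

    species: list[Species]
    reactions: list[Reaction]
    provenance: dict[str, list[Reaction]]
    params: KineticParams
    unit_conc: float
    mode: str = "one-step"
    netlist: Optional[Netlist] = None
    owner: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {sp.name: sp for sp in self.species}

    def by_name(self, name: str) -> Species:
        try:
            return self._by_name[name]
        except KeyError:
            raise DomainCodeError(f"no species named {name!r}") from None

    def signal_species(self, wire: str, logic_value: int) -> Species:
        key = signal_key(wire, logic_value)
        for sp in self.species:
            if sp.structure == ("single", key):
                return sp
        raise DomainCodeError(f"no signal species for wire {wire!r}={logic_value}")

    def initial_species(self) -> list[Species]:
        return [sp for sp in self.species if sp.init_conc > 0]

    def gate_family(self, gate_id: str) -> Optional[str]:
        if self.netlist is None:
            return None
        for g in self.netlist.gates:
            if g.gate_id == gate_id:
                return g.family
        return None

    # -- counting ----------------------------------------------------------

    def flux_reachable(self) -> tuple[set[tuple], list[Reaction]]:
        """Species that ever hold positive concentration, and the reactions
        that carry positive flux, by structural fixpoint."""
        avail = {sp.structure for sp in self.initial_species()}
        fired: list[Reaction] = []
        fired_set: set[int] = set()
        changed = True
        while changed:
            changed = False
            for i, rxn in enumerate(self.reactions):
                if i in fired_set:
                    continue
                if all(sp.structure in avail for sp in rxn.reactants):
                    fired.append(rxn)
                    fired_set.add(i)
                    for sp in rxn.products:
                        if sp.structure not in avail:
                            avail.add(sp.structure)
                            changed = True
        return avail, fired

    def count_initial_species(self, involved_only: bool = False) -> int:
        """Number of distinct initially-present species.

        With ``involved_only`` the count is restricted to initial species
        that actually take part in the computation for this input
        assignment, i.e. appear as a reactant of a positive-flux reaction
        (the "species involved in the calculation" inventory);
        gates parked on the inactive logic path are initially present but
        uninvolved.
        """
        initial = self.initial_species()
        if not involved_only:
            return len(initial)
        _, fired = self.flux_reachable()
        consumed = {sp.structure for rxn in fired for sp in rxn.reactants}
        return sum(1 for sp in initial if sp.structure in consumed)

    def count_component_strands(self, stages="core", dedup: bool = False) -> int:
        """Elementary-strand inventory over the selected circuit stages.

        ``stages`` is a preset (``"core"`` = inputs + mapping modules +
        fan-out gates incl. fuels; ``"full"`` = everything) or an iterable
        drawn from {"inputs", "mapping", "fanout", "amplifier", "reporter"}.
        Each initially-present duplex contributes its two component strands
        and each single strand one.  By default this is a per-component
        inventory (the strands one would order to build each component); with
        ``dedup`` identical strands shared between components are counted
        once.
        """
        if isinstance(stages, str):
            try:
                selected = set(_STAGE_PRESETS[stages])
            except KeyError:
                raise CompileError(
                    f"unknown stage selector {stages!r}; use one of "
                    f"{sorted(_STAGE_PRESETS)} or a set of families"
                ) from None
        else:
            selected = set(stages)
            unknown = selected - ({"inputs"} | set(_FAMILIES))
            if unknown:
                raise CompileError(f"unknown stage families: {sorted(unknown)}")
        total = 0
        seen: set[tuple] = set()
        for sp in self.initial_species():
            owner = self.owner.get(sp.structure)
            if owner == INPUT_OWNER:
                if "inputs" not in selected:
                    continue
            else:
                family = self.gate_family(owner) if owner else None
                if family not in selected:
                    continue
            counts = sp.strand_counts()
            if dedup:
                seen.update(counts)
            else:
                total += sum(counts.values())
        return len(seen) if dedup else total

    # -- validation & export ----------------------------------------------

    def validate(self) -> None:
        bad = conservation_violations(self.reactions)
        if bad:
            rxn, imbalance = bad[0]
            raise CompileError(
                f"reaction {rxn.label!r} does not conserve strands: {imbalance}"
            )
        names = [canonical_name(sp) for sp in self.species]
        if len(names) != len(set(names)):
            raise CompileError("canonical species names collide")

    def species_table(self) -> pd.DataFrame:
        rows = [
            {
                "name": sp.name,
                "role": sp.role,
                "init_conc_nM": sp.init_conc,
                "structure": canonical_name(sp),
            }
            for sp in self.species
        ]
        return pd.DataFrame(rows, columns=["name", "role", "init_conc_nM",
                                           "structure"])

    def write_species_table(self, path) -> None:
        self.species_table().to_csv(path, index=False, float_format="%.10g")


def count_initial_species(crn: CRN, involved_only: bool = False) -> int:
    return crn.count_initial_species(involved_only=involved_only)


def count_component_strands(crn: CRN, stages="core", dedup: bool = False) -> int:
    return crn.count_component_strands(stages=stages, dedup=dedup)


def write_species_table(crn: CRN, path) -> None:
    crn.write_species_table(path)


# ---------------------------------------------------------------------------
# Compilation entry points


def _canonicalize(builder: _Builder) -> tuple[list[Species], list[Reaction]]:
    species = sorted(builder.registry.values(),
                     key=lambda sp: (_ROLE_RANK[sp.role], canonical_name(sp)))
    reactions = sorted(
        builder.reactions,
        key=lambda r: (tuple(sorted(canonical_name(s) for s in r.reactants)),
                       tuple(sorted(canonical_name(s) for s in r.products)),
                       r.rate, r.label))
    return species, reactions


def compile_netlist(netlist: Netlist, mode: str = "one-step") -> CRN:
    """Expand a validated netlist into its full reaction network."""
    netlist.validate()
    builder = _Builder(netlist.params, netlist.unit_conc, mode,
                       input_wires=netlist.input_assignment)
    for wire, bit in sorted(netlist.input_assignment.items()):
        builder.add_input(wire, bit, netlist.unit_conc)
    for gate in netlist.gates:
        builder.expand(gate)
    species, reactions = _canonicalize(builder)
    crn = CRN(species=species, reactions=reactions,
              provenance=builder.provenance, params=netlist.params,
              unit_conc=netlist.unit_conc, mode=mode, netlist=netlist,
              owner=builder.owner)
    crn.validate()
    return crn


def expand_gate(gate: Gate, params: Optional[KineticParams] = None,
                unit_conc: Optional[float] = None,
                mode: str = "one-step") -> list[Reaction]:
    """Reaction template of a single gate, outside any netlist."""
    params = params or KineticParams()
    builder = _Builder(params, unit_conc or params.unit_conc_1X, mode)
    builder.expand(gate)
    _, reactions = _canonicalize(builder)
    return reactions


def crn_from_reactions(reactions: Sequence[Reaction],
                       params: Optional[KineticParams] = None,
                       unit_conc: Optional[float] = None,
                       mode: str = "one-step") -> CRN:
    """Assemble a CRN directly from reactions (gate templates, test rigs)."""
    params = params or KineticParams()
    seen: dict[tuple, Species] = {}
    for rxn in reactions:
        for sp in (*rxn.reactants, *rxn.products):
            seen.setdefault(sp.structure, sp)
    species = sorted(seen.values(),
                     key=lambda sp: (_ROLE_RANK[sp.role], canonical_name(sp)))
    crn = CRN(species=species, reactions=list(reactions), provenance={},
              params=params, unit_conc=unit_conc or params.unit_conc_1X,
              mode=mode)
    crn.validate()
    return crn
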
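"""Heuristic base-sequence assignment for abstract domains.

The circuits are designed entirely at domain level; this module supports
wet-lab engineering by assigning concrete A/C/G/T sequences to the primary
domains (flanks, coded domains, toehold, fluorophore carriers) by seeded
rejection sampling.  Constraints are deliberately simple k-mer heuristics,
not thermodynamics:

* per-domain GC content within a band (default 0.30-0.70);
* no homopolymer run longer than 4 nt;
* no unintended complementary run of >= ``xtalk_k`` nt (default 6) between
  any two non-partner domains, enforced with a global k-mer index.

Complement domains (gate templates) are never sampled: their sequences are
the reverse complements of their partners by construction, so the intended
pairings are exact while everything else is screened.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .compiler import CRN
from .errors import DesignError, DomainCodeError
from .gates import AuxGate, GateModule
from .strands import (
    AMP_TMPL, FAN_TMPL, FLUOR, FUEL, MAP_TMPL, REP_TMPL, SIG,
    Domain, code_domain, flank, fluor_domain, make_signal_strand, toehold,
)

#: A strand plan entry: the 5'->3' run of (domain, is_complement) segments.
DomainRun = tuple[tuple[Domain, bool], ...]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def strand_domain_plan(crn: CRN) -> dict[tuple, DomainRun]:
    """Domain-level layout of every elementary strand in a compiled CRN.

    Template (bottom) strands are laid out as the reverse complement of the
    segments they are meant to bind; fuels and signals are plain top
    strands.
    """
    if crn.netlist is None:
        raise DomainCodeError("sequence design needs a compiled netlist CRN")
    gates = {g.gate_id: g for g in crn.netlist.gates}
    tlen = 6
    llen = 15

    def comp_of(binding: Sequence[Domain]) -> DomainRun:
        return tuple((d, True) for d in reversed(binding))

    def in_half(wire: str, bit: int) -> list[Domain]:
        return [flank(wire, "c", llen), code_domain(bit, llen),
                flank(wire, "d", llen)]

    def out_half(wire: str, bit: int) -> list[Domain]:
        return [flank(wire, "a", llen), code_domain(bit, llen),
                flank(wire, "b", llen)]

    plan: dict[tuple, DomainRun] = {}
    for sp in crn.species:
        for key in sp.strand_counts():
            if key in plan:
                continue
            tag = key[0]
            if tag == SIG:
                _, wire, left, right = key
                strand = make_signal_strand(wire, left, right)
                plan[key] = tuple((d, False) for d in strand.domains(llen, tlen))
            elif tag == MAP_TMPL:
                _, gid, match, out_code = key
                gate: GateModule = gates[gid]
                binding: list[Domain] = [toehold(tlen)]
                for j, wire in enumerate(gate.in_wires):
                    binding += in_half(wire, match[j])
                binding += out_half(gate.out_wire, out_code)
                plan[key] = comp_of(binding)
            elif tag in (FAN_TMPL, AMP_TMPL):
                gid, v = key[1], key[2]
                gate: AuxGate = gates[gid]
                branch = key[3] if tag == FAN_TMPL else 0
                ow = gate.out_wires[branch]
                binding = [toehold(tlen)] + in_half(gate.in_wire, v) \
                    + out_half(ow, v)
                plan[key] = comp_of(binding)
            elif tag == REP_TMPL:
                _, gid, v = key
                gate = gates[gid]
                binding = [toehold(tlen)] + in_half(gate.in_wire, v) \
                    + [fluor_domain(gate.in_wire, v, llen)]
                plan[key] = comp_of(binding)
            elif tag == FUEL:
                _, gid, v = key
                gate = gates[gid]
                plan[key] = tuple(
                    (d, False)
                    for d in in_half(gate.in_wire, v) + [toehold(tlen)])
            elif tag == FLUOR:
                _, wire, v = key
                plan[key] = ((fluor_domain(wire, v, llen), False),)
            else:
                raise DomainCodeError(f"no domain layout for strand {key!r}")
    return plan


@dataclass
class SequenceAssignment:
    """Deterministic domain -> sequence map plus the per-strand layouts."""

    sequences: dict[str, str]
    domains: dict[str, Domain]
    plan: dict[tuple, DomainRun]
    seed: int
    toehold_len: int = 6
    long_len: int = 15

    def domain_sequence(self, domain: Domain, complemented: bool = False) -> str:
        seq = self.sequences[domain.name]
        return _revcomp(seq) if complemented else seq

    def strand_sequence(self, key: tuple) -> str:
        return "".join(self.domain_sequence(d, c) for d, c in self.plan[key])

    def strand_segments(self, key: tuple) -> list[tuple[str, bool, str]]:
        return [(d.name, c, self.domain_sequence(d, c))
                for d, c in self.plan[key]]


def _gc_fraction(seq: str) -> float:
    return sum(base in "GC" for base in seq) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def assign_sequences(
    crn: CRN,
    seed: int = 0,
    gc_band: tuple[float, float] = (0.3, 0.7),
    xtalk_k: int = 6,
    three_letter_toeholds: bool = False,
    max_retries: int = 2000,
) -> SequenceAssignment:
    """Assign concrete sequences to every primary domain of a circuit.

    Deterministic for a given seed.  Raises :class:`DesignError` naming the
    offending domain if a constraint cannot be met within ``max_retries``
    samples (loosen the band or shorten the circuit in that case).
    """
    plan = strand_domain_plan(crn)
    domains: dict[str, Domain] = {}
    for run in plan.values():
        for d, _ in run:
            domains.setdefault(d.name, d)

    rng = random.Random(seed)
    kmer_index: set[str] = set()
    sequences: dict[str, str] = {}

    def ok(seq: str) -> bool:
        lo, hi = gc_band
        if not lo <= _gc_fraction(seq) <= hi:
            return False
        if _max_homopolymer(seq) > 4:
            return False
        kmers = {seq[i:i + xtalk_k] for i in range(len(seq) - xtalk_k + 1)}
        for m in kmers:
            rc = _revcomp(m)
            if rc in kmer_index or rc in kmers:
                return False
        return True

    for name in sorted(domains):
        d = domains[name]
        alphabet = "ACT" if (three_letter_toeholds and d.kind == "toehold") \
            else "ACGT"
        for _ in range(max_retries):
            seq = "".join(rng.choice(alphabet) for _ in range(d.length_nt))
            if ok(seq):
                break
        else:
            raise DesignError(
                f"could not satisfy constraints for domain {name!r} after "
                f"{max_retries} samples (GC band {gc_band}, k={xtalk_k})"
            )
        sequences[name] = seq
        kmer_index.update(seq[i:i + xtalk_k]
                          for i in range(len(seq) - xtalk_k + 1))

    return SequenceAssignment(sequences=sequences, domains=domains, plan=plan,
                              seed=seed)


def crosstalk_violations(assignment: SequenceAssignment,
                         k: int = 6) -> list[tuple[str, str]]:
    """Pairs of distinct primary domains with a complementary run >= k."""
    items = sorted(assignment.sequences.items())
    kmers = {
        name: {seq[i:i + k] for i in range(len(seq) - k + 1)}
        for name, seq in items
    }
    bad = []
    for i, (n1, _) in enumerate(items):
        rc1 = {_revcomp(m) for m in kmers[n1]}
        for n2, _ in items[i:]:
            if rc1 & kmers[n2]:
                bad.append((n1, n2))
    return bad


def write_fasta(assignment: SequenceAssignment, path,
                keys: Optional[Iterable[tuple]] = None) -> int:
    """Write one FASTA record per elementary strand; returns the count.

    Record ids are the serialised strand keys (stable and unique);
    sequences are the concatenated domain assignments.  Raises
    :class:`DesignError` if a requested strand has no layout.
    """
    selected = list(keys) if keys is not None else sorted(assignment.plan)
    records = []
    for key in selected:
        if key not in assignment.plan:
            raise DesignError(f"no sequence layout for strand {key!r}")
        rid = "/".join(str(p) for p in key).replace(" ", "")
        records.append(SeqRecord(Seq(assignment.strand_sequence(key)),
                                 id=rid, description=""))
    SeqIO.write(records, path, "fasta")
    return len(records)
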
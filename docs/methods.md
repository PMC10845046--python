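# Methods

## Signal model

A logic signal is a seven-domain strand `flank–code–flank–T–flank–code–flank`.
The right coded domain is the logic value; the left coded domain is the
upstream-hybridisation bit. Flank domains are wire-specific, so signals on
different wires cannot cross-react; the code domains (C0, C1) and the
toehold `T` are global. All four per-wire code variants A0–A3 exist in the
strand model, but the compiler represents the circuit-level signal of logic
value v by the (v, v) variant: a gate releases its output strand with the
upstream-match bit equal to the logic value. Nothing downstream reads the
left code (gates match on the incoming strand's right code), so this
convention only fixes species identity; it keeps each wire to at most two
signal species and makes the regenerated input of a catalytic gate the same
species as the supplied input.

## Gate templates and kinetics

Every gate expands into irreversible mass-action displacements:

* **Mapping module, arity n.** One duplex per input combination; inputs are
  consumed strictly in wire order (input 0 first). Steps 1..n−1 sequester
  the input into the intermediate; step n releases the coded output strand
  plus a fully hybridised waste. A duplex whose next expected code does not
  match the arriving strand is inert: unproductive toehold encounters
  bind and unbind without net flux, so they are omitted from the network.
  Consequently a module contributes n·2ⁿ reactions and exactly 2ⁿ duplexes
  regardless of coding.
* **Fan-out (m copies) and amplifier.** Per logic path: each duplex
  releases one coded copy while capturing the input; the fuel strand then
  displaces the input back out of the intermediate. The input is a
  catalyst: at steady state its free concentration returns to its initial
  value (to within the slow bimolecular tail when fuel is exactly
  stoichiometric).
* **Reporter.** One irreversible displacement per logic value, releasing
  the fluorescence species Y_x1 (logic 0) or Y_x2 (logic 1). Fluorescence
  is therefore monotone non-decreasing.

Rate constants: every productive displacement runs at k_bind =
3.0×10⁻⁴ nM⁻¹s⁻¹; the unbinding rate 0.1126 s⁻¹ only enters the optional
**two-step mode**, which replaces each displacement by reversible toehold
binding (k_bind / k_unbind) plus an irreversible resolution step
(k_resolve, default 1.0 s⁻¹ — a package choice standing in for fast branch
migration; there is no published value at this abstraction level). One-step
is the default and is what all quantitative checks use; two-step reaches
the same plateaus slightly more slowly.

Concentrations: inputs and gate duplexes default to the circuit unit (1X).
Fan-out fuel = fuel_mult × (total same-path duplex concentration), with
fuel_mult = 1 by default (twice a single duplex at m = 2, i.e. exactly
stoichiometric) and fuel_mult = 2 in the exponentiation circuit. Amplifier
fuel = 2 × duplex concentration. Reporter duplexes default to the circuit
unit (their concentration is a free choice; it bounds the fluorescence
plateau).

## Wiring rules

Each wire has exactly one driver. A wire consumed by several gates must be
a fan-out output or be explicitly declared shared. Shared literal rails are
how the exponentiation netlist follows its circuit diagram: each input
passes a fan-out-two (one copy to its NOT module, one copy shared by the
four AND modules using the positive literal), and each NOT output is shared
by four AND modules. Sharing divides the signal among consumers — the
declared trade-off is that every output rail carries an amplifier, which
catalytically restores the divided level to full duplex concentration
before the reporter, so decoding is unaffected.

## Counting conventions

Two inventories are reported because circuit-size claims can be counted at
either the species or the strand level:

* **Initial species** — distinct species with nonzero initial
  concentration. The *involved* variant restricts to those that carry
  positive reaction flux for the given input assignment (computed by
  structural reachability from the initial set), i.e. the species actually
  participating in the computation; gates parked on the inactive logic path
  are present but uninvolved. For the exponentiation circuit this gives
  139 present / 71 involved, independent of the input word.
* **Component strands** — a per-component inventory over selected stages
  (core = inputs + mapping modules + fan-out gates including fuels; full =
  everything): each initially present duplex contributes its two component
  strands, each single strand one. Cross-component deduplication is off by
  default (this counts the strands needed to assemble each component); a
  `dedup` flag collapses identical strands. The square-root computational
  core gives 4 + 2×10 + 8 + 32 = 64.

## Numerics

ODEs are integrated with the stiff-capable implicit BDF method, analytic
Jacobian assembled from the bilinear mass-action structure, rtol 10⁻⁸,
atol 10⁻⁶ nM, on a dense output grid of 0.1 s (auto-coarsened above
~20 000 points). Benchmark-scale networks (≈500 species) integrate in a
couple of seconds. Solver cross-checks: an exact two-body closed form and a
pseudo-first-order limit to 10⁻⁶ relative, and an independent fixed-step
RK4 oracle on small sub-networks to 10⁻⁴. Halving tolerances moves plateaus
by far less than 0.1%. Tiny negative excursions are bounded by atol.

**Settle time** is the earliest grid time after which every tracked
fluorescence output stays within ε (default 5%) of its final value, plus a
1e-3 nM absolute floor so identically-zero outputs do not trip on solver
noise. The sustained-band criterion is the package's own formalisation of
"reaches a stable state"; simulations use a horizon of at least ten times
the expected settle scale (600 s for the square-root circuit, 6000 s for
exponentiation, 2000 s for single stages).

**Decoding** compares the two fluorescence plateaus per output wire as a
ratio (default threshold 10×), not absolutely, because absolute
fluorescence scales with the circuit unit (10⁴ nM vs 10³ nM in the two
benchmarks). A bit that meets neither ratio, or a wire with both channels
below 1 nM, raises a decoding error rather than guessing — ambiguity means
the circuit malfunctioned.

## Benchmark circuits

* **Square root (4-bit), 10,000 nM.** Y1 = two-input module on (X2, X3)
  coded (0,1,1,1) (⌊√x⌋ ≥ 2 ⇔ x ≥ 4, i.e. OR); Y0 = four-input module
  coded from bit 0 of ⌊√x⌋; fan-out-two on the shared inputs X3 and X2;
  amplifier + reporter per output. This is the minimal-module realisation;
  both codings are derived from `math.isqrt` at build time.
* **Exponentiation 2^x, 1,000 nM.** Decoder layout: 3 NOT modules + 8
  three-input AND modules (k = 0…01) on literal rails as described above,
  8 amplifiers, 8 reporters; output word Y7…Y0, MSB first. The NOT modules
  are kept even though a mapping module could absorb negation into its
  coding, because the circuit is defined by its gate-level diagram.

Exhaustive verification simulates one input word per run (a multiplexed
all-words run would mix signals on shared wires) and loops over rows.
Single-bit fault injection (flipping any one k code) changes at least one
decoded row — there is no silent redundancy in the codings.

## Sequence design

Supporting engineering only; the circuits are designed at domain level.
Primary domains get sequences by seeded rejection sampling: GC fraction in
[0.30, 0.70], no homopolymer longer than 4 nt, and no complementary run of
≥6 nt between any two non-partner domains (global k-mer index). Template
strands are reverse complements of the segments they bind, by construction.
Toeholds are 6 nt (optionally three-letter A/C/T), long domains 15 nt.
None of this is thermodynamic design: no free-energy model, no secondary-
structure prediction, no orthogonality guarantees beyond the k-mer screen.

## Random fixtures

The fixture generator emulates the *space of circuits*, not experimental
data: seeded random module codings (arities 1–3) and random two-level
netlists with a fan-out on the shared middle input, whose composed truth
table is computed arithmetically and then checked against the simulated,
decoded chemistry. Passing these loops shows the compiler/simulator/decoder
stack is self-consistent over the design space; it says nothing about
leak reactions, crosstalk, synthesis errors or other properties of real
molecules, which the idealised kinetics (no leaks, perfect orthogonality,
sequence-independent rates) deliberately excludes.

## Known limitations

* No leak pathways, remote toeholds or 4-way branch migration; the
  reaction-template level is fixed, not enumerated from structures.
* The two-step mode's resolution rate is a placeholder constant.
* Dual-rail baseline circuits are out of scope and not reproduced here.
* Settle times depend mildly on the band criterion; ε is exposed
  everywhere rather than hard-coded.
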
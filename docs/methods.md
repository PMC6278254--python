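# Methods

## Species model and notation

A species is either a free upper strand or a complex of one bottom strand
with bound upper strands. Text notation: `<...>` upper strand, `{...}`
exposed bottom domains, `[...]` duplex (written as the upper strand's
domains; the bottom holds the complements), `:` a nick in the upper strand
across a shared bottom, `^` toehold, `*` complement. The canonical printer
emits single spaces between domains and between chunks of a segment, `^`
before `*`, segments left to right; `parse ∘ render` is the identity
(property-tested over randomly generated species).

Logic values are structural: the long domains `t` and `f` encode 1 and 0.
A canonical signal strand `<aL^ x aR^ T^ bL^ y bR^>` carries a history
label `x` (the port it was released from) and the logic value `y`; only
the right label is the bit. All circuits share the universal toehold name
`T` (configurable per gate). Internal wires receive globally unique
machine-generated port names (`w12L`/`w12R`), so distinct gates can never
cross-react; operand ports of the built-in circuits use the
fixed reference names (`A0L`..`B3R` for the multiplier, `S0L`..`S17R` for the 8-bit
circuit) so that encoded input strands match the printed listings exactly.

## Gate set

* **Mapping module (K inputs).** One gate double strand per label pattern:
  a bottom strand `T* (p1L x1 p1R T)* ... (pKL xK pKR T)*` with K nicked
  upper strands, the last carrying the output `<outL y outR>` tail where
  `y` is the table entry for that pattern. Input i performs a toehold
  exchange at stage i, exposing the nick toehold for stage i+1; the final
  exchange releases the output signal. Since an input strand is shared by
  every gate species whose slot label matches, a K-input module splits its
  inputs across species and releases its output at 1/2^(K-1) of a unit (or
  less when several modules share an input); this attenuation is by design
  and is restored downstream.
* **Amplification gate.** Per label: an identity-mapping double strand at
  the target concentration plus a fuel strand at twice that concentration.
  The input catalyses gate turnover (input opens the gate and is recycled
  by the fuel), so the output amplitude equals the *gate* concentration —
  the set-point — independent of the input amplitude. The two label
  channels share no strands, so an f input can never produce the t output.
* **Fan-out gate (degree N).** Per label: a receiver double strand
  translating the input port onto an internal port, N branch gates (one
  per output port) at one unit each, and a fuel at 2N units (twice the
  per-label branch total, by analogy with the amplifier's stated 2× rule).
  The receiver-released internal strand is the catalyst; outputs total N
  units per unit of input. The 2-fan-out expands to 8 species (6 double
  strands + 2 fuels).
* **Reporter gate.** Per label: a duplex `{T^*}[pL^ y pR^] <fluor tail>`
  whose bottom ends at the port — displacement is complete rather than an
  exchange, so reporting is irreversible and the waste is inert. The
  released `<pL^ y pR^ fluor>` strand contains no invading toehold context
  and participates in no further reaction.

## Reaction semantics

Enumeration is structural: a free upper strand may invade a complex
wherever an exposed bottom toehold matches one of its domains; branch
migration extends maximally in both directions; any incumbent strand left
holding only toehold pairings dissociates. If no incumbent is released the
encounter is transient and no reaction is emitted; an invasion that would
leave an incumbent still bound through a long domain does not enter that
strand at all. Only free single strands invade (every reaction in the gate
set is of this form); complex–complex interactions, leak (zero-toehold)
displacement, remote toeholds and 4-way migration are out of scope.

**Lumped mode (default).** Each net transformation is a single
*irreversible* bimolecular step with `k_displace = 3e-4 /nM/s`. Closure is
a breadth-first productive frontier: starting from the initial pool, a
displacement joins the network only if it contributes at least one new
species. The microscopic reverse of a toehold exchange (the released
strand re-invading its own waste) regenerates only known species and is
dropped, which is exactly what makes the lumped step irreversible;
productive channels such as fuel-driven catalyst recycling always create
new complexes and are kept. Without this rule the catalytic amplifier
would equilibrate at 2/3 of its set-point (equal forward and reverse
exchange rates) instead of restoring to the gate concentration. The
closure is finite, deterministic, independent of pool ordering, and
idempotent (re-closing a closed network reproduces it); a round cap
(default 80) guards against malformed gates. The trade-off: in pools
where two genuinely distinct pathways converge on an identical species
set, the later pathway would be dropped — this does not occur in the gate
family, whose port names make every productive step novel.

**Detailed mode.** Each lumped step expands to reversible toehold binding
(`k_on = 3e-4 /nM/s`, `k_off = 0.1 /s`) followed by committed unimolecular
resolution (`k_migrate = 1 /s`), with an explicit toehold-bound
intermediate complex. Intermediates are treated as transient (they are not
themselves invaded).

The circuit family fixes no rate constants; the defaults are
order-of-magnitude values typical of toehold-mediated displacement
(~3×10^5 /M/s). Absolute time axes are therefore qualitative: the
simulated 1-bit adder settles at ≈580 s against the reference ≈540 s, and
the multiplier at ≈600 s against "within 2100 s" — same order of
magnitude, and asserted only as such.

## Kinetics and decoding

Mass-action ODEs are integrated with `scipy.solve_ivp` (BDF, analytic
sparse Jacobian, `rtol = 1e-8`, `atol = 1e-4 nM`), concentrations in nM
internally and units of 10,000 nM externally. Default horizon 10,000 s;
"settled" means every species moves slower than 1e-6 units/s. Halving
tolerances changes final readouts by far less than 1e-4 units. Per-strand
conservation (each physical strand's total across complexes) gives exact
left null vectors of the stoichiometry matrix and is checked numerically;
drift stays below 1e-6 units over the full 8-bit run. Decoding: bit 1 iff
the t-fluorophore ≥ 0.9 units and the f-fluorophore ≤ 0.1; bit 0 in the
mirror case; otherwise the bit is reported `ambiguous`, never coerced.

## Circuits

* **Full adder**: two K=3 mapping modules (sum = parity, carry =
  majority), each with an output amplifier; standalone, each input is
  distributed to the two modules by a 2-fan-out. The reference 1-bit demonstration
  cases are half-additions, run as the full adder with the carry-in strand
  held at 0.
* **4×4 multiplier**: 16 AND partial-product modules, then a 3-row array
  of 4 half adders (XOR+AND) and 8 full adders, reporters only on
  S7..S0; every module output is amplified. Internal adders carry no
  reporters — fluorophores are inert, so detection gates are omittable
  without affecting results.
* **8-bit adder/subtractor**: one 9-fan-out distributes the switch strand
  to 8 B-conditioning XOR gates and the initial carry-in; each bit slice
  is XOR + amplifier and a full adder (two K=3 modules, each with its
  amplifier) — 3 amplification gates per slice, 24 in total, 16 operand
  inputs + 1 switch, 9 reporters. Inside a slice the operand and carry
  signals are shared directly by the two modules (amplifiers absorb the
  extra attenuation), so the compiled circuit contains exactly one fan-out
  gate, matching the reference inventory.

Every compiled circuit carries a Boolean netlist twin evaluated in
topological order; verification requires ODE decode = netlist = integer
arithmetic. The single-rail reference full adder (6 AND, 3 OR, 4 NOT, 6
layers) is included as a netlist for comparison.

## Dual-rail baseline

The seesaw comparison lives at the ODE abstraction: a dual-rail 1-bit
adder fragment of integrating seesaw units (AND threshold 1+θ, OR
threshold θ), each unit holding an irreversible absorber (20× the exchange
rate, reflecting the longer threshold toehold) and a one-unit restoration
gate driven catalytically by the surviving input. Rails encode 1 as 0.9
and 0 as 0.1 units; the seesaw exchange rate is 1e-6 /nM/s (0.01
/unit/s), the hours-scale regime of concentration-encoded circuits, with
readout at 2000 s. At θ = 0.5 all input cases decode correctly; in the
0.1–0.2 band the absorber is too small and logic-0 leak-through is
amplified into the ambiguous region; in the 0.8–0.9 band the absorber eats
most of a logic-1 and restoration cannot complete within the window. The
strand-level gate inventory of the reference dual-rail comparison is not
recoverable from its description, so this module makes no strand-level
claims; its acceptance is the qualitative dichotomy, not trace-matching.

## Synthetic conditions, and what passing does not show

All inputs are generated programmatically at the reference operating
point: gates at 1 unit = 10,000 nM, fuels at twice their gates, operands
at 1 unit. The simulator is deterministic mass-action chemistry at a
single shared rate constant: it does not emulate leak reactions, spurious
(zero-toehold) displacement, sequence-dependent rate variation,
crosstalk from imperfect orthogonality, stochastic fluctuations at low
copy number, or enzyme-free synthesis artefacts. Passing the oracle
equivalence therefore shows the *architecture* is logically sound under
idealised displacement kinetics, not that a wet-lab realisation would be
robust.

## Known limitations

* The productive-frontier closure is tailored to feed-forward gate
  cascades; it is not a general-purpose DSD enumerator (no bulges, no
  multi-bottom complexes, no complex–complex reactions).
* `compile_adder_subtractor` is fixed at width 8 (the generalisation is
  mechanical but untested widths are refused rather than guessed).
* Detailed-mode intermediates do not themselves accept invaders.
* The dual-rail baseline's failing thresholds depend on its readout
  window; the claim defended is existence of failures in each edge band,
  with correctness at 0.5 — not specific failure values.
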
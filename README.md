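# dsdlabel

Domain-label DNA strand-displacement logic circuits: a gate compiler,
toehold-mediated reaction enumerator, mass-action simulator, and
threshold decoder, with built-in 1-bit full adder, 4×4 multiplier, and
8-bit adder/subtractor circuits verified against logic-level and integer
oracles.

## The problem

DNA strand-displacement (DSD) circuits usually encode a logical wire in a
species' *concentration*: ~1 unit means 1, ~0 means 0. Separating the two
then requires threshold gates, and thresholds near the signal bands make
seesaw-style (dual-rail) circuits unstable — a NOT gate cannot even be
built single-rail. The **domain-label** encoding sidesteps the thresholds:
every signal strand carries an explicit label domain, `t` for logic 1 and
`f` for logic 0, placed between toehold-flagged flanks,

```
<aL^ x aR^ T^ bL^ y bR^>      x = history label, y = logic value
```

so Watson–Crick hybridization itself reads the bit. A *K-input mapping
module* is a bank of 2^K gate double strands, one per input label pattern
`{t,f}^K`; the strand matching the inputs opens stage by stage through
toehold exchange and releases an output strand carrying the truth table's
label — there are `2^(2^K)` such modules (4 for K=1, 16 for K=2).
Amplification gates restore attenuated signals to the gate concentration
catalytically (fuel strands held at twice the gate concentration), fan-out
gates copy a signal onto N fresh ports, and reporter gates irreversibly
convert signals into inert fluorophore strands read out against the bands
0.9–1 unit (logic 1) and 0–0.1 unit (logic 0), with 1 unit = 10,000 nM.

This package compiles those gates into strand-level species, closes the
pool into a finite chemical reaction network under lumped
(single-irreversible-step) displacement semantics, integrates the
mass-action ODEs with a stiff solver, and decodes the fluorophores. Every
compiled circuit carries a Boolean netlist twin, so each simulation is
checked three ways: strand-level ODE decode = netlist evaluation = integer
arithmetic. Subtraction on the 8-bit circuit uses the 2^n-complement
construction, `a − b = a + (2^n − b) mod 2^n`, with a switch strand that
conditions the B operand through XOR gates and drives the initial carry.

A small dual-rail seesaw baseline (`dsdlabel.dualrail`) reproduces the
contrast case: at threshold 0.5 units the concentration-encoded adder
decodes correctly, while thresholds in the edge bands 0.1–0.2 (logic-0
leak-through) or 0.8–0.9 units (logic-1 over-absorption) yield wrong or
ambiguous outputs — the domain-label circuits are immune by construction.

## Worked example

The 8-bit subtraction 00101101 − 10010110 (switch strand
`<S0L^ t S0R^ T^ S0L^ t S0R^>` present selects subtraction mode):

```
$ dsdlabel simulate --circuit adder_subtractor \
      --a 00101101 --b 10010110 --switch 1 -o out
decoded word (S8..S0): 010010111
```

The nine reporters settle with the asserted fluorophore at 1.0 unit and
its counterpart at 0.0 (e.g. S0: t-fluorophore 1.0, f-fluorophore 0.0 →
bit 1). The word `010010111` is the 2^8-complement result: the low eight
bits are 10010111 and the leading 0 is the adder's carry-out, reporting a
borrow (the minuend is smaller than the subtrahend). The multiplier's
worked example:

```
$ dsdlabel verify --circuit multiplier_4x4 --a 1111 --b 1111
A0=1,A1=1,A2=1,A3=1,B0=1,B1=1,B2=1,B3=1 -> 11100001 (expected 11100001) [settled=True]
verify: PASS
```

Other subcommands: `compile` (canonical species list, plain-text reaction
list, SBML L3 export), `enumerate-modules`, `dualrail-demo`, `fixtures`.
Exit codes: 0 pass, 1 logic mismatch, 2 ambiguous decode, 3 input error.

## Library use

```python
from dsdlabel import compile_adder_subtractor
from dsdlabel.circuits import adder_subtractor_assignment, decode_outputs

circuit = compile_adder_subtractor()
crn, traj = circuit.run(adder_subtractor_assignment("00101101", "10010110", 1))
bits = decode_outputs(traj, circuit)          # per-reporter levels + bits
```

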
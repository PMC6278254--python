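"""Circuit assembly, operand encoding, readout decoding, and oracles.

A compiled circuit is a list of gate instances wired by shared port names,
together with a logic-level netlist twin.  The twin is evaluated purely as
Boolean algebra and serves as the independent oracle for the strand-level
simulation: for every input assignment the decoded fluorophore readout must
match the netlist, which in turn must match ordinary integer arithmetic.

The three built-in circuits are the 1-bit full adder (two 3-input mapping
modules computing parity and majority), the 4x4 array multiplier
(16 AND partial products, 4 half adders, 8 full adders), and the 8-bit
ripple-carry adder/subtractor (8 XOR conditioning gates, 8 full adders,
24 amplification gates, one 9-fan-out distributing the mode switch).
Subtraction uses the 2^n-complement construction: the switch inverts the B
operand through the XOR gates and drives the initial carry-in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dsd import FreeStrand, Species, render_species, signal_strand
from .gates import (
    AmplificationGate,
    FanOutGate,
    GateInstance,
    LOGIC_TABLES,
    MappingModule,
    Port,
    ReporterGate,
    make_amplification_gate,
    make_fanout_gate,
    make_mapping_module,
    make_reporter_gate,
)
from .kinetics import UNIT_NM, Trajectory, readout, simulate
from .reactions import RateSet, close_crn

__all__ = [
    "Netlist",
    "CompiledCircuit",
    "BinaryWord",
    "compile_full_adder",
    "compile_multiplier_4x4",
    "compile_adder_subtractor",
    "encode_inputs",
    "decode_outputs",
    "boolean_oracle",
    "twos_complement_sub",
    "single_rail_full_adder_netlist",
    "DECODE_HIGH",
    "DECODE_LOW",
]

DECODE_HIGH = 0.9  # units; >= this is a confident 1 on the asserted rail
DECODE_LOW = 0.1  # units; <= this is a confident 0 on the counter rail

PARITY3 = {
    p: ("t" if (p.count("t") % 2 == 1) else "f")
    for p in itertools.product("ft", repeat=3)
}
MAJORITY3 = {
    p: ("t" if p.count("t") >= 2 else "f") for p in itertools.product("ft", repeat=3)
}


# ---------------------------------------------------------------------------
# logic-level netlist twin


@dataclass
class NetNode:
    fn: str  # TABLE | COPY
    inputs: tuple[str, ...]
    output: str
    table: dict[tuple[str, ...], str] | None = None


@dataclass
class Netlist:
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    nodes: list[NetNode] = field(default_factory=list)

    def add_table(self, inputs: Sequence[str], output: str, table) -> None:
        self.nodes.append(NetNode("TABLE", tuple(inputs), output, dict(table)))

    def add_copy(self, src: str, dst: str) -> None:
        self.nodes.append(NetNode("COPY", (src,), dst))

    def layer_count(self) -> int:
        depth = {w: 0 for w in self.inputs}
        for node in self._topo():
            d = 1 + max(depth[w] for w in node.inputs)
            depth[node.output] = d
        return max((depth.get(w, 0) for w in self.outputs), default=0)

    def _topo(self) -> list[NetNode]:
        pending = list(self.nodes)
        known = set(self.inputs)
        ordered: list[NetNode] = []
        while pending:
            progressed = False
            rest = []
            for node in pending:
                if all(w in known for w in node.inputs):
                    ordered.append(node)
                    known.add(node.output)
                    progressed = True
                else:
                    rest.append(node)
            pending = rest
            if not progressed:
                raise ValueError("combinational cycle in netlist")
        return ordered

    def eval(self, assignment: Mapping[str, int]) -> dict[str, int]:
        values = {w: int(v) for w, v in assignment.items()}
        missing = [w for w in self.inputs if w not in values]
        if missing:
            raise ValueError(f"missing input bits {missing}")
        for node in self._topo():
            bits = [values[w] for w in node.inputs]
            if node.fn == "COPY":
                values[node.output] = bits[0]
            else:
                pattern = tuple("t" if b else "f" for b in bits)
                values[node.output] = 1 if node.table[pattern] == "t" else 0
        return {w: values[w] for w in self.outputs}


def boolean_oracle(netlist: Netlist, assignment: Mapping[str, int]) -> dict[str, int]:
    """Pure Boolean evaluation of a netlist twin in topological order."""
    return netlist.eval(assignment)


def single_rail_full_adder_netlist() -> Netlist:
    """Reference single-rail full adder: 6 AND, 3 OR, 4 NOT, 6 layers.

    sum = (x xor y) xor c with each xor as (a AND NOT b) OR (NOT a AND b);
    carry = (x AND y) OR (c AND (x xor y)).
    """
    nl = Netlist(inputs=["x1", "x2", "c1"], outputs=["y", "c2"])
    NOT, AND, OR = LOGIC_TABLES["NOT"], LOGIC_TABLES["AND"], LOGIC_TABLES["OR"]

    def xor(a: str, b: str, out: str, tag: str) -> None:
        nl.add_table([a], f"{tag}na", NOT)
        nl.add_table([b], f"{tag}nb", NOT)
        nl.add_table([a, f"{tag}nb"], f"{tag}p", AND)
        nl.add_table([f"{tag}na", b], f"{tag}q", AND)
        nl.add_table([f"{tag}p", f"{tag}q"], out, OR)

    xor("x1", "x2", "h", "u")
    xor("h", "c1", "y", "v")
    nl.add_table(["x1", "x2"], "w1", AND)
    nl.add_table(["c1", "h"], "w2", AND)
    nl.add_table(["w1", "w2"], "c2", OR)
    return nl


# ---------------------------------------------------------------------------
# compiled circuits


@dataclass
class BinaryWord:
    """Bits most-significant first."""

    bits: tuple[int, ...]

    @classmethod
    def from_string(cls, s: str, width: int | None = None) -> "BinaryWord":
        if width is not None and len(s) != width:
            raise ValueError(f"expected a {width}-bit word, got {s!r}")
        if any(c not in "01" for c in s):
            raise ValueError(f"not a binary word: {s!r}")
        return cls(tuple(int(c) for c in s))

    @classmethod
    def from_int(cls, value: int, width: int) -> "BinaryWord":
        if not 0 <= value < 2**width:
            raise ValueError(f"{value} out of range for {width} bits")
        return cls(tuple((value >> (width - 1 - i)) & 1 for i in range(width)))

    @property
    def width(self) -> int:
        return len(self.bits)

    def __int__(self) -> int:
        v = 0
        for b in self.bits:
            v = (v << 1) | b
        return v

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


class _Builder:
    def __init__(self) -> None:
        self.gates: list[GateInstance] = []
        self.netlist = Netlist()
        self._wire = itertools.count()
        self._gate = itertools.count()
        self.producer: dict[str, int] = {}  # wire -> producing mapping-gate index

    def wire(self, name: str | None = None) -> str:
        return name if name else f"w{next(self._wire)}"

    def gid(self) -> str:
        return f"g{next(self._gate)}"

    @staticmethod
    def port(wire: str) -> Port:
        return (f"{wire}L", f"{wire}R")

    def mapping(
        self, table, in_wires: Sequence[str], out_wire: str, role: str = ""
    ) -> MappingModule:
        g = make_mapping_module(
            len(in_wires),
            table,
            [self.port(w) for w in in_wires],
            self.port(out_wire),
            gid=self.gid(),
        )
        g.role = role
        self.gates.append(g)
        self.netlist.add_table(in_wires, out_wire, table)
        self.producer[out_wire] = len(self.gates) - 1
        return g

    def amp(self, in_wire: str, out_wire: str) -> AmplificationGate:
        g = make_amplification_gate(self.port(in_wire), self.port(out_wire), gid=self.gid())
        self.gates.append(g)
        self.netlist.add_copy(in_wire, out_wire)
        return g

    def fanout(self, in_wire: str, out_wires: Sequence[str]) -> FanOutGate:
        g = make_fanout_gate(
            len(out_wires), self.port(in_wire), [self.port(w) for w in out_wires],
            gid=self.gid(),
        )
        self.gates.append(g)
        for w in out_wires:
            self.netlist.add_copy(in_wire, w)
        return g

    def reporter(self, wire: str) -> ReporterGate:
        g = make_reporter_gate(self.port(wire), gid=self.gid())
        self.gates.append(g)
        return g

    def module_output(self, in_wires: Sequence[str], table, role: str = "") -> str:
        """Mapping module followed by its restoring amplifier."""
        raw = self.wire()
        out = self.wire()
        self.mapping(table, in_wires, raw, role=role)
        idx = self.producer[raw]
        self.amp(raw, out)
        self.producer[out] = idx  # amp output traces back to the module
        return out


@dataclass
class CompiledCircuit:
    name: str
    gates: list[GateInstance]
    input_ports: dict[str, Port]  # bit name -> operand port
    reporters: dict[str, ReporterGate]  # output bit name -> reporter
    netlist: Netlist
    producer: dict[str, int] = field(default_factory=dict)

    def gate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.gates:
            counts[g.kind] = counts.get(g.kind, 0) + 1
        return counts

    def count(self, kind: str, where=None) -> int:
        return sum(
            1 for g in self.gates if g.kind == kind and (where is None or where(g))
        )

    def base_species(self) -> dict[Species, float]:
        out: dict[Species, float] = {}
        for g in self.gates:
            for sp, conc in g.species().items():
                if sp in out:
                    raise ValueError(f"species collision between gates: {sp}")
                out[sp] = conc
        return out

    def input_strand(self, bit_name: str, value: int) -> FreeStrand:
        port = self.input_ports[bit_name]
        x = "t" if value else "f"
        return signal_strand(port, x, port, x)

    def encode(self, assignment: Mapping[str, int]) -> dict[Species, float]:
        missing = [k for k in self.input_ports if k not in assignment]
        if missing:
            raise ValueError(f"missing input bits {missing}")
        return {
            self.input_strand(k, int(v)): UNIT_NM
            for k, v in assignment.items()
            if k in self.input_ports
        }

    def initial_pool(self, assignment: Mapping[str, int]) -> dict[Species, float]:
        pool = self.base_species()
        pool.update(self.encode(assignment))
        return pool

    def run(
        self,
        assignment: Mapping[str, int],
        t_end: float = 10_000.0,
        rates: RateSet | None = None,
        rtol: float = 1e-8,
    ):
        """compile -> close -> integrate; returns (CRN, Trajectory)."""
        crn = close_crn(self.initial_pool(assignment), rates=rates)
        traj = simulate(crn, t_end=t_end, rtol=rtol)
        return crn, traj

    def corrupted(self, output_name: str) -> "CompiledCircuit":
        """Copy with the mapping module feeding ``output_name`` inverted.

        The netlist twin is left intact, so verification against the oracle
        reports a mismatch on that bit (negative control).
        """
        import copy

        c = copy.deepcopy(self)
        rep = c.reporters[output_name]
        wire = rep.port_in[0][:-1]
        idx = c.producer[wire]
        g = c.gates[idx]
        if not isinstance(g, MappingModule):
            raise ValueError("can only corrupt a mapping module")
        g.table = {k: ("t" if v == "f" else "f") for k, v in g.table.items()}
        return c


def encode_inputs(
    circuit: CompiledCircuit, assignment: Mapping[str, int]
) -> dict[Species, float]:
    """Signal strands (1 unit each) for an input-bit assignment.

    Bit 1 encodes as right label t, bit 0 as f; the strand's two halves
    both carry the operand port, e.g. ``<S2L^ t S2R^ T^ S2L^ t S2R^>``.
    """
    return circuit.encode(assignment)


def decode_levels(t_units: float, f_units: float):
    """Band decode of a fluorophore pair (units of 10,000 nM).

    bit = 1 if the t-fluorophore is >= 0.9 units and the f-fluorophore
    <= 0.1 units; 0 in the mirrored case; "ambiguous" otherwise (never
    silently coerced to a bit).
    """
    if t_units >= DECODE_HIGH and f_units <= DECODE_LOW:
        return 1
    if f_units >= DECODE_HIGH and t_units <= DECODE_LOW:
        return 0
    return "ambiguous"


def decode_outputs(
    traj: Trajectory, circuit: CompiledCircuit, t: float | None = None
) -> dict[str, dict]:
    """Threshold-decode every reporter's fluorophore pair (see decode_levels)."""
    t = traj.times[-1] if t is None else t
    out: dict[str, dict] = {}
    for name, rep in circuit.reporters.items():
        ft = render_species(rep.fluorophore("t"))
        ff = render_species(rep.fluorophore("f"))
        levels = {}
        for key in (ft, ff):
            try:
                levels[key] = readout(traj, [key], t)[key]
            except KeyError:
                levels[key] = 0.0  # reporter channel never opened
        hi, lo = levels[ft], levels[ff]
        out[name] = {"bit": decode_levels(hi, lo), "t_units": hi, "f_units": lo}
    return out


def run_mapping_module(table, pattern: str, t_end: float = 2000.0):
    """Simulate one mapping module (with amplifier and reporter) on a pattern.

    Returns the decoded output bit for the given input label pattern, the
    ODE-level ground truth for the module's table.
    """
    b = _Builder()
    K = len(pattern)
    in_wires = [f"I{k}" for k in range(K)]
    b.netlist.inputs = in_wires
    out = b.module_output(in_wires, table)
    rep = b.reporter(out)
    b.netlist.add_copy(out, "O")
    b.netlist.outputs = ["O"]
    cc = CompiledCircuit(
        name="module",
        gates=b.gates,
        input_ports={w: b.port(w) for w in in_wires},
        reporters={"O": rep},
        netlist=b.netlist,
        producer=b.producer,
    )
    assignment = {w: (1 if c == "t" else 0) for w, c in zip(in_wires, pattern)}
    _, traj = cc.run(assignment, t_end=t_end)
    return decode_outputs(traj, cc)["O"]["bit"]


def decoded_word(decoded: Mapping[str, dict], order: Sequence[str]) -> str:
    bits = []
    for name in order:
        b = decoded[name]["bit"]
        if b == "ambiguous":
            raise ValueError(f"output {name} is ambiguous")
        bits.append(str(b))
    return "".join(bits)


# ---------------------------------------------------------------------------
# the three circuits


def compile_full_adder(
    prefix: str = "", with_reporters: bool = True, use_fanout: bool = True
) -> CompiledCircuit:
    """1-bit full adder: two 3-input mapping modules (parity and majority).

    Inputs A0, B0, C0 (carry-in; hold at 0 for the half-add demonstrations);
    outputs S0 (sum) and S1 (carry).  Each input is distributed to both
    modules by a 2-fan-out gate, and each module output is restored by an
    amplification gate before its reporter.
    """
    b = _Builder()
    names = [f"{prefix}A0", f"{prefix}B0", f"{prefix}C0"]
    b.netlist.inputs = list(names)
    if use_fanout:
        pairs = {}
        for nm in names:
            w1, w2 = b.wire(), b.wire()
            b.fanout(nm, [w1, w2])
            pairs[nm] = (w1, w2)
        sum_in = [pairs[nm][0] for nm in names]
        car_in = [pairs[nm][1] for nm in names]
    else:
        sum_in = car_in = list(names)
    s_out = b.module_output(sum_in, PARITY3, role="fa_sum")
    c_out = b.module_output(car_in, MAJORITY3, role="fa_carry")
    reporters = {}
    if with_reporters:
        reporters["S0"] = b.reporter(s_out)
        reporters["S1"] = b.reporter(c_out)
    b.netlist.add_copy(s_out, "S0")
    b.netlist.add_copy(c_out, "S1")
    b.netlist.outputs = ["S0", "S1"]
    return CompiledCircuit(
        name="full_adder",
        gates=b.gates,
        input_ports={nm: b.port(nm) for nm in names},
        reporters=reporters,
        netlist=b.netlist,
        producer=b.producer,
    )


def _adder_block(b: _Builder, x: str, y: str, c: str | None) -> tuple[str, str]:
    """Half or full adder block (modules + amplifiers, no reporters)."""
    if c is None:
        s = b.module_output([x, y], LOGIC_TABLES["XOR"], role="ha_sum")
        co = b.module_output([x, y], LOGIC_TABLES["AND"], role="ha_carry")
    else:
        s = b.module_output([x, y, c], PARITY3, role="fa_sum")
        co = b.module_output([x, y, c], MAJORITY3, role="fa_carry")
    return s, co


def compile_multiplier_4x4() -> CompiledCircuit:
    """4x4 binary array multiplier.

    16 AND partial-product mapping gates, 4 half adders and 8 full adders
    (adders without detection gates), and 8 terminal reporters for
    S7..S0.  Every module output is restored by an amplification gate.
    """
    b = _Builder()
    a_names = [f"A{i}" for i in range(4)]
    b_names = [f"B{j}" for j in range(4)]
    b.netlist.inputs = a_names + b_names
    P = {}
    for i in range(4):
        for j in range(4):
            P[i, j] = b.module_output(
                [a_names[i], b_names[j]], LOGIC_TABLES["AND"], role="partial_product"
            )
    out = {}
    out[0] = P[0, 0]
    # row 1: add the A1 partial products
    s1, c1 = _adder_block(b, P[0, 1], P[1, 0], None)  # half adder
    s2, c2 = _adder_block(b, P[0, 2], P[1, 1], c1)
    s3, c3 = _adder_block(b, P[0, 3], P[1, 2], c2)
    s4, c4 = _adder_block(b, P[1, 3], c3, None)  # half adder
    out[1] = s1
    # row 2: add the A2 partial products
    t2, d1 = _adder_block(b, s2, P[2, 0], None)  # half adder
    t3, d2 = _adder_block(b, s3, P[2, 1], d1)
    t4, d3 = _adder_block(b, s4, P[2, 2], d2)
    t5, d4 = _adder_block(b, c4, P[2, 3], d3)
    out[2] = t2
    # row 3: add the A3 partial products
    u3, e1 = _adder_block(b, t3, P[3, 0], None)  # half adder
    u4, e2 = _adder_block(b, t4, P[3, 1], e1)
    u5, e3 = _adder_block(b, t5, P[3, 2], e2)
    u6, e4 = _adder_block(b, d4, P[3, 3], e3)
    out[3], out[4], out[5], out[6], out[7] = u3, u4, u5, u6, e4
    reporters = {}
    for k in range(8):
        reporters[f"S{k}"] = b.reporter(out[k])
        b.netlist.add_copy(out[k], f"S{k}")
    b.netlist.outputs = [f"S{k}" for k in range(8)]
    return CompiledCircuit(
        name="multiplier_4x4",
        gates=b.gates,
        input_ports={nm: b.port(nm) for nm in a_names + b_names},
        reporters=reporters,
        netlist=b.netlist,
        producer=b.producer,
    )


def compile_adder_subtractor(width: int = 8) -> CompiledCircuit:
    """8-bit ripple-carry adder/subtractor with a mode switch.

    Operand bits ride ports S2..S9 (A0..A7) and S10..S17 (B0..B7); the
    switch strand rides port S0.  A 9-fan-out distributes the switch to the
    eight B-conditioning XOR gates and the initial carry-in; each bit slice
    is XOR + amplifier, then a full adder (parity + majority modules, each
    with its amplifier): 3 amplification gates per slice, 24 in total.
    Reporters S8..S0 read out the 9-bit result.
    """
    if width != 8:
        raise ValueError("only the 8-bit adder/subtractor is compiled")
    b = _Builder()
    a_names = [f"A{i}" for i in range(width)]
    b_names = [f"B{i}" for i in range(width)]
    ports: dict[str, Port] = {"A#S": ("S0L", "S0R")}
    for i in range(width):
        ports[a_names[i]] = (f"S{2+i}L", f"S{2+i}R")
        ports[b_names[i]] = (f"S{10+i}L", f"S{10+i}R")
    b.netlist.inputs = a_names + b_names + ["A#S"]

    # operand wires must use the fixed port names above
    wire_of = {"A#S": "S0"}
    for i in range(width):
        wire_of[a_names[i]] = f"S{2+i}"
        wire_of[b_names[i]] = f"S{10+i}"

    for bit, wire in wire_of.items():
        b.netlist.add_copy(bit, wire)

    sw_wires = [b.wire() for _ in range(width + 1)]
    b.fanout(wire_of["A#S"], sw_wires)
    carry = sw_wires[width]  # initial carry-in = switch (1 for subtraction)
    reporters = {}
    for i in range(width):
        xo = b.module_output(
            [wire_of[b_names[i]], sw_wires[i]], LOGIC_TABLES["XOR"], role="b_conditioning"
        )
        s, carry = _adder_block(b, wire_of[a_names[i]], xo, carry)
        reporters[f"S{i}"] = b.reporter(s)
        b.netlist.add_copy(s, f"S{i}")
    reporters[f"S{width}"] = b.reporter(carry)
    b.netlist.add_copy(carry, f"S{width}")
    b.netlist.outputs = [f"S{i}" for i in range(width + 1)]
    return CompiledCircuit(
        name="adder_subtractor_8bit",
        gates=b.gates,
        input_ports=ports,
        reporters=reporters,
        netlist=b.netlist,
        producer=b.producer,
    )


# ---------------------------------------------------------------------------
# arithmetic helpers


def twos_complement_sub(a: int, b: int, width: int = 8) -> tuple[int, BinaryWord]:
    """a - b via the 2^width complement: (a + (2^width - b)) mod 2^width.

    Returns the modular result and the (width+1)-bit circuit word whose top
    bit is the adder's carry-out (1 iff a >= b, i.e. no borrow).
    """
    if not (0 <= a < 2**width and 0 <= b < 2**width):
        raise ValueError("operands out of range")
    # the circuit computes a + ~b + 1; the top bit is its carry-out
    full = a + ((2**width - 1) ^ b) + 1
    value = full % 2**width
    carry = full >> width
    return value, BinaryWord(((carry,) + BinaryWord.from_int(value, width).bits))


def adder_subtractor_assignment(
    a_word: str, b_word: str, switch: int, width: int = 8
) -> dict[str, int]:
    """Input-bit assignment from MSB-first operand words and the mode bit."""
    A = BinaryWord.from_string(a_word, width)
    B = BinaryWord.from_string(b_word, width)
    out = {"A#S": int(switch)}
    for i in range(width):
        out[f"A{i}"] = A.bits[width - 1 - i]
        out[f"B{i}"] = B.bits[width - 1 - i]
    return out


def multiplier_assignment(a_word: str, b_word: str) -> dict[str, int]:
    A = BinaryWord.from_string(a_word, 4)
    B = BinaryWord.from_string(b_word, 4)
    out = {}
    for i in range(4):
        out[f"A{i}"] = A.bits[3 - i]
        out[f"B{i}"] = B.bits[3 - i]
    return out


def expected_addsub(a_word: str, b_word: str, switch: int, width: int = 8) -> str:
    """Oracle (width+1)-bit output word S_width..S0, MSB first."""
    a = int(BinaryWord.from_string(a_word, width))
    bv = int(BinaryWord.from_string(b_word, width))
    if switch:
        value, word = twos_complement_sub(a, bv, width)
        return str(word)
    total = a + bv
    return str(BinaryWord.from_int(total, width + 1))


def expected_product(a_word: str, b_word: str) -> str:
    a = int(BinaryWord.from_string(a_word, 4))
    bv = int(BinaryWord.from_string(b_word, 4))
    return str(BinaryWord.from_int(a * bv, 8))
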
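"""Domain-label gate constructors.

Every gate is expanded into strand-level species with initial
concentrations.  A *port* is a pair of toehold-flagged flanking domain
names ``(pL, pR)``; the signal strand travelling on a port carries its
logic label between the flanks, so hybridization itself selects the
matching gate species and no thresholding is ever needed.

Gate inventory (all use the universal toehold ``T`` unless configured):

* mapping module -- the K-input lookup gate: one double strand per input
  label pattern (2^K species), each releasing an output strand bearing the
  truth table's label for that pattern;
* amplification gate -- catalytically restores a signal to the gate
  concentration (two double strands + two fuels at twice the gate
  concentration);
* fan-out gate -- converts one signal into N identical signals on distinct
  ports at N times the input concentration, input acting catalytically;
* reporter gate -- irreversibly converts a signal into an inert
  fluorophore strand for readout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .dsd import BoundStrand, Complex, Domain, FreeStrand, Species
from .kinetics import UNIT_NM

__all__ = [
    "Port",
    "GateInstance",
    "MappingModule",
    "AmplificationGate",
    "FanOutGate",
    "ReporterGate",
    "make_mapping_module",
    "make_logic_gate",
    "make_amplification_gate",
    "make_fanout_gate",
    "make_reporter_gate",
    "enumerate_mapping_modules",
    "LOGIC_TABLES",
]

Port = tuple[str, str]
LABELS = ("f", "t")  # table pattern order: ff, ft, tf, tt


def _th(name: str) -> Domain:
    return Domain(name, toehold=True)


def _label(x: str) -> Domain:
    if x not in ("t", "f"):
        raise ValueError(f"label must be t or f, got {x!r}")
    return Domain(x)


def _slot(port: Port, x: str, toehold: str) -> tuple[Domain, ...]:
    return (_th(port[0]), _label(x), _th(port[1]), _th(toehold))


def _gate_duplex(
    slots: Sequence[tuple[Port, str]], out_port: Port, out_label: str, toehold: str = "T"
) -> Complex:
    """A mapping-style double strand ``{T^*}[p1 x1 ... T^]:...<out y>``."""
    bottom: list[Domain] = [_th(toehold).comp()]
    uppers: list[BoundStrand] = []
    for k, (port, x) in enumerate(slots):
        seg = _slot(port, x, toehold)
        start = len(bottom)
        bottom.extend(d.comp() for d in seg)
        strand = seg
        if k == len(slots) - 1:
            strand = seg + (_th(out_port[0]), _label(out_label), _th(out_port[1]))
        uppers.append(BoundStrand(strand, start=start, offset=0, length=4))
    return Complex(tuple(bottom), tuple(uppers))


@dataclass
class GateInstance:
    """Base class: a named gate expanded into species with concentrations."""

    gid: str

    @property
    def kind(self) -> str:
        raise NotImplementedError

    def species(self) -> dict[Species, float]:
        raise NotImplementedError


@dataclass
class MappingModule(GateInstance):
    K: int
    table: dict[tuple[str, ...], str]
    input_ports: tuple[Port, ...]
    output_port: Port
    concentration: float = UNIT_NM
    toehold: str = "T"

    @property
    def kind(self) -> str:
        return "mapping"

    def species(self) -> dict[Species, float]:
        out: dict[Species, float] = {}
        for pattern in itertools.product(LABELS, repeat=self.K):
            cx = _gate_duplex(
                list(zip(self.input_ports, pattern)),
                self.output_port,
                self.table[pattern],
                self.toehold,
            )
            out[cx] = self.concentration
        return out

    def eval(self, bits: Sequence[int]) -> int:
        pattern = tuple("t" if b else "f" for b in bits)
        return 1 if self.table[pattern] == "t" else 0


@dataclass
class AmplificationGate(GateInstance):
    port_in: Port = ("", "")
    port_out: Port = ("", "")
    gate_concentration: float = UNIT_NM
    fuel_concentration: float = 2 * UNIT_NM
    toehold: str = "T"

    @property
    def kind(self) -> str:
        return "amplification"

    def fuel(self, x: str) -> FreeStrand:
        iL, iR, j = f"{self.gid}iL", f"{self.gid}iR", f"{self.gid}j"
        return FreeStrand(
            _slot(self.port_in, x, self.toehold) + (_th(iL), Domain(j), _th(iR))
        )

    def species(self) -> dict[Species, float]:
        out: dict[Species, float] = {}
        for x in LABELS:
            gate = _gate_duplex([(self.port_in, x)], self.port_out, x, self.toehold)
            out[gate] = self.gate_concentration
            out[self.fuel(x)] = self.fuel_concentration
        return out

    def eval(self, bits: Sequence[int]) -> int:
        return bits[0]


@dataclass
class FanOutGate(GateInstance):
    N: int = 2
    port_in: Port = ("", "")
    ports_out: tuple[Port, ...] = ()
    concentration: float = UNIT_NM
    toehold: str = "T"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("fan-out degree must be at least 2")
        if len(self.ports_out) != self.N:
            raise ValueError("need one output port per fan-out branch")

    @property
    def kind(self) -> str:
        return "fanout"

    @property
    def internal_port(self) -> Port:
        return (f"{self.gid}cL", f"{self.gid}cR")

    def species(self) -> dict[Species, float]:
        out: dict[Species, float] = {}
        c = self.internal_port
        iL, iR, j = f"{self.gid}iL", f"{self.gid}iR", f"{self.gid}j"
        for x in LABELS:
            # receiver translates the input port onto the internal port;
            # the released internal strand is the catalyst of the branch gates
            out[_gate_duplex([(self.port_in, x)], c, x, self.toehold)] = self.concentration
            for port in self.ports_out:
                out[_gate_duplex([(c, x)], port, x, self.toehold)] = self.concentration
            fuel = FreeStrand(_slot(c, x, self.toehold) + (_th(iL), Domain(j), _th(iR)))
            # 2x the per-label branch-gate total, by analogy with the amplifier
            out[fuel] = 2 * self.N * self.concentration
        return out

    def eval(self, bits: Sequence[int]) -> tuple[int, ...]:
        return (bits[0],) * self.N


@dataclass
class ReporterGate(GateInstance):
    port_in: Port = ("", "")
    concentration: float = UNIT_NM
    toehold: str = "T"
    fluor_domain: str = "fluor"

    @property
    def kind(self) -> str:
        return "reporter"

    def fluorophore(self, x: str) -> FreeStrand:
        """The released (inert) fluorescent strand for label ``x``."""
        pL, pR = self.port_in
        return FreeStrand((_th(pL), _label(x), _th(pR), Domain(self.fluor_domain)))

    def species(self) -> dict[Species, float]:
        out: dict[Species, float] = {}
        for x in LABELS:
            strand = self.fluorophore(x).domains
            bottom = (_th(self.toehold).comp(),) + tuple(d.comp() for d in strand[:3])
            cx = Complex(bottom, (BoundStrand(strand, start=1, offset=0, length=3),))
            out[cx] = self.concentration
        return out

    def eval(self, bits: Sequence[int]) -> int:
        return bits[0]


# ---------------------------------------------------------------------------
# constructors


def make_mapping_module(
    K: int,
    table: Mapping[tuple[str, ...], str] | Mapping[str, str],
    input_ports: Sequence[Port],
    output_port: Port,
    concentration: float = UNIT_NM,
    gid: str = "m0",
    toehold: str = "T",
) -> MappingModule:
    """Build the K-input mapping module for a total truth table.

    ``table`` maps each label pattern (tuple like ``('f','t')`` or string
    like ``'ft'``) to an output label; it must be total on {t,f}^K.
    """
    if not 1 <= K <= 4:
        raise ValueError("K must be between 1 and 4")
    norm: dict[tuple[str, ...], str] = {}
    for key, val in table.items():
        pattern = tuple(key) if not isinstance(key, tuple) else key
        if len(pattern) != K or any(c not in "tf" for c in pattern):
            raise ValueError(f"bad table pattern {key!r} for K={K}")
        if val not in "tf":
            raise ValueError(f"bad table output {val!r}")
        norm[pattern] = val
    missing = [p for p in itertools.product(LABELS, repeat=K) if p not in norm]
    if missing:
        raise ValueError(f"partial table: missing patterns {missing}")
    ports = list(input_ports)
    if len(ports) != K:
        raise ValueError("need one input port per table position")
    names = [n for p in ports + [output_port] for n in p]
    if len(set(names)) != len(names):
        raise ValueError("duplicate port names in a mapping module")
    return MappingModule(
        gid=gid,
        K=K,
        table=norm,
        input_ports=tuple(ports),
        output_port=tuple(output_port),
        concentration=concentration,
        toehold=toehold,
    )


LOGIC_TABLES: dict[str, dict[tuple[str, ...], str]] = {
    "NOT": {("f",): "t", ("t",): "f"},
    "AND": {("f", "f"): "f", ("f", "t"): "f", ("t", "f"): "f", ("t", "t"): "t"},
    "OR": {("f", "f"): "f", ("f", "t"): "t", ("t", "f"): "t", ("t", "t"): "t"},
    "XOR": {("f", "f"): "f", ("f", "t"): "t", ("t", "f"): "t", ("t", "t"): "f"},
}


def make_logic_gate(
    kind: str,
    input_ports: Sequence[Port],
    output_port: Port,
    concentration: float = UNIT_NM,
    gid: str = "g0",
) -> MappingModule:
    """NOT/AND/OR/XOR as the corresponding mapping module."""
    try:
        table = LOGIC_TABLES[kind.upper()]
    except KeyError:
        raise ValueError(f"unknown gate kind {kind!r}") from None
    K = 1 if kind.upper() == "NOT" else 2
    return make_mapping_module(K, table, input_ports, output_port, concentration, gid)


def make_amplification_gate(
    port_in: Port,
    port_out: Port,
    target_concentration: float = UNIT_NM,
    gid: str = "a0",
) -> AmplificationGate:
    """Amplifier restoring the signal on ``port_in`` to ``target_concentration``.

    Fuel single strands are held at twice the double-strand concentration.
    """
    if target_concentration <= 0:
        raise ValueError("target concentration must be positive")
    return AmplificationGate(
        gid=gid,
        port_in=tuple(port_in),
        port_out=tuple(port_out),
        gate_concentration=target_concentration,
        fuel_concentration=2 * target_concentration,
    )


def make_fanout_gate(
    N: int,
    port_in: Port,
    ports_out: Sequence[Port],
    concentration: float = UNIT_NM,
    gid: str = "f0",
) -> FanOutGate:
    return FanOutGate(
        gid=gid,
        N=N,
        port_in=tuple(port_in),
        ports_out=tuple(tuple(p) for p in ports_out),
        concentration=concentration,
    )


def make_reporter_gate(
    port_in: Port, concentration: float = UNIT_NM, gid: str = "r0"
) -> ReporterGate:
    return ReporterGate(gid=gid, port_in=tuple(port_in), concentration=concentration)


def table_from_bits(K: int, bits: str) -> dict[tuple[str, ...], str]:
    """Truth table from a bit-string of length 2^K, patterns in ff..tt order."""
    patterns = list(itertools.product(LABELS, repeat=K))
    if len(bits) != len(patterns) or any(c not in "01" for c in bits):
        raise ValueError(f"table bit-string must be {len(patterns)} bits of 0/1")
    return {p: ("t" if c == "1" else "f") for p, c in zip(patterns, bits)}


def gates_from_config(entries: Sequence[Mapping]) -> list[GateInstance]:
    """Build gate instances from a config list (e.g. parsed from YAML).

    Each entry has ``kind`` (mapping | amplification | fanout | reporter),
    port name pairs, and for mapping modules ``K`` plus ``table`` as a
    2^K bit-string; concentrations are optional and in nM.
    """
    out: list[GateInstance] = []
    for n, e in enumerate(entries):
        kind = e.get("kind")
        gid = e.get("id", f"cfg{n}")
        conc = float(e.get("concentration", UNIT_NM))
        if kind == "mapping":
            K = int(e["K"])
            out.append(
                make_mapping_module(
                    K,
                    table_from_bits(K, str(e["table"])),
                    [tuple(p) for p in e["inputs"]],
                    tuple(e["output"]),
                    concentration=conc,
                    gid=gid,
                )
            )
        elif kind == "amplification":
            out.append(
                make_amplification_gate(
                    tuple(e["input"]), tuple(e["output"]), conc, gid=gid
                )
            )
        elif kind == "fanout":
            out.append(
                make_fanout_gate(
                    len(e["outputs"]), tuple(e["input"]),
                    [tuple(p) for p in e["outputs"]], conc, gid=gid,
                )
            )
        elif kind == "reporter":
            out.append(make_reporter_gate(tuple(e["input"]), conc, gid=gid))
        else:
            raise ValueError(f"unknown gate kind {kind!r} in config entry {n}")
    return out


def enumerate_mapping_modules(K: int) -> list[dict[tuple[str, ...], str]]:
    """All 2^(2^K) total truth tables on {t,f}^K, in deterministic order."""
    if K < 1:
        raise ValueError("K must be at least 1")
    patterns = list(itertools.product(LABELS, repeat=K))
    tables = []
    for outputs in itertools.product(LABELS, repeat=len(patterns)):
        tables.append(dict(zip(patterns, outputs)))
    return tables
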
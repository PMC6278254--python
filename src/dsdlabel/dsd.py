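"""Core data model for domain-label DSD species.

Species are written in the compact strand-displacement notation used
throughout the domain-label gate listings:

* ``<aL^ t aR^ T^ bL^ t bR^>`` -- a free upper strand (5'->3' left to right);
* ``{T^*}`` -- exposed lower-strand (bottom) domains, usually toeholds;
* ``[mL^ f mR^ T^]`` -- a duplex, written as the *upper* strand's domains
  (the bottom strand holds the complements);
* ``:`` -- a nick in the upper strand: the two flanking duplexes share one
  continuous bottom strand but their top strands are distinct;
* ``^`` marks a toehold domain, ``*`` a complemented (bottom-strand) domain.

The logic value of a signal strand is carried structurally: the long domain
``t`` encodes bit 1 and ``f`` encodes bit 0, placed between toehold-flagged
flanking domains.  A canonical signal strand is
``<aL^ x aR^ T^ bL^ y bR^>`` where ``x`` is the left (history) label and
``y`` the right label; only the right label is the logic value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Domain",
    "FreeStrand",
    "Complex",
    "Species",
    "SignalStrand",
    "ParseError",
    "parse_species",
    "render_species",
    "canonical",
    "logic_value",
    "signal_strand",
    "read_species_file",
    "write_species_file",
    "TOEHOLD",
    "LABELS",
]

LABELS = ("t", "f")


@dataclass(frozen=True, slots=True)
class Domain:
    """A named sequence segment; the atom of every species.

    ``toehold`` renders as ``^`` (short domain able to nucleate displacement),
    ``complement`` as ``*`` (bottom-strand sense).  Two domains hybridize iff
    they agree in name and toehold flag and differ in complement flag; the
    logic labels t/f are ordinary long domains, so hybridization itself
    distinguishes the two logic values.
    """

    name: str
    toehold: bool = False
    complement: bool = False
    # species are dictionary keys throughout the reaction engine, so the
    # (deep, recursive) hash is computed once per object
    _h: int = field(default=0, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_h", hash((self.name, self.toehold, self.complement)))

    def __hash__(self) -> int:
        return self._h

    def comp(self) -> "Domain":
        """The Watson-Crick complement; an involution."""
        return Domain(self.name, self.toehold, not self.complement)

    def hybridizes(self, other: "Domain") -> bool:
        return (
            self.name == other.name
            and self.toehold == other.toehold
            and self.complement != other.complement
        )

    def __str__(self) -> str:
        return f"{self.name}{'^' if self.toehold else ''}{'*' if self.complement else ''}"


TOEHOLD = Domain("T", toehold=True)

_DOMAIN_RE = re.compile(r"([A-Za-z0-9_#']+)(\^?)(\*?)$")


def _parse_domain(tok: str) -> Domain:
    m = _DOMAIN_RE.match(tok)
    if not m:
        raise ParseError(f"malformed domain token {tok!r}")
    name, caret, star = m.groups()
    return Domain(name, toehold=bool(caret), complement=bool(star))


Strand = tuple[Domain, ...]


def _render_domains(domains: Iterable[Domain]) -> str:
    return " ".join(str(d) for d in domains)


@dataclass(frozen=True, slots=True)
class FreeStrand:
    """A free single strand in upper (``<...>``) sense."""

    domains: Strand
    _h: int = field(default=0, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("empty strand")
        object.__setattr__(self, "_h", hash(("F", self.domains)))

    def __hash__(self) -> int:
        return self._h

    def render(self) -> str:
        return f"<{_render_domains(self.domains)}>"

    @property
    def strands(self) -> tuple[Strand, ...]:
        return (self.domains,)

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True, slots=True)
class BoundStrand:
    """An upper strand bound to a contiguous run of bottom positions.

    ``start`` indexes the bottom (display order); the strand's domains
    ``[offset, offset+length)`` are paired with bottom positions
    ``[start, start+length)``; the rest are unpaired overhangs.
    """

    strand: Strand
    start: int
    offset: int
    length: int
    _h: int = field(default=0, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_h", hash((self.strand, self.start, self.offset, self.length))
        )

    def __hash__(self) -> int:
        return self._h

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def left_tail(self) -> Strand:
        return self.strand[: self.offset]

    @property
    def right_tail(self) -> Strand:
        return self.strand[self.offset + self.length:]

    @property
    def bound(self) -> Strand:
        return self.strand[self.offset: self.offset + self.length]


@dataclass(frozen=True, slots=True)
class Complex:
    """One bottom strand with zero or more bound upper strands.

    The bottom is stored in display order (left to right as printed), its
    domains carrying the ``*`` flag.  A complex with no uppers is a free
    lower strand, rendered ``{...}``.
    """

    bottom: Strand
    uppers: tuple[BoundStrand, ...] = ()
    _h: int = field(default=0, init=False, repr=False, compare=False)

    def __hash__(self) -> int:
        return self._h

    def __post_init__(self) -> None:
        object.__setattr__(self, "_h", hash(("C", self.bottom, self.uppers)))
        prev_end = 0
        for u in self.uppers:
            if u.start < prev_end:
                raise ValueError("overlapping bound strands")
            if u.length <= 0:
                raise ValueError("bound strand with empty duplex")
            for i in range(u.length):
                if not u.strand[u.offset + i].hybridizes(self.bottom[u.start + i]):
                    raise ValueError(
                        f"duplex mismatch at bottom position {u.start + i}: "
                        f"{u.strand[u.offset + i]} vs {self.bottom[u.start + i]}"
                    )
            prev_end = u.end

    @property
    def strands(self) -> tuple[Strand, ...]:
        """Constituent physical strands (bottom first), for conservation."""
        return (self.bottom,) + tuple(u.strand for u in self.uppers)

    def exposed_runs(self) -> Iterator[tuple[int, int]]:
        """Maximal uncovered bottom intervals, left to right."""
        pos = 0
        for u in self.uppers:
            if u.start > pos:
                yield (pos, u.start)
            pos = u.end
        if pos < len(self.bottom):
            yield (pos, len(self.bottom))

    def covered_by(self) -> list[int]:
        """Map bottom position -> index into uppers, or -1 if exposed."""
        cov = [-1] * len(self.bottom)
        for k, u in enumerate(self.uppers):
            for i in range(u.start, u.end):
                cov[i] = k
        return cov

    def has_exposed_toehold(self) -> bool:
        return any(
            self.bottom[i].toehold for a, b in self.exposed_runs() for i in range(a, b)
        )

    def render(self) -> str:
        if not self.uppers:
            return f"{{{_render_domains(self.bottom)}}}"
        parts: list[str] = []
        pos = 0
        for k, u in enumerate(self.uppers):
            chunks: list[str] = []
            if u.start > pos:
                # exposed bottom run; leading run opens the first segment,
                # later runs were attached to the previous segment below
                chunks.append(f"{{{_render_domains(self.bottom[pos:u.start])}}}")
            if u.left_tail:
                chunks.append(f"<{_render_domains(u.left_tail)}>")
            chunks.append(f"[{_render_domains(u.bound)}]")
            if u.right_tail:
                chunks.append(f"<{_render_domains(u.right_tail)}>")
            nxt = self.uppers[k + 1].start if k + 1 < len(self.uppers) else len(self.bottom)
            if nxt > u.end:
                chunks.append(f"{{{_render_domains(self.bottom[u.end:nxt])}}}")
                pos = nxt
            else:
                pos = u.end
            parts.append(" ".join(chunks))
        return ":".join(parts)

    def __str__(self) -> str:
        return self.render()


Species = FreeStrand | Complex


class ParseError(ValueError):
    """Malformed DSD notation; carries the offending position."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


_TOKEN_RE = re.compile(r"\s*([{}\[\]<>:]|[A-Za-z0-9_#'^*]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    toks: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        toks.append((m.group(1), m.start(1)))
        pos = m.end()
    return toks


_CLOSER = {"{": "}", "<": ">", "[": "]"}
_KIND = {"{": "lower", "<": "upper", "[": "duplex"}


def _parse_chunks(text: str) -> list[list[tuple[str, list[Domain], int]]]:
    """Parse into segments (split at ':'), each a list of (kind, domains, pos)."""
    toks = _tokenize(text)
    segments: list[list[tuple[str, list[Domain], int]]] = [[]]
    i = 0
    while i < len(toks):
        tok, pos = toks[i]
        if tok == ":":
            if not segments[-1]:
                raise ParseError("empty segment before ':'", pos)
            segments.append([])
            i += 1
            continue
        if tok in _CLOSER:
            closer = _CLOSER[tok]
            domains: list[Domain] = []
            i += 1
            while i < len(toks) and toks[i][0] != closer:
                dtok, dpos = toks[i]
                if dtok in "{}[]<>:":
                    raise ParseError(f"unbalanced bracket, expected {closer!r}", dpos)
                try:
                    domains.append(_parse_domain(dtok))
                except ParseError:
                    raise ParseError(f"malformed domain token {dtok!r}", dpos) from None
                i += 1
            if i == len(toks):
                raise ParseError(f"unbalanced bracket, missing {closer!r}", pos)
            if not domains:
                raise ParseError("empty bracket group", pos)
            segments[-1].append((_KIND[tok], domains, pos))
            i += 1
            continue
        raise ParseError(f"unexpected token {tok!r}", pos)
    if not segments[-1]:
        if len(segments) == 1:
            raise ParseError("empty species text")
        raise ParseError("trailing ':'")
    return segments


def parse_species(text: str) -> Species:
    """Parse one species from DSD notation.

    Raises :class:`ParseError` (with position) on malformed input,
    unbalanced brackets, or structurally inconsistent segments.
    """
    segments = _parse_chunks(text)

    # free strand cases: a single segment that is purely upper or purely lower
    if len(segments) == 1:
        kinds = [k for k, _, _ in segments[0]]
        if all(k == "upper" for k in kinds):
            domains: list[Domain] = []
            for _, ds, _ in segments[0]:
                domains.extend(ds)
            return FreeStrand(tuple(domains))
        if all(k == "lower" for k in kinds):
            domains = []
            for _, ds, _ in segments[0]:
                domains.extend(ds)
            return Complex(tuple(domains), ())

    bottom: list[Domain] = []
    uppers: list[BoundStrand] = []
    for seg in segments:
        # within a segment: {low}* <up>? [duplex] <up>? {low}*
        left_tail: list[Domain] = []
        right_tail: list[Domain] = []
        duplex: list[Domain] | None = None
        dup_start = -1
        seen_dup = False
        for kind, ds, pos in seg:
            if kind == "lower":
                bottom.extend(ds)
            elif kind == "duplex":
                if seen_dup:
                    raise ParseError("two duplexes in one segment (missing ':')", pos)
                seen_dup = True
                dup_start = len(bottom)
                duplex = ds
                bottom.extend(d.comp() for d in ds)
            else:  # upper
                if not seen_dup:
                    if left_tail:
                        raise ParseError("two upper overhangs before duplex", pos)
                    left_tail = ds
                else:
                    if right_tail:
                        raise ParseError("two upper overhangs after duplex", pos)
                    right_tail = ds
        if duplex is None:
            if left_tail or right_tail:
                raise ParseError("upper overhang without a duplex in a complex")
            continue  # pure lower-overhang segment extends the bottom
        strand = tuple(left_tail) + tuple(duplex) + tuple(right_tail)
        uppers.append(
            BoundStrand(strand, start=dup_start, offset=len(left_tail), length=len(duplex))
        )
    if not uppers and not bottom:
        raise ParseError("empty species")
    try:
        return Complex(tuple(bottom), tuple(uppers))
    except ValueError as e:
        raise ParseError(str(e)) from None


def render_species(sp: Species) -> str:
    """Deterministic canonical text; ``parse_species`` inverts it exactly."""
    return sp.render()


def canonical(text: str) -> str:
    """Canonical form of a well-formed species string."""
    return render_species(parse_species(text))


# ---------------------------------------------------------------------------
# signal strands and the domain-label logic encoding


@dataclass(frozen=True, slots=True)
class SignalStrand:
    """Canonical 7-domain signal strand ``<aL^ x aR^ T^ bL^ y bR^>``.

    The right label ``y`` alone is the logic value (t=1, f=0); the left
    half records which port the strand was released from.
    """

    left_flank: tuple[str, str]
    left_label: str
    right_flank: tuple[str, str]
    right_label: str
    toehold: Domain = TOEHOLD

    def __post_init__(self) -> None:
        if self.left_label not in LABELS or self.right_label not in LABELS:
            raise ValueError("labels must be 't' or 'f'")

    @property
    def strand(self) -> FreeStrand:
        aL, aR = self.left_flank
        bL, bR = self.right_flank
        return FreeStrand(
            (
                Domain(aL, toehold=True),
                Domain(self.left_label),
                Domain(aR, toehold=True),
                self.toehold,
                Domain(bL, toehold=True),
                Domain(self.right_label),
                Domain(bR, toehold=True),
            )
        )

    @property
    def logic(self) -> int:
        return 1 if self.right_label == "t" else 0


def signal_strand(
    left_port: tuple[str, str],
    left_label: str,
    right_port: tuple[str, str],
    right_label: str,
) -> FreeStrand:
    """Build the canonical signal strand for a wire."""
    return SignalStrand(left_port, left_label, right_port, right_label).strand


def as_signal(sp: Species) -> SignalStrand:
    """Interpret a free strand as a canonical signal strand, or raise."""
    if not isinstance(sp, FreeStrand) or len(sp.domains) != 7:
        raise ValueError(f"not a canonical signal strand: {sp}")
    d = sp.domains
    flags = [x.toehold for x in d]
    if flags != [True, False, True, True, True, False, True]:
        raise ValueError(f"not a canonical signal strand: {sp}")
    if d[1].name not in LABELS or d[5].name not in LABELS:
        raise ValueError(f"label positions must hold t or f: {sp}")
    if any(x.complement for x in d):
        raise ValueError(f"signal strands carry no complement domains: {sp}")
    return SignalStrand(
        (d[0].name, d[2].name), d[1].name, (d[4].name, d[6].name), d[5].name, d[3]
    )


def logic_value(sp: Species) -> int:
    """1 iff the right label is t, 0 iff f; error for non-signal shapes."""
    return as_signal(sp).logic


# ---------------------------------------------------------------------------
# species files: one canonical species per line, '#' comments


def read_species_file(path: str) -> list[Species]:
    out: list[Species] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            try:
                out.append(parse_species(body))
            except ParseError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
    return out


def write_species_file(path: str, species: Sequence[Species], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for sp in species:
            fh.write(render_species(sp) + "\n")
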
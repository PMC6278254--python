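"""Toehold-mediated displacement enumeration and CRN closure.

The enumerator is purely structural: a free upper strand can invade a
complex wherever an exposed bottom toehold matches one of its domains;
branch migration then extends maximally in both directions, and every
incumbent strand left holding nothing but toehold pairings dissociates.
The net transformation is emitted as a single irreversible bimolecular
displacement step (the "lumped" semantics); a "detailed" mode expands each
step into reversible toehold binding followed by unimolecular resolution.

Closure is a breadth-first *productive frontier*: starting from the initial
species, a displacement joins the network only if it contributes at least
one species not already present.  This is what makes each lumped step
irreversible in effect -- the mirror-image re-invasion of a freshly released
strand into its own waste complex (the microscopic reverse of a toehold
exchange) regenerates only known species and is therefore dropped, while
productive channels such as fuel-driven catalyst recycling always reach new
complexes and are kept.  The resulting network is finite, deterministic,
and independent of pool ordering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .dsd import BoundStrand, Complex, FreeStrand, Species, render_species

__all__ = [
    "RateSet",
    "Reaction",
    "CRN",
    "enumerate_reactions",
    "close_crn",
    "ClosureError",
]


@dataclass(frozen=True, slots=True)
class RateSet:
    """Rate constants; bimolecular in /nM/s, unimolecular in /s.

    The source circuits print no rate constants, so these are
    order-of-magnitude defaults typical of toehold-mediated displacement
    (k ~ 3e5 /M/s); absolute time axes are qualitative.
    """

    k_displace: float = 3e-4
    k_on: float = 3e-4
    k_off: float = 0.1
    k_migrate: float = 1.0
    mode: str = "lumped"  # or "detailed"


@dataclass(frozen=True, slots=True)
class Reaction:
    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate: float
    kind: str  # displacement | toehold_binding | toehold_unbinding

    def __str__(self) -> str:
        lhs = " + ".join(render_species(s) for s in self.reactants)
        rhs = " + ".join(render_species(s) for s in self.products)
        return f"{lhs} -> {rhs} @ {self.rate:g}"

    def conserves_strands(self) -> bool:
        lhs = Counter()
        for s in self.reactants:
            lhs.update(s.strands)
        rhs = Counter()
        for s in self.products:
            rhs.update(s.strands)
        return lhs == rhs


class ClosureError(RuntimeError):
    """Fixed-point iteration exceeded its cap (malformed gate suspected)."""


# immutable-species caches: invasion outcomes are purely structural, so they
# are shared across closures (different input assignments reuse most pairs)
_INVASION_CACHE: dict[tuple[FreeStrand, Complex], list] = {}
_STRAND_GRAMS: dict[FreeStrand, frozenset] = {}
_COMPLEX_GRAMS: dict[Complex, frozenset] = {}


def _strand_grams(st: FreeStrand) -> frozenset:
    g = _STRAND_GRAMS.get(st)
    if g is None:
        d = st.domains
        g = frozenset(zip(d, d[1:]))
        _STRAND_GRAMS[st] = g
    return g


def _complex_grams(cx: Complex) -> frozenset:
    """Adjacent-domain pairs an invader must contain to displace anything."""
    g = _COMPLEX_GRAMS.get(cx)
    if g is None:
        bottom = cx.bottom
        cov = cx.covered_by()
        grams = set()
        for p in range(len(bottom)):
            if cov[p] != -1 or not bottom[p].toehold:
                continue
            target = bottom[p].comp()
            if p + 1 < len(bottom):
                grams.add((target, bottom[p + 1].comp()))
            if p > 0:
                grams.add((bottom[p - 1].comp(), target))
        g = frozenset(grams)
        _COMPLEX_GRAMS[cx] = g
    return g


def _invasions(strand: FreeStrand, cx: Complex) -> list:
    key = (strand, cx)
    hit = _INVASION_CACHE.get(key)
    if hit is None:
        if _strand_grams(strand) & _complex_grams(cx):
            hit = _attempt_invasions(strand, cx)
        else:
            hit = []
        _INVASION_CACHE[key] = hit
    return hit


def _attempt_invasions(strand: FreeStrand, cx: Complex) -> list[tuple[tuple, int, int]]:
    """All lumped displacement outcomes of ``strand`` invading ``cx``.

    Returns (products, p, q) triples, deduplicated by outcome; ``p`` is the
    seeding exposed-toehold bottom position and ``q`` the strand index bound
    there (used by detailed-mode expansion).
    """
    S = strand.domains
    bottom = cx.bottom
    n = len(bottom)
    cov = cx.covered_by()
    results: dict[tuple, tuple[tuple, int, int]] = {}

    exposed = [i for i in range(n) if cov[i] == -1]
    for p in exposed:
        if not bottom[p].toehold:
            continue
        target = bottom[p].comp()
        for q, dom in enumerate(S):
            if dom != target:
                continue
            # maximal bidirectional extension from the seed pairing
            L, R, qL, qR = p, p + 1, q, q + 1
            while R < n and qR < len(S) and S[qR] == bottom[R].comp():
                R += 1
                qR += 1
            while L > 0 and qL > 0 and S[qL - 1] == bottom[L - 1].comp():
                L -= 1
                qL -= 1

            # retreat from incumbents that would survive with long domains:
            # partial displacement does not commit, so the invader does not
            # enter such a strand at all
            def trim(Lv: int, Rv: int, qLv: int, qRv: int) -> tuple[int, int, int, int]:
                changed = True
                while changed:
                    changed = False
                    for u in cx.uppers:
                        if u.start < Rv and u.end > Lv:  # overlap
                            rem = [i for i in range(u.start, u.end) if i < Lv or i >= Rv]
                            if rem and any(not bottom[i].toehold for i in rem):
                                if u.start >= p + 1 and Rv > u.start:
                                    d = Rv - u.start
                                    Rv, qRv = u.start, qRv - d
                                    changed = True
                                elif u.end <= p and Lv < u.end:
                                    d = u.end - Lv
                                    Lv, qLv = u.end, qLv + d
                                    changed = True
                return Lv, Rv, qLv, qRv

            L, R, qL, qR = trim(L, R, qL, qR)
            if R - L <= 0:
                continue

            released: list[FreeStrand] = []
            survivors: list[BoundStrand] = []
            for u in cx.uppers:
                if u.start < R and u.end > L:
                    rem = [i for i in range(u.start, u.end) if i < L or i >= R]
                    # remaining pairings are toeholds only -> dissociates
                    released.append(FreeStrand(u.strand))
                else:
                    survivors.append(u)
            if not released:
                continue  # no net displacement: transient binding only
            invader = BoundStrand(S, start=L, offset=qL, length=R - L)
            uppers = tuple(sorted(survivors + [invader], key=lambda u: u.start))
            try:
                newcx = Complex(bottom, uppers)
            except ValueError:
                continue
            products = (newcx,) + tuple(released)
            key = tuple(render_species(s) for s in products)
            results.setdefault(key, (products, p, q))
    return list(results.values())


def enumerate_reactions(
    pool: Iterable[Species], rates: RateSet | None = None
) -> list[Reaction]:
    """All displacement reactions among the given species (single pass).

    Free single strands invade complexes; complex-complex and
    strand-strand interactions are not enumerated (every reaction figure
    in the gate set is of the strand-invades-complex form).
    """
    rates = rates or RateSet()
    pool = list(pool)
    frees = [s for s in pool if isinstance(s, FreeStrand)]
    cplxs = [s for s in pool if isinstance(s, Complex)]
    out: list[Reaction] = []
    for st in frees:
        for cx in cplxs:
            for products, p, q in _invasions(st, cx):
                out.extend(_emit(st, cx, products, p, q, rates))
    return out


def _emit(
    st: FreeStrand, cx: Complex, products: tuple, p: int, q: int, rates: RateSet
) -> list[Reaction]:
    if rates.mode == "lumped":
        return [Reaction((st, cx), products, rates.k_displace, "displacement")]
    # detailed: reversible toehold binding, then committed resolution
    seed = BoundStrand(st.domains, start=p, offset=q, length=1)
    uppers = tuple(sorted(cx.uppers + (seed,), key=lambda u: u.start))
    inter = Complex(cx.bottom, uppers)
    return [
        Reaction((st, cx), (inter,), rates.k_on, "toehold_binding"),
        Reaction((inter,), (st, cx), rates.k_off, "toehold_unbinding"),
        Reaction((inter,), products, rates.k_migrate, "displacement"),
    ]


@dataclass
class CRN:
    """A finite chemical reaction network with initial concentrations (nM)."""

    species: dict[Species, float]
    reactions: list[Reaction]
    initial: dict[Species, float] = field(default_factory=dict)
    rates: RateSet = field(default_factory=RateSet)

    @property
    def names(self) -> list[str]:
        return [render_species(s) for s in self.species]

    def index(self) -> dict[Species, int]:
        return {s: i for i, s in enumerate(self.species)}

    def concentration_vector(self):
        import numpy as np

        return np.array(list(self.species.values()), dtype=float)

    def stoichiometry(self):
        """Sparse stoichiometry matrix (species x reactions)."""
        import numpy as np
        from scipy import sparse

        idx = self.index()
        rows, cols, data = [], [], []
        for j, rx in enumerate(self.reactions):
            net: Counter = Counter()
            for s in rx.reactants:
                net[idx[s]] -= 1
            for s in rx.products:
                net[idx[s]] += 1
            for i, v in net.items():
                if v:
                    rows.append(i)
                    cols.append(j)
                    data.append(float(v))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.species), len(self.reactions))
        )

    def conservation_laws(self):
        """Per-strand conservation vectors (left null vectors of stoichiometry).

        Each physical strand's total count across all complexes is invariant
        under every displacement, so the count-of-strand-per-species matrix
        annihilates the stoichiometry matrix.
        """
        import numpy as np

        strands: dict[tuple, int] = {}
        for s in self.species:
            for st in s.strands:
                strands.setdefault(st, len(strands))
        M = np.zeros((len(strands), len(self.species)))
        for i, s in enumerate(self.species):
            for st in s.strands:
                M[strands[st], i] += 1
        return M

    def to_text(self) -> str:
        lines = [f"# species: {len(self.species)}  reactions: {len(self.reactions)}"]
        for rx in self.reactions:
            lines.append(str(rx))
        return "\n".join(lines) + "\n"

    def to_sbml(self) -> str:
        from .sbml import crn_to_sbml

        return crn_to_sbml(self)


def close_crn(
    initial: Mapping[Species, float] | CRN,
    rates: RateSet | None = None,
    max_rounds: int = 80,
) -> CRN:
    """Close a species pool under displacement into a finite CRN.

    Fixed-point breadth-first iteration; productive-frontier semantics (see
    module docstring).  Closing an already-closed CRN returns an identical
    network (the original initial pool is retained as the anchor), and the
    result does not depend on pool ordering.
    """
    if isinstance(initial, CRN):
        rates = rates or initial.rates
        initial = dict(initial.initial)
    rates = rates or RateSet()
    init = dict(initial)

    species: dict[Species, float] = dict(init)
    reactions: list[Reaction] = []
    attempted: set[tuple[Species, Species]] = set()
    frontier = list(species)
    for _round in range(max_rounds):
        frees = [s for s in species if isinstance(s, FreeStrand)]
        cplxs = [s for s in species if isinstance(s, Complex)]
        new_frontier: dict[Species, None] = {}
        snapshot = set(species)
        pairs = []
        fr = set(frontier)
        for st in frees:
            for cx in cplxs:
                if (st in fr or cx in fr) and (st, cx) not in attempted:
                    pairs.append((st, cx))
        for st, cx in pairs:
            attempted.add((st, cx))
            for products, p, q in _invasions(st, cx):
                if all(pr in snapshot for pr in products):
                    continue  # unproductive: backward/futile channel
                reactions.extend(_emit(st, cx, products, p, q, rates))
                for pr in products:
                    if pr not in species and pr not in new_frontier:
                        new_frontier[pr] = None
        if not new_frontier:
            break
        for sp in new_frontier:
            species[sp] = 0.0
        frontier = list(new_frontier)
    else:
        raise ClosureError(
            f"closure did not terminate within {max_rounds} rounds "
            f"({len(species)} species); malformed gate producing unbounded species?"
        )
    # detailed mode introduces intermediates referenced by reactions
    for rx in reactions:
        for sp in rx.reactants + rx.products:
            if sp not in species:
                species[sp] = 0.0
    return CRN(species=species, reactions=reactions, initial=init, rates=rates)
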
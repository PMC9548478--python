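"""Exchange automorphisms and simplicial group actions.

An exchange automorphism swaps two vertices and fixes all others while
mapping the simplex family onto itself; a pair admitting one is
*exchangeable* and is the raw material of the quotient pipeline.  The module
also implements the regularity test (Condition A) that exchange actions
deliberately violate.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

from .core import (
    DomainError,
    SimplicialRepresentation,
    UnknownVertexError,
    Vertex,
    adjacent_vertices,
    vertex_key,
)

__all__ = [
    "VertexPermutation",
    "ExchangeAction",
    "apply_vertex_permutation",
    "is_simplicial_automorphism",
    "are_exchangeable",
    "exchangeable_pairs",
    "generated_group",
    "is_regular_action",
]

#: Hard cap on explicit group enumeration (regularity check only).
GROUP_ENUMERATION_BUDGET = 10_000


class VertexPermutation:
    """A bijection on a finite set of vertex identifiers.

    Composition is right-to-left: ``(p * q)(x) == p(q(x))``.
    """

    __slots__ = ("mapping",)

    def __init__(self, mapping: dict):
        mapping = {k: v for k, v in mapping.items() if k != v}
        if frozenset(mapping.keys()) != frozenset(mapping.values()):
            raise DomainError("mapping is not a bijection onto its own domain")
        self.mapping = mapping

    @classmethod
    def identity(cls) -> "VertexPermutation":
        return cls({})

    @classmethod
    def transposition(cls, u: Vertex, v: Vertex) -> "VertexPermutation":
        if u == v:
            raise DomainError("a transposition exchanges two distinct vertices")
        return cls({u: v, v: u})

    @classmethod
    def from_cycles(cls, cycles: Iterable[Iterable[Vertex]]) -> "VertexPermutation":
        mapping: dict = {}
        for cyc in cycles:
            cyc = list(cyc)
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                if a in mapping:
                    raise DomainError(f"vertex {a!r} appears in two cycles")
                mapping[a] = b
        return cls(mapping)

    def __call__(self, v: Vertex) -> Vertex:
        return self.mapping.get(v, v)

    def __mul__(self, other: "VertexPermutation") -> "VertexPermutation":
        support = set(self.mapping) | set(other.mapping)
        return VertexPermutation({v: self(other(v)) for v in support})

    def inverse(self) -> "VertexPermutation":
        return VertexPermutation({v: k for k, v in self.mapping.items()})

    @property
    def is_identity(self) -> bool:
        return not self.mapping

    @property
    def cycle_form(self) -> list:
        """Disjoint non-trivial cycles, canonically ordered."""
        seen: set = set()
        cycles = []
        for start in sorted(self.mapping, key=vertex_key):
            if start in seen:
                continue
            cyc = [start]
            seen.add(start)
            nxt = self.mapping[start]
            while nxt != start:
                cyc.append(nxt)
                seen.add(nxt)
                nxt = self.mapping[nxt]
            cycles.append(tuple(cyc))
        return cycles

    def __eq__(self, other):
        return isinstance(other, VertexPermutation) and self.mapping == other.mapping

    def __hash__(self):
        return hash(frozenset(self.mapping.items()))

    def __repr__(self):
        if self.is_identity:
            return "VertexPermutation(identity)"
        return f"VertexPermutation(cycles={self.cycle_form!r})"


class ExchangeAction:
    """A set of transpositions on ``Vert(K)``, each verified exchangeable.

    Generates the group acting on ``K`` by exchangeable vertices.
    """

    __slots__ = ("base", "transpositions")

    def __init__(self, base: SimplicialRepresentation, pairs: Iterable):
        norm = set()
        for u, v in pairs:
            if not are_exchangeable(base, u, v):
                raise DomainError(
                    f"pair ({set(u)!r}, {set(v)!r}) is not exchangeable in K"
                )
            norm.add(frozenset({u, v}))
        self.base = base
        self.transpositions = frozenset(norm)

    def generators(self) -> list:
        out = []
        for pair in sorted(self.transpositions, key=lambda p: sorted(map(vertex_key, p))):
            u, v = sorted(pair, key=vertex_key)
            out.append(VertexPermutation.transposition(u, v))
        return out

    def __len__(self):
        return len(self.transpositions)

    def __iter__(self):
        return iter(self.transpositions)


def _check_bijection_on(K: SimplicialRepresentation, p: VertexPermutation) -> None:
    moved = set(p.mapping)
    if not moved <= K.vertices:
        raise DomainError("permutation moves vertices outside Vert(K)")


def apply_vertex_permutation(
    K: SimplicialRepresentation, p: VertexPermutation
) -> SimplicialRepresentation:
    """Element-wise image of every simplex of ``K`` under ``p``."""
    _check_bijection_on(K, p)
    return K.replace(frozenset(p(v) for v in s) for s in K.simplices)


def is_simplicial_automorphism(K: SimplicialRepresentation, p: VertexPermutation) -> bool:
    """True iff ``p`` maps the simplex family of ``K`` onto itself."""
    _check_bijection_on(K, p)
    return apply_vertex_permutation(K, p).simplices == K.simplices


def are_exchangeable(K: SimplicialRepresentation, u: Vertex, v: Vertex) -> bool:
    """True iff the transposition ``(u v)``, fixing all other vertices, is an
    automorphism of ``K``."""
    for w in (u, v):
        if w not in K.vertices:
            raise UnknownVertexError(f"unknown vertex {set(w)!r}")
    if u == v:
        raise DomainError("exchangeability is defined for distinct vertices")
    t = VertexPermutation.transposition(u, v)
    return is_simplicial_automorphism(K, t)


def exchangeable_pairs(K: SimplicialRepresentation, prefilter: bool = True) -> frozenset:
    """All unordered exchangeable pairs of ``K``.

    With ``prefilter`` the quadratic scan skips pairs with differing numbers
    of adjacencies; the filter is sound (exchangeable vertices always have
    equal degree) so the result is unchanged, only the cost.
    """
    verts = K.sorted_vertices()
    degrees = {v: len(adjacent_vertices(K, v)) for v in verts} if prefilter else None
    pairs = set()
    for i, u in enumerate(verts):
        for v in verts[i + 1 :]:
            if prefilter and degrees[u] != degrees[v]:
                continue
            if are_exchangeable(K, u, v):
                pairs.add(frozenset({u, v}))
    return frozenset(pairs)


def generated_group(
    generators: Iterable[VertexPermutation],
    budget: int = GROUP_ENUMERATION_BUDGET,
) -> list:
    """Explicitly enumerate the group generated by ``generators``.

    Breadth-first closure under composition; raises once ``budget`` elements
    are exceeded.  Intended for worked-example scale only.
    """
    gens = list(generators)
    group = {VertexPermutation.identity()}
    frontier = list(group)
    while frontier:
        nxt = []
        for g in frontier:
            for h in gens:
                e = h * g
                if e not in group:
                    group.add(e)
                    nxt.append(e)
                    if len(group) > budget:
                        raise DomainError(
                            "regularity check exceeds enumeration budget"
                        )
        frontier = nxt
    return sorted(
        group,
        key=lambda p: sorted((vertex_key(k), vertex_key(v)) for k, v in p.mapping.items()),
    )


def is_regular_action(
    K: SimplicialRepresentation, generators: Iterable[VertexPermutation]
) -> bool:
    """Condition (A) for the group generated by ``generators``.

    For every simplex ``{v_1..v_m}`` and every tuple ``(g_1..g_m)`` of group
    elements whose vertex-wise image is again a simplex, some single group
    element must realize the whole tuple vertex-wise.  Checked by brute force
    over the explicitly enumerated group.
    """
    gens = list(generators)
    for g in gens:
        if not is_simplicial_automorphism(K, g):
            raise DomainError("action not simplicial: generator is not an automorphism")
    group = generated_group(gens)
    for s in K.sorted_simplices():
        verts = sorted(s, key=vertex_key)
        m = len(verts)
        if len(group) ** m > 100_000:
            raise DomainError("regularity check exceeds enumeration budget")
        for tup in product(group, repeat=m):
            image = frozenset(g(v) for g, v in zip(tup, verts))
            if image not in K.simplices:
                continue
            if not any(
                all(g(v) == gi(v) for gi, v in zip(tup, verts)) for g in group
            ):
                return False
    return True
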
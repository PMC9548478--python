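"""The group encoding of a simplicial representation.

The set of all subsets of a complex's simplices forms an elementary abelian
2-group under symmetric difference.  The group is never materialized (it has
``2^|K|`` elements): elements are sparse simplex sets over a reference
complex, and the structure is carried by the singleton generators, one per
simplex.  Identification and substitution operations act on this group as
homomorphisms (a canonical projection dropping one vertex's simplices, and a
renaming isomorphism, respectively).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .core import (
    DomainError,
    SimplicialRepresentation,
    Vertex,
    flatten,
    simplex_key,
)
from .operations import (
    PreconditionError,
    identification_violations,
    vertex_substitution,
)

__all__ = [
    "GElement",
    "Classification",
    "GHomomorphism",
    "g_product",
    "g_order",
    "classify_element",
    "minimal_generators",
    "rho",
    "g_distance",
    "phi_identify",
    "phi_substitute",
    "coordinates",
]


@dataclass(frozen=True)
class GElement:
    """A finite set of simplices of a reference complex; identity is empty."""

    base: SimplicialRepresentation
    simplices: frozenset

    def __post_init__(self):
        object.__setattr__(self, "simplices", frozenset(map(frozenset, self.simplices)))
        stray = self.simplices - self.base.simplices
        if stray:
            raise DomainError("element contains simplices outside the reference complex")

    @property
    def is_identity(self) -> bool:
        return not self.simplices

    def __len__(self):
        return len(self.simplices)

    def __iter__(self):
        return iter(self.simplices)


@dataclass(frozen=True)
class Classification:
    kind: str  # "simplex" | "subcomplex" | "simplex-set"
    is_simplex: bool
    is_subcomplex: bool


@dataclass(frozen=True)
class GHomomorphism:
    """A map between group encodings, applied element-wise to simplex sets.

    ``vertex_map`` renames vertices (identity for projections); simplices
    containing a vertex in ``dropped`` are deleted first.
    """

    source: SimplicialRepresentation
    target: SimplicialRepresentation
    dropped: frozenset
    vertex_map: dict

    def __call__(self, a: GElement) -> GElement:
        if a.base.simplices != self.source.simplices:
            raise DomainError("element does not belong to the source group")
        kept = (s for s in a.simplices if not (s & self.dropped))
        image = frozenset(
            frozenset(self.vertex_map.get(v, v) for v in s) for s in kept
        )
        return GElement(self.target, image)


def g_product(a: GElement, b: GElement) -> GElement:
    """Symmetric difference of the two simplex sets."""
    if a.base.simplices != b.base.simplices:
        raise DomainError("elements belong to groups over different complexes")
    return GElement(a.base, a.simplices ^ b.simplices)


def g_order(a: GElement) -> int:
    """1 for the identity, 2 otherwise (every element is self-inverse)."""
    return 1 if a.is_identity else 2


def classify_element(a: GElement) -> Classification:
    """Classify a nonempty element as simplex, subcomplex, or simplex set.

    A singleton containing a single vertex is both a simplex and a
    subcomplex; both flags are reported.
    """
    if a.is_identity:
        raise DomainError("identity has no classification")
    closed = all(
        len(s) == 1 or all(s - {v} in a.simplices for v in s) for s in a.simplices
    )
    if len(a.simplices) == 1:
        (s,) = a.simplices
        return Classification("simplex", True, len(s) == 1)
    if closed:
        return Classification("subcomplex", False, True)
    return Classification("simplex-set", False, False)


def minimal_generators(K: SimplicialRepresentation) -> list:
    """The singleton of each simplex: a minimal generating set, one per
    simplex of ``K``."""
    if K.is_void:
        raise DomainError("the void complex has a trivial group with no generators")
    return [
        GElement(K, frozenset({s})) for s in K.sorted_simplices()
    ]


def rho(K: SimplicialRepresentation, S: Iterable[GElement]):
    """Send a set of group vertices to the simplex their vertices span.

    Each member must be a singleton containing one 0-simplex of ``K``; the
    spanned vertex set must be a simplex of ``K``.
    """
    verts: set = set()
    for el in S:
        if len(el.simplices) != 1:
            raise DomainError("members must be singleton vertex elements")
        (s,) = el.simplices
        if len(s) != 1:
            raise DomainError("members must contain a single 0-simplex")
        verts |= s
    if not verts:
        raise DomainError("rho is undefined on the empty set")
    spanned = frozenset(verts)
    if spanned not in K.simplices:
        raise DomainError(
            f"vertices {sorted(map(sorted, map(flatten, spanned)))!r} do not span a simplex"
        )
    return spanned


def _labelled_simplices(K: SimplicialRepresentation) -> frozenset:
    # Simplices compared across complexes by the flattened labels of their
    # vertices, so representations over one component universe are comparable.
    return frozenset(
        frozenset(flatten(v) for v in s) for s in K.simplices
    )


def g_distance(K: SimplicialRepresentation, L: SimplicialRepresentation) -> int:
    """Cardinality of the symmetric difference of the labelled simplex sets."""
    return len(_labelled_simplices(K) ^ _labelled_simplices(L))


def phi_identify(
    K: SimplicialRepresentation,
    u: Vertex,
    v: Vertex,
    kind: str = "adjacent",
    remove: str = "second",
) -> GHomomorphism:
    """The identification homomorphism: the canonical projection that deletes
    every simplex containing the removed vertex (default: ``v``).

    Requires the same preconditions as the corresponding simplicial
    identification.
    """
    violations = identification_violations(K, u, v, kind)
    if violations:
        clause, msg = violations[0]
        raise PreconditionError(clause, msg)
    dropped_vertex = v if remove == "second" else u
    target = K.replace(s for s in K.simplices if dropped_vertex not in s)
    return GHomomorphism(
        source=K, target=target, dropped=frozenset({dropped_vertex}), vertex_map={}
    )


def phi_substitute(K: SimplicialRepresentation, u: Vertex, c: Vertex) -> GHomomorphism:
    """The renaming isomorphism induced by substituting ``u`` with ``c``."""
    target = vertex_substitution(K, u, c)
    return GHomomorphism(
        source=K, target=target, dropped=frozenset(), vertex_map={u: frozenset(c)}
    )


def coordinates(a: GElement) -> tuple:
    """GF(2) coordinate vector over the canonical ordering of base simplices.

    Cross-check hook for linear-algebra oracles: the product of elements is
    the XOR of their coordinate vectors.
    """
    order = sorted(a.base.simplices, key=simplex_key)
    return tuple(1 if s in a.simplices else 0 for s in order)
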
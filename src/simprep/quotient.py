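"""Orbits, orbit spaces, fundamental domains, and the iterated reduction.

The orbit space ``K/G`` of a simplicial action has one vertex per vertex
orbit and, as simplices, the images of ``K``'s simplices under the
vertex-to-orbit map.  Iterating the construction over the full set of
exchangeable pairs of each stage yields the *final orbit space*, the object
the equivalence decision compares between models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .core import (
    DomainError,
    SimplicialRepresentation,
    Vertex,
    full_subcomplex,
    vertex_key,
)
from .symmetry import (
    ExchangeAction,
    VertexPermutation,
    are_exchangeable,
    exchangeable_pairs,
    is_simplicial_automorphism,
)

__all__ = [
    "IDENTITY",
    "OrbitPartition",
    "ProjectionMap",
    "ReductionStage",
    "ReductionTrace",
    "vertex_orbits",
    "orbit_space",
    "fundamental_domain",
    "project_transposition",
    "final_orbit_space",
    "batched_final_orbit_space",
]


class _IdentityMarker:
    """Returned by :func:`project_transposition` when both endpoints of the
    transposition fall into one orbit, so the projected transposition is the
    identity."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "IDENTITY"


IDENTITY = _IdentityMarker()


@dataclass(frozen=True)
class OrbitPartition:
    """Partition of ``Vert(K)`` into the orbits of a permutation group."""

    blocks: frozenset

    def block_of(self, v: Vertex) -> frozenset:
        for b in self.blocks:
            if v in b:
                return b
        raise DomainError(f"vertex {set(v)!r} not covered by the partition")

    def sorted_blocks(self) -> list:
        return sorted(self.blocks, key=lambda b: sorted(map(vertex_key, b)))


@dataclass(frozen=True)
class ProjectionMap:
    """The canonical vertex map ``v -> G.v`` underlying ``p : K -> K/G``."""

    vertex_map: dict  # Vertex -> Vertex of K/G (an orbit block)

    def __call__(self, v: Vertex) -> Vertex:
        return self.vertex_map[v]

    def image_simplex(self, s) -> frozenset:
        return frozenset(self.vertex_map[v] for v in s)


@dataclass(frozen=True)
class ReductionStage:
    transpositions: frozenset  # the exchangeable pairs quotiented at this stage
    projection: ProjectionMap
    result: SimplicialRepresentation


@dataclass
class ReductionTrace:
    """Every stage of an iterated reduction, plus the final complex."""

    start: SimplicialRepresentation
    stages: list = field(default_factory=list)

    @property
    def final(self) -> SimplicialRepresentation:
        return self.stages[-1].result if self.stages else self.start

    def project_vertex(self, v: Vertex) -> Vertex:
        """Where an original vertex lands in the final complex."""
        for stage in self.stages:
            v = stage.projection(v)
        return v

    def __len__(self):
        return len(self.stages)


def _resolve_generators(K: SimplicialRepresentation, generators) -> list:
    """Accept VertexPermutations, an ExchangeAction, or bare vertex pairs."""
    if isinstance(generators, ExchangeAction):
        if generators.base is not K and generators.base != K:
            raise DomainError("action was built over a different complex")
        return generators.generators()
    gens = []
    for g in generators:
        if isinstance(g, VertexPermutation):
            gens.append(g)
        else:
            u, v = g
            gens.append(VertexPermutation.transposition(u, v))
    return gens


def vertex_orbits(K: SimplicialRepresentation, generators) -> OrbitPartition:
    """Orbits of the generated group on ``Vert(K)``.

    Computed as connected components of the union of the generator cycles;
    each generator must act simplicially.
    """
    gens = _resolve_generators(K, generators)
    for g in gens:
        if not is_simplicial_automorphism(K, g):
            raise DomainError("action not simplicial: generator is not an automorphism")
    parent = {v: v for v in K.vertices}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for g in gens:
        for a, b in g.mapping.items():
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    blocks: dict = {}
    for v in K.vertices:
        blocks.setdefault(find(v), set()).add(v)
    return OrbitPartition(frozenset(frozenset(b) for b in blocks.values()))


def orbit_space(
    K: SimplicialRepresentation, generators
) -> tuple[SimplicialRepresentation, ProjectionMap]:
    """The quotient ``K/G`` together with its projection map.

    Orbit vertices are named by the set of their members' identifiers
    (nested), so singleton orbits also gain one level of nesting, matching
    the convention that ``Vert(K/G)`` consists of orbits.
    """
    partition = vertex_orbits(K, generators)
    vmap = {}
    for block in partition.blocks:
        orbit_vertex = frozenset(block)
        for v in block:
            vmap[v] = orbit_vertex
    p = ProjectionMap(vmap)
    quotient = K.replace(p.image_simplex(s) for s in K.simplices)
    return quotient, p


def fundamental_domain(
    K: SimplicialRepresentation,
    action: ExchangeAction,
    representative_rule: Optional[Callable] = None,
) -> SimplicialRepresentation:
    """The full subcomplex on one representative per vertex orbit.

    ``representative_rule`` picks the representative from each orbit block;
    default is the minimum under the canonical vertex order.  All choices
    give isomorphic complexes, each isomorphic to ``K/G``.
    """
    rule = representative_rule or (lambda block: min(block, key=vertex_key))
    partition = vertex_orbits(K, action)
    reps = set()
    for block in partition.blocks:
        r = rule(block)
        if r not in block:
            raise DomainError("representative rule chose a vertex outside its orbit")
        reps.add(r)
    return full_subcomplex(K, reps)


def project_transposition(K: SimplicialRepresentation, action: ExchangeAction, t):
    """Image of an exchangeable transposition of ``K`` on ``Vert(K/G)``.

    Returns the pair of orbit vertices containing ``t``'s endpoints, or
    :data:`IDENTITY` when both endpoints share an orbit (equivalently, when
    ``t`` lies in the generated group).
    """
    u, v = t
    if not are_exchangeable(K, u, v):
        raise DomainError(
            f"({set(u)!r}, {set(v)!r}) is not an exchangeable pair of K"
        )
    _, p = orbit_space(K, action)
    a, b = p(u), p(v)
    if a == b:
        return IDENTITY
    return (a, b)


def final_orbit_space(
    K: SimplicialRepresentation,
    admissible: Optional[Callable] = None,
) -> ReductionTrace:
    """Iterate full-exchange quotients until no exchangeable pairs remain.

    Each stage quotients by *all* exchangeable pairs of its input at once
    (optionally filtered by the ``admissible(u, v) -> bool`` predicate).  The
    stage count is bounded by ``|Vert(K)|`` since the vertex count strictly
    decreases while pairs exist.
    """
    trace = ReductionTrace(start=K)
    current = K
    bound = len(K.vertices)
    while True:
        pairs = exchangeable_pairs(current)
        if admissible is not None:
            pairs = frozenset(p for p in pairs if admissible(*sorted(p, key=vertex_key)))
        if not pairs:
            break
        quotient, p = orbit_space(current, pairs)
        trace.stages.append(ReductionStage(pairs, p, quotient))
        current = quotient
        assert len(trace.stages) <= bound, "reduction failed to terminate"
    return trace


def batched_final_orbit_space(
    K: SimplicialRepresentation,
    choose_batch: Callable,
) -> ReductionTrace:
    """Reduction applying, at each stage, only a chosen nonempty subset of the
    current exchangeable pairs.

    ``choose_batch(pairs)`` receives the current frozenset of pairs and must
    return a nonempty subset.  Used to check confluence against the
    simultaneous reduction of :func:`final_orbit_space`.
    """
    trace = ReductionTrace(start=K)
    current = K
    bound = len(K.vertices)
    while True:
        pairs = exchangeable_pairs(current)
        if not pairs:
            break
        batch = frozenset(choose_batch(pairs))
        if not batch or not batch <= pairs:
            raise DomainError("batch must be a nonempty subset of the current pairs")
        quotient, p = orbit_space(current, batch)
        trace.stages.append(ReductionStage(batch, p, quotient))
        current = quotient
        assert len(trace.stages) <= bound, "reduction failed to terminate"
    return trace
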
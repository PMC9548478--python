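"""Deciding equivalence of simplicial representations.

Both inputs are reduced to their final orbit spaces, then a label-constrained
backtracking search enumerates bijective vertex maps between the finals and
keeps those extending to simplicial isomorphisms.  A nonempty set of
isomorphisms means the representations are equivalent: the audit trail of
identifications plus closing vertex substitutions realizes the equivalence.

The software records and constrains; whether a matched pair of component
sets is *conceptually* meaningful is a human decision, supported by the
``component_pairings`` carried on each verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import (
    SimplicialRepresentation,
    Vertex,
    adjacent_vertices,
    flatten,
    vertex_key,
)
from .operations import vertex_substitution
from .quotient import ReductionTrace, final_orbit_space

__all__ = [
    "IsomorphismCandidate",
    "EquivalenceVerdict",
    "label_consistency_check",
    "candidate_vertex_bijections",
    "is_isomorphism",
    "isomorphisms",
    "are_isomorphic",
    "apply_isomorphism_substitutions",
    "decide_equivalence",
    "restricted_final_orbit_space",
    "partition_by_equivalence",
]


@dataclass
class IsomorphismCandidate:
    """A bijective vertex map between two finals, with its label status."""

    vertex_map: dict  # Vertex of K-hat -> Vertex of L-hat
    label_consistent: bool


@dataclass
class EquivalenceVerdict:
    equivalent: bool
    isomorphisms: list  # IsomorphismCandidate, only maps extending to isomorphisms
    component_pairings: list  # per isomorphism: [(K-hat label set, L-hat label set)]
    trace_K: ReductionTrace
    trace_L: ReductionTrace
    diagnostics: list = field(default_factory=list)
    operation_sequence: list = field(default_factory=list)


def _vertex_profile(K: SimplicialRepresentation, v: Vertex) -> tuple:
    """Isomorphism-invariant pruning key: degree and largest coface size."""
    degree = len(adjacent_vertices(K, v))
    max_coface = max(len(s) for s in K.simplices if v in s)
    return (degree, max_coface)


def label_consistency_check(
    Khat: SimplicialRepresentation, Lhat: SimplicialRepresentation
) -> list:
    """One diagnostic per vertex whose flattened label shares components with
    two or more distinct vertices of the other complex."""
    diagnostics = []
    for src_name, A, B in (("K", Khat, Lhat), ("L", Lhat, Khat)):
        for u in A.sorted_vertices():
            hits = [w for w in B.sorted_vertices() if flatten(u) & flatten(w)]
            if len(hits) >= 2:
                diagnostics.append(
                    (
                        src_name,
                        sorted(flatten(u)),
                        [sorted(flatten(w)) for w in hits],
                    )
                )
    return diagnostics


def candidate_vertex_bijections(
    Khat: SimplicialRepresentation,
    Lhat: SimplicialRepresentation,
    enforce_shared_components: bool = True,
) -> list:
    """All vertex bijections compatible with the pruning invariants.

    Candidates must preserve per-vertex degree and maximal-coface size; with
    ``enforce_shared_components`` a vertex sharing a model component with
    vertices of the other complex may only map among those.
    """
    vk = Khat.sorted_vertices()
    vl = Lhat.sorted_vertices()
    if len(vk) != len(vl):
        return []
    profiles_l: dict = {}
    for w in vl:
        profiles_l.setdefault(_vertex_profile(Lhat, w), []).append(w)
    allowed: dict = {}
    for u in vk:
        cands = list(profiles_l.get(_vertex_profile(Khat, u), []))
        if enforce_shared_components:
            sharing = [w for w in vl if flatten(u) & flatten(w)]
            if sharing:
                cands = [w for w in cands if w in sharing]
        if not cands:
            return []
        allowed[u] = cands

    out: list = []
    used: set = set()
    assignment: dict = {}

    def backtrack(i: int) -> None:
        if i == len(vk):
            out.append(dict(assignment))
            return
        u = vk[i]
        for w in allowed[u]:
            if w in used:
                continue
            used.add(w)
            assignment[u] = w
            backtrack(i + 1)
            used.discard(w)
            del assignment[u]

    backtrack(0)
    return out


def is_isomorphism(
    Khat: SimplicialRepresentation,
    Lhat: SimplicialRepresentation,
    vertex_map: dict,
) -> bool:
    """True iff the bijective vertex map is a simplicial isomorphism."""
    if len(Khat.simplices) != len(Lhat.simplices):
        return False
    return all(
        frozenset(vertex_map[v] for v in s) in Lhat.simplices for s in Khat.simplices
    )


def isomorphisms(
    Khat: SimplicialRepresentation,
    Lhat: SimplicialRepresentation,
    enforce_shared_components: bool = True,
) -> list:
    return [
        vm
        for vm in candidate_vertex_bijections(Khat, Lhat, enforce_shared_components)
        if is_isomorphism(Khat, Lhat, vm)
    ]


def are_isomorphic(
    Khat: SimplicialRepresentation,
    Lhat: SimplicialRepresentation,
    enforce_shared_components: bool = False,
) -> bool:
    return bool(isomorphisms(Khat, Lhat, enforce_shared_components))


def apply_isomorphism_substitutions(
    Khat: SimplicialRepresentation, vertex_map: dict
) -> SimplicialRepresentation:
    """Realize an isomorphism as a sequence of vertex substitutions.

    Renames through fresh intermediate identifiers so that overlapping
    source/target identifier sets (e.g. a swap) stay collision-free; the
    result equals the relabelled complex exactly.
    """
    ints = {i for v in Khat.vertices for i in flatten(v)}
    ints |= {i for v in vertex_map.values() for i in flatten(v)}
    base = max(ints, default=0) + 1
    current = Khat
    temp_of = {}
    for idx, u in enumerate(Khat.sorted_vertices()):
        tmp = frozenset({base + idx})
        temp_of[u] = tmp
        current = vertex_substitution(current, u, tmp)
    for u, tmp in temp_of.items():
        current = vertex_substitution(current, tmp, vertex_map[u])
    return current


def _label_consistent(vertex_map: dict, Lhat: SimplicialRepresentation) -> bool:
    for u, w in vertex_map.items():
        for x in Lhat.vertices:
            if flatten(u) & flatten(x) and x != w:
                return False
    return True


def decide_equivalence(
    K: SimplicialRepresentation,
    L: SimplicialRepresentation,
    enforce_shared_components: bool = True,
) -> EquivalenceVerdict:
    """Reduce both representations and search for isomorphisms of the finals.

    The verdict carries every isomorphism found, the per-isomorphism pairing
    of flattened component sets (for human sign-off), both reduction traces,
    and — when equivalent — an explicit operation sequence: the per-stage
    identifications on each side followed by the substitutions induced by the
    first isomorphism.
    """
    trace_K = final_orbit_space(K)
    trace_L = final_orbit_space(L)
    Khat, Lhat = trace_K.final, trace_L.final
    diagnostics = label_consistency_check(Khat, Lhat)
    isos = isomorphisms(Khat, Lhat, enforce_shared_components)
    candidates = [
        IsomorphismCandidate(vm, _label_consistent(vm, Lhat)) for vm in isos
    ]
    pairings = [
        [
            (sorted(flatten(u)), sorted(flatten(vm[u])))
            for u in sorted(vm, key=vertex_key)
        ]
        for vm in isos
    ]
    sequence: list = []
    if isos:
        for side, trace in (("K", trace_K), ("L", trace_L)):
            for stage in trace.stages:
                sequence.append(
                    (
                        "identify",
                        side,
                        sorted(
                            tuple(sorted(map(sorted, map(flatten, pair))))
                            for pair in stage.transpositions
                        ),
                    )
                )
        vm = isos[0]
        for u in sorted(vm, key=vertex_key):
            if vm[u] != u:
                sequence.append(
                    ("substitute", "K", sorted(flatten(u)), sorted(flatten(vm[u])))
                )
    return EquivalenceVerdict(
        equivalent=bool(isos),
        isomorphisms=candidates,
        component_pairings=pairings,
        trace_K=trace_K,
        trace_L=trace_L,
        diagnostics=diagnostics,
        operation_sequence=sequence,
    )


def restricted_final_orbit_space(
    K: SimplicialRepresentation, allowed_pairs: Iterable
) -> ReductionTrace:
    """Reduction using only identifications whose component pairs are allowed.

    ``allowed_pairs`` is a collection of unordered pairs of component
    integers; merging vertices ``u`` and ``v`` is admissible only when every
    cross pair of their flattened labels is allowed.
    """
    allowed = {frozenset(p) for p in allowed_pairs}

    def admissible(u: Vertex, v: Vertex) -> bool:
        return all(
            frozenset({a, b}) in allowed
            for a in flatten(u)
            for b in flatten(v)
            if a != b
        )

    return final_orbit_space(K, admissible=admissible)


def partition_by_equivalence(
    representations: Sequence[SimplicialRepresentation],
    enforce_shared_components: bool = True,
) -> list:
    """Equivalence classes of a model collection under pairwise verdicts.

    Verdicts are computed for every pair; the classes are the connected
    components.  Transitivity of the pairwise verdicts is asserted — a
    violation signals an implementation bug, not a property of the inputs.
    """
    n = len(representations)
    finals = [final_orbit_space(K).final for K in representations]
    eq = [[True] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            verdict = bool(
                isomorphisms(finals[i], finals[j], enforce_shared_components)
            )
            eq[i][j] = eq[j][i] = verdict
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if eq[i][j] and eq[j][k] and not eq[i][k]:
                    raise RuntimeError(
                        "pairwise equivalence verdicts violate transitivity"
                    )
    classes: list = []
    assigned = [False] * n
    for i in range(n):
        if assigned[i]:
            continue
        cls = [representations[j] for j in range(i, n) if eq[i][j] and not assigned[j]]
        for j in range(i, n):
            if eq[i][j]:
                assigned[j] = True
        classes.append(cls)
    return classes
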
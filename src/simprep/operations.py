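"""The admissible partial operations on simplicial representations.

Three operations are public: adjacent-vertex identification, nonadjacent-
vertex identification, and vertex substitution.  The two identification
flavours merge a link-compatible vertex pair into one vertex; substitution
is a bijective relabelling of a single vertex.  Vertex split and inclusion
are the implicit inverses of the identifications and are not exposed
standalone; invertibility is exercised through recorded traces.

Precondition checking returns the violated clause by name, which feeds the
CLI's error reporting.
"""

from __future__ import annotations

from typing import Optional

from .core import (
    PreconditionError,
    SimplicialRepresentation,
    UnknownVertexError,
    Vertex,
    adjacent_vertices,
)

__all__ = [
    "identification_violations",
    "adjacent_vertex_identification",
    "nonadjacent_vertex_identification",
    "vertex_substitution",
]


def _require_vertices(K: SimplicialRepresentation, *vs: Vertex) -> None:
    for v in vs:
        if v not in K.vertices:
            raise UnknownVertexError(f"unknown vertex {set(v)!r}")


def identification_violations(
    K: SimplicialRepresentation, u: Vertex, v: Vertex, kind: str
) -> list:
    """Violated clauses of the identification preconditions, empty if legal.

    ``kind`` is ``"adjacent"`` or ``"nonadjacent"``.  Clause (i) is the
    shared-neighbourhood condition, clause (ii) the co-face condition: for
    every nonempty ``W`` inside the common neighbourhood, ``W + {u}`` spans a
    simplex iff ``W + {v}`` does.  Clause (ii) is checked only over subsets
    ``W`` that occur as ``simplex - {u, v}`` supports, which is equivalent
    (both directions of the biconditional need a simplex witness) and avoids
    the exponential scan.
    """
    _require_vertices(K, u, v)
    if u == v:
        return [("distinct-vertices", "u and v must be distinct")]
    adjacent = any(u in s and v in s for s in K.simplices)
    violations = []
    if kind == "adjacent":
        if not adjacent:
            violations.append(("adjacency", "u and v are not adjacent"))
        nu = adjacent_vertices(K, u) - {v}
        nv = adjacent_vertices(K, v) - {u}
    elif kind == "nonadjacent":
        if adjacent:
            violations.append(("nonadjacency", "u and v are adjacent; use Operation 1"))
        nu = adjacent_vertices(K, u)
        nv = adjacent_vertices(K, v)
    else:
        raise ValueError(f"kind must be 'adjacent' or 'nonadjacent', got {kind!r}")
    if nu != nv:
        violations.append(
            (
                "shared-neighbourhood",
                "deleted neighbourhoods of u and v differ",
            )
        )
        return violations
    common = nu
    supports = set()
    for s in K.simplices:
        if u in s or v in s:
            w = frozenset(s) - {u, v}
            if w and w <= common:
                supports.add(w)
    for w in supports:
        left = (w | {u}) in K.simplices
        right = (w | {v}) in K.simplices
        if left != right:
            violations.append(
                (
                    "co-face",
                    f"W={sorted(map(set, w), key=str)!r} spans with "
                    f"{'u' if left else 'v'} but not with the other",
                )
            )
    return violations


def _identify(
    K: SimplicialRepresentation,
    u: Vertex,
    v: Vertex,
    kind: str,
    merged_label: Optional[frozenset],
) -> SimplicialRepresentation:
    violations = identification_violations(K, u, v, kind)
    if violations:
        clause, msg = violations[0]
        raise PreconditionError(clause, msg)
    c = frozenset(u | v) if merged_label is None else frozenset(merged_label)
    if c in K.vertices - {u, v}:
        raise PreconditionError(
            "merged-label", f"identifier {set(c)!r} collides with an existing vertex"
        )

    def image(s):
        return frozenset(c if x in (u, v) else x for x in s)

    return K.replace(image(s) for s in K.simplices)


def adjacent_vertex_identification(
    K: SimplicialRepresentation,
    u: Vertex,
    v: Vertex,
    merged_label: Optional[frozenset] = None,
) -> SimplicialRepresentation:
    """Operation 1: merge the adjacent pair ``(u, v)`` into one vertex.

    The merged vertex carries ``merged_label`` (default: the union of the two
    identifier sets); all other vertices are fixed and label-preserved.
    """
    return _identify(K, u, v, "adjacent", merged_label)


def nonadjacent_vertex_identification(
    K: SimplicialRepresentation,
    u: Vertex,
    v: Vertex,
    merged_label: Optional[frozenset] = None,
) -> SimplicialRepresentation:
    """Operation 2: merge the nonadjacent pair ``(u, v)`` into one vertex."""
    return _identify(K, u, v, "nonadjacent", merged_label)


def vertex_substitution(
    K: SimplicialRepresentation, u: Vertex, c: Vertex
) -> SimplicialRepresentation:
    """Operation 5: bijectively relabel vertex ``u`` as ``c``.

    Inverse to the substitution of ``c`` back to ``u``.
    """
    _require_vertices(K, u)
    c = frozenset(c)
    if c in K.vertices - {u}:
        raise PreconditionError(
            "identifier-collision",
            f"identifier {set(c)!r} already names a distinct vertex",
        )
    if c == u:
        return K
    return K.replace(
        frozenset(c if x == u else x for x in s) for s in K.simplices
    )
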
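"""Fixtures and generators for exercising the pipeline without external data.

The named fixtures are small hand-checkable complexes; the generators build
random graph-first complexes and plant exchangeable vertex pairs whose
detection and recovery can be verified against ground truth.
"""

from __future__ import annotations

import random
from itertools import combinations
from typing import Optional

from .core import (
    DomainError,
    SimplicialRepresentation,
    Vertex,
    clique_completion,
    close_under_faces,
    flatten,
    singleton,
)

__all__ = ["FIXTURES", "fixture", "random_complex", "plant_exchangeable"]


def _edge():
    return close_under_faces([{1, 2}])


def _triangle():
    return close_under_faces([{1, 2, 3}])


def _square():
    return close_under_faces([{1, 2}, {2, 3}, {3, 4}, {1, 4}])


#: Fixture name -> zero-argument builder.  "edge" is the labelled 1-simplex
#: on components 1 and 2 (three simplices); "triangle" the full 2-simplex on
#: {1,2,3}; "square" the chordless 4-cycle.
FIXTURES = {
    "edge": _edge,
    "triangle": _triangle,
    "square": _square,
}


def fixture(name: str, n: Optional[int] = None) -> SimplicialRepresentation:
    """A named example complex; ``path`` takes the vertex count ``n``."""
    if name == "path":
        if n is None or n < 1:
            raise DomainError("fixture 'path' needs a vertex count n >= 1")
        if n == 1:
            return close_under_faces([{1}])
        return close_under_faces([{i, i + 1} for i in range(1, n)])
    try:
        return FIXTURES[name]()
    except KeyError:
        available = ", ".join(sorted(FIXTURES) + ["path"])
        raise DomainError(f"unknown fixture {name!r}; available: {available}") from None


def random_complex(
    n_vertices: int,
    edge_density: float,
    clique_complete: bool = False,
    seed=None,
) -> SimplicialRepresentation:
    """Random graph on ``n_vertices`` with independent edge probability
    ``edge_density``, optionally flag-completed.  Deterministic under ``seed``.
    """
    if not 1 <= n_vertices <= 12:
        raise DomainError("n_vertices must be between 1 and 12")
    if not 0 <= edge_density <= 1:
        raise DomainError("edge_density must be in [0, 1]")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    maximal = [{i} for i in range(1, n_vertices + 1)]
    for i, j in combinations(range(1, n_vertices + 1), 2):
        if rng.random() < edge_density:
            maximal.append({i, j})
    K = close_under_faces(maximal)
    if clique_complete:
        K = clique_completion(K)
    return K


def plant_exchangeable(
    K: SimplicialRepresentation,
    v: Vertex,
    mode: str = "nonadjacent",
    new_id: Optional[int] = None,
) -> SimplicialRepresentation:
    """Duplicate the closed star of ``v`` onto a fresh vertex.

    Every simplex through ``v`` spawns a copy with the new vertex in place of
    ``v``; in ``adjacent`` mode the joint simplex (original plus new vertex)
    is added as well, so the pair co-faces everywhere.  Either way the pair
    ``(v, new)`` is exchangeable in the output by construction.
    """
    if v not in K.vertices:
        raise DomainError(f"unknown vertex {set(v)!r}")
    if mode not in ("adjacent", "nonadjacent"):
        raise DomainError("mode must be 'adjacent' or 'nonadjacent'")
    taken = {i for w in K.vertices for i in flatten(w)}
    if new_id is None:
        new_id = max(taken) + 1
    elif new_id in taken:
        raise DomainError(f"identifier {new_id} collides with an existing component")
    w = singleton(new_id)
    extra = []
    for s in K.simplices:
        if v in s:
            extra.append((s - {v}) | {w})
            if mode == "adjacent":
                extra.append(s | {w})
    return close_under_faces(list(K.simplices) + extra)
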
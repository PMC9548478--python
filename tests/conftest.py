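"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own primitives where they
are the thing under test: isomorphism is decided by scanning *all* vertex
bijections, exchange preconditions are re-derived from neighbourhood/co-face
conditions, and small complexes are enumerated exhaustively as face-closed
families.
"""

from __future__ import annotations

import random
from itertools import combinations, permutations

import pytest

from simprep.core import (
    SimplicialRepresentation,
    close_under_faces,
    singleton,
)


# ---------------------------------------------------------------------------
# exhaustive enumeration of face-closed families over a small ground set
# ---------------------------------------------------------------------------

def enumerate_complexes(n: int):
    """Every simplicial complex whose vertices lie in {1..n}, incl. the void.

    Candidate simplices are processed in order of increasing cardinality; a
    set may be included only when all its facets already are, which generates
    each downward-closed family exactly once.
    """
    ground = [singleton(i) for i in range(1, n + 1)]
    candidates = []
    for r in range(1, n + 1):
        for c in combinations(ground, r):
            candidates.append(frozenset(c))
    out = []

    def rec(i: int, family: set):
        if i == len(candidates):
            out.append(SimplicialRepresentation(frozenset(family)))
            return
        s = candidates[i]
        rec(i + 1, family)
        if len(s) == 1 or all((s - {v}) in family for v in s):
            family.add(s)
            rec(i + 1, family)
            family.discard(s)

    rec(0, set())
    return out


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_isomorphisms(K, L):
    """All simplicial isomorphisms, by scanning every vertex bijection."""
    vk, vl = sorted(K.vertices, key=repr), sorted(L.vertices, key=repr)
    if len(vk) != len(vl):
        return []
    found = []
    for perm in permutations(vl):
        vm = dict(zip(vk, perm))
        if len(K.simplices) == len(L.simplices) and all(
            frozenset(vm[v] for v in s) in L.simplices for s in K.simplices
        ):
            found.append(vm)
    return found


def brute_isomorphic(K, L) -> bool:
    return bool(brute_isomorphisms(K, L))


def brute_exchange_preconditions(K, u, v) -> bool:
    """Link-condition form of the identification preconditions.

    Independent of the transposition-image implementation: checks the shared
    deleted neighbourhoods and the full co-face biconditional over *all*
    nonempty subsets of the common neighbourhood.
    """
    def neighbours(x):
        out = set()
        for s in K.simplices:
            if x in s:
                out |= s
        out.discard(x)
        return out

    adjacent = any(u in s and v in s for s in K.simplices)
    nu = neighbours(u) - {v} if adjacent else neighbours(u)
    nv = neighbours(v) - {u} if adjacent else neighbours(v)
    if nu != nv:
        return False
    common = sorted(nu, key=repr)
    for r in range(1, len(common) + 1):
        for c in combinations(common, r):
            w = frozenset(c)
            if ((w | {u}) in K.simplices) != ((w | {v}) in K.simplices):
                return False
    return True


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def triangle():
    return close_under_faces([{1, 2, 3}])


@pytest.fixture
def edge():
    return close_under_faces([{1, 2}])


@pytest.fixture
def square():
    return close_under_faces([{1, 2}, {2, 3}, {3, 4}, {1, 4}])


@pytest.fixture
def path3():
    return close_under_faces([{1, 2}, {2, 3}])


@pytest.fixture
def rng():
    return random.Random(20240917)
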
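from itertools import product

import pytest

from conftest import brute_isomorphic
from simprep.core import DomainError, close_under_faces, dimension, singleton, validate
from simprep.quotient import (
    IDENTITY,
    batched_final_orbit_space,
    final_orbit_space,
    fundamental_domain,
    orbit_space,
    project_transposition,
    vertex_orbits,
)
from simprep.symmetry import ExchangeAction, VertexPermutation, are_exchangeable, exchangeable_pairs
from simprep.synthetic import random_complex
from simprep.core import vertex_key

V1, V2, V3, V4 = (singleton(i) for i in range(1, 5))


class TestVertexOrbits:
    def test_swap_merges_pair(self, triangle):
        blocks = vertex_orbits(triangle, [(V1, V2)]).blocks
        assert blocks == frozenset({frozenset({V1, V2}), frozenset({V3})})

    def test_three_cycle_single_orbit(self, triangle):
        rot = VertexPermutation.from_cycles([[V1, V2, V3]])
        blocks = vertex_orbits(triangle, [rot]).blocks
        assert blocks == frozenset({frozenset({V1, V2, V3})})

    def test_trivial_group_gives_singletons(self, square):
        blocks = vertex_orbits(square, []).blocks
        assert blocks == frozenset(frozenset({v}) for v in square.vertices)

    def test_non_automorphism_rejected(self, path3):
        with pytest.raises(DomainError):
            vertex_orbits(path3, [(V1, V2)])


class TestOrbitSpace:
    def test_swap_quotient_is_one_simplex(self, triangle):
        Q, p = orbit_space(triangle, [(V1, V2)])
        assert dimension(Q) == 1
        assert Q.vertices == frozenset(
            {frozenset({V1, V2}), frozenset({V3})}
        )
        assert p(V1) == p(V2) == frozenset({V1, V2})

    def test_rotation_quotient_is_zero_simplex(self, triangle):
        rot = VertexPermutation.from_cycles([[V1, V2, V3]])
        Q, _ = orbit_space(triangle, [rot])
        assert dimension(Q) == 0
        assert Q.vertices == frozenset({frozenset({V1, V2, V3})})

    def test_trivial_quotient_isomorphic_to_input(self, square):
        Q, _ = orbit_space(square, [])
        assert brute_isomorphic(Q, square)

    def test_quotient_validates_on_random_inputs(self, rng):
        for _ in range(40):
            K = random_complex(rng.randint(1, 8), rng.random(), seed=rng)
            pairs = exchangeable_pairs(K)
            Q, p = orbit_space(K, pairs)
            assert validate(Q).ok
            # projection is simplicial and surjective on simplices
            images = {p.image_simplex(s) for s in K.simplices}
            assert images == Q.simplices

    def test_same_orbit_implies_exchangeable(self, rng):
        # vertices merged by an exchange action are pairwise exchangeable
        for _ in range(30):
            K = random_complex(rng.randint(2, 7), rng.random(), seed=rng)
            pairs = exchangeable_pairs(K)
            if not pairs:
                continue
            for block in vertex_orbits(K, pairs).blocks:
                members = sorted(block, key=vertex_key)
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        assert are_exchangeable(K, a, b)

    def test_simplex_representative_independence(self, rng):
        # every system of orbit representatives of a quotient simplex spans a
        # simplex upstairs
        for _ in range(20):
            K = random_complex(rng.randint(2, 7), rng.random(), seed=rng)
            pairs = exchangeable_pairs(K)
            if not pairs:
                continue
            Q, p = orbit_space(K, pairs)
            for s in Q.simplices:
                blocks = [sorted(block, key=vertex_key) for block in s]
                for reps in product(*blocks):
                    if len(set(reps)) == len(reps):
                        assert frozenset(reps) in K.simplices


class TestFundamentalDomain:
    def test_min_rule_on_triangle(self, triangle):
        action = ExchangeAction(triangle, [(V1, V2)])
        L = fundamental_domain(triangle, action)
        assert L.vertices == frozenset({V1, V3})
        assert frozenset({V1, V3}) in L.simplices

    def test_empty_action_is_identity(self, square):
        action = ExchangeAction(square, [])
        assert fundamental_domain(square, action) == square

    def test_max_rule_isomorphic_to_min_rule(self, triangle):
        action = ExchangeAction(triangle, [(V1, V2)])
        lo = fundamental_domain(triangle, action)
        hi = fundamental_domain(
            triangle, action, representative_rule=lambda b: max(b, key=vertex_key)
        )
        assert hi.vertices == frozenset({V2, V3})
        assert brute_isomorphic(lo, hi)

    def test_quotient_isomorphic_to_every_domain(self, rng):
        for _ in range(30):
            K = random_complex(rng.randint(1, 8), rng.random(), seed=rng)
            pairs = exchangeable_pairs(K)
            action = ExchangeAction(K, [tuple(p) for p in pairs])
            Q, _ = orbit_space(K, pairs)
            for rule in (
                lambda b: min(b, key=vertex_key),
                lambda b: max(b, key=vertex_key),
            ):
                assert brute_isomorphic(Q, fundamental_domain(K, action, rule))


class TestProjectTransposition:
    def test_square_other_diagonal_projects_to_pair(self, square):
        action = ExchangeAction(square, [(V1, V3)])
        result = project_transposition(square, action, (V2, V4))
        assert result is not IDENTITY
        a, b = result
        assert {a, b} == {frozenset({V2}), frozenset({V4})}
        Q, _ = orbit_space(square, action)
        assert are_exchangeable(Q, a, b)

    def test_absorbed_transposition_is_identity(self, triangle):
        action = ExchangeAction(triangle, [(V1, V2)])
        assert project_transposition(triangle, action, (V1, V2)) is IDENTITY

    def test_surviving_pair_exchangeable_downstairs(self, triangle):
        action = ExchangeAction(triangle, [(V1, V2)])
        result = project_transposition(triangle, action, (V1, V3))
        assert result is not IDENTITY
        a, b = result
        assert {a, b} == {frozenset({V1, V2}), frozenset({V3})}
        Q, _ = orbit_space(triangle, action)
        assert are_exchangeable(Q, a, b)

    def test_non_exchangeable_input_rejected(self, path3):
        action = ExchangeAction(path3, [])
        with pytest.raises(DomainError):
            project_transposition(path3, action, (V1, V2))


class TestFinalOrbitSpace:
    def test_triangle_reduces_in_one_stage(self, triangle):
        trace = final_orbit_space(triangle)
        assert len(trace) == 1
        assert len(trace.final.vertices) == 1
        (v,) = trace.final.vertices
        assert v == frozenset({V1, V2, V3})

    def test_square_reduces_in_two_stages(self, square):
        trace = final_orbit_space(square)
        assert len(trace) == 2
        assert len(trace.stages[0].result.vertices) == 2
        assert len(trace.final.vertices) == 1

    def test_rigid_complex_reduces_in_zero_stages(self):
        # the 4-path has no exchangeable pairs at all
        K = close_under_faces([{1, 2}, {2, 3}, {3, 4}])
        assert exchangeable_pairs(K) == frozenset()
        trace = final_orbit_space(K)
        assert len(trace) == 0
        assert trace.final == K

    def test_final_has_no_exchangeable_pairs(self, rng):
        for _ in range(30):
            K = random_complex(rng.randint(1, 8), rng.random(), seed=rng)
            trace = final_orbit_space(K)
            assert exchangeable_pairs(trace.final) == frozenset()
            assert validate(trace.final).ok

    def test_project_vertex_lands_in_final(self, square):
        trace = final_orbit_space(square)
        for v in square.vertices:
            assert trace.project_vertex(v) in trace.final.vertices

    def test_vertex_count_drops_by_merges(self, rng):
        for _ in range(30):
            K = random_complex(rng.randint(2, 8), rng.random(), seed=rng)
            pairs = exchangeable_pairs(K)
            Q, _ = orbit_space(K, pairs)
            blocks = vertex_orbits(K, pairs).blocks
            merges = sum(len(b) - 1 for b in blocks)
            assert len(Q.vertices) == len(K.vertices) - merges


class TestConfluence:
    def test_batched_reduction_matches_simultaneous(self, rng):
        for _ in range(40):
            K = random_complex(rng.randint(1, 7), rng.random(), seed=rng)
            simultaneous = final_orbit_space(K).final

            def choose(pairs):
                k = rng.randint(1, len(pairs))
                return rng.sample(sorted(pairs, key=repr), k)

            batched = batched_final_orbit_space(K, choose).final
            assert brute_isomorphic(simultaneous, batched)

    def test_batch_must_be_nonempty_subset(self, triangle):
        with pytest.raises(DomainError):
            batched_final_orbit_space(triangle, lambda pairs: frozenset())
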
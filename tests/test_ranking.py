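"""Filtering, seven-criteria ranking and the rank-order property tests."""

import functools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcpath.fixtures import FixtureBundle
from arcpath.milp import PathwaySolution, enumerate_pathways
from arcpath.ranking import (
    RankVector,
    execution_order,
    filter_start_feasible,
    rank_candidates,
    score_candidate,
)


def solution(path_arcs, zprime, supplying=(), fluxes=None, target=None):
    """Hand-build a PathwaySolution for unit tests."""
    active = frozenset(zprime) | frozenset(supplying)
    return PathwaySolution(
        target=target or path_arcs[-1][1],
        start_metabolite=path_arcs[0][0],
        path_arcs=tuple(path_arcs),
        active_reactions=active,
        path_reactions=frozenset(zprime),
        supplying_reactions=frozenset(supplying),
        fluxes=tuple(sorted((fluxes or {r: 1.0 for r in active}).items())),
        objective_value=float(len(path_arcs)),
    )


# ---------------------------------------------------------------------------
# start-feasibility filter
# ---------------------------------------------------------------------------

class TestStartFeasibility:
    def test_fig3_candidate_passes(self, fig3_network):
        (sol,) = enumerate_pathways(fig3_network, "P", max_solutions=1)
        order = execution_order(sol, fig3_network)
        assert order is not None
        # constructive soundness: producers precede consumers
        pool = fig3_network.categories.pool
        produced = set()
        for rid in order:
            r = fig3_network.reaction(rid)
            assert all(m in pool or m in produced for m, c in r.coeffs if c < 0)
            produced |= {m for m, c in r.coeffs if c > 0}

    def test_cyclic_supply_fails(self):
        # R2/R3 feed each other (W <-> X) with no pool input; R1 needs X
        bundle = FixtureBundle(
            reaction_records=[
                ("R1", "A + X <=> P", ""),
                ("R2", "W <=> X", ""),
                ("R3", "X <=> W", ""),
            ],
            pairs=[("R1", "A", "P", "main")],
            thermo={"R1": -20.0, "R2": -20.0, "R3": -20.0},
            masses={"A": 100.0, "P": 400.0, "W": 400.0, "X": 400.0},
            target="P",
        )
        net, _ = bundle.reconstruct()
        cand = solution([("A", "P")], ["R1"], supplying=["R2", "R3"])
        assert not filter_start_feasible(cand, net)

    def test_pool_only_first_reaction_passes(self, dual_reaction_network):
        cand = solution([("A", "P")], ["R2"])  # consumes A (start) + W (excluded)
        assert filter_start_feasible(cand, dual_reaction_network)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestScoring:
    def two_step_network(self, dg1, dg2):
        bundle = FixtureBundle(
            reaction_records=[("R1", "A <=> B", ""), ("R2", "B <=> P", "")],
            pairs=[("R1", "A", "B", "main"), ("R2", "B", "P", "main")],
            thermo={"R1": dg1, "R2": dg2},
            masses={"A": 100.0, "B": 400.0, "P": 400.0},
            target="P",
        )
        net, _ = bundle.reconstruct()
        return net

    def test_all_negative_profile_has_zero_trap(self):
        net = self.two_step_network(-5.0, -10.0)
        cand = solution([("A", "B"), ("B", "P")], ["R1", "R2"])
        rv = score_candidate(cand, net)
        assert rv.kinetic_trap_score == 0.0
        assert rv.total_dg == -15.0

    def test_endergonic_step_scores_by_formula(self):
        # (+4 + |+4|) + (-10 + |-10|) = 8; total = -6
        net = self.two_step_network(4.0, -10.0)
        cand = solution([("A", "B"), ("B", "P")], ["R1", "R2"])
        rv = score_candidate(cand, net)
        assert rv.kinetic_trap_score == 8.0
        assert rv.total_dg == -6.0

    def test_missing_dg_counts_and_contributes_nothing(self):
        net = self.two_step_network(None, -10.0)
        cand = solution([("A", "B"), ("B", "P")], ["R1", "R2"])
        rv = score_candidate(cand, net)
        assert rv.n_reactions_missing_dg == 1
        assert rv.total_dg == -10.0

    def test_heterologous_counting(self, fig3_network):
        (sol,) = enumerate_pathways(fig3_network, "P", max_solutions=1)
        assert score_candidate(sol, fig3_network).n_heterologous == 4
        rv = score_candidate(
            sol, fig3_network, host_reactions={"R1", "R2", "R3", "R4"}
        )
        assert rv.n_heterologous == 0
        rv = score_candidate(sol, fig3_network, host_reactions={"R1"})
        assert rv.n_heterologous == 3

    def test_cofactor_species_counting(self, dual_reaction_network):
        cand = solution([("A", "P")], ["R2"])
        rv = score_candidate(
            cand, dual_reaction_network, cofactor_set={"W", "NAD"}
        )
        assert rv.n_cofactor_species == 1

    def test_basis_start_flag(self, fig3_network):
        (sol,) = enumerate_pathways(fig3_network, "P", max_solutions=1)
        assert score_candidate(sol, fig3_network).starts_with_basis

    @given(
        st.lists(
            st.one_of(st.none(), st.floats(-50, 50, allow_nan=False)),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_trap_zero_iff_no_endergonic_step(self, dgs):
        known = [g for g in dgs if g is not None]
        trap = sum(g + abs(g) for g in known)
        assert (trap == 0) == all(g <= 0 for g in known)


# ---------------------------------------------------------------------------
# lexicographic ranking
# ---------------------------------------------------------------------------

def naive_compare(a: RankVector, b: RankVector) -> int:
    """Independent criterion-by-criterion comparator."""
    for x, y in [
        (a.n_active_reactions, b.n_active_reactions),
        (not a.starts_with_basis, not b.starts_with_basis),
        (a.n_reactions_missing_dg, b.n_reactions_missing_dg),
        (a.kinetic_trap_score, b.kinetic_trap_score),
        (a.total_dg, b.total_dg),
        (a.n_heterologous, b.n_heterologous),
        (a.n_cofactor_species, b.n_cofactor_species),
    ]:
        if x < y:
            return -1
        if x > y:
            return 1
    return 0


rank_vectors = st.builds(
    RankVector,
    n_active_reactions=st.integers(1, 6),
    starts_with_basis=st.booleans(),
    n_reactions_missing_dg=st.integers(0, 3),
    kinetic_trap_score=st.sampled_from([0.0, 4.0, 8.0, 20.0]),
    total_dg=st.sampled_from([-40.0, -15.0, -6.0, 3.0]),
    n_heterologous=st.integers(0, 4),
    n_cofactor_species=st.integers(0, 3),
)


class TestRanking:
    def test_shorter_pathway_beats_basis_start(self):
        a = RankVector(5, True, 0, 0.0, -10.0, 0, 0)
        b = RankVector(4, False, 2, 9.0, 5.0, 3, 3)
        assert rank_candidates([(None, a), (None, b)])[0][1] is b

    def test_stability_on_full_ties(self):
        rv = RankVector(3, True, 0, 0.0, -10.0, 1, 1)
        ranked = rank_candidates([("first", rv), ("second", rv)])
        assert [c for c, _ in ranked] == ["first", "second"]

    @given(st.lists(rank_vectors, max_size=30))
    @settings(deadline=None, max_examples=200)
    def test_matches_naive_comparator(self, vectors):
        ranked = [rv for _, rv in rank_candidates([(None, rv) for rv in vectors])]
        expected = sorted(vectors, key=functools.cmp_to_key(naive_compare))
        assert [r.as_tuple() for r in ranked] == [e.as_tuple() for e in expected]

    @given(st.lists(rank_vectors, max_size=20), st.randoms())
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance_of_order(self, vectors, rnd):
        shuffled = list(vectors)
        rnd.shuffle(shuffled)
        a = [rv.as_tuple() for _, rv in rank_candidates([(None, v) for v in vectors])]
        b = [rv.as_tuple() for _, rv in rank_candidates([(None, v) for v in shuffled])]
        assert a == b
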
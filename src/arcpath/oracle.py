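"""Brute-force pathway oracle.

Exhaustive, MILP-free enumeration of minimum-objective pathway candidates
on small networks, used as the independent reference for the optimizer.
Path enumeration walks the arc graph with networkx; stoichiometric
feasibility of an active-reaction set is checked with a plain LP
(fluxes in [1, Max], externals net-produced, target produced >= 1);
objective values use exact rational arithmetic so ties are classified
without float noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = ["OracleResult", "brute_force_pathways"]

Identity = tuple[tuple[tuple[str, str], ...], frozenset[str]]


@dataclass
class OracleResult:
    """Minimum-objective candidates found by exhaustive search."""

    feasible: bool
    min_path_len: int | None
    min_objective: Fraction | None
    #: (ordered path arcs, Z') pairs at the minimum objective
    candidates: frozenset[Identity] = frozenset()
    #: identity -> minimal supplying-reaction sets realizing it
    supplying_sets: dict[Identity, list[frozenset[str]]] = field(default_factory=dict)


def _lp_feasible(
    network: MetabolicNetwork,
    active: frozenset[str],
    target: str,
    flux_cap: float,
    cache: dict[frozenset[str], bool],
) -> bool:
    """Is there a flux assignment v_r in [1, Max] for exactly these reactions
    with every non-pool metabolite net-produced and the target >= 1?"""
    if active in cache:
        return cache[active]
    for lam, mu in network.reverse_pairs():
        if lam in active and mu in active:
            cache[active] = False
            return False
    rxns = sorted(active)
    touched: set[str] = set()
    for rid in rxns:
        touched |= {m for m, _ in network.reaction(rid).coeffs}
    pool = network.categories.pool
    rows, b = [], []
    for m in sorted(touched):
        if m in pool:
            continue
        row = [-network.reaction(rid).coeff_map.get(m, 0.0) for rid in rxns]
        rows.append(row)
        b.append(-1.0 if m == target else 0.0)
    if target not in touched:
        cache[active] = False
        return False
    res = linprog(
        c=np.zeros(len(rxns)),
        A_ub=np.array(rows) if rows else None,
        b_ub=np.array(b) if rows else None,
        bounds=[(1.0, flux_cap)] * len(rxns),
        method="highs",
    )
    ok = res.status == 0
    cache[active] = ok
    return ok


def _supplying_candidates(
    network: MetabolicNetwork, cover: frozenset[str]
) -> list[str]:
    """Reactions that could supply non-pool substrates of the active set,
    closed under their own substrate needs."""
    pool = network.categories.pool
    producers: dict[str, set[str]] = {}
    for r in network.reactions:
        for m, c in r.coeffs:
            if c > 0 and m not in pool:
                producers.setdefault(m, set()).add(r.id)
    needed = {
        m
        for rid in cover
        for m, c in network.reaction(rid).coeffs
        if c < 0 and m not in pool
    }
    cand: set[str] = set()
    frontier = set(needed)
    while frontier:
        new_rxns = set()
        for m in frontier:
            new_rxns |= producers.get(m, set())
        new_rxns -= cand | cover
        if not new_rxns:
            break
        cand |= new_rxns
        frontier = {
            m
            for rid in new_rxns
            for m, c in network.reaction(rid).coeffs
            if c < 0 and m not in pool
        }
    return sorted(cand)


def brute_force_pathways(
    network: MetabolicNetwork,
    target: str,
    max_len: int = 6,
    flux_cap: float = 1000.0,
    max_supplying: int | None = None,
    max_metabolites: int = 25,
) -> OracleResult:
    """Enumerate all minimum-objective (linear path, Z') candidates.

    Simple arc paths from any start metabolite to ``target`` are listed in
    order of length; for the shortest feasible length, every way of
    covering the path arcs with reactions and every minimal supplying set
    is enumerated, and the candidates with the fewest total active
    reactions are returned. Objective per candidate:
    ``len(path) + |active| / (|R| + 1)`` held as an exact Fraction.
    """
    if len(network.metabolites) > max_metabolites:
        raise ValueError(
            f"oracle guard: {len(network.metabolites)} metabolites > {max_metabolites}"
        )
    d = network.arc_reactions()
    G = nx.DiGraph()
    G.add_edges_from(d)
    cats = network.categories
    if target not in G:
        return OracleResult(False, None, None)

    starts = sorted((cats.start & set(G.nodes)) - {target})
    by_len: dict[int, list[tuple[str, ...]]] = {}
    for s in starts:
        for nodes in nx.all_simple_paths(G, s, target, cutoff=max_len):
            if any(n in cats.basis for n in nodes[1:-1]):
                continue  # basis metabolites may only open a path
            by_len.setdefault(len(nodes) - 1, []).append(tuple(nodes))

    R1 = len(network.reactions) + 1
    lp_cache: dict[frozenset[str], bool] = {}
    for L in sorted(by_len):
        # all feasible active sets at this path length, keyed by identity
        found: dict[Identity, dict[frozenset[str], frozenset[str]]] = {}
        best_active = None
        for nodes in by_len[L]:
            arcs = tuple(zip(nodes[:-1], nodes[1:]))
            choice_lists = [sorted(d[ij]) for ij in arcs]
            covers = {frozenset(c) for c in itertools.product(*choice_lists)}
            for cover in sorted(covers, key=sorted):
                cand_pool = _supplying_candidates(network, cover)
                t_cap = len(cand_pool) if max_supplying is None else max_supplying
                hit_size: int | None = None
                for t in range(0, t_cap + 1):
                    if hit_size is not None:
                        break
                    for extra in itertools.combinations(cand_pool, t):
                        active = cover | frozenset(extra)
                        if not _lp_feasible(
                            network, active, target, flux_cap, lp_cache
                        ):
                            continue
                        hit_size = t
                        zprime = frozenset(
                            r for r in active if any(r in d[ij] for ij in arcs)
                        )
                        ident = (arcs, zprime)
                        found.setdefault(ident, {})[active] = frozenset(extra)
                        if best_active is None or len(active) < best_active:
                            best_active = len(active)
        if not found:
            continue
        assert best_active is not None
        winners = {
            ident: sets
            for ident, sets in found.items()
            if any(len(a) == best_active for a in sets)
        }
        supplying = {
            ident: sorted(
                {supp for a, supp in sets.items() if len(a) == best_active},
                key=sorted,
            )
            for ident, sets in winners.items()
        }
        return OracleResult(
            feasible=True,
            min_path_len=L,
            min_objective=Fraction(L) + Fraction(best_active, R1),
            candidates=frozenset(winners),
            supplying_sets=supplying,
        )
    return OracleResult(False, None, None)
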
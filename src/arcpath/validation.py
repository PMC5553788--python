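"""Independent re-evaluation of the path-finding constraints.

Given a returned :class:`~arcpath.milp.PathwaySolution`, re-check every
structural and stoichiometric condition directly against the network data,
without going through the MILP model or the solver. Used both as an
internal sanity gate after each solve and by the test suite.
"""

from __future__ import annotations

from .milp import PathwaySolution
from .network import MetabolicNetwork

__all__ = ["check_solution"]


def check_solution(
    network: MetabolicNetwork,
    target: str,
    sol: PathwaySolution,
    flux_cap: float = 1000.0,
    tol: float = 1e-6,
) -> list[str]:
    """Return a list of violated conditions (empty when the solution is valid)."""
    errors: list[str] = []
    cats = network.categories
    d = network.arc_reactions()
    pairs = set(sol.path_arcs)
    fluxes = sol.flux_map
    active = sol.active_reactions

    in_deg: dict[str, int] = {}
    out_deg: dict[str, int] = {}
    for i, j in pairs:
        if (i, j) not in d:
            errors.append(f"path arc ({i},{j}) does not exist in the network")
        out_deg[i] = out_deg.get(i, 0) + 1
        in_deg[j] = in_deg.get(j, 0) + 1

    nodes = set(in_deg) | set(out_deg)
    # one arc into the target, none out of it
    if in_deg.get(target, 0) != 1:
        errors.append(f"target in-degree {in_deg.get(target, 0)} != 1")
    if out_deg.get(target, 0) != 0:
        errors.append("path leaves the target")
    for k in nodes:
        if k == target:
            continue
        i_k, o_k = in_deg.get(k, 0), out_deg.get(k, 0)
        if k in cats.basis:
            if i_k != 0:
                errors.append(f"basis metabolite {k} is entered on the path")
        elif k in cats.start:
            if i_k > o_k:
                errors.append(f"start-set node {k}: in-degree {i_k} > out-degree {o_k}")
        else:
            if i_k != o_k:
                errors.append(f"non-start node {k}: in-degree {i_k} != out-degree {o_k}")
    for k, i_k in in_deg.items():
        if i_k > 1:
            errors.append(f"node {k} entered {i_k} times")
    if sol.path_arcs and sol.path_arcs[0][0] not in cats.start:
        errors.append(f"path starts at non-start metabolite {sol.path_arcs[0][0]}")

    # stoichiometric feasibility of the flux assignment
    balance: dict[str, float] = {}
    for rid, v in fluxes.items():
        for m, c in network.reaction(rid).coeffs:
            balance[m] = balance.get(m, 0.0) + c * v
    for m in network.metabolites:
        if m in cats.pool or m == target:
            continue
        if balance.get(m, 0.0) < -tol * max(1.0, flux_cap):
            errors.append(f"external metabolite {m} net-consumed ({balance[m]:.4g})")
    if balance.get(target, 0.0) < 1.0 - tol * max(1.0, flux_cap):
        errors.append(f"target production {balance.get(target, 0.0):.4g} < 1")

    # active reactions carry flux in [1, cap]; inactive carry none
    for r in network.reactions:
        v = fluxes.get(r.id, 0.0)
        if r.id in active:
            if not (1.0 - tol <= v <= flux_cap * (1.0 + tol)):
                errors.append(f"active reaction {r.id} flux {v:.4g} outside [1, cap]")
        elif abs(v) > tol:
            errors.append(f"inactive reaction {r.id} carries flux {v:.4g}")
    # reverse pairs never both active
    for lam, mu in network.reverse_pairs():
        if lam in active and mu in active:
            errors.append(f"reverse pair ({lam},{mu}) both active")
    # every path arc is covered by an active reaction realizing it
    for ij in pairs:
        if not (d.get(ij, frozenset()) & active):
            errors.append(f"path arc {ij} not covered by any active reaction")
    # bookkeeping consistency of the solution object itself
    covered = set()
    for ij in pairs:
        covered |= d.get(ij, frozenset()) & active
    if frozenset(covered) != sol.path_reactions:
        errors.append("path_reactions (Z') inconsistent with active arc coverage")
    if sol.supplying_reactions != active - sol.path_reactions:
        errors.append("supplying_reactions != active \\ Z'")
    return errors
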
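"""Filtering, ranking and per-candidate reports.

Candidates surviving a start-feasibility filter are ordered by a stable
lexicographic comparison over seven biochemical criteria, applied in this
order:

1. number of active reactions (fewer first),
2. path starts with a basis metabolite (yes first),
3. number of linear-path reactions without ΔrG'm data (fewer first),
4. kinetic-trap score Σ(ΔrG + |ΔrG|) over the linear path (lower first;
   zero iff no endergonic step),
5. total ΔrG of the linear path (lower first),
6. number of heterologous reactions, i.e. active reactions absent from the
   host organism (fewer first),
7. number of distinct cofactor species touched by active reactions (fewer
   first).

Per-candidate reports: a step-by-step thermodynamic profile with
cumulative ΔrG (unknown values carry the cumulative sum forward), the net
reactant balance Σ_r S_mr·v_r, potential side reactions in a host
organism, and an SBML L3V1 document.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .milp import PathwaySolution
from .network import MetabolicNetwork

__all__ = [
    "RankVector",
    "ProfileRow",
    "CandidateReport",
    "filter_start_feasible",
    "execution_order",
    "score_candidate",
    "rank_candidates",
    "thermodynamic_profile",
    "reactant_balance",
    "side_reactions",
    "build_report",
]


# ---------------------------------------------------------------------------
# Start-feasibility filter
# ---------------------------------------------------------------------------

def execution_order(
    candidate: PathwaySolution, network: MetabolicNetwork
) -> list[str] | None:
    """A reaction order in which every non-pool substrate is produced before
    it is consumed, or None if no such order exists.

    Pool metabolites are free; a reaction becomes executable once each of
    its other substrates has been produced by an earlier reaction. This is
    the constructive form of the requirement that a candidate be runnable
    starting from the metabolite pool alone (the global MILP does not see
    this ordering constraint).
    """
    pool = network.categories.pool
    pending = sorted(candidate.active_reactions)
    produced: set[str] = set()
    order: list[str] = []
    while pending:
        ready = [
            rid
            for rid in pending
            if all(
                m in pool or m in produced
                for m, c in network.reaction(rid).coeffs
                if c < 0
            )
        ]
        if not ready:
            return None
        for rid in ready:
            order.append(rid)
            produced |= {m for m, c in network.reaction(rid).coeffs if c > 0}
        pending = [r for r in pending if r not in ready]
    return order


def filter_start_feasible(
    candidate: PathwaySolution, network: MetabolicNetwork
) -> bool:
    """True iff the candidate can be executed from the metabolite pool."""
    return execution_order(candidate, network) is not None


# ---------------------------------------------------------------------------
# Rank vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankVector:
    """The seven ranking criteria for one candidate (lower key sorts first)."""

    n_active_reactions: int
    starts_with_basis: bool
    n_reactions_missing_dg: int
    kinetic_trap_score: float  # kJ/mol, >= 0; 0 iff all known path ΔrG <= 0
    total_dg: float  # kJ/mol over linear-path reactions with known ΔrG
    n_heterologous: int
    n_cofactor_species: int

    def sort_key(self) -> tuple:
        return (
            self.n_active_reactions,
            not self.starts_with_basis,
            self.n_reactions_missing_dg,
            self.kinetic_trap_score,
            self.total_dg,
            self.n_heterologous,
            self.n_cofactor_species,
        )

    def as_tuple(self) -> tuple:
        return (
            self.n_active_reactions,
            self.starts_with_basis,
            self.n_reactions_missing_dg,
            self.kinetic_trap_score,
            self.total_dg,
            self.n_heterologous,
            self.n_cofactor_species,
        )


def score_candidate(
    candidate: PathwaySolution,
    network: MetabolicNetwork,
    host_reactions: Iterable[str] | None = None,
    cofactor_set: Iterable[str] | None = None,
) -> RankVector:
    """Compute the seven-criteria rank vector for one candidate.

    ``host_reactions`` holds source (pre-split) reaction ids; with no host
    given every active reaction counts as heterologous. Criteria 3-5 are
    computed over the linear-path reactions Z' only; criteria 1, 6 and 7
    over all active reactions.
    """
    cats = network.categories
    cofactors = frozenset(cofactor_set) if cofactor_set is not None else cats.cofactors

    path_dgs = [network.reaction(r).dg for r in sorted(candidate.path_reactions)]
    known = [g for g in path_dgs if g is not None]
    trap = sum(g + abs(g) for g in known)
    total = sum(known)

    if host_reactions is None:
        n_het = len(candidate.active_reactions)
    else:
        host = frozenset(host_reactions)
        n_het = sum(
            1
            for rid in candidate.active_reactions
            if network.reaction(rid).source_id not in host
        )
    touched = {
        m
        for rid in candidate.active_reactions
        for m, _ in network.reaction(rid).coeffs
    }
    return RankVector(
        n_active_reactions=len(candidate.active_reactions),
        starts_with_basis=candidate.start_metabolite in cats.basis,
        n_reactions_missing_dg=sum(1 for g in path_dgs if g is None),
        kinetic_trap_score=float(trap),
        total_dg=float(total),
        n_heterologous=n_het,
        n_cofactor_species=len(touched & cofactors),
    )


def rank_candidates(
    scored: Sequence[tuple[PathwaySolution, RankVector]],
) -> list[tuple[PathwaySolution, RankVector]]:
    """Stable lexicographic sort over the seven criteria (ties keep input order)."""
    return sorted(scored, key=lambda cr: cr[1].sort_key())


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileRow:
    step: int
    reaction: str
    dg: float | None  # kJ/mol; None = unknown, carried forward
    cumulative_dg: float


def thermodynamic_profile(
    candidate: PathwaySolution, network: MetabolicNetwork
) -> list[ProfileRow]:
    """Cumulative ΔrG'm along the linear path, one row per step.

    When an arc is realized by several Z' reactions the lexicographically
    first is reported for that step. Unknown ΔrG contributes nothing; the
    cumulative value carries forward and the row is flagged with dg=None.
    """
    d = network.arc_reactions()
    rows: list[ProfileRow] = []
    cum = 0.0
    for step, ij in enumerate(candidate.path_arcs, start=1):
        realizing = sorted(d.get(ij, frozenset()) & candidate.path_reactions)
        rid = realizing[0] if realizing else ""
        dg = network.reaction(rid).dg if rid else None
        if dg is not None:
            cum += dg
        rows.append(ProfileRow(step, rid, dg, cum))
    return rows


def reactant_balance(
    candidate: PathwaySolution, network: MetabolicNetwork
) -> dict[str, float]:
    """Net production Σ_r S_mr·v_r of every metabolite touched by the candidate."""
    balance: dict[str, float] = {}
    for rid, v in candidate.fluxes:
        for m, c in network.reaction(rid).coeffs:
            balance[m] = balance.get(m, 0.0) + c * v
    return {m: (0.0 if math.isclose(b, 0.0, abs_tol=1e-9) else b)
            for m, b in balance.items()}


def balance_sections(
    balance: dict[str, float], network: MetabolicNetwork, target: str
) -> dict[str, dict[str, float]]:
    """Split a balance into consumed pool members / produced externals / target."""
    pool = network.categories.pool
    return {
        "consumed_pool": {
            m: b for m, b in balance.items() if m in pool and b < 0
        },
        "produced_external": {
            m: b for m, b in balance.items() if m not in pool and m != target
        },
        "target": {target: balance.get(target, 0.0)},
    }


def side_reactions(
    candidate: PathwaySolution,
    network: MetabolicNetwork,
    host_reactions: Iterable[str],
) -> list[tuple[str, str]]:
    """Host reactions that would drain pathway metabolites.

    Lists every host reaction (by source id) outside the candidate's active
    set that consumes the start metabolite, a linear-path intermediate, the
    target, or a non-pool product of a supplying reaction. One row per
    reaction (its lexicographically first shared metabolite), sorted by
    reaction id.
    """
    host = frozenset(host_reactions)
    pool = network.categories.pool
    pathway_metabolites = set(candidate.path_nodes)
    for rid in candidate.supplying_reactions:
        pathway_metabolites |= {
            m for m, c in network.reaction(rid).coeffs if c > 0 and m not in pool
        }
    active_sources = {
        network.reaction(rid).source_id for rid in candidate.active_reactions
    }
    hits: dict[str, str] = {}
    for r in network.reactions:
        if r.source_id not in host or r.source_id in active_sources:
            continue
        shared = sorted(
            m for m, c in r.coeffs if c < 0 and m in pathway_metabolites
        )
        if shared:
            prev = hits.get(r.source_id)
            hits[r.source_id] = min(prev, shared[0]) if prev else shared[0]
    return sorted(hits.items())


@dataclass
class CandidateReport:
    """All per-candidate report artefacts bundled together."""

    profile: list[ProfileRow]
    balance: dict[str, float]
    side_reactions: list[tuple[str, str]]
    sbml_text: str


def build_report(
    candidate: PathwaySolution,
    network: MetabolicNetwork,
    host_reactions: Iterable[str] = (),
) -> CandidateReport:
    from .sbml import export_sbml  # deferred: libsbml import is slow

    return CandidateReport(
        profile=thermodynamic_profile(candidate, network),
        balance=reactant_balance(candidate, network),
        side_reactions=side_reactions(candidate, network, host_reactions),
        sbml_text=export_sbml(candidate, network),
    )
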
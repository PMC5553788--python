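"""Mixed-integer linear program for pathway search.

The program finds a *linear path* — a simple arc sequence from some start
metabolite to the target product P — together with a minimal set of active
reactions whose fluxes make the path stoichiometrically feasible (external
metabolites may only be net-produced; the target is produced with at least
one flux unit). No start metabolite is fixed: the solver picks any member
of the start set S.

Variables
    u_ij ∈ {0,1}   arc (i→j) is on the linear path (only for existing arcs)
    v_r  ≥ 0       flux through directed reaction r (in [1, Max] when active)
    z_r  ∈ {0,1}   reaction r is active
    s_k  ∈ {0,1}   current solution repeats the k-th seen metabolite path

Base constraints
    exactly one arc enters P, none leaves it; start metabolites have
    in-degree ≤ out-degree; basis metabolites take no in-arc (first node
    only); all other non-target nodes conserve path flow; each node is
    entered at most once; Σ_r S_mr v_r ≥ 0 for every non-pool metabolite
    (≥ 1 for P); z_r ≤ v_r ≤ Max·z_r; a reversible reaction and its
    reverse are never both active; every path arc is covered by an active
    reaction realizing it.

Objective: minimize Σ u_ij + Σ z_r / (|R|+1) — path length first, then
total active-reaction count (the second term is always < 1, so it only
breaks ties among equally short paths).

Enumeration: after each solution, exclusion constraints are appended so
that no (metabolite path, path-reaction set Z') pair is returned twice,
while still allowing the same path with a different Z' (an arc can be
realized by more than one reaction) and one-arc extensions of earlier
paths. The model is re-solved until infeasible.

The model is held as a solver-agnostic list of linear constraints
(:class:`MilpModel`) and handed to scipy's HiGHS backend by
:func:`solve_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import Arc, MetabolicNetwork

__all__ = [
    "ConfigurationError",
    "SolverError",
    "ConsistencyError",
    "MilpModel",
    "solve_model",
    "PathwaySolution",
    "PathfindingProblem",
    "build_milp",
    "extract_solution",
    "enumerate_pathways",
    "DEFAULT_FLUX_CAP",
]

DEFAULT_FLUX_CAP = 1000.0
INTEGER_TOL = 1e-6


class ConfigurationError(ValueError):
    """The requested search is ill-posed (e.g. target inside the pool)."""


class SolverError(RuntimeError):
    """The backend failed for a reason other than proven infeasibility."""


class ConsistencyError(RuntimeError):
    """A solver assignment violates the model when re-checked."""


# ---------------------------------------------------------------------------
# Solver-agnostic model + scipy adapter
# ---------------------------------------------------------------------------

@dataclass
class MilpModel:
    """Minimal MILP container: named variables, linear constraints, min-objective."""

    var_names: list[str] = field(default_factory=list)
    var_kinds: list[str] = field(default_factory=list)  # 'bin' | 'cont'
    var_lb: list[float] = field(default_factory=list)
    var_ub: list[float] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)
    # constraints as (coeff dict, lb, ub)
    constraints: list[tuple[dict[int, float], float, float]] = field(
        default_factory=list
    )
    objective: dict[int, float] = field(default_factory=dict)

    def add_var(self, name: str, kind: str, lb: float = 0.0, ub: float = 1.0) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name}")
        idx = len(self.var_names)
        self.var_names.append(name)
        self.var_kinds.append(kind)
        self.var_lb.append(lb)
        self.var_ub.append(ub)
        self._index[name] = idx
        return idx

    def var(self, name: str) -> int:
        return self._index[name]

    def add_constraint(
        self, coeffs: Mapping[int, float], lb: float = -np.inf, ub: float = np.inf
    ) -> None:
        self.constraints.append((dict(coeffs), lb, ub))

    def set_objective(self, coeffs: Mapping[int, float]) -> None:
        self.objective = dict(coeffs)


def solve_model(
    model: MilpModel, time_limit_s: float | None = None
) -> tuple[str, np.ndarray | None, float | None]:
    """Solve with scipy/HiGHS. Returns (status, values, objective).

    status is 'optimal', 'infeasible' or raises :class:`SolverError`.
    """
    n = len(model.var_names)
    c = np.zeros(n)
    for i, w in model.objective.items():
        c[i] = w
    integrality = np.array(
        [1 if k == "bin" else 0 for k in model.var_kinds], dtype=np.uint8
    )
    bounds = Bounds(np.array(model.var_lb), np.array(model.var_ub))
    cons = []
    if model.constraints:
        rows, cols, data, lbs, ubs = [], [], [], [], []
        for ci, (coeffs, lb, ub) in enumerate(model.constraints):
            for vi, w in coeffs.items():
                rows.append(ci)
                cols.append(vi)
                data.append(w)
            lbs.append(lb)
            ubs.append(ub)
        A = sp.csr_matrix((data, (rows, cols)), shape=(len(model.constraints), n))
        cons = [LinearConstraint(A, np.array(lbs), np.array(ubs))]
    options = {}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    if res.status == 0:
        return "optimal", res.x, float(res.fun)
    if res.status == 2:
        return "infeasible", None, None
    raise SolverError(f"MILP solver failed: status={res.status} ({res.message})")


# ---------------------------------------------------------------------------
# Pathway solutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwaySolution:
    """One pathway candidate: ordered linear path plus active reactions.

    ``path_arcs`` is the ordered (substrate, product) node sequence of the
    linear path; ``path_reactions`` (Z') are the active reactions realizing
    at least one path arc; ``supplying_reactions`` are the remaining active
    reactions, which produce non-pool substrates consumed along the path.
    """

    target: str
    start_metabolite: str
    path_arcs: tuple[tuple[str, str], ...]
    active_reactions: frozenset[str]
    path_reactions: frozenset[str]
    supplying_reactions: frozenset[str]
    fluxes: tuple[tuple[str, float], ...]
    objective_value: float

    @property
    def path_nodes(self) -> tuple[str, ...]:
        return (self.path_arcs[0][0],) + tuple(j for _, j in self.path_arcs)

    @property
    def path_key(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.path_arcs)

    @property
    def identity(self) -> tuple[frozenset[tuple[str, str]], frozenset[str]]:
        """Distinctness key used by the exclusion constraints."""
        return (self.path_key, self.path_reactions)

    @property
    def flux_map(self) -> dict[str, float]:
        return dict(self.fluxes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target,
                "start": self.start_metabolite,
                "path": [list(a) for a in self.path_arcs],
                "path_reactions": sorted(self.path_reactions),
                "supplying_reactions": sorted(self.supplying_reactions),
                "fluxes": {r: v for r, v in self.fluxes},
                "objective": self.objective_value,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PathwaySolution":
        d = json.loads(text)
        path_rxns = frozenset(d["path_reactions"])
        supplying = frozenset(d["supplying_reactions"])
        return cls(
            target=d["target"],
            start_metabolite=d["start"],
            path_arcs=tuple((a, b) for a, b in d["path"]),
            active_reactions=path_rxns | supplying,
            path_reactions=path_rxns,
            supplying_reactions=supplying,
            fluxes=tuple(sorted(d["fluxes"].items())),
            objective_value=d["objective"],
        )


def extract_solution(
    u_values: Mapping[tuple[str, str], float],
    z_values: Mapping[str, float],
    v_values: Mapping[str, float],
    network: MetabolicNetwork,
    target: str,
    objective_value: float | None = None,
    tol: float = INTEGER_TOL,
) -> PathwaySolution:
    """Turn a variable assignment into an ordered :class:`PathwaySolution`.

    Orders the path by following arcs from the unique start node (the path
    node without an in-arc) to the target; raises
    :class:`ConsistencyError` on cyclic, branched or disconnected
    assignments.
    """
    pairs = {ij for ij, x in u_values.items() if x > 0.5}
    for ij, x in u_values.items():
        if min(abs(x), abs(1 - x)) > max(tol, 1e-5):
            raise ConsistencyError(f"non-integral u value {x} for arc {ij}")
    if not pairs:
        raise ConsistencyError("empty path assignment")
    succ: dict[str, str] = {}
    pred: dict[str, str] = {}
    for i, j in pairs:
        if i in succ or j in pred:
            raise ConsistencyError("branched path assignment")
        succ[i] = j
        pred[j] = i
    starts = [i for i in succ if i not in pred]
    if len(starts) != 1:
        raise ConsistencyError(f"path has {len(starts)} start nodes (cycle?)")
    node = starts[0]
    ordered: list[tuple[str, str]] = []
    seen = {node}
    while node in succ:
        nxt = succ[node]
        if nxt in seen:
            raise ConsistencyError("cyclic path assignment")
        ordered.append((node, nxt))
        seen.add(nxt)
        node = nxt
    if len(ordered) != len(pairs):
        raise ConsistencyError("disconnected path assignment")
    if node != target:
        raise ConsistencyError(f"path ends at {node}, not target {target}")

    active = frozenset(r for r, x in z_values.items() if x > 0.5)
    d = network.arc_reactions()
    covered: set[str] = set()
    for ij in ordered:
        covered |= d.get(ij, frozenset()) & active
    zprime = frozenset(covered)
    if objective_value is None:
        objective_value = len(ordered) + len(active) / (len(network.reactions) + 1)
    return PathwaySolution(
        target=target,
        start_metabolite=ordered[0][0],
        path_arcs=tuple(ordered),
        active_reactions=active,
        path_reactions=zprime,
        supplying_reactions=active - zprime,
        fluxes=tuple(sorted((r, float(v_values.get(r, 0.0))) for r in active)),
        objective_value=float(objective_value),
    )


# ---------------------------------------------------------------------------
# Problem construction and iterative solving
# ---------------------------------------------------------------------------

class PathfindingProblem:
    """MILP instance for one target, with mutable solution-exclusion state.

    Each :meth:`solve_next` call rebuilds the model (base constraints plus
    all exclusion constraints accumulated so far), solves it, validates the
    returned assignment independently, records the new solution in the
    exclusion state and returns it; ``None`` signals exhaustion.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        target: str,
        flux_cap: float = DEFAULT_FLUX_CAP,
        integer_tolerance: float = INTEGER_TOL,
        time_limit_s: float | None = None,
    ) -> None:
        if target not in network._met_index:
            raise ConfigurationError(f"target {target!r} not in network")
        if target in network.categories.pool:
            raise ConfigurationError(
                f"target {target!r} is in the metabolite pool; nothing to search"
            )
        if flux_cap < 1:
            raise ConfigurationError("flux_cap must be >= 1")
        self.network = network
        self.target = target
        self.flux_cap = float(flux_cap)
        self.integer_tolerance = integer_tolerance
        self.time_limit_s = time_limit_s

        self.d = network.arc_reactions()  # (i, j) -> directed reaction ids
        self.pairs: list[tuple[str, str]] = sorted(self.d)
        self._in: dict[str, list[tuple[str, str]]] = {}
        self._out: dict[str, list[tuple[str, str]]] = {}
        for i, j in self.pairs:
            self._out.setdefault(i, []).append((i, j))
            self._in.setdefault(j, []).append((i, j))
        self.nodes = sorted(set(self._in) | set(self._out))
        # exclusion bookkeeping: one entry per distinct metabolite path
        # path_key -> (s-var name, alpha, arc set); plus all seen Z' per path
        self._paths: dict[frozenset[tuple[str, str]], tuple[str, str]] = {}
        self._seen_zprimes: list[tuple[frozenset[tuple[str, str]], frozenset[str]]] = []
        self._infeasible = target not in self._in  # no arc can enter P

    # -- model -------------------------------------------------------------

    def build_model(self) -> MilpModel:
        net, P = self.network, self.target
        cats = net.categories
        M = len(net.metabolites)
        R = len(net.reactions)
        model = MilpModel()

        u = {ij: model.add_var(f"u[{ij[0]},{ij[1]}]", "bin") for ij in self.pairs}
        v = {
            r.id: model.add_var(f"v[{r.id}]", "cont", 0.0, self.flux_cap)
            for r in net.reactions
        }
        z = {r.id: model.add_var(f"z[{r.id}]", "bin") for r in net.reactions}

        def in_arcs(k: str) -> list[tuple[str, str]]:
            return self._in.get(k, [])

        def out_arcs(k: str) -> list[tuple[str, str]]:
            return self._out.get(k, [])

        # one arc into P; no arc out of P
        model.add_constraint({u[ij]: 1.0 for ij in in_arcs(P)}, 1.0, 1.0)
        if out_arcs(P):
            model.add_constraint({u[ij]: 1.0 for ij in out_arcs(P)}, 0.0, 0.0)
        for k in self.nodes:
            if k == P:
                continue
            coeffs = {u[ij]: 1.0 for ij in in_arcs(k)}
            for ij in out_arcs(k):
                coeffs[u[ij]] = coeffs.get(u[ij], 0.0) - 1.0
            if k in cats.basis:
                # basis metabolites may only open a path: zero in-arcs
                if in_arcs(k):
                    model.add_constraint(
                        {u[ij]: 1.0 for ij in in_arcs(k)}, 0.0, 0.0
                    )
            elif k in cats.start:
                # start node or pass-through: in-degree <= out-degree
                model.add_constraint(coeffs, -np.inf, 0.0)
            else:
                # interior metabolites conserve path flow
                model.add_constraint(coeffs, 0.0, 0.0)
        # simple path: each node entered at most once ...
        for k in self.nodes:
            if in_arcs(k):
                model.add_constraint({u[ij]: 1.0 for ij in in_arcs(k)}, -np.inf, 1.0)
        # ... and left at most once. The in-degree bound alone admits
        # branchy assignments (a start-set node feeding both the path and a
        # back-arc into the path's first metabolite) once the solution-
        # exclusion constraints are in play; together the two bounds
        # restrict u to a single simple chain ending in P.
        for k in self.nodes:
            if out_arcs(k):
                model.add_constraint(
                    {u[ij]: 1.0 for ij in out_arcs(k)}, -np.inf, 1.0
                )

        # stoichiometric feasibility over all reactions
        S = net.stoichiometric_matrix().tocsr()
        rxn_ids = [r.id for r in net.reactions]
        for m in net.metabolites:
            if m in cats.pool:
                continue
            row = S.getrow(net.metabolite_index(m))
            coeffs = {
                v[rxn_ids[jj]]: float(w) for jj, w in zip(row.indices, row.data)
            }
            if not coeffs:
                if m == P:
                    model.add_constraint({}, 1.0, np.inf)  # infeasible: no producer
                continue
            lb = 1.0 if m == P else 0.0
            model.add_constraint(coeffs, lb, np.inf)

        # active reactions carry flux in [1, Max]
        for rid in rxn_ids:
            model.add_constraint({z[rid]: 1.0, v[rid]: -1.0}, -np.inf, 0.0)
            model.add_constraint({v[rid]: 1.0, z[rid]: -self.flux_cap}, -np.inf, 0.0)
        # a reaction and its reverse never run together
        for lam, mu in net.reverse_pairs():
            model.add_constraint({z[lam]: 1.0, z[mu]: 1.0}, -np.inf, 1.0)
        # every path arc is realized by at least one active reaction
        for ij in self.pairs:
            coeffs = {z[r]: 1.0 for r in self.d[ij]}
            coeffs[u[ij]] = coeffs.get(u[ij], 0.0) - 1.0
            model.add_constraint(coeffs, 0.0, np.inf)

        # objective: path length first, then total active reactions
        obj = {ui: 1.0 for ui in u.values()}
        w = 1.0 / (R + 1)
        for zi in z.values():
            obj[zi] = w
        model.set_objective(obj)

        # exclusion constraints for previously seen solutions
        s_vars: dict[frozenset[tuple[str, str]], int] = {}
        for path_key, (s_name, alpha) in self._paths.items():
            sk = model.add_var(s_name, "bin")
            s_vars[path_key] = sk
            n_path = len(path_key)
            in_path = {u[ij] for ij in path_key}
            # s_k = 1 only if all arcs of path k are active ...
            coeffs = {ui: -1.0 for ui in in_path}
            coeffs[sk] = float(n_path)
            model.add_constraint(coeffs, -np.inf, 0.0)
            # ... and no arc outside path k is active
            coeffs = {u[ij]: 1.0 for ij in self.pairs if ij not in path_key}
            if coeffs:
                coeffs[sk] = float(M * M)
                model.add_constraint(coeffs, -np.inf, float(M * M))
            # new solution repeats path k, drops one of its arcs, or extends
            # it by one arc into its first metabolite alpha
            coeffs = {ui: 1.0 for ui in in_path}
            for ij in self._in.get(alpha, []):
                coeffs[u[ij]] = coeffs.get(u[ij], 0.0) - 1.0
            coeffs[sk] = coeffs.get(sk, 0.0) - 1.0
            model.add_constraint(coeffs, -np.inf, float(n_path - 1))
        # never repeat an exact (path, Z') pair
        for path_key, zprime in self._seen_zprimes:
            sk = s_vars[path_key]
            coeffs = {z[r]: 1.0 for r in zprime}
            coeffs[sk] = coeffs.get(sk, 0.0) + float(R)
            model.add_constraint(coeffs, -np.inf, float(len(zprime) - 1 + R))
        return model

    # -- solving -----------------------------------------------------------

    def solve_next(self) -> PathwaySolution | None:
        """Return the next distinct pathway candidate, or None when exhausted."""
        if self._infeasible:
            return None
        model = self.build_model()
        status, x, obj = solve_model(model, self.time_limit_s)
        if status == "infeasible":
            return None
        assert x is not None
        u_values = {ij: x[model.var(f"u[{ij[0]},{ij[1]}]")] for ij in self.pairs}
        z_values = {r.id: x[model.var(f"z[{r.id}]")] for r in self.network.reactions}
        v_values = {r.id: x[model.var(f"v[{r.id}]")] for r in self.network.reactions}
        sol = extract_solution(
            u_values,
            z_values,
            v_values,
            self.network,
            self.target,
            objective_value=obj,
            tol=self.integer_tolerance,
        )
        polished = minimize_fluxes(
            self.network, sol.active_reactions, self.target, self.flux_cap
        )
        if polished is not None:
            sol = PathwaySolution(
                target=sol.target,
                start_metabolite=sol.start_metabolite,
                path_arcs=sol.path_arcs,
                active_reactions=sol.active_reactions,
                path_reactions=sol.path_reactions,
                supplying_reactions=sol.supplying_reactions,
                fluxes=tuple(sorted(polished.items())),
                objective_value=sol.objective_value,
            )
        from .validation import check_solution  # local import avoids cycle

        violations = check_solution(
            self.network, self.target, sol, flux_cap=self.flux_cap
        )
        if violations:
            raise ConsistencyError(
                "solver assignment violates model constraints: "
                + "; ".join(violations)
            )
        self._record(sol)
        return sol

    def _record(self, sol: PathwaySolution) -> None:
        key = sol.path_key
        if key not in self._paths:
            self._paths[key] = (f"s[{len(self._paths)}]", sol.start_metabolite)
        self._seen_zprimes.append((key, sol.path_reactions))

    def __iter__(self) -> Iterator[PathwaySolution]:
        while True:
            sol = self.solve_next()
            if sol is None:
                return
            yield sol


def minimize_fluxes(
    network: MetabolicNetwork,
    active: frozenset[str],
    target: str,
    flux_cap: float,
) -> dict[str, float] | None:
    """Canonical flux assignment for a fixed active set: minimize total flux.

    The MILP only requires fluxes in [1, Max], so the solver's v values are
    arbitrary within that band; reports use this minimal-flux polish
    instead (a chain of unary reactions gets unit fluxes).
    """
    from scipy.optimize import linprog

    rxns = sorted(active)
    pool = network.categories.pool
    touched: set[str] = set()
    for rid in rxns:
        touched |= {m for m, _ in network.reaction(rid).coeffs}
    rows, b = [], []
    for m in sorted(touched):
        if m in pool:
            continue
        rows.append([-network.reaction(rid).coeff_map.get(m, 0.0) for rid in rxns])
        b.append(-1.0 if m == target else 0.0)
    res = linprog(
        c=np.ones(len(rxns)),
        A_ub=np.array(rows) if rows else None,
        b_ub=np.array(b) if rows else None,
        bounds=[(1.0, flux_cap)] * len(rxns),
        method="highs",
    )
    if res.status != 0:
        return None
    return dict(zip(rxns, (float(x) for x in res.x)))


def build_milp(
    network: MetabolicNetwork,
    target: str,
    flux_cap: float = DEFAULT_FLUX_CAP,
    **kwargs,
) -> PathfindingProblem:
    """Construct the path-finding problem for ``target``."""
    return PathfindingProblem(network, target, flux_cap=flux_cap, **kwargs)


def enumerate_pathways(
    network: MetabolicNetwork,
    target: str,
    max_solutions: int = 20,
    flux_cap: float = DEFAULT_FLUX_CAP,
    logger=None,
    **kwargs,
) -> list[PathwaySolution]:
    """Enumerate up to ``max_solutions`` distinct candidates, best first.

    Solutions come out in nondecreasing objective order; enumeration stops
    early when the model becomes infeasible (all candidates exhausted).
    """
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    problem = build_milp(network, target, flux_cap=flux_cap, **kwargs)
    out: list[PathwaySolution] = []
    for sol in problem:
        out.append(sol)
        if logger is not None:
            logger.info(
                "solution %d: %s -> %s, %d arcs, %d supplying, objective %.4f",
                len(out),
                sol.start_metabolite,
                target,
                len(sol.path_arcs),
                len(sol.supplying_reactions),
                sol.objective_value,
            )
        if len(out) >= max_solutions:
            break
    return out
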
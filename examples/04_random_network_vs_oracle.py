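"""Cross-check the optimizer against the brute-force oracle.

Generates a seeded random network with a planted feasible pathway, runs
the full MILP enumeration, and compares the minimum-objective candidate
set against an exhaustive search (simple-path enumeration plus LP
feasibility of every reaction cover and supplying set). Agreement on the
candidate set and on the minimum path length is the package's core
correctness property.
"""

from arcpath.fixtures import FixtureSpec, brute_force_pathways, generate_random_bundle
from arcpath.milp import build_milp
from arcpath.validation import check_solution

spec = FixtureSpec(n_metabolites=12, n_reactions=12, planted_path_length=3, seed=5)
bundle = generate_random_bundle(spec)
network, _ = bundle.reconstruct()
print(f"random network (seed {spec.seed}): "
      f"{len(network.metabolites)} metabolites, "
      f"{len(network.reactions)} directed reactions, "
      f"{len(network.arcs)} arcs; target {bundle.target}")

oracle = brute_force_pathways(network, bundle.target)
print(f"oracle: min path length {oracle.min_path_len}, "
      f"min objective {oracle.min_objective}, "
      f"{len(oracle.candidates)} optimal candidate(s)")

problem = build_milp(network, bundle.target)
solutions = []
for sol in problem:
    assert check_solution(network, bundle.target, sol) == []
    solutions.append(sol)
    if sol.objective_value > float(oracle.min_objective) + 1e-6:
        break

milp_min = {
    (s.path_arcs, s.path_reactions)
    for s in solutions
    if abs(s.objective_value - float(oracle.min_objective)) <= 1e-6
}
print(f"optimizer returned {len(solutions)} candidate(s); "
      f"{len(milp_min)} at the minimum objective")
print("candidate sets identical:", milp_min == set(oracle.candidates))
for path, zprime in sorted(milp_min):
    chain = path[0][0] + " -> " + " -> ".join(j for _, j in path)
    print(f"  {chain}   Z' = {{{', '.join(sorted(zprime))}}}")
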
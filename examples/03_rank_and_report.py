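"""Score, rank and report pathway candidates.

Enumerates candidates on the toy network, applies the start-feasibility
filter, computes the seven ranking criteria (pathway length, basis start,
missing ΔrG'm, kinetic-trap score, total ΔrG'm, heterologous reactions,
cofactor species) against an E. coli-like host list, and prints the
thermodynamic profile and reactant balance of the best candidate. A
negative, monotonically dropping cumulative ΔrG'm indicates a
thermodynamically smooth pathway.
"""

from arcpath.fixtures import make_fig3_bundle
from arcpath.milp import enumerate_pathways
from arcpath.ranking import (
    filter_start_feasible,
    rank_candidates,
    reactant_balance,
    score_candidate,
    thermodynamic_profile,
)

bundle = make_fig3_bundle()
network, _ = bundle.reconstruct()
candidates = enumerate_pathways(network, "P", max_solutions=10)
host = bundle.host  # reactions natively present in the host organism

kept = [c for c in candidates if filter_start_feasible(c, network)]
scored = [(c, score_candidate(c, network, host_reactions=host)) for c in kept]
ranked = rank_candidates(scored)

print(f"{len(ranked)} candidate(s) after filtering\n")
print("rank  start  n_active  basis  miss_dG  trap  total_dG  heterologous  cofactors")
for pos, (cand, rv) in enumerate(ranked, 1):
    print(f"{pos:>4}  {cand.start_metabolite:<5} {rv.n_active_reactions:>8}  "
          f"{str(rv.starts_with_basis):<5} {rv.n_reactions_missing_dg:>7}  "
          f"{rv.kinetic_trap_score:>4g}  {rv.total_dg:>8g}  "
          f"{rv.n_heterologous:>12}  {rv.n_cofactor_species:>9}")

best, _ = ranked[0]
print("\nthermodynamic profile of the best candidate (kJ/mol):")
print("step  reaction  dG      cumulative")
for row in thermodynamic_profile(best, network):
    dg = "n/a" if row.dg is None else f"{row.dg:g}"
    print(f"{row.step:>4}  {row.reaction:<8} {dg:>6}  {row.cumulative_dg:>10g}")

print("\nreactant balance (net production, flux units):")
for met, bal in sorted(reactant_balance(best, network).items()):
    print(f"  {met:<4} {bal:+g}")
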
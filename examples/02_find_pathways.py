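"""Enumerate pathway candidates to a target metabolite.

On the toy network the optimizer picks its own start metabolite: the
unique optimum is the three-arc chain M1 -> M2 -> M3 -> P. Reaction R3
also consumes the external metabolite M4, so the supplying reaction R4
(M5 -> M4, with M5 in the pool) joins the candidate. The objective is
path length plus a small tie-breaking term counting active reactions:
3 + 4/8 = 3.5 here (7 directed reactions in the network).
"""

from arcpath.fixtures import make_fig3_network
from arcpath.milp import enumerate_pathways

network = make_fig3_network()
solutions = enumerate_pathways(network, "P", max_solutions=10)

print(f"{len(solutions)} candidate(s) to P\n")
for k, sol in enumerate(solutions, 1):
    chain = " -> ".join(sol.path_nodes)
    print(f"candidate {k}: {chain}")
    print(f"  linear-path reactions Z' : {', '.join(sorted(sol.path_reactions))}")
    print(f"  supplying reactions      : {', '.join(sorted(sol.supplying_reactions)) or '-'}")
    print(f"  fluxes                   : "
          + ", ".join(f"{r}={v:g}" for r, v in sol.fluxes))
    print(f"  objective                : {sol.objective_value:g}")
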
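# arcpath

Design of multi-enzyme biosynthesis pathways: reconstruct a reaction-pair
network from KEGG-style data, enumerate pathway candidates to a target
metabolite with a mixed-integer linear program that chooses its own start
metabolite, and filter, rank and report the candidates by biochemical
criteria.

## Who this is for

Biocatalysis and synthetic-biology groups planning syntheses with in
vitro enzyme cascades, cell hydrolysates or permeabilized cells. In these
systems the reaction vessel *is* the compartment, so steady-state methods
(FBA, elementary modes) do not fit; what matters is a concrete chain of
enzyme steps from a cheap, available precursor to the product, with
workable thermodynamics and few side reactions in the chosen host.

## The model in brief

The network's edges are **arcs** — curated substrate→product pairs within
single reactions (KEGG main/trans reaction pairs), which prevents paths
from hopping through cofactors. Reactions are split into directed copies
by the transformed Gibbs energy ΔrG′m (reversible iff |ΔrG′m| <
15 kJ/mol; endergonic-as-written reactions are flipped; missing data
means irreversible as written). Metabolites are categorized into start
metabolites S (in an arc, mass ∈ (0, 300] Da), curated basis hubs B ⊆ S
(allowed only as a path's first node), cofactors and excluded compounds;
their union is the freely available pool E_m, and everything else is
external and must be net-produced.

The search MILP uses arc binaries u_ij, reaction binaries z_r and fluxes
v_r ∈ [1, Max] when active, with degree constraints shaping u into a
simple path from any start metabolite to the target P, Σ_r S_mr v_r ≥ 0
for externals (≥ 1 for P), and a coverage constraint Σ_r d_ijr z_r ≥ u_ij
linking path arcs to active reactions. The objective

    min  Σ u_ij  +  (1/(|R|+1)) Σ z_r

minimizes path length first and total active reactions as a tie-break. A
candidate is the linear path plus its realizing reactions Z′ and the
supplying reactions that feed non-pool co-substrates. Exclusion
constraints then enumerate distinct (path, Z′) candidates in
nondecreasing objective order until the model is infeasible.

Candidates that cannot actually be executed starting from the pool are
filtered out, and the rest are ranked lexicographically by seven
criteria: active-reaction count, basis start, missing-ΔrG′m count,
kinetic-trap score Σ(ΔrG′m + |ΔrG′m|), total ΔrG′m, heterologous-reaction
count, cofactor-species count. Each candidate gets a thermodynamic
profile, a reactant balance, a side-reaction list for a host organism,
and an SBML L3V1 file.

See `docs/methods.md` for the full model, parameter meanings and design
choices.

## Worked example

`examples/` holds one narrative script per capability. On the built-in
toy network (three-step chain M1→M2→M3→P whose last step consumes an
external metabolite M4 supplied from the pool metabolite M5):

```bash
$ python examples/02_find_pathways.py
1 candidate(s) to P

candidate 1: M1 -> M2 -> M3 -> P
  linear-path reactions Z' : R1, R2, R3
  supplying reactions      : R4
  fluxes                   : R1=1, R2=1, R3=1, R4=1
  objective                : 3.5
```

The optimizer picked M1 as the start on its own; the objective 3.5 is
3 path arcs + 4 active reactions / 8 (seven directed reactions in the
network, plus one). Ranking and reporting the same candidate:

```bash
$ python examples/03_rank_and_report.py
1 candidate(s) after filtering

rank  start  n_active  basis  miss_dG  trap  total_dG  heterologous  cofactors
   1  M1           4  True        0     0       -63             1          0

thermodynamic profile of the best candidate (kJ/mol):
step  reaction  dG      cumulative
   1  R1          -20         -20
   2  R2          -18         -38
   3  R3          -25         -63
...
```

A kinetic-trap score of 0 with a steadily dropping cumulative ΔrG′m marks
a thermodynamically smooth cascade; one reaction (R3) is heterologous for
the example host list. `examples/04_random_network_vs_oracle.py` shows
the optimizer agreeing exactly with a brute-force search on a random
network.

The same workflow is available as a command line:

```bash
arcpath reconstruct --reactions reactions.keg --pairs pairs.tsv \
    --thermo thermo.tsv --compounds compounds.tsv --basis basis.txt -o net.json
arcpath find --network net.json --target P --max-solutions 20 -o cands.json
arcpath rank --network net.json --candidates cands.json --host host.txt -o out/
```

`out/` then contains `ranked.tsv`, per-candidate `profile_*.tsv`,
`balance_*.tsv`, `side_*.tsv` and `candidate_*.sbml`.

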
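# Methods

`arcpath` designs multi-enzyme biosynthesis pathways for in vitro enzyme
cascades, cell hydrolysates and permeabilized cells. In those systems the
reaction compartment is the bioreactor itself, so the usual steady-state
assumption of flux-balance methods does not apply: substrates are batched
in, intermediates accumulate, and the practical question is "which chain
of enzymes, starting from something cheap and available, makes the target
compound — and is each step workable?" The package answers it in three
stages: network reconstruction, optimization-based path-finding, and
filtering/ranking with per-candidate reports.

## Network model

The substrate of the search is a network of **arcs**: directed
substrate→product edges within single reactions, taken from a curated
reaction-pair table (KEGG-style main- and trans-pairs by default;
cofac-, ligase- and leave-pairs can be admitted by configuration). Arcs,
not plain shared-metabolite adjacency, keep the graph biologically
meaningful: a path cannot hop through ATP just because two reactions both
touch it.

Reaction records are dropped when they are unusable for stoichiometric
reasoning: a `generic` or `incomplete` comment, a symbolic stoichiometric
coefficient *n*, or glycan (G-number) participants. Each rejection carries
one reason code with fixed precedence (comment > symbolic coefficient >
glycan) so logs are deterministic.

Direction comes from the transformed reaction Gibbs energy ΔrG′m
(1 mM reactants, pH 7, 25 °C), supplied as a per-reaction table.
With threshold T = 15 kJ/mol (configurable):

* |ΔrG′m| < T — the reaction is split into a reversible pair (λ, μ) with
  negated stoichiometry, the backward copy carrying −ΔrG′m;
* ΔrG′m ≤ −T — irreversible as written;
* ΔrG′m ≥ +T — irreversible in the reverse direction (the equation is
  flipped and ΔrG′m negated); flipping rather than dropping keeps the
  exergonic direction usable, and flipped reactions reverse their arcs;
* missing data — irreversible as written (conservative: nothing is
  assumed reversible without evidence).

Metabolites fall into categories that drive the search semantics:

* **start metabolites S** — everything occurring in at least one arc with
  molecular mass in (0, 300] Da (the window is half-open and
  configurable; metabolites without mass data never qualify). These are
  plausible purchasable precursors.
* **basis metabolites B ⊆ S** — a curated list of cheap hub compounds
  (glucose, pyruvate, ...). They may only *open* a path, never appear as
  intermediates: hubs in the middle of a path are almost always
  shortcuts through central metabolism. A heavy compound (e.g. sucrose,
  342 Da) becomes a start metabolite simply by listing it in the basis.
* **cofactors** and **excluded metabolites** — curated lists (ATP/ADP/AMP,
  NAD(P)(H), water, O2, CO2, phosphate, ...). Arcs touching them are
  removed to prevent meaningless shortcuts, but as pool members they may
  be freely consumed by any reaction.
* the **metabolite pool** E_m = S ∪ B ∪ cofactors ∪ excluded is what the
  reactor can be loaded with; everything else is **external** and must be
  net-produced. **Generic** metabolites (peptide, protein, ...) are
  externals whose arcs are removed.

The stoichiometric matrix S (|M|×|R|, reversibles split into two opposite
columns) is kept sparse; reverse pairs satisfy S·,λ = −S·,μ exactly.

## Path-finding MILP

A **pathway candidate** is a *linear path* — a simple arc sequence from
some start metabolite to the target P — plus a minimal set of *supplying
reactions* producing the non-pool co-substrates the path consumes. No
start metabolite is fixed; the optimizer chooses any member of S, which is
the point of the pan-network formulation: the designer should not have to
guess the precursor.

Variables: binary u_ij per existing arc endpoint pair (arc on the path),
binary z_r (reaction active), continuous v_r ∈ [0, Max] (flux, forced
into [1, Max] when active via z_r ≤ v_r ≤ Max·z_r; Max defaults to 1000
and only needs Max ≥ 1). Constraints:

* exactly one path arc enters P and none leaves it;
* start-set nodes have path in-degree ≤ out-degree (they may open a path
  or pass through); basis nodes take no in-arc at all; every other
  non-target node conserves path flow (in-degree = out-degree);
* each node is entered at most once *and left at most once* (see below);
* Σ_r S_mr v_r ≥ 0 for every non-pool metabolite except P, and ≥ 1 for P
  (externals only produced, target actually made);
* a reversible reaction and its reverse are never both active;
* coverage: for every arc pair (i,j), Σ_r d_ijr z_r ≥ u_ij, where d_ijr
  marks that reaction r realizes the arc — a path arc needs at least one
  active realizing reaction.

Objective: minimize Σ u_ij + Σ z_r/(|R|+1). The second term is strictly
below 1, so path length dominates lexicographically and the active-reaction
count only breaks ties; the first solution always has the minimum feasible
path length.

**Enumeration.** A candidate's identity is (metabolite path, Z′), where
Z′ is the set of active reactions realizing path arcs; the same path with
a different realizing reaction is a genuinely different enzyme choice.
After each solution, exclusion constraints are appended: per newly seen
path U^k a binary s_k is introduced with three linked constraints that
force s_k = 1 exactly when the current assignment reproduces U^k, while
still permitting (a) the same path with different reactions, (b) any
path missing one of U^k's arcs, and (c) a one-arc extension of U^k
through its first metabolite; and per returned solution a cut
Σ_{i∈Z′} z_i + s_k·|R| ≤ |Z′| − 1 + |R| bans the exact (path, Z′) pair.
The model is re-solved until infeasible.

**A structural repair.** With only the in-degree bound, the constraint
system admits non-path u assignments once exclusion constraints are
active: the "extension" disjunct can be satisfied by a back-arc into the
path's first metabolite from an on-path start-set node, whose in ≤ out
inequality tolerates the extra outgoing arc. The symmetric out-degree ≤ 1
bound removes these artifacts; every simple (possibly prepended) chain
satisfies it, so no legitimate candidate is lost. Without it, enumeration
can return the same (path, Z′) padded with a junk arc.

**Numerics.** The model is held as a solver-agnostic constraint list and
solved with HiGHS through `scipy.optimize.milp` (branch-and-bound with
binaries, re-built per iteration; the models here are small, so rebuild
cost is negligible). Binaries are read at tolerance 1e-6; the
nondecreasing-objective check uses 1e-6·(1+|obj|). Because the MILP only
constrains active fluxes into [1, Max], the returned v values are
arbitrary within that band; each solution's fluxes are therefore polished
by a small LP (minimize total flux at fixed active set), which makes
balance reports canonical and runs deterministic. A target with no
incoming arc is reported as immediately exhausted; a target inside the
pool is a configuration error.

## Filtering and ranking

The MILP guarantees a feasible flux pattern but not *executability from
the pool*: it cannot see that the first reaction might need an
intermediate that only becomes available later. The filter performs a
constructive check over the whole candidate: pool metabolites are free,
and a reaction becomes executable once all its other substrates have been
produced by previously executed reactions; the candidate passes iff all
active reactions can be ordered this way (the weaker reading — check only
the first path reaction — would accept supply cycles that feed each other
with no pool input).

Survivors are ordered by a stable lexicographic sort over seven criteria,
in order: (1) number of active reactions (shorter cascades are cheaper to
realize), (2) basis start preferred, (3) fewer linear-path reactions
without ΔrG′m data (unknown thermodynamics usually means a poorly
characterized enzyme), (4) kinetic-trap score Σ(ΔrG′m + |ΔrG′m|) — zero
iff no endergonic step, each positive step penalized by twice its ΔrG′m,
(5) total linear-path ΔrG′m, (6) fewer heterologous reactions relative to
a host reaction list (less genetic engineering; with no host everything
counts as heterologous), (7) fewer distinct cofactor species (cofactors
are expensive and need regeneration). Criteria 3–5 run over the
linear-path reactions Z′ only; 1, 6, 7 over all active reactions.
Heterologous and side-reaction bookkeeping is by reaction identifier, not
EC number (the enzyme-to-reaction mapping is many-to-many and not part of
the inputs). Unknown ΔrG′m contributes nothing to sums and is counted by
criterion 3; full ties keep enumeration order.

Per candidate, the reports are: a step-by-step thermodynamic profile
(cumulative ΔrG′m, unknown steps flagged and carried forward), the net
reactant balance Σ_r S_mr·v_r split into consumed pool members, produced
externals and the target, potential side reactions — host reactions
outside the candidate that consume the start metabolite, a path
intermediate, the target, or a non-pool supplying product (relevant for
permeabilized cells and lysates, where the rest of the host proteome is
present) — and an SBML L3V1 document (species for every metabolite
touched, pool members flagged as boundary species, one reaction element
per active directed reaction; identifiers that are not valid SIds are
escaped reversibly).

## Synthetic data and the oracle

The fixtures module generates everything the pipeline consumes, so no
database access is needed anywhere:

* a hand-built seven-metabolite toy (linear three-arc chain to the target
  whose last step needs an external co-substrate fed by one supplying
  reaction, plus decoys including a reversible pair and a
  missing-ΔrG′m reaction) with a unique, hand-verifiable optimum;
* seeded random networks with a planted feasible pathway. Defaults:
  12 metabolites, 12 reactions, planted path of 3 arcs — small enough for
  exhaustive verification, large enough for decoys, reversible pairs,
  supplying chains and multi-reaction arcs to occur. Each planted step
  takes a side substrate with probability 0.6, drawn from the pool with
  probability 0.7 + 0.3·fraction_pool (at fraction_pool = 1 no supplying
  reactions are ever needed), otherwise from the externals with a planted
  pool-fed supplying reaction. A designated feeder metabolite is listed
  among the excluded (freely available) compounds so the planted pathway
  stays executable regardless of which arcs the draw produces. ΔrG′m
  values are uniform with 15% missing; planted reactions avoid the
  flip regime so the planted direction survives. Bundles serialize to the
  same flat files the CLI reads, with four optional records exercising
  every rejection rule.

These fixtures emulate the *structure* of curated reaction-pair networks
(arcs, categories, reversibility, supplying chains), not their biology:
no mass conservation across reactions, no realistic degree distribution,
no correlated thermodynamics. Passing tests therefore demonstrate the
correctness of the algorithms on networks with the right formal shape,
not predictive power on any organism's metabolism.

The **brute-force oracle** re-derives the minimum-objective candidate set
without the MILP: networkx enumerates simple arc paths from every start
metabolite (shortest feasible length first), every way of covering the
path arcs with realizing reactions is expanded, supplying sets are grown
over the closure of producers of needed externals, and each active set is
checked by a plain LP (fluxes in [1, Max], externals ≥ 0, target ≥ 1).
Objective values use exact rational arithmetic (`fractions.Fraction`) so
the 1/(|R|+1) tie term never suffers float ties. The guard |M| ≤ 25
keeps the search honest about its exponential nature.

## Problem sizes and verification

The shipped test-and-acceptance setup verifies, per seed batch: solver
output validity by independent constraint re-evaluation, exact agreement
of the MILP's minimum-objective (path, Z′) set with the oracle on 50
random 12-metabolite fixtures, minimum-path-length agreement, exclusion
semantics (no duplicate identities; both realizations of a doubly covered
arc; path extensions), the reconstruction filter and reversibility rules,
ranking order against a naive comparator on 1000 random criterion
vectors, SBML round-trips, balance invariants, and byte-identical
end-to-end CLI reruns. These sizes were chosen so exhaustive oracles stay
exact; the MILP itself has no such limits beyond solver capacity.

## Known limitations

* Enzyme kinetics (k_cat, K_m, enzyme loading) are out of scope; ranking
  is purely stoichiometric/thermodynamic.
* ΔrG′m values are taken at fixed 1 mM concentrations; no
  concentration-adjusted recomputation along the pathway.
* The ΔrG′m estimator itself is upstream — values arrive as a table.
* Curated lists (basis, cofactors, excluded) are inputs; nothing is
  detected automatically.
* The side-reaction report flags consumers of pathway metabolites only;
  producers competing for cofactor pools are not modeled.
* Enumeration order among equal-objective candidates is solver-dependent;
  consumers should treat equal-objective solutions as a set.
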
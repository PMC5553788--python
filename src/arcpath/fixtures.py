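"""Deterministic synthetic networks and input-file bundles.

Everything downstream modules need for testing without any download: a
hand-built toy network (a linear chain whose last step needs an external
metabolite fed by one supplying reaction), a seeded random-network
generator with a planted feasible pathway, and writers that serialize a
bundle into the tabular input formats the reconstruction consumes.

The brute-force pathway oracle lives in :mod:`arcpath.oracle` and is
re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_id_list
from .network import (
    DEFAULT_CATEGORIES,
    DEFAULT_DG_THRESHOLD,
    DEFAULT_MASS_BOUNDS,
    MetabolicNetwork,
    ReconstructionLog,
    reconstruct_network,
)
from .oracle import OracleResult, brute_force_pathways  # noqa: F401  (re-export)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_fig3_bundle",
    "make_fig3_network",
    "generate_random_bundle",
    "generate_random_network",
    "write_kegg_fixture",
    "brute_force_pathways",
    "OracleResult",
]

#: records exercising each rejection rule, appended to written fixtures
REJECT_RECORDS = [
    ("RX0001", "C90001 <=> C90002", "a generic reaction"),
    ("RX0002", "C90001 <=> C90003", "incomplete"),
    ("RX0003", "n C90001 <=> n C90004", ""),
    ("RX0004", "C90001 <=> G90005", ""),
]


@dataclass
class FixtureBundle:
    """In-memory form of one input-file bundle."""

    reaction_records: list[tuple[str, str, str]]  # (id, equation, comment)
    pairs: list[tuple[str, str, str, str]]
    thermo: dict[str, float | None]
    masses: dict[str, float | None]
    names: dict[str, str] = field(default_factory=dict)
    basis: list[str] = field(default_factory=list)
    cofactors: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    generic: list[str] = field(default_factory=list)
    host: list[str] = field(default_factory=list)
    target: str = ""

    def reactions_text(self) -> str:
        out = []
        for rid, eq, comment in self.reaction_records:
            out.append(f"ENTRY       {rid}  Reaction")
            if comment:
                out.append(f"COMMENT     {comment}")
            out.append(f"EQUATION    {eq}")
            out.append("///")
        return "\n".join(out) + "\n"

    def reconstruct(
        self,
        dg_threshold: float = DEFAULT_DG_THRESHOLD,
        mass_bounds: tuple[float, float] = DEFAULT_MASS_BOUNDS,
        admitted_categories=DEFAULT_CATEGORIES,
    ) -> tuple[MetabolicNetwork, ReconstructionLog]:
        return reconstruct_network(
            self.reactions_text(),
            self.pairs,
            self.thermo,
            self.masses,
            basis_list=self.basis,
            cofactor_list=self.cofactors,
            excluded_list=self.excluded,
            generic_list=self.generic,
            dg_threshold=dg_threshold,
            mass_bounds=mass_bounds,
            admitted_categories=admitted_categories,
        )

    def write(self, outdir: str | Path) -> Path:
        """Write the bundle files (reactions.keg, pairs.tsv, thermo.tsv,
        compounds.tsv, basis.txt, cofactors.txt, excluded.txt, host.txt)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "reactions.keg").write_text(self.reactions_text())
        lines = ["reaction_id\tsubstrate_id\tproduct_id\tcategory"]
        lines += ["\t".join(p) for p in self.pairs]
        (outdir / "pairs.tsv").write_text("\n".join(lines) + "\n")
        lines = ["reaction_id\tdrG_m_kJ_mol"]
        for rid in sorted(self.thermo):
            dg = self.thermo[rid]
            lines.append(f"{rid}\t{'' if dg is None else f'{dg:g}'}")
        (outdir / "thermo.tsv").write_text("\n".join(lines) + "\n")
        lines = ["id\tname\tmass\tgeneric"]
        for mid in sorted(self.masses):
            mass = self.masses[mid]
            lines.append(
                "\t".join(
                    [
                        mid,
                        self.names.get(mid, mid),
                        "" if mass is None else f"{mass:g}",
                        "1" if mid in self.generic else "0",
                    ]
                )
            )
        (outdir / "compounds.tsv").write_text("\n".join(lines) + "\n")
        write_id_list(outdir / "basis.txt", self.basis)
        write_id_list(outdir / "cofactors.txt", self.cofactors)
        write_id_list(outdir / "excluded.txt", self.excluded)
        write_id_list(outdir / "host.txt", self.host)
        return outdir


def write_kegg_fixture(
    bundle: FixtureBundle, outdir: str | Path, with_reject_records: bool = True
) -> Path:
    """Write a bundle to disk, optionally appending the four records that
    exercise every rejection rule (generic / incomplete comment, symbolic
    coefficient n, glycan G number)."""
    if with_reject_records:
        bundle = FixtureBundle(
            reaction_records=bundle.reaction_records + REJECT_RECORDS,
            pairs=bundle.pairs,
            thermo=bundle.thermo,
            masses=dict(
                bundle.masses,
                **{"C90001": 100.0, "C90002": 100.0, "C90003": 100.0,
                   "C90004": 100.0, "G90005": 100.0},
            ),
            names=bundle.names,
            basis=bundle.basis,
            cofactors=bundle.cofactors,
            excluded=bundle.excluded,
            generic=bundle.generic,
            host=bundle.host,
            target=bundle.target,
        )
    return bundle.write(outdir)


# ---------------------------------------------------------------------------
# Hand-built toy: linear chain + one supplying reaction + decoys
# ---------------------------------------------------------------------------

def make_fig3_bundle() -> FixtureBundle:
    """A seven-metabolite toy with a unique optimal pathway.

    M1 (basis) -R1-> M2 -R2-> M3 -R3-> P, where R3 also consumes the
    external metabolite M4; M4 is produced from the pool metabolite M5 by
    R4. Decoys: R5 (M6 -> M1, a longer way in) and R6 (M5 <-> M6,
    reversible, unrelated to P). The unique optimum is the three-arc chain
    from M1 with supplying reaction {R4}.
    """
    records = [
        ("R1", "M1 <=> M2", ""),
        ("R2", "M2 <=> M3", ""),
        ("R3", "M3 + M4 <=> P", ""),
        ("R4", "M5 <=> M4", ""),
        ("R5", "M6 <=> M1", ""),
        ("R6", "M5 <=> M6", ""),
    ]
    pairs = [
        ("R1", "M1", "M2", "main"),
        ("R2", "M2", "M3", "main"),
        ("R3", "M3", "P", "main"),
        ("R4", "M5", "M4", "main"),
        ("R5", "M6", "M1", "main"),
        ("R6", "M5", "M6", "main"),
    ]
    thermo = {
        "R1": -20.0,
        "R2": -18.0,
        "R3": -25.0,
        "R4": -16.0,
        "R5": None,  # no data: irreversible as written
        "R6": 5.0,  # |5| < 15: reversible pair
    }
    masses = {
        "M1": 100.0,
        "M2": 350.0,
        "M3": 350.0,
        "M4": 350.0,
        "M5": 90.0,
        "M6": 120.0,
        "P": 400.0,
    }
    return FixtureBundle(
        reaction_records=records,
        pairs=pairs,
        thermo=thermo,
        masses=masses,
        basis=["M1"],
        host=["R1", "R2", "R4"],
        target="P",
    )


def make_fig3_network() -> MetabolicNetwork:
    net, _ = make_fig3_bundle().reconstruct()
    return net


# ---------------------------------------------------------------------------
# Seeded random networks with a planted feasible pathway
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random network draw.

    ``fraction_start`` is the probability that a metabolite receives a
    start-qualifying molecular mass; ``fraction_pool`` biases planted side
    substrates toward the pool (at 1.0 every side substrate is a pool
    member, so candidates need no supplying reactions).
    """

    n_metabolites: int = 12
    n_reactions: int = 12
    arc_density: float = 0.3
    fraction_start: float = 0.5
    fraction_pool: float = 0.3
    planted_path_length: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.planted_path_length < self.n_metabolites:
            raise ValueError("planted_path_length must be in [1, n_metabolites)")
        for name in ("arc_density", "fraction_start", "fraction_pool"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        # path nodes + a pool feeder + room for at least one decoy
        if self.n_metabolites < self.planted_path_length + 3:
            raise ValueError("n_metabolites too small for planted path + pool")
        if self.n_reactions < self.planted_path_length + 2:
            raise ValueError("n_reactions too small for planted path")


def generate_random_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Draw a reproducible bundle with at least one feasible pathway.

    A path of ``planted_path_length`` arcs is laid from a start metabolite
    to the target; each step may consume a side substrate, drawn from the
    pool with probability 0.7 + 0.3·fraction_pool, otherwise from the
    externals, in which case a supplying reaction from a pool metabolite is
    planted. Remaining reactions are random decoys; extra same-reaction
    pairs appear with probability ``arc_density``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_metabolites
    L = spec.planted_path_length

    mets = [f"C{i + 1:05d}" for i in range(n)]
    order = list(rng.permutation(n))
    target = mets[order[0]]
    path_nodes = [mets[i] for i in order[1 : L + 1]][::-1] + [target]
    free = [mets[i] for i in order[L + 1 :]]
    # reserve a guaranteed pool feeder (start-mass, used as side substrate
    # and as substrate of supplying reactions; never an excluded metabolite)
    feeder = free[0]
    free = free[1:]

    masses: dict[str, float | None] = {target: 400.0, feeder: 80.0}
    for m in path_nodes[:-1]:
        masses[m] = (
            float(rng.uniform(50, 295))
            if (m == path_nodes[0] or rng.random() < spec.fraction_start)
            else float(rng.uniform(305, 500))
        )
    for m in free:
        if rng.random() < spec.fraction_start:
            masses[m] = float(rng.uniform(50, 295))
        elif rng.random() < 0.1:
            masses[m] = None  # no mass data: never a start metabolite
        else:
            masses[m] = float(rng.uniform(305, 500))

    basis: list[str] = []
    if rng.random() < 0.5:
        basis.append(path_nodes[0])

    records: list[tuple[str, str, str]] = []
    pairs: list[tuple[str, str, str, str]] = []
    thermo: dict[str, float | None] = {}
    rid_counter = 0

    def next_rid() -> str:
        nonlocal rid_counter
        rid_counter += 1
        return f"R{rid_counter:05d}"

    def draw_dg(forward_must_exist: bool) -> float | None:
        if rng.random() < 0.15:
            return None
        lo, hi = (-30.0, 10.0) if forward_must_exist else (-25.0, 25.0)
        return float(np.round(rng.uniform(lo, hi), 2))

    externals = [m for m in free if masses.get(m) is not None and masses[m] > 300]
    p_pool_side = 0.7 + 0.3 * spec.fraction_pool
    supplying_needed: list[str] = []
    for a, b in zip(path_nodes[:-1], path_nodes[1:]):
        rid = next_rid()
        subs = {a: -1.0}
        prods = {b: 1.0}
        if rng.random() < 0.6:  # this step takes a side substrate
            if externals and rng.random() >= p_pool_side:
                side = externals[int(rng.integers(len(externals)))]
                if side not in supplying_needed:
                    supplying_needed.append(side)
            else:
                side = feeder
            if side not in subs and side not in prods:
                subs[side] = -1.0
        if free and rng.random() < 0.3:  # byproduct
            bp = free[int(rng.integers(len(free)))]
            if bp not in subs and bp not in prods:
                prods[bp] = 1.0
        eq = " + ".join(sorted(subs)) + " <=> " + " + ".join(sorted(prods))
        records.append((rid, eq, ""))
        pairs.append((rid, a, b, "trans" if rng.random() < 0.2 else "main"))
        thermo[rid] = draw_dg(forward_must_exist=True)

    for side in supplying_needed:
        rid = next_rid()
        records.append((rid, f"{feeder} <=> {side}", ""))
        pairs.append((rid, feeder, side, "main"))
        thermo[rid] = draw_dg(forward_must_exist=True)

    n_decoys = spec.n_reactions - len(records)
    if n_decoys < 0:
        raise ValueError(
            f"spec infeasible: planted pathway needs {len(records)} reactions, "
            f"budget is {spec.n_reactions}"
        )
    candidates = [m for m in mets if m != target]
    for _ in range(n_decoys):
        a = candidates[int(rng.integers(len(candidates)))]
        b_pool = mets if rng.random() < 0.3 else candidates
        b = b_pool[int(rng.integers(len(b_pool)))]
        if a == b:
            b = target
        if a == b:
            continue
        rid = next_rid()
        subs = {a: -1.0}
        prods = {b: 1.0}
        if rng.random() < 0.3:
            side = candidates[int(rng.integers(len(candidates)))]
            if side not in subs and side not in prods:
                subs[side] = -1.0
        eq = " + ".join(sorted(subs)) + " <=> " + " + ".join(sorted(prods))
        records.append((rid, eq, ""))
        cat = "cofac" if rng.random() < 0.15 else "main"
        pairs.append((rid, a, b, cat))
        # extra pair inside the same reaction with probability arc_density
        extra_subs = [m for m in subs if m != a]
        if extra_subs and rng.random() < spec.arc_density:
            pairs.append((rid, extra_subs[0], b, "main"))
        thermo[rid] = draw_dg(forward_must_exist=False)

    host = sorted(rid for rid, _, _ in records if rng.random() < 0.5)
    # the feeder is freely available by construction; listing it under the
    # excluded metabolites keeps it in the pool even when no planted
    # reaction gives it an arc (excluded endpoints simply lose their arcs,
    # which supplying reactions do not need)
    return FixtureBundle(
        reaction_records=records,
        pairs=pairs,
        thermo=thermo,
        masses=masses,
        basis=basis,
        cofactors=[],
        excluded=[feeder],
        generic=[],
        host=host,
        target=target,
    )


def generate_random_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Reconstructed network for a random bundle (deterministic per spec)."""
    net, _ = generate_random_bundle(spec).reconstruct()
    return net
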
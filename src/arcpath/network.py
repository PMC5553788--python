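"""Reaction-pair network reconstruction.

This module turns KEGG-style reaction records, a reaction-pair (arc) table,
thermodynamic data and curated metabolite lists into a
:class:`MetabolicNetwork` ready for path-finding:

1. parse reaction records (a minimal KEGG flat-file subset or a TSV dialect),
2. exclude unusable records (generic/incomplete comments, symbolic
   stoichiometric coefficient ``n``, glycans with ``G`` numbers),
3. split reactions into directed reactions using the transformed reaction
   Gibbs energy ΔrG'm (reversible iff |ΔrG'm| < threshold, default
   15 kJ/mol; endergonic-as-written reactions are flipped; missing data
   means irreversible in the written direction),
4. keep only admitted reaction-pair categories (main/trans by default) and
   drop arcs touching cofactors, excluded or generic metabolites,
5. categorize metabolites into start / basis / cofactor / excluded /
   external / generic sets and assemble the sparse stoichiometric matrix.

Input dialects
--------------
KEGG flat-file subset::

    ENTRY       R00200  Reaction
    COMMENT     free-text; the words 'generic' and 'incomplete' are flags
    EQUATION    C00031 + C00002 <=> C00092 + C00008
    ///

Field names start in column 0; continuation lines are indented. Only
ENTRY, COMMENT and EQUATION are interpreted. Equation terms are
``[coefficient] compound-id`` joined by `` + ``; an integer coefficient is
stoichiometry, anything else (``n``, ``2n``, ``(n+1)``...) marks the record
as symbolically parameterised.

TSV dialect: one record per line, columns ``reaction_id``, ``equation``,
``comment`` (tab-separated, ``#`` comments and blank lines ignored).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import scipy.sparse as sp

__all__ = [
    "NetworkError",
    "ParseError",
    "ReactionEntry",
    "DirectedReaction",
    "Arc",
    "MetaboliteCategories",
    "MetabolicNetwork",
    "ReconstructionLog",
    "parse_reaction_file",
    "serialize_reactions",
    "filter_reactions",
    "assign_reversibility",
    "build_arcs",
    "categorize_metabolites",
    "build_stoichiometric_matrix",
    "reconstruct_network",
    "DEFAULT_DG_THRESHOLD",
    "DEFAULT_MASS_BOUNDS",
    "DEFAULT_CATEGORIES",
    "REJECT_COMMENT",
    "REJECT_SYMBOLIC",
    "REJECT_GLYCAN",
]


class NetworkError(ValueError):
    """Inconsistent network data (bad reference, violated invariant)."""


class ParseError(NetworkError):
    """Malformed input text; the message names the offending record."""


#: comment keywords that exclude a reaction record
EXCLUDING_COMMENT_FLAGS = frozenset({"generic", "incomplete"})

REJECT_COMMENT = "comment"
REJECT_SYMBOLIC = "symbolic"
REJECT_GLYCAN = "glycan"

DEFAULT_DG_THRESHOLD = 15.0  # kJ/mol, reversible iff |dg| below this
DEFAULT_MASS_BOUNDS = (0.0, 300.0)  # Da, half-open (0, 300]
DEFAULT_CATEGORIES = frozenset({"main", "trans"})
PAIR_CATEGORIES = frozenset({"main", "trans", "cofac", "ligase", "leave"})


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionEntry:
    """One parsed reaction record, before any filtering.

    ``equation`` holds (metabolite id, signed stoichiometric coefficient)
    pairs; negative coefficients are substrates. A metabolite appears at
    most once (substrate and product sides are disjoint).
    """

    id: str
    equation: tuple[tuple[str, float], ...]
    comment_flags: frozenset[str] = frozenset()
    has_symbolic_coefficient: bool = False
    involves_glycan: bool = False

    def __post_init__(self) -> None:
        if not self.equation:
            raise NetworkError(f"reaction {self.id}: empty equation")
        seen: set[str] = set()
        for met, coef in self.equation:
            if coef == 0:
                raise NetworkError(f"reaction {self.id}: zero coefficient for {met}")
            if met in seen:
                raise NetworkError(
                    f"reaction {self.id}: metabolite {met} on both sides"
                )
            seen.add(met)

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.equation if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.equation if c > 0)


_INT_COEF_RE = re.compile(r"^\d+$")
_COMPOUND_RE = re.compile(r"^[A-Za-z]\w*$")
_WORD_RE = re.compile(r"[a-z0-9]+")


def _parse_equation(text: str, rid: str) -> tuple[tuple[tuple[str, float], ...], bool]:
    """Parse ``A + 2 B <=> C`` into signed pairs; returns (pairs, symbolic)."""
    sides = re.split(r"<=>|=>|<->|=", text)
    if len(sides) != 2:
        raise ParseError(f"reaction {rid}: equation lacks a single arrow: {text!r}")
    symbolic = False
    pairs: list[tuple[str, float]] = []
    seen: dict[str, int] = {}
    for sign, side in zip((-1.0, 1.0), sides):
        terms = [t.strip() for t in side.split(" + ")]
        for term in terms:
            if not term:
                raise ParseError(f"reaction {rid}: empty term in equation")
            tokens = term.split()
            if len(tokens) == 1:
                coef_s, met = "1", tokens[0]
            elif len(tokens) == 2:
                coef_s, met = tokens
            else:
                raise ParseError(f"reaction {rid}: cannot parse term {term!r}")
            if not _COMPOUND_RE.match(met):
                raise ParseError(f"reaction {rid}: bad compound id {met!r}")
            if _INT_COEF_RE.match(coef_s):
                coef = float(coef_s)
            else:
                symbolic = True  # 'n', '2n', '(n+1)' ... keep coefficient 1
                coef = 1.0
            if met in seen:
                raise ParseError(
                    f"reaction {rid}: metabolite {met} appears twice in equation"
                )
            seen[met] = 1
            pairs.append((met, sign * coef))
    return tuple(pairs), symbolic


def _entry_from_fields(rid: str, equation: str, comment: str) -> ReactionEntry:
    pairs, symbolic = _parse_equation(equation, rid)
    flags = frozenset(_WORD_RE.findall(comment.lower()))
    glycan = any(m.startswith("G") for m, _ in pairs)
    return ReactionEntry(
        id=rid,
        equation=pairs,
        comment_flags=flags,
        has_symbolic_coefficient=symbolic,
        involves_glycan=glycan,
    )


def _parse_kegg(text: str) -> list[ReactionEntry]:
    entries: list[ReactionEntry] = []
    for block in text.split("///"):
        if not block.strip():
            continue
        fields: dict[str, list[str]] = {}
        current: str | None = None
        for line in block.splitlines():
            if not line.strip():
                continue
            if line[:1].isspace():
                if current is None:
                    raise ParseError(f"continuation line before any field: {line!r}")
                fields[current].append(line.strip())
            else:
                parts = line.split(None, 1)
                current = parts[0]
                fields.setdefault(current, []).append(
                    parts[1].strip() if len(parts) > 1 else ""
                )
        if "ENTRY" not in fields:
            raise ParseError("record without ENTRY field")
        rid = fields["ENTRY"][0].split()[0]
        if "EQUATION" not in fields:
            raise ParseError(f"reaction {rid}: missing EQUATION")
        equation = " ".join(fields["EQUATION"])
        comment = " ".join(fields.get("COMMENT", []))
        entries.append(_entry_from_fields(rid, equation, comment))
    return entries


def _parse_tsv(text: str) -> list[ReactionEntry]:
    entries: list[ReactionEntry] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ParseError(f"line {lineno}: need reaction_id<TAB>equation")
        rid = cols[0].strip()
        comment = cols[2] if len(cols) > 2 else ""
        entries.append(_entry_from_fields(rid, cols[1].strip(), comment))
    return entries


def parse_reaction_file(text: str, dialect: str = "auto") -> list[ReactionEntry]:
    """Parse reaction records from KEGG-flat-file or TSV text.

    ``dialect`` is ``"kegg"``, ``"tsv"`` or ``"auto"`` (KEGG iff an ENTRY
    field is present at the start of a line).
    """
    if dialect == "auto":
        dialect = "kegg" if re.search(r"^ENTRY\b", text, re.M) else "tsv"
    if dialect == "kegg":
        return _parse_kegg(text)
    if dialect == "tsv":
        return _parse_tsv(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_equation(entry: ReactionEntry, symbolic_first: bool = False) -> str:
    first_met = entry.equation[0][0] if symbolic_first else None

    def side(pairs: Iterable[tuple[str, float]]) -> str:
        terms = []
        for met, coef in pairs:
            c = abs(coef)
            if met == first_met:
                terms.append(f"n {met}")
            else:
                terms.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(terms)

    subs = [(m, c) for m, c in entry.equation if c < 0]
    prods = [(m, c) for m, c in entry.equation if c > 0]
    return f"{side(subs)} <=> {side(prods)}"


def serialize_reactions(entries: Sequence[ReactionEntry], dialect: str = "kegg") -> str:
    """Inverse of :func:`parse_reaction_file` (round-trips parsed fields).

    Symbolic coefficients are written back as ``n`` so the flag survives a
    round trip; the numeric placeholder value is not recoverable by design.
    """
    out: list[str] = []
    for e in entries:
        eq = _format_equation(e, symbolic_first=e.has_symbolic_coefficient)
        if dialect == "kegg":
            out.append(f"ENTRY       {e.id}  Reaction")
            if e.comment_flags:
                out.append(f"COMMENT     {' '.join(sorted(e.comment_flags))}")
            out.append(f"EQUATION    {eq}")
            out.append("///")
        elif dialect == "tsv":
            out.append("\t".join([e.id, eq, " ".join(sorted(e.comment_flags))]))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_reactions(
    entries: Sequence[ReactionEntry],
) -> tuple[list[ReactionEntry], list[tuple[ReactionEntry, str]]]:
    """Split records into kept and rejected (with a single reason code each).

    A record is rejected iff it carries a 'generic' or 'incomplete' comment
    flag, has a symbolic stoichiometric coefficient, or involves a glycan.
    Reason precedence: comment > symbolic > glycan.
    """
    kept: list[ReactionEntry] = []
    rejected: list[tuple[ReactionEntry, str]] = []
    for e in entries:
        if e.comment_flags & EXCLUDING_COMMENT_FLAGS:
            rejected.append((e, REJECT_COMMENT))
        elif e.has_symbolic_coefficient:
            rejected.append((e, REJECT_SYMBOLIC))
        elif e.involves_glycan:
            rejected.append((e, REJECT_GLYCAN))
        else:
            kept.append(e)
    return kept, rejected


# ---------------------------------------------------------------------------
# Directed reactions and reversibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectedReaction:
    """A single-direction reaction in the final network.

    ``flipped`` is True when the equation runs opposite to the source
    record (either the backward copy of a reversible reaction, or an
    endergonic-as-written reaction rewritten in its exergonic direction).
    ``reverse_of`` links the two members of a reversible pair.
    """

    id: str
    source_id: str
    coeffs: tuple[tuple[str, float], ...]
    dg: float | None = None
    flipped: bool = False
    reverse_of: str | None = None

    @property
    def coeff_map(self) -> dict[str, float]:
        return dict(self.coeffs)


REVERSE_SUFFIX = "_rev"


def assign_reversibility(
    entry: ReactionEntry,
    dg: float | None,
    threshold: float = DEFAULT_DG_THRESHOLD,
) -> list[DirectedReaction]:
    """Split a record into directed reactions based on ΔrG'm (kJ/mol).

    * dg absent      → one forward reaction (irreversible as written)
    * |dg| < threshold → a reversible pair (forward dg, backward −dg)
    * dg ≤ −threshold → forward only
    * dg ≥ +threshold → backward only (equation flipped, dg negated)
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if dg is not None and not math.isfinite(dg):
        raise NetworkError(f"reaction {entry.id}: non-finite ΔrG {dg!r}")
    fwd = entry.equation
    bwd = tuple((m, -c) for m, c in entry.equation)
    rid, rev_id = entry.id, entry.id + REVERSE_SUFFIX
    if dg is None or dg <= -threshold:
        return [DirectedReaction(rid, entry.id, fwd, dg=dg)]
    if dg >= threshold:
        return [DirectedReaction(rev_id, entry.id, bwd, dg=-dg, flipped=True)]
    return [
        DirectedReaction(rid, entry.id, fwd, dg=dg, reverse_of=rev_id),
        DirectedReaction(rev_id, entry.id, bwd, dg=-dg, flipped=True, reverse_of=rid),
    ]


# ---------------------------------------------------------------------------
# Metabolite categories (the Venn-diagram sets)
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteCategories:
    """Partition of metabolites into the path-finding roles.

    ``pool`` (freely available from the start) is the union of start,
    basis, cofactor and excluded metabolites; everything else is external
    and may only be net-produced. Generic metabolites are a flavour of
    external whose arcs were removed from the network.
    """

    metabolites: frozenset[str]
    start: frozenset[str]
    basis: frozenset[str]
    cofactors: frozenset[str]
    excluded: frozenset[str]
    generic: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.basis <= self.start:
            missing = sorted(self.basis - self.start)
            raise NetworkError(f"basis metabolites not in start set: {missing}")
        for name in ("start", "basis", "cofactors", "excluded", "generic"):
            extra = getattr(self, name) - self.metabolites
            if extra:
                raise NetworkError(
                    f"{name} list references unknown metabolites: {sorted(extra)}"
                )

    @property
    def pool(self) -> frozenset[str]:
        return self.start | self.basis | self.cofactors | self.excluded

    @property
    def external(self) -> frozenset[str]:
        return self.metabolites - self.pool


def categorize_metabolites(
    metabolites: Iterable[str],
    arcs: Iterable["Arc"],
    masses: Mapping[str, float | None],
    basis_list: Iterable[str] = (),
    cofactor_list: Iterable[str] = (),
    excluded_list: Iterable[str] = (),
    generic_list: Iterable[str] = (),
    mass_bounds: tuple[float, float] = DEFAULT_MASS_BOUNDS,
) -> MetaboliteCategories:
    """Derive the metabolite category sets.

    Start metabolites are every metabolite that occurs in at least one arc
    and has a molecular mass in the half-open interval
    ``(mass_bounds[0], mass_bounds[1]]``, plus the curated basis list.
    Metabolites without mass data never qualify by mass.
    """
    mets = frozenset(metabolites)
    basis = frozenset(basis_list)
    if not basis <= mets:
        raise NetworkError(
            f"basis metabolites absent from network: {sorted(basis - mets)}"
        )
    lo, hi = mass_bounds
    in_arc = {a.substrate for a in arcs} | {a.product for a in arcs}
    by_mass = {
        m
        for m in in_arc
        if masses.get(m) is not None and lo < float(masses[m]) <= hi  # type: ignore[arg-type]
    }
    return MetaboliteCategories(
        metabolites=mets,
        start=frozenset(by_mass) | basis,
        basis=basis,
        cofactors=frozenset(cofactor_list) & mets,
        excluded=frozenset(excluded_list) & mets,
        generic=frozenset(generic_list) & mets,
    )


# ---------------------------------------------------------------------------
# Arcs
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Arc:
    """Directed substrate→product edge realized by one directed reaction."""

    substrate: str
    product: str
    reaction: str  # directed-reaction id
    category: str  # main/trans/cofac/ligase/leave

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise NetworkError(f"self-arc on {self.substrate} ({self.reaction})")


def build_arcs(
    pair_rows: Iterable[tuple[str, str, str, str]],
    reactions: Sequence[DirectedReaction],
    categories: MetaboliteCategories | None = None,
    admitted_categories: Iterable[str] = DEFAULT_CATEGORIES,
    *,
    cofactors: Iterable[str] = (),
    excluded: Iterable[str] = (),
    generic: Iterable[str] = (),
) -> frozenset[Arc]:
    """Build the arc set from a reaction-pair table.

    ``pair_rows`` are (source reaction id, substrate, product, category)
    tuples. Pairs are admitted iff their category is in
    ``admitted_categories`` and neither endpoint is a cofactor, excluded or
    generic metabolite. Each pair is attached to every directed reaction
    derived from its source record; on flipped/backward copies the arc is
    reversed. One arc is kept per (substrate, product, reaction) triple.

    Endpoint-exclusion sets may be passed either via ``categories`` (only
    its cofactor/excluded/generic fields are used — the start set may not
    exist yet at this stage) or via the keyword sets.
    """
    admitted = frozenset(admitted_categories)
    unknown_cat = admitted - PAIR_CATEGORIES
    if unknown_cat:
        raise ValueError(f"unknown pair categories: {sorted(unknown_cat)}")
    if categories is not None:
        cofactors = categories.cofactors
        excluded = categories.excluded
        generic = categories.generic
    banned = frozenset(cofactors) | frozenset(excluded) | frozenset(generic)

    by_source: dict[str, list[DirectedReaction]] = {}
    for r in reactions:
        by_source.setdefault(r.source_id, []).append(r)

    arcs: set[Arc] = set()
    for rid, sub, prod, cat in pair_rows:
        if cat not in PAIR_CATEGORIES:
            raise NetworkError(f"pair on {rid}: unknown category {cat!r}")
        if rid not in by_source:
            raise NetworkError(f"pair references unknown/filtered reaction {rid}")
        if cat not in admitted:
            continue
        if sub in banned or prod in banned:
            continue
        for dr in by_source[rid]:
            s, p = (prod, sub) if dr.flipped else (sub, prod)
            cm = dr.coeff_map
            if cm.get(s, 0) >= 0 or cm.get(p, 0) <= 0:
                raise NetworkError(
                    f"pair ({sub},{prod}) inconsistent with equation of {dr.id}"
                )
            arcs.add(Arc(s, p, dr.id, cat))
    return frozenset(arcs)


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicNetwork:
    """Directed-reaction network with arcs, categories and stoichiometry."""

    metabolites: tuple[str, ...]
    reactions: tuple[DirectedReaction, ...]
    arcs: frozenset[Arc]
    categories: MetaboliteCategories
    _met_index: dict[str, int] = field(init=False, repr=False)
    _rxn_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        for a in self.arcs:
            r = self.reaction(a.reaction)
            cm = r.coeff_map
            if cm.get(a.substrate, 0) >= 0 or cm.get(a.product, 0) <= 0:
                raise NetworkError(f"arc {a} inconsistent with reaction equation")

    # -- lookups ------------------------------------------------------------

    def metabolite_index(self, m: str) -> int:
        return self._met_index[m]

    def reaction(self, rid: str) -> DirectedReaction:
        return self.reactions[self._rxn_index[rid]]

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def delta_g(self) -> dict[str, float | None]:
        return {r.id: r.dg for r in self.reactions}

    def reverse_pairs(self) -> list[tuple[str, str]]:
        """Reverse-pair reaction ids (λ, μ), each unordered pair once."""
        pairs = []
        for r in self.reactions:
            if r.reverse_of is not None and r.id < r.reverse_of:
                if r.reverse_of in self._rxn_index:
                    pairs.append((r.id, r.reverse_of))
        return pairs

    def arc_reactions(self) -> dict[tuple[str, str], frozenset[str]]:
        """d_ijr support: endpoint pair (i, j) → directed reactions with an arc."""
        d: dict[tuple[str, str], set[str]] = {}
        for a in self.arcs:
            d.setdefault((a.substrate, a.product), set()).add(a.reaction)
        return {k: frozenset(v) for k, v in d.items()}

    def stoichiometric_matrix(self) -> sp.csc_matrix:
        return build_stoichiometric_matrix(self)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        """Canonical JSON interchange form (sorted keys, stable order)."""
        doc = {
            "metabolites": list(self.metabolites),
            "reactions": [
                {
                    "id": r.id,
                    "source_id": r.source_id,
                    "coeffs": {m: c for m, c in r.coeffs},
                    "dg": r.dg,
                    "flipped": r.flipped,
                    "reverse_of": r.reverse_of,
                }
                for r in self.reactions
            ],
            "arcs": [
                {
                    "substrate": a.substrate,
                    "product": a.product,
                    "reaction": a.reaction,
                    "category": a.category,
                }
                for a in sorted(self.arcs)
            ],
            "categories": {
                "start": sorted(self.categories.start),
                "basis": sorted(self.categories.basis),
                "cofactors": sorted(self.categories.cofactors),
                "excluded": sorted(self.categories.excluded),
                "generic": sorted(self.categories.generic),
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicNetwork":
        doc = json.loads(text)
        reactions = tuple(
            DirectedReaction(
                id=r["id"],
                source_id=r["source_id"],
                coeffs=tuple(sorted(r["coeffs"].items())),
                dg=r["dg"],
                flipped=r["flipped"],
                reverse_of=r["reverse_of"],
            )
            for r in doc["reactions"]
        )
        arcs = frozenset(
            Arc(a["substrate"], a["product"], a["reaction"], a["category"])
            for a in doc["arcs"]
        )
        mets = tuple(doc["metabolites"])
        cats = MetaboliteCategories(
            metabolites=frozenset(mets),
            start=frozenset(doc["categories"]["start"]),
            basis=frozenset(doc["categories"]["basis"]),
            cofactors=frozenset(doc["categories"]["cofactors"]),
            excluded=frozenset(doc["categories"]["excluded"]),
            generic=frozenset(doc["categories"]["generic"]),
        )
        return cls(mets, reactions, arcs, cats)


def build_stoichiometric_matrix(network: MetabolicNetwork) -> sp.csc_matrix:
    """Sparse |M|×|R| matrix; column r reproduces reaction r's equation."""
    rows, cols, data = [], [], []
    for j, r in enumerate(network.reactions):
        for m, c in r.coeffs:
            rows.append(network.metabolite_index(m))
            cols.append(j)
            data.append(c)
    return sp.csc_matrix(
        (data, (rows, cols)),
        shape=(len(network.metabolites), len(network.reactions)),
    )


# ---------------------------------------------------------------------------
# End-to-end reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionLog:
    n_input: int = 0
    n_kept: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    rejected_ids: list[tuple[str, str]] = field(default_factory=list)
    n_directed_reactions: int = 0
    n_reverse_pairs: int = 0
    n_arcs: int = 0
    category_sizes: dict[str, int] = field(default_factory=dict)

    def lines(self) -> list[str]:
        out = [
            f"input records: {self.n_input}",
            f"kept: {self.n_kept}",
        ]
        for reason in (REJECT_COMMENT, REJECT_SYMBOLIC, REJECT_GLYCAN):
            out.append(
                f"rejected ({reason}): {self.rejected_by_reason.get(reason, 0)}"
            )
        out += [
            f"directed reactions: {self.n_directed_reactions}"
            f" ({self.n_reverse_pairs} reversible pairs)",
            f"arcs: {self.n_arcs}",
        ]
        for k, v in sorted(self.category_sizes.items()):
            out.append(f"metabolites ({k}): {v}")
        return out


def reconstruct_network(
    reaction_text: str,
    pair_rows: Iterable[tuple[str, str, str, str]],
    thermo: Mapping[str, float | None],
    masses: Mapping[str, float | None],
    basis_list: Iterable[str] = (),
    cofactor_list: Iterable[str] = (),
    excluded_list: Iterable[str] = (),
    generic_list: Iterable[str] = (),
    dg_threshold: float = DEFAULT_DG_THRESHOLD,
    mass_bounds: tuple[float, float] = DEFAULT_MASS_BOUNDS,
    admitted_categories: Iterable[str] = DEFAULT_CATEGORIES,
    dialect: str = "auto",
) -> tuple[MetabolicNetwork, ReconstructionLog]:
    """Run the full reconstruction: parse → filter → split → arcs → categorize."""
    log = ReconstructionLog()
    entries = parse_reaction_file(reaction_text, dialect=dialect)
    log.n_input = len(entries)
    kept, rejected = filter_reactions(entries)
    log.n_kept = len(kept)
    for e, reason in rejected:
        log.rejected_by_reason[reason] = log.rejected_by_reason.get(reason, 0) + 1
        log.rejected_ids.append((e.id, reason))

    reactions: list[DirectedReaction] = []
    for e in kept:
        reactions.extend(assign_reversibility(e, thermo.get(e.id), dg_threshold))
    log.n_directed_reactions = len(reactions)
    log.n_reverse_pairs = sum(1 for r in reactions if r.reverse_of and not r.flipped)

    # pairs referencing filtered-out reactions are dropped silently; pairs
    # referencing reactions never seen at all are an error
    kept_sources = {e.id for e in kept}
    seen_sources = {e.id for e in entries}
    pairs_final = []
    for row in pair_rows:
        if row[0] not in seen_sources:
            raise NetworkError(f"pair references unknown reaction {row[0]}")
        if row[0] in kept_sources:
            pairs_final.append(row)

    metabolites = tuple(sorted({m for r in reactions for m, _ in r.coeffs}))
    arcs = build_arcs(
        pairs_final,
        reactions,
        admitted_categories=admitted_categories,
        cofactors=cofactor_list,
        excluded=excluded_list,
        generic=generic_list,
    )
    log.n_arcs = len(arcs)
    cats = categorize_metabolites(
        metabolites,
        arcs,
        masses,
        basis_list=frozenset(basis_list) & set(metabolites),
        cofactor_list=cofactor_list,
        excluded_list=excluded_list,
        generic_list=generic_list,
        mass_bounds=mass_bounds,
    )
    missing_basis = frozenset(basis_list) - set(metabolites)
    if missing_basis:
        raise NetworkError(
            f"basis metabolites absent from network: {sorted(missing_basis)}"
        )
    net = MetabolicNetwork(metabolites, tuple(reactions), arcs, cats)
    log.category_sizes = {
        "all": len(metabolites),
        "start": len(cats.start),
        "basis": len(cats.basis),
        "cofactors": len(cats.cofactors),
        "excluded": len(cats.excluded),
        "generic": len(cats.generic),
        "external": len(cats.external),
        "pool": len(cats.pool),
    }
    return net, log
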
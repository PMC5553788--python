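"""Reconstruction: parsing, filters, reversibility, arcs, categories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcpath.network import (
    Arc,
    MetabolicNetwork,
    NetworkError,
    ParseError,
    ReactionEntry,
    assign_reversibility,
    build_arcs,
    build_stoichiometric_matrix,
    categorize_metabolites,
    filter_reactions,
    parse_reaction_file,
    reconstruct_network,
    serialize_reactions,
)

KEGG_TEXT = """\
ENTRY       R00200  Reaction
EQUATION    C00031 + C00002 <=> C00092 + C00008
///
ENTRY       R00300  Reaction
COMMENT     a generic reaction
EQUATION    C00031 <=> C00092
///
ENTRY       R00400  Reaction
EQUATION    n C00031 <=> n C00092
///
ENTRY       R00500  Reaction
EQUATION    C00031 <=> G00001
///
"""


class TestParsing:
    def test_equation_signs(self):
        entries = parse_reaction_file(KEGG_TEXT)
        e = entries[0]
        assert e.id == "R00200"
        assert dict(e.equation) == {
            "C00031": -1.0, "C00002": -1.0, "C00092": 1.0, "C00008": 1.0,
        }

    def test_comment_symbolic_glycan_flags(self):
        entries = {e.id: e for e in parse_reaction_file(KEGG_TEXT)}
        assert "generic" in entries["R00300"].comment_flags
        assert entries["R00400"].has_symbolic_coefficient
        assert entries["R00500"].involves_glycan

    def test_integer_coefficients(self):
        (e,) = parse_reaction_file("R1\t2 A + B <=> 3 C", dialect="tsv")
        assert dict(e.equation) == {"A": -2.0, "B": -1.0, "C": 3.0}

    @pytest.mark.parametrize(
        "bad",
        ["R1\tA + B", "R1\tA <=> B <=> C", "R1\tA <=> ", "R1\tA <=> A"],
    )
    def test_malformed_equation_names_record(self, bad):
        with pytest.raises(ParseError, match="R1"):
            parse_reaction_file(bad, dialect="tsv")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C00001", "C00002", "C00003", "C00004", "C00005"]),
                st.integers(min_value=1, max_value=4),
            ),
            min_size=2,
            max_size=5,
            unique_by=lambda t: t[0],
        ),
        st.booleans(),
        st.sets(st.sampled_from(["generic", "incomplete", "note"])),
    )
    @settings(deadline=None, max_examples=50)
    def test_parse_serialize_round_trip(self, mets, symbolic, flags):
        half = max(1, len(mets) // 2)
        eq = tuple(
            (m, float(-c) if i < half else float(c))
            for i, (m, c) in enumerate(mets)
        )
        if not any(c > 0 for _, c in eq):
            eq = eq[:-1] + ((eq[-1][0], abs(eq[-1][1])),)
        if symbolic:
            # the parser stores placeholder 1 for a symbolic coefficient,
            # so only such entries are reachable round-trip states
            m0, c0 = eq[0]
            eq = ((m0, -1.0 if c0 < 0 else 1.0),) + eq[1:]
        entry = ReactionEntry(
            id="R99999",
            equation=eq,
            comment_flags=frozenset(flags),
            has_symbolic_coefficient=symbolic,
            involves_glycan=False,
        )
        for dialect in ("kegg", "tsv"):
            (back,) = parse_reaction_file(
                serialize_reactions([entry], dialect), dialect=dialect
            )
            assert back.id == entry.id
            assert dict(back.equation) == dict(entry.equation)
            assert back.comment_flags == entry.comment_flags
            assert back.has_symbolic_coefficient == entry.has_symbolic_coefficient


class TestFiltering:
    def test_each_rule_and_completeness(self):
        entries = parse_reaction_file(KEGG_TEXT)
        kept, rejected = filter_reactions(entries)
        assert [e.id for e in kept] == ["R00200"]
        assert {(e.id, r) for e, r in rejected} == {
            ("R00300", "comment"), ("R00400", "symbolic"), ("R00500", "glycan"),
        }
        assert len(kept) + len(rejected) == len(entries)

    def test_reason_precedence_single_code(self):
        (e,) = parse_reaction_file("R1\tn C1 <=> G0002\tincomplete", dialect="tsv")
        _, rejected = filter_reactions([e])
        assert rejected == [(e, "comment")]
        (e2,) = parse_reaction_file("R1\tn C1 <=> G0002", dialect="tsv")
        _, rejected = filter_reactions([e2])
        assert rejected == [(e2, "symbolic")]


class TestReversibility:
    def entry(self):
        (e,) = parse_reaction_file("R1\tA <=> B", dialect="tsv")
        return e

    def test_strongly_exergonic_is_forward_only(self):
        (r,) = assign_reversibility(self.entry(), -20.0)
        assert not r.flipped and dict(r.coeffs) == {"A": -1.0, "B": 1.0}
        assert r.reverse_of is None

    def test_near_equilibrium_gives_reverse_pair(self):
        fwd, bwd = assign_reversibility(self.entry(), 5.0)
        assert fwd.reverse_of == bwd.id and bwd.reverse_of == fwd.id
        assert dict(bwd.coeffs) == {"A": 1.0, "B": -1.0}
        assert bwd.dg == -5.0 and fwd.dg == 5.0

    def test_missing_dg_is_irreversible_forward(self):
        (r,) = assign_reversibility(self.entry(), None)
        assert not r.flipped and r.dg is None and r.reverse_of is None

    def test_strongly_endergonic_is_flipped(self):
        (r,) = assign_reversibility(self.entry(), 20.0)
        assert r.flipped and r.dg == -20.0
        assert dict(r.coeffs) == {"A": 1.0, "B": -1.0}

    def test_nonfinite_dg_rejected(self):
        with pytest.raises(NetworkError):
            assign_reversibility(self.entry(), float("nan"))

    def test_reverse_pair_antisymmetry_threshold_boundary(self):
        # |dg| exactly at the threshold is irreversible
        (r,) = assign_reversibility(self.entry(), -15.0)
        assert r.reverse_of is None
        pair = assign_reversibility(self.entry(), -14.999)
        assert len(pair) == 2


class TestArcs:
    def reactions(self):
        (e,) = parse_reaction_file("R1\tA + X <=> B", dialect="tsv")
        return assign_reversibility(e, 5.0)  # reversible pair

    def test_main_pair_kept_and_mirrored_on_reverse(self):
        arcs = build_arcs([("R1", "A", "B", "main")], self.reactions())
        assert {(a.substrate, a.product, a.reaction) for a in arcs} == {
            ("A", "B", "R1"), ("B", "A", "R1_rev"),
        }

    def test_non_admitted_category_dropped(self):
        arcs = build_arcs([("R1", "X", "B", "cofac")], self.reactions())
        assert arcs == frozenset()

    def test_cofactor_endpoint_dropped(self):
        arcs = build_arcs(
            [("R1", "A", "B", "main")], self.reactions(), cofactors={"A"}
        )
        assert arcs == frozenset()

    def test_unknown_reaction_is_error(self):
        with pytest.raises(NetworkError, match="R9"):
            build_arcs([("R9", "A", "B", "main")], self.reactions())

    def test_pair_inconsistent_with_equation_is_error(self):
        with pytest.raises(NetworkError):
            build_arcs([("R1", "B", "A", "main")], self.reactions()[:1])


class TestCategories:
    def arcs(self):
        return [Arc("A", "B", "R1", "main"), Arc("B", "P", "R2", "main")]

    def test_mass_window_and_basis_union(self):
        cats = categorize_metabolites(
            ["A", "B", "P", "Z"],
            self.arcs(),
            {"A": 180.06, "B": 342.3, "P": 400.0, "Z": 50.0},
            basis_list=["A"],
        )
        assert cats.start == {"A"}  # B too heavy, Z not in any arc
        assert "Z" in cats.external and "B" in cats.external

    def test_heavy_metabolite_becomes_start_via_basis(self):
        cats = categorize_metabolites(
            ["A", "B", "P"],
            self.arcs(),
            {"A": 180.0, "B": 342.3, "P": 400.0},
            basis_list=["B"],
        )
        assert "B" in cats.start and "B" in cats.basis

    def test_missing_mass_never_start(self):
        cats = categorize_metabolites(
            ["A", "B", "P"], self.arcs(), {"A": None, "B": 100.0, "P": 400.0}
        )
        assert cats.start == {"B"}

    def test_mass_bounds_half_open(self):
        cats = categorize_metabolites(
            ["A", "B", "P"], self.arcs(), {"A": 0.0, "B": 300.0, "P": 301.0}
        )
        assert cats.start == {"B"}

    def test_absent_basis_is_error(self):
        with pytest.raises(NetworkError, match="Q"):
            categorize_metabolites(["A"], [], {"A": 10.0}, basis_list=["Q"])

    def test_partition_covers_all(self):
        cats = categorize_metabolites(
            ["A", "B", "P", "Z"],
            self.arcs(),
            {"A": 100.0, "B": 100.0, "P": 400.0, "Z": None},
            cofactor_list=["Z"],
        )
        assert cats.pool | cats.external == cats.metabolites
        assert not cats.pool & cats.external


class TestStoichiometryAndSerialization:
    def test_matrix_columns_match_equations(self, fig3_network):
        S = build_stoichiometric_matrix(fig3_network)
        assert S.shape == (
            len(fig3_network.metabolites), len(fig3_network.reactions)
        )
        for j, r in enumerate(fig3_network.reactions):
            col = S.getcol(j).toarray().ravel()
            expect = np.zeros(len(fig3_network.metabolites))
            for m, c in r.coeffs:
                expect[fig3_network.metabolite_index(m)] = c
            assert np.array_equal(col, expect)

    def test_reverse_pair_columns_negate(self, fig3_network):
        S = build_stoichiometric_matrix(fig3_network).toarray()
        for lam, mu in fig3_network.reverse_pairs():
            jl = fig3_network.reaction_index(lam)
            jm = fig3_network.reaction_index(mu)
            assert np.array_equal(S[:, jl], -S[:, jm])

    def test_scaled_coefficient(self):
        net, _ = reconstruct_network(
            "R1\t2 A <=> B", [("R1", "A", "B", "main")], {"R1": -20.0},
            {"A": 100.0, "B": 100.0},
        )
        S = net.stoichiometric_matrix().toarray()
        assert S[net.metabolite_index("A"), 0] == -2.0

    def test_arc_soundness_invariant(self, fig3_network):
        for a in fig3_network.arcs:
            cm = fig3_network.reaction(a.reaction).coeff_map
            assert cm[a.substrate] < 0 < cm[a.product]

    def test_json_round_trip(self, fig3_network):
        text = fig3_network.to_json()
        back = MetabolicNetwork.from_json(text)
        assert back.to_json() == text
        assert back.arcs == fig3_network.arcs
        assert back.categories.pool == fig3_network.categories.pool
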
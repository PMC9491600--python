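"""Unit tests for the core data model: parsing, splitting, matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdas import (NetworkError, PartitionError, Reaction, ReactionNetwork,
                  ReactionParseError, SdasError, Species, build_matrix,
                  format_equation, merge_split_pair, parse_reaction,
                  split_reversible, toy, validate_mass_balance)


class TestParseReaction:
    @pytest.mark.parametrize("text,reactants,products,reversible", [
        ("A + F -> 2 A", {"A": 1, "F": 1}, {"A": 2}, False),
        ("B + C <=> A", {"B": 1, "C": 1}, {"A": 1}, True),
        ("2 A2 + F2 -> A1", {"A2": 2, "F2": 1}, {"A1": 1}, False),
        ("NAD+ + H2S <=> NADH + H+ + S",
         {"NAD+": 1, "H2S": 1}, {"NADH": 1, "H+": 1, "S": 1}, True),
        ("0.5 O2 + H2 -> H2O", {"O2": 0.5, "H2": 1}, {"H2O": 1}, False),
    ])
    def test_grammar(self, text, reactants, products, reversible):
        r = parse_reaction(text)
        assert dict(r.reactants) == pytest.approx(reactants)
        assert dict(r.products) == pytest.approx(products)
        assert r.reversible is reversible

    def test_catalyst_annotation(self):
        r = parse_reaction("F -> A | cat: U, V")
        assert r.catalysts == {"U", "V"}
        assert dict(r.reactants) == {"F": 1}

    def test_catalyst_written_on_both_sides_is_normalised(self):
        # explicit catalysis written stoichiometrically
        r = parse_reaction("F + U -> A + U")
        assert r.catalysts == {"U"}
        assert "U" not in r.reactants and "U" not in r.products

    def test_unequal_both_sides_is_not_catalysis(self):
        r = parse_reaction("A + F -> 2 A")
        assert r.catalysts == frozenset()
        assert r.reactants["A"] == 1 and r.products["A"] == 2

    @pytest.mark.parametrize("bad", [
        "A + B",                 # no arrow
        "A -> B -> C",           # two arrows
        "A <=> B -> C",          # mixed arrows
        " -> B",                 # empty side
        "A -> ",
        "-1 A -> B",             # non-positive coefficient
        "0 A -> B",
        "A -> B | kat: U",       # malformed catalyst tag
    ])
    def test_malformed(self, bad):
        with pytest.raises(ReactionParseError):
            parse_reaction(bad)

    def test_identity_reaction_rejected(self):
        # A -> A has no net transformation; rejected by validation
        with pytest.raises(SdasError):
            parse_reaction("A -> A")

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(
        st.tuples(st.sampled_from(["Aa", "B2", "C+", "H2O", "NADH"]),
                  st.integers(1, 9)),
        min_size=1, max_size=3, unique_by=lambda t: t[0]),
        st.lists(
        st.tuples(st.sampled_from(["X", "Y2", "Z-p", "CO2"]),
                  st.integers(1, 9)),
        min_size=1, max_size=3, unique_by=lambda t: t[0]),
        st.booleans())
    def test_format_parse_roundtrip(self, lhs, rhs, reversible):
        r = Reaction(id="R", reactants=dict(lhs), products=dict(rhs),
                     reversible=reversible)
        r2 = parse_reaction(format_equation(r), id="R")
        assert dict(r2.reactants) == dict(r.reactants)
        assert dict(r2.products) == dict(r.products)
        assert r2.reversible is r.reversible


class TestSplitReversible:
    def test_split(self):
        r = parse_reaction("B + C <=> A", id="R06974")
        fwd, rev = split_reversible(r)
        assert fwd.id == "R06974.a" and rev.id == "R06974.b"
        assert dict(fwd.reactants) == {"B": 1, "C": 1}
        assert dict(rev.reactants) == {"A": 1}
        assert dict(rev.products) == {"B": 1, "C": 1}
        assert not fwd.reversible and not rev.reversible

    def test_catalysts_preserved_on_both_directions(self):
        r = parse_reaction("A <=> B | cat: U", id="R1")
        fwd, rev = split_reversible(r)
        assert fwd.catalysts == rev.catalysts == {"U"}

    def test_split_irreversible_is_contract_violation(self):
        with pytest.raises(NetworkError):
            split_reversible(parse_reaction("A -> B", id="R1"))

    def test_split_then_merge_is_identity(self):
        r = parse_reaction("2 B + C <=> A + D | cat: U", id="R9")
        merged = merge_split_pair(*split_reversible(r))
        assert dict(merged.reactants) == dict(r.reactants)
        assert dict(merged.products) == dict(r.products)
        assert merged.catalysts == r.catalysts
        assert merged.reversible


class TestReactionInvariants:
    def test_positive_coefficients_enforced(self):
        with pytest.raises(NetworkError):
            Reaction(id="R", reactants={"A": 0.0}, products={"B": 1.0})

    def test_catalyst_clash_with_reactant(self):
        with pytest.raises(NetworkError):
            Reaction(id="R", reactants={"A": 1.0, "U": 1.0},
                     products={"B": 1.0}, catalysts=frozenset({"U"}))

    def test_duplicate_reaction_id(self):
        net = ReactionNetwork([parse_reaction("A -> B", id="R1")])
        with pytest.raises(NetworkError):
            net.add_reaction(parse_reaction("B -> A", id="R1"))

    def test_network_species_closure(self):
        net = ReactionNetwork([parse_reaction("F -> A | cat: U", id="R1")])
        assert net.species_ids == {"F", "A", "U"}


class TestBuildMatrix:
    def test_simple_autocat_matrix(self):
        # net {A + F -> 2A}, external {F}: 2x1 with s(F)=-1, s(A)=+1
        net = ReactionNetwork([parse_reaction("A + F -> 2 A", id="R1")])
        M = build_matrix(net, external_species={"F"}, external_reactions=set())
        assert M.row_ids == ["F", "A"] and M.col_ids == ["R1"]
        assert M.p == 2 and M.q == 1
        assert M.entries[M.row_ids.index("F"), 0] == -1
        assert M.entries[M.row_ids.index("A"), 0] == 1

    def test_tier0_partition_has_empty_internal_block(self):
        f = toy("fig1_like")
        sub = f.network.subnetwork({"R0"})
        M = build_matrix(sub, external_species={"F0", "F1", "F2"},
                         external_reactions={"R0"})
        assert M.internal_block.size == 0
        assert M.internal_species == [] and M.internal_reactions == []

    def test_catalyzed_column_zero_entry_but_requirement_recorded(self):
        net = ReactionNetwork([parse_reaction("F -> A | cat: U", id="R1")])
        M = build_matrix(net, external_species={"F"}, external_reactions=set())
        assert M.entries[M.row_ids.index("U"), 0] == 0
        assert M.catalyst_requirements["R1"] == {"U"}

    def test_column_equals_products_minus_reactants(self):
        net = ReactionNetwork([parse_reaction("2 A + F -> A + 3 B", id="R1")])
        M = build_matrix(net, external_species={"F"}, external_reactions=set())
        col = {s: M.entries[i, 0] for i, s in enumerate(M.row_ids)}
        assert col == {"F": -1, "A": -1, "B": 3}

    def test_external_reaction_touching_internal_species_rejected(self):
        net = ReactionNetwork([parse_reaction("F -> A", id="R1")])
        with pytest.raises(PartitionError):
            build_matrix(net, external_species={"F"}, external_reactions={"R1"})

    def test_internal_rows_external_cols_block_is_zero(self):
        f = toy("fig1_like")
        sub = f.network.subnetwork({"R0", "R1", "R2", "R3"})
        M = build_matrix(sub, external_species={"F0", "F1", "F2"},
                         external_reactions={"R0"})
        block = M.entries[M.n_external_rows:, :M.n_external_cols]
        assert np.all(block == 0)


class TestMassBalance:
    def test_fig1_masses_consistent(self):
        assert validate_mass_balance(toy("fig1_like").network) == []

    def test_unbalanced_reaction_flagged(self):
        net = ReactionNetwork(
            [parse_reaction("A -> B", id="R1")],
            species=[Species("A", mass=2), Species("B", mass=5)])
        assert validate_mass_balance(net) == ["R1"]

    def test_pseudo_species_columns_skipped(self):
        net = ReactionNetwork(
            [parse_reaction("A -> B + hv", id="R1")],
            species=[Species("A", mass=2), Species("B", mass=2),
                     Species("hv", is_pseudo=True)])
        assert validate_mass_balance(net) == []
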
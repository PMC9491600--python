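"""Seed detection: LP certification, scanning, cliques, tiers."""

import numpy as np
import pytest

from sdas import (ReactionNetwork, SeedSet, TierConfig, build_tiers,
                  classify_unsupported_seeds, find_composite_seeds,
                  group_cliques, internal_partition, is_autocatalytic,
                  network_expand, parse_reaction, scan_singleton_seeds, tier0,
                  toy)
from sdas.detect import DetectionError

from conftest import integer_flux_certificate, random_partition, \
    verify_flux_certificate


class TestInternalPartition:
    def test_simple_autocat(self):
        t = toy("simple_autocat")
        t0 = tier0(t.food, t.network)
        M = internal_partition(t0, ["A"], t.network)
        assert M.internal_species == ["A"]
        assert M.internal_reactions == ["R1"]
        assert M.external_species == ["F"]

    def test_fig1_seed_a1(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        M = internal_partition(t0, ["A1"], f.network)
        assert M.internal_species == ["A1", "A2", "A3"]
        assert M.internal_reactions == ["R1", "R2", "R3"]
        assert set(M.external_species) == {"F0", "F1", "F2"}
        assert M.external_reactions == ["R0"]

    def test_seed_inside_food_rejected(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        with pytest.raises(DetectionError):
            internal_partition(t0, ["F1"], f.network)

    def test_inert_seed_gives_empty_internal_columns(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        M = internal_partition(t0, ["A3"], f.network)   # A3 fires nothing
        assert M.internal_reactions == []
        assert not is_autocatalytic(M).feasible
        assert is_autocatalytic(M).solver_status == "empty-internal"


class TestIsAutocatalytic:
    def test_simple_autocat_feasible(self):
        t = toy("simple_autocat")
        M = internal_partition(tier0(t.food, t.network), ["A"], t.network)
        lp = is_autocatalytic(M)
        assert lp.feasible
        assert lp.flux["R1"] >= 1  # x=1 gives net +1 A

    def test_fig1_certificate_net_production(self):
        f = toy("fig1_like")
        M = internal_partition(tier0(f.food, f.network), ["A1"], f.network)
        lp = is_autocatalytic(M)
        assert lp.feasible
        x = np.array([lp.flux[r] for r in M.internal_reactions])
        assert np.all(M.internal_block @ x >= 1 - 1e-6)

    def test_three_reaction_sdas_feasible(self):
        t = toy("sdas_not_pseudoraf")
        M = internal_partition(tier0(t.food, t.network), ["A"], t.network)
        assert is_autocatalytic(M).feasible

    def test_pseudoraf_chain_infeasible(self):
        t = toy("pseudoraf_not_stoich")
        t0 = tier0(t.food, t.network)
        M = internal_partition(t0, ["B"], t.network)
        assert M.internal_reactions  # the catalyzed B<->C cycle fires
        assert not is_autocatalytic(M).feasible

    def test_objective_probe_agrees_with_feasibility(self):
        for name, seed in [("simple_autocat", "A"), ("clique_pair", "A"),
                           ("sdas_not_pseudoraf", "A"),
                           ("pseudoraf_not_stoich", "B")]:
            t = toy(name)
            M = internal_partition(tier0(t.food, t.network), [seed], t.network)
            a = is_autocatalytic(M, mode="feasibility")
            b = is_autocatalytic(M, mode="objective")
            assert a.feasible == b.feasible, name

    @pytest.mark.parametrize("seed", range(40))
    def test_agrees_with_integer_grid_oracle(self, seed):
        """Dual-route check on random partitions: a grid certificate forces
        LP feasibility; an LP verdict of feasible must be backed by a grid
        certificate or by arithmetic verification of its own flux; an LP
        verdict of infeasible forbids any grid certificate."""
        rng = np.random.default_rng(seed)
        M = random_partition(rng)
        A = M.internal_block
        lp = is_autocatalytic(M)
        cert = integer_flux_certificate(A, bound=12)
        if cert is not None:
            assert lp.feasible, "oracle found a certificate the LP missed"
        if lp.feasible:
            x = np.array([lp.flux[r] for r in M.internal_reactions])
            assert verify_flux_certificate(A, x), \
                "LP flux fails arithmetic verification"
        else:
            assert cert is None, "LP claims infeasible but a certificate exists"


class TestScanSeeds:
    def test_fig1_tier1_scan(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        hits = scan_singleton_seeds(t0, f.network)
        assert {tuple(sorted(s.members))[0] for s, _ in hits} == {"A1", "A2"}
        for s, sdas in hits:
            assert sdas.species == {"A1", "A2", "A3"}
            assert sdas.reactions == {"R1", "R2", "R3"}

    def test_scan_is_order_independent(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        all_c = sorted(set(f.network.species) - t0.species)
        a = scan_singleton_seeds(t0, f.network, candidates=all_c)
        b = scan_singleton_seeds(t0, f.network, candidates=all_c[::-1])
        assert [(s.members, d.fingerprint) for s, d in a] == \
            [(s.members, d.fingerprint) for s, d in b]

    def test_empty_candidates(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        assert scan_singleton_seeds(t0, f.network, candidates=[]) == []

    def test_candidate_in_food_rejected(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        with pytest.raises(DetectionError):
            scan_singleton_seeds(t0, f.network, candidates=["F1"])

    def test_seed_dependence_of_certified_sdas(self):
        # re-expansion from food alone contains none of the internal reactions
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        for s, sdas in scan_singleton_seeds(t0, f.network):
            re = network_expand(t0.species, f.network)
            assert not (sdas.reactions & re.reactions)


class TestCompositeSeeds:
    def test_composite_pair_found(self):
        t = toy("composite_seed")
        t0 = tier0(t.food, t.network)
        found = find_composite_seeds(t0, t.network)
        assert [sorted(s.members) for s, _ in found] == [["B", "C"]]
        _, sdas = found[0]
        assert sdas.species == {"A", "B", "C"}

    def test_minimality_rejects_pairs_containing_a_singleton_seed(self):
        t = toy("composite_seed")
        t0 = tier0(t.food, t.network)
        # A alone is a seed, so {A, B} must be rejected as non-minimal
        found = find_composite_seeds(t0, t.network, pairs=[("A", "B")])
        assert found == []

    def test_no_composite_in_simple_toy(self):
        t = toy("simple_autocat")
        t0 = tier0(t.food, t.network)
        assert find_composite_seeds(t0, t.network) == []


class TestCliques:
    def test_clique_pair_toy(self):
        t = toy("clique_pair")
        t0 = tier0(t.food, t.network)
        cliques = group_cliques(scan_singleton_seeds(t0, t.network))
        assert len(cliques) == 1
        assert cliques[0].seeds == {"A", "B"}

    def test_clique_members_are_in_their_sdas(self):
        for name in ("clique_pair", "fig1_like", "non_raf_cycle"):
            t = toy(name)
            t0 = tier0(t.food, t.network)
            for c in group_cliques(scan_singleton_seeds(t0, t.network)):
                assert c.seeds <= c.sdas.species, name

    def test_single_seed_single_clique(self):
        t = toy("simple_autocat")
        t0 = tier0(t.food, t.network)
        cliques = group_cliques(scan_singleton_seeds(t0, t.network))
        assert len(cliques) == 1 and cliques[0].seeds == {"A"}

    def test_non_singleton_input_rejected(self):
        t = toy("simple_autocat")
        t0 = tier0(t.food, t.network)
        [(seed, sdas)] = scan_singleton_seeds(t0, t.network)
        bad = SeedSet(frozenset({"X", "Y"}), "composite", "supported")
        with pytest.raises(DetectionError):
            group_cliques([(bad, sdas)])


class TestUnsupportedSeeds:
    def test_fig1_u1_is_unsupported_seed_of_tier1_sdas(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        hits = scan_singleton_seeds(t0, f.network)
        sdas = hits[0][1]
        cands = set(f.network.species) - t0.species
        out = classify_unsupported_seeds(cands, [sdas], t0, f.network)
        assert set(out) == {"U1"}
        assert out["U1"].fingerprint == sdas.fingerprint

    def test_supported_seeds_excluded(self):
        f = toy("fig1_like")
        t0 = tier0(f.food, f.network)
        hits = scan_singleton_seeds(t0, f.network)
        out = classify_unsupported_seeds({"A1", "A2"},
                                         [h[1] for h in hits], t0, f.network)
        assert out == {}

    def test_nested_assignment_to_maximal_sdas(self):
        # two nested systems; the unsupported seed triggers both and must be
        # assigned to the larger one
        net = ReactionNetwork([
            parse_reaction("A + F -> 2 A", id="R1"),
            parse_reaction("B + F -> A + 2 B", id="R2"),
            parse_reaction("U -> A + B + W", id="R3"),
        ])
        t0 = tier0({"F"}, net)
        hits = scan_singleton_seeds(t0, net, candidates={"A", "B"})
        sdass = [h[1] for h in hits]
        assert len(sdass) == 2
        out = classify_unsupported_seeds({"U", "W"}, sdass, t0, net)
        assert set(out) == {"U"}
        assert out["U"].reactions == max((s.reactions for s in sdass), key=len)


class TestBuildTiers:
    def test_fig1_three_tiers(self):
        f = toy("fig1_like")
        levels = build_tiers(f.food, f.network)
        assert [lvl.tier for lvl in levels] == [0, 1, 2, 3]
        t1, t2, t3 = levels[1], levels[2], levels[3]
        assert [sorted(c.seeds) for c in t1.cliques] == [["A1", "A2"]]
        assert t1.cliques[0].sdas.reactions == {"R1", "R2", "R3"}
        assert [sorted(c.seeds) for c in t2.cliques] == [["B1", "B2"]]
        assert t2.cliques[0].sdas.species == {"B1", "B2", "B3"}
        assert [sorted(c.seeds) for c in t3.cliques] == [["C1"]]
        assert t1.unsupported == {"U1": t1.sdass[0].id}

    def test_no_seed_network_stops_at_tier0(self):
        for name in ("catalyzed_chain", "raf_not_stoich"):
            t = toy(name)
            levels = build_tiers(t.food, t.network)
            assert len(levels) == 1, name

    def test_max_tier_respected(self):
        f = toy("fig1_like")
        levels = build_tiers(f.food, f.network, TierConfig(max_tier=1))
        assert [lvl.tier for lvl in levels] == [0, 1]

    def test_higher_tier_food_includes_lower_sdas_species(self):
        f = toy("fig1_like")
        levels = build_tiers(f.food, f.network)
        assert {"A1", "A2", "A3"} <= levels[2].food_closure.species
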
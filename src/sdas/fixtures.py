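"""Toy networks and a synthetic tiered-network generator.

The toy registry embeds the small printed examples used throughout the
SDAS literature (single-reaction autocatalysis, composite seeds, cliques,
explicitly catalyzed chains, RAF/pseudo-RAF contrasts) together with their
expected verdicts, so detection behaviour can be pinned exactly.

``fig1_like`` is a *synthetic reconstruction* of the classic worked example
of a tiered SDAS network: a hypothetical universe with ultimate food
{F0, F2} whose food closure is S0 = {F0, F1, F2}, R0 = {R0}, a tier-1
system ({A1, A2, A3}, {R1, R2, R3}) seeded by A1 with the 4:5:1 flux
certificate giving the net conversion 4 F1 + 5 F2 -> A1 + A2 + A3, plus
higher-tier systems (one producing a waste species B3 that a yet higher
system feeds on mutualistically) and an unsupported seed U1.  The exact
published stoichiometries of that figure are not available in text form;
this network satisfies every stated constraint but is not the figure
itself.  Species carry consistent integer pseudo-masses.

:func:`generate_tiered_network` plants per-tier autocatalytic cycles with
known seeds, motif sizes and waste into random tiered universes, alongside
decoy (non-autocatalytic) chains, for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import NetworkError, Reaction, ReactionNetwork, Species, parse_reaction


@dataclass(frozen=True)
class ToyNetwork:
    """A registered toy: the (already split) network, its food set, and the
    expected verdicts as loose metadata for tests and demos."""

    name: str
    network: ReactionNetwork
    food: frozenset[str]
    expected: Mapping[str, object] = field(default_factory=dict)


def _net(equations: list[tuple[str, str]],
         species: list[Species] = ()) -> ReactionNetwork:
    net = ReactionNetwork(species=species)
    for rid, eq in equations:
        net.add_reaction(parse_reaction(eq, id=rid))
    return net.split_all_reversible()


def _toy_specs() -> dict[str, ToyNetwork]:
    reg: dict[str, ToyNetwork] = {}

    def add(name, equations, food, expected, species=()):
        reg[name] = ToyNetwork(name=name, network=_net(equations, species),
                               food=frozenset(food), expected=dict(expected))

    # A + F -> 2A : the simplest seed-dependent autocatalytic system.
    add("simple_autocat",
        [("R1", "A + F -> 2 A")],
        {"F"},
        {"autocatalytic": True, "supported_seeds": {"A"},
         "sdas": ({"A"}, {"R1"}), "min_motif_size": 1})

    # B and C jointly (but not separately) seed the A-cycle.
    add("composite_seed",
        [("R1", "B + C <=> A"), ("R2", "A + F -> 2 A")],
        {"F"},
        {"autocatalytic": True, "supported_seeds": {"A"},
         "composite_seeds": [{"B", "C"}]})

    # A and B induce the identical closure: one clique.
    add("clique_pair",
        [("R1", "A + F <=> B"), ("R2", "B + F -> 2 A")],
        {"F"},
        {"autocatalytic": True, "supported_seeds": {"A", "B"},
         "cliques": [{"A", "B"}], "min_motif_size": 2})

    # Explicitly catalyzed linear chain: food-generated, no stoichiometric
    # increase, hence no seed-dependent system at all.
    add("catalyzed_chain",
        [("R1", "A <=> B | cat: U"), ("R2", "B <=> C | cat: V")],
        {"A", "U", "V"},
        {"autocatalytic": False, "supported_seeds": set()})

    # Autocatalytic cycle without any explicit catalyst (not a RAF).
    add("non_raf_cycle",
        [("R1", "A + B <=> C"), ("R2", "C + A <=> 2 B")],
        {"A"},
        {"autocatalytic": True, "supported_seeds": {"B", "C"}})

    # A SDAS in which no reaction is explicitly catalyzed (not a pseudo-RAF).
    add("sdas_not_pseudoraf",
        [("R1", "A + F1 -> B + C"), ("R2", "B + F2 -> A + D"),
         ("R3", "C + D -> A")],
        {"F1", "F2"},
        {"autocatalytic": True, "supported_seeds": {"A", "B"},
         "min_motif_size": 3})

    # A RAF (every reaction catalyzed, catalysts food-generated) that is
    # not stoichiometrically autocatalytic: everything grows from food.
    add("raf_not_stoich",
        [("R1", "F1 -> A | cat: F2"), ("R2", "F3 -> B | cat: A")],
        {"F1", "F2", "F3"},
        {"autocatalytic": False, "supported_seeds": set()})

    # A pseudo-RAF (catalyzed cycle among non-food species) without
    # stoichiometric increase: seeding B or C cannot be sustained.
    add("pseudoraf_not_stoich",
        [("R1", "F1 -> A | cat: F2"), ("R2", "B -> C | cat: A"),
         ("R3", "C -> B | cat: A")],
        {"F1", "F2", "F3"},
        {"autocatalytic": False, "supported_seeds": set()},
        species=[Species("F3")])

    # Tiered reconstruction (see module docstring).  Integer pseudo-masses
    # keep every reaction mass-consistent.
    fig1_species = [
        Species("F0", mass=1), Species("F1", mass=3), Species("F2", mass=2),
        Species("A1", mass=12), Species("A2", mass=5), Species("A3", mass=5),
        Species("B1", mass=4), Species("B2", mass=4), Species("B3", mass=1),
        Species("C1", mass=1), Species("U1", mass=7), Species("U2", mass=2),
    ]
    add("fig1_like",
        [("R0", "F0 + F2 -> F1"),
         ("R1", "A1 + F1 -> 3 A2"),
         ("R2", "2 A2 + F2 -> A1"),
         ("R3", "A2 -> A3"),
         ("R4", "B1 + A3 -> 2 B2 + B3"),
         ("R5", "B2 -> B1"),
         ("R6", "C1 + B3 -> 2 C1"),
         ("R7", "U1 -> A2 + U2")],
        {"F0", "F2"},
        {"autocatalytic": True,
         "supported_seeds": {"A1", "A2"},
         "tier0": ({"F0", "F1", "F2"}, {"R0"}),
         "tier1_sdas": ({"A1", "A2", "A3"}, {"R1", "R2", "R3"}),
         "tier1_clique": {"A1", "A2"},
         "flux_certificate": {"R1": 4.0, "R2": 5.0, "R3": 1.0},
         "tier2_sdas": ({"B1", "B2", "B3"}, {"R4", "R5"}),
         "tier2_clique": {"B1", "B2"},
         "tier2_waste": {"B3"},
         "tier3_sdas": ({"C1"}, {"R6"}),
         "unsupported_seeds": {"U1"},
         "min_motif_size": 2},
        species=fig1_species)

    return reg


_REGISTRY: dict[str, ToyNetwork] | None = None


def toy_names() -> list[str]:
    return sorted(_registry())


def _registry() -> dict[str, ToyNetwork]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _toy_specs()
    return _REGISTRY


def toy(name: str) -> ToyNetwork:
    """Return a registered toy network by name (fresh metadata, shared
    immutable reactions).  Raises :class:`NetworkError` for unknown names."""
    reg = _registry()
    if name not in reg:
        raise NetworkError(
            f"unknown toy {name!r}; available: {', '.join(sorted(reg))}")
    return reg[name]


# ---------------------------------------------------------------------------
# Random tiered networks with planted autocatalytic cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Shape of a generated tiered universe.

    Each tier plants ``cycles_per_tier`` autocatalytic cycles whose length
    is drawn from ``motif_size_range`` (inclusive); a ``waste_fraction`` of
    cycle steps additionally emit a waste byproduct; tiers above the first
    draw ``cross_tier_food_edges`` of their consumed food species from the
    previous tier's cycle members (so they need that tier activated);
    ``decoys_per_tier`` non-autocatalytic two-species chains are added as
    distractors.  Identical ``rng_seed`` yields the identical network.
    """

    n_tiers: int = 2
    species_per_tier: int = 8
    motif_size_range: tuple[int, int] = (2, 4)
    waste_fraction: float = 0.3
    cross_tier_food_edges: int = 1
    cycles_per_tier: int = 1
    decoys_per_tier: int = 2
    n_food_species: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiers < 1 or self.species_per_tier < 1 or \
                self.n_food_species < 1 or self.cycles_per_tier < 0 or \
                self.decoys_per_tier < 0:
            raise ValueError("all counts must be >= 1 (>= 0 for cycles/decoys)")
        lo, hi = self.motif_size_range
        if not (1 <= lo <= hi):
            raise ValueError("motif_size_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.waste_fraction <= 1.0):
            raise ValueError("waste_fraction must lie in [0, 1]")
        if self.cross_tier_food_edges < 0:
            raise ValueError("cross_tier_food_edges must be >= 0")


@dataclass(frozen=True)
class PlantedCycle:
    tier: int
    seeds: frozenset[str]          # cycle members; each is a supported seed
    sdas_species: frozenset[str]   # members + waste
    sdas_reactions: frozenset[str]
    motif_size: int
    waste: frozenset[str]


@dataclass(frozen=True)
class GroundTruth:
    food: frozenset[str]
    cycles: tuple[PlantedCycle, ...]

    def cycles_at(self, tier: int) -> tuple[PlantedCycle, ...]:
        return tuple(c for c in self.cycles if c.tier == tier)


def generate_tiered_network(params: GeneratorParams
                            ) -> tuple[ReactionNetwork, GroundTruth]:
    """Generate a random tiered universe with planted autocatalytic cycles.

    Each planted cycle X1 -> X2 -> ... -> Xk -> 2 X1 consumes one food (or
    lower-tier) species per step; the doubling step makes the cycle
    stoichiometrically autocatalytic, every cycle member is a supported
    singleton seed of the same clique, and the minimal motif is the whole
    k-reaction cycle.  Waste-emitting steps consume one extra food unit so
    integer pseudo-masses stay balanced.  Decoy chains D1 -> D2 are
    reachable only by seeding D1 and are never self-sustaining.

    Returns the network and the ground truth of planted structure.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    net = ReactionNetwork()
    food_ids = [f"F{i}" for i in range(p.n_food_species)]
    masses: dict[str, int] = {fid: 1 for fid in food_ids}
    for fid in food_ids:
        net.add_species(Species(fid, mass=1))

    cycles: list[PlantedCycle] = []
    prev_members: list[str] = []
    for t in range(1, p.n_tiers + 1):
        lo, hi = p.motif_size_range
        tier_members: list[str] = []
        budget = p.species_per_tier
        for c in range(p.cycles_per_tier):
            k = int(rng.integers(lo, hi + 1))
            n_waste = int(round(p.waste_fraction * k))
            need = k + n_waste
            if need > budget:
                raise ValueError(
                    f"tier {t} cycle {c}: motif size {k} plus {n_waste} "
                    f"waste species exceed the species budget "
                    f"({budget} left of {p.species_per_tier})")
            budget -= need
            members = [f"T{t}C{c}X{i}" for i in range(k)]
            waste_steps = sorted(
                rng.choice(k, size=n_waste, replace=False).tolist())
            waste_ids = {step: f"T{t}C{c}W{step}" for step in waste_steps}
            # pick the food each step consumes
            pool_lower = prev_members if t > 1 else []
            step_food: list[str] = []
            n_cross = min(p.cross_tier_food_edges, k) if pool_lower else 0
            cross_steps = set(
                rng.choice(k, size=n_cross, replace=False).tolist())
            for step in range(k):
                if step in cross_steps:
                    step_food.append(str(rng.choice(pool_lower)))
                else:
                    step_food.append(str(rng.choice(food_ids)))
            # masses: m(X1) = sum of per-step food-minus-waste mass
            step_gain = [masses[f] for f in step_food]
            m1 = sum(step_gain)  # waste mass always equals the extra food unit
            m = m1
            member_mass = {}
            for i, sp in enumerate(members):
                member_mass[sp] = m
                m += step_gain[i]
            rids = []
            for i in range(k):
                src, dst = members[i], members[(i + 1) % k]
                rid = f"T{t}C{c}R{i}"
                reactants = {src: 1.0, step_food[i]: 1.0}
                products = {dst: 2.0 if i == k - 1 else 1.0}
                if i in waste_ids:
                    wid = waste_ids[i]
                    reactants[step_food[i]] = reactants.get(step_food[i], 0) + 1.0
                    products[wid] = 1.0
                    masses[wid] = masses[step_food[i]]
                    net.add_species(Species(wid, mass=masses[wid]))
                net.add_reaction(Reaction(id=rid, reactants=reactants,
                                          products=products))
                rids.append(rid)
            for sp in members:
                masses[sp] = member_mass[sp]
                net.add_species(Species(sp, mass=member_mass[sp]))
            tier_members.extend(members)
            cycles.append(PlantedCycle(
                tier=t, seeds=frozenset(members),
                sdas_species=frozenset(members) | frozenset(waste_ids.values()),
                sdas_reactions=frozenset(rids), motif_size=k,
                waste=frozenset(waste_ids.values())))
        for d in range(p.decoys_per_tier):
            fid = str(rng.choice(food_ids))
            d1, d2 = f"T{t}D{d}a", f"T{t}D{d}b"
            net.add_species(Species(d1, mass=5))
            net.add_species(Species(d2, mass=5 + masses[fid]))
            masses[d1], masses[d2] = 5, 5 + masses[fid]
            net.add_reaction(Reaction(id=f"T{t}D{d}",
                                      reactants={d1: 1.0, fid: 1.0},
                                      products={d2: 1.0}))
        prev_members = tier_members if tier_members else prev_members

    return net, GroundTruth(food=frozenset(food_ids), cycles=tuple(cycles))
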
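"""Inter-SDAS ecology: interaction classification, waste, scaffolding.

Coexisting SDASs in one food-driven network interact much like organisms in
an ecosystem:

* **competition** — two SDASs consume a common food species;
* **predation / parasitism** — a higher-tier SDAS consumes a *member*
  species of an autocatalytic motif of a lower SDAS (it eats the lower
  system's self-amplifying core);
* **mutualism** — the higher SDAS consumes a *waste* species of the lower
  motifs (a byproduct the lower system does not itself need);
* **catalytic facilitation** — a higher-tier species is consumed and fully
  regenerated across a pair of reactions whose combined net conversion
  duplicates an existing one-step conversion.  Whether this accelerates the
  conversion depends on kinetics outside the model's scope, so candidates
  are reported as composite paths, not asserted as catalysis.

*Scaffolding* — a structure needed to activate, but not to maintain, a
higher-tier system — is probed by reaction-removal ablation:
:func:`robustness_to_removal` re-runs expansion + LP with chosen reactions
deleted and reports whether a seed still induces a SDAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import ReactionNetwork
from .detect import (LPResult, SDAS, SeedSet, internal_partition,
                     is_autocatalytic)
from .expansion import network_expand
from .motifs import Motif

INTERACTION_LABELS = ("competition", "predation-parasitism", "mutualism",
                      "catalytic-facilitation")


@dataclass(frozen=True)
class InteractionReport:
    """Classified interactions of an ordered (lower, higher) SDAS pair.

    ``labels`` is the subset of interaction kinds detected; ``evidence``
    maps each label to the witnessing species (or, for facilitation, to
    ``(catalyst, (r_consume, r_regenerate), bridged_reaction)`` tuples).
    """

    pair: tuple[str, str]
    labels: frozenset[str]
    evidence: Mapping[str, tuple] = field(default_factory=dict, compare=False)


def _consumed_by(sdas: SDAS, net: ReactionNetwork) -> set[str]:
    """Species consumed (as net reactants) by the SDAS's reactions."""
    out: set[str] = set()
    for rid in sdas.reactions:
        out |= set(net.reactions[rid].reactants)
    return out


def find_waste(sdas: SDAS, motifs: Sequence[Motif]) -> frozenset[str]:
    """Waste of a SDAS relative to a motif list: species produced by motif
    reactions, internal to the SDAS, that are members of no supplied motif."""
    for m in motifs:
        if not m.reactions <= sdas.reactions:
            raise ValueError("motif reactions are not part of the SDAS")
    members = set().union(*(m.members for m in motifs)) if motifs else set()
    waste = set().union(*(m.waste for m in motifs)) if motifs else set()
    return frozenset((waste & sdas.species) - members)


def find_catalytic_facilitation(low: SDAS, high: SDAS, net: ReactionNetwork
                                ) -> list[tuple[str, tuple[str, str], str]]:
    """Candidate composite catalytic paths.

    A higher-SDAS species ``c`` is a facilitation candidate if some
    reaction pair consumes and regenerates ``c`` with zero net effect on it
    while their combined net conversion equals the net of an existing
    single reaction not involving ``c``.  No rate comparison is attempted.
    """
    out: list[tuple[str, tuple[str, str], str]] = []
    reactions = net.reactions
    # index reactions by consumed / produced species
    nets = {rid: r.net() for rid, r in reactions.items()}
    by_net: dict[tuple, list[str]] = {}
    for rid, n in nets.items():
        key = tuple(sorted((s, round(v, 9)) for s, v in n.items()))
        by_net.setdefault(key, []).append(rid)
    for c in sorted(high.species):
        consumers = [rid for rid, n in nets.items() if n.get(c, 0) < 0]
        producers = [rid for rid, n in nets.items() if n.get(c, 0) > 0]
        for r1 in consumers:
            for r2 in producers:
                if r1 == r2:
                    continue
                combined: dict[str, float] = dict(nets[r1])
                for s, v in nets[r2].items():
                    combined[s] = combined.get(s, 0.0) + v
                combined = {s: v for s, v in combined.items() if abs(v) > 1e-9}
                if c in combined:
                    continue  # not fully regenerated at 1:1 flux
                key = tuple(sorted((s, round(v, 9)) for s, v in combined.items()))
                for bridged in by_net.get(key, ()):
                    if bridged in (r1, r2):
                        continue
                    if c in reactions[bridged].touched:
                        continue
                    out.append((c, (r1, r2), bridged))
    return sorted(set(out))


def classify_interaction(low: SDAS, high: SDAS,
                         low_motifs: Sequence[Motif],
                         net: ReactionNetwork) -> InteractionReport:
    """Classify the ecological interactions of a (lower, higher) SDAS pair.

    Member/waste classification uses the union over ``low_motifs``.  When no
    motifs are supplied every species of the lower SDAS is conservatively
    treated as a member, which suppresses mutualism labels (nothing is
    waste).  Multiple labels may co-occur.
    """
    labels: set[str] = set()
    evidence: dict[str, tuple] = {}

    high_consumes = _consumed_by(high, net)
    low_consumes = _consumed_by(low, net)
    shared_food = high_consumes & low_consumes & low.food & high.food
    if shared_food:
        labels.add("competition")
        evidence["competition"] = tuple(sorted(shared_food))

    if low_motifs:
        members = set().union(*(m.members for m in low_motifs))
        waste = find_waste(low, low_motifs)
    else:
        members = set(low.species)
        waste = frozenset()

    eaten_members = high_consumes & members
    if eaten_members:
        labels.add("predation-parasitism")
        evidence["predation-parasitism"] = tuple(sorted(eaten_members))

    eaten_waste = high_consumes & waste
    if eaten_waste:
        labels.add("mutualism")
        evidence["mutualism"] = tuple(sorted(eaten_waste))

    facilitation = find_catalytic_facilitation(low, high, net)
    if facilitation:
        labels.add("catalytic-facilitation")
        evidence["catalytic-facilitation"] = tuple(facilitation)

    return InteractionReport(pair=(low.id, high.id), labels=frozenset(labels),
                             evidence=evidence)


def robustness_to_removal(net: ReactionNetwork, food: Iterable[str],
                          seed: "SeedSet | Iterable[str]",
                          removed_reactions: Iterable[str]) -> LPResult:
    """Ablation probe: does the seed still induce a SDAS with the given
    reactions deleted?

    Re-runs the food expansion, the seeded expansion and the LP on the
    reduced network.  Removing reactions outside the seeded closure leaves
    the certificate unchanged; removing an essential one flips the verdict
    to infeasible.  An empty removal set reproduces plain detection.
    """
    removed = set(removed_reactions)
    unknown = removed - set(net.reactions)
    if unknown:
        raise ValueError(f"unknown reactions to remove: {sorted(unknown)}")
    members = seed.members if isinstance(seed, SeedSet) else frozenset(seed)
    reduced = ReactionNetwork(
        reactions=[r for rid, r in sorted(net.reactions.items())
                   if rid not in removed],
        species=net.species.values())
    food_closure = network_expand(food, reduced, universe=set(reduced.species))
    if members & food_closure.species:
        # removal can only shrink closures, but guard the contract anyway
        return LPResult(feasible=False, solver_status="seed-is-food")
    closure = network_expand(food_closure.species | members, reduced)
    if closure.reactions == food_closure.reactions:
        return LPResult(feasible=False, solver_status="empty-internal")
    M = internal_partition(food_closure, members, reduced)
    return is_autocatalytic(M)
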
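"""Catalyst-aware network expansion.

Network expansion is the iterative closure operation Xi(S_O, R): starting
from a species set S_O, repeatedly add every reaction whose reactants *and*
explicit catalysts are all currently available, then add its products, until
no further reaction can fire.  Catalysts gate firing exactly like reactants
but are never added as products (they are requirements, not outputs).

The closure is a unique fixpoint independent of iteration order.  The
implementation uses a counting/queue scheme — each reaction tracks how many
of its required species are still missing and is indexed by those species —
so a full-database closure costs time near-linear in total reaction arity
rather than |R| full passes.  Reactions are processed in waves (products
enter the species set only after the whole wave has been scanned), and the
wave index of each fired reaction is recorded as its ``generation`` for
provenance; generations never affect the result.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import NetworkError, Reaction, ReactionNetwork


@dataclass(frozen=True)
class Closure:
    """Result of a network expansion: the reachable species and reactions.

    ``generation`` maps each fired reaction to the wave in which it fired
    (0 = fires directly from the start set).  ``kind`` is bookkeeping only
    ("closure" in general, "tier0" for the food closure of the ultimate
    food set).
    """

    start_species: frozenset[str]
    species: frozenset[str]
    reactions: frozenset[str]
    generation: dict[str, int] = field(default_factory=dict, compare=False)
    kind: str = field(default="closure", compare=False)

    @property
    def fingerprint(self) -> tuple[frozenset[str], frozenset[str]]:
        """Hashable identity of the closure (species set, reaction set)."""
        return (self.species, self.reactions)


def _reaction_map(R: "ReactionNetwork | Iterable[Reaction] | Mapping[str, Reaction]"
                  ) -> dict[str, Reaction]:
    if isinstance(R, ReactionNetwork):
        return dict(R.reactions)
    if isinstance(R, Mapping):
        return dict(R)
    return {r.id: r for r in R}


def network_expand(start_species: Iterable[str],
                   R: "ReactionNetwork | Iterable[Reaction]",
                   universe: Iterable[str] | None = None,
                   kind: str = "closure") -> Closure:
    """Compute the expansion closure Xi(S_O, R).

    Parameters
    ----------
    start_species
        The starting species set S_O.
    R
        The allowed reactions (a :class:`ReactionNetwork`, a mapping, or an
        iterable of :class:`Reaction`).
    universe
        Known species universe used to reject unknown start ids.  Defaults
        to the species touched by ``R`` (plus, when ``R`` is a
        :class:`ReactionNetwork`, its declared species); a start species
        outside it raises :class:`NetworkError`.

    Returns the unique fixpoint: no reaction outside the closure has all of
    its reactants and catalysts inside the closure's species set.
    """
    reactions = _reaction_map(R)
    start = frozenset(start_species)
    if universe is None:
        universe = set().union(*(r.touched for r in reactions.values())) \
            if reactions else set()
        if isinstance(R, ReactionNetwork):
            universe |= set(R.species)
    else:
        universe = set(universe)
    unknown = start - universe
    if unknown:
        raise NetworkError(f"start species not in universe: {sorted(unknown)}")

    missing: dict[str, int] = {}
    by_species: dict[str, list[str]] = defaultdict(list)
    available = set(start)
    ready: list[str] = []
    for rid, r in reactions.items():
        need = r.required - available
        missing[rid] = len(need)
        if not need:
            ready.append(rid)
        for sp in need:
            by_species[sp].append(rid)

    fired: set[str] = set()
    generation: dict[str, int] = {}
    gen = 0
    while ready:
        new_species: list[str] = []
        for rid in ready:
            fired.add(rid)
            generation[rid] = gen
            for sp in reactions[rid].products:
                if sp not in available:
                    available.add(sp)
                    new_species.append(sp)
        ready = []
        for sp in new_species:
            for rid in by_species[sp]:
                if rid in fired:
                    continue
                missing[rid] -= 1
                if missing[rid] == 0:
                    ready.append(rid)
        gen += 1

    return Closure(start_species=start, species=frozenset(available),
                   reactions=frozenset(fired), generation=generation, kind=kind)


def tier0(S_U: Iterable[str], R: "ReactionNetwork | Iterable[Reaction]",
          universe: Iterable[str] | None = None) -> Closure:
    """Closure of the ultimate food set: the tier-0 system (S0, R0).

    Everything in it is reachable without any seed and is treated as
    external food by the seed-detection machinery.
    """
    return network_expand(S_U, R, universe=universe, kind="tier0")
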
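"""Detection of seed-dependent autocatalytic systems (SDASs).

A SDAS is an internal subnetwork that cannot arise by expansion from food
alone but, once triggered by a transient *seed*, can stoichiometrically
regenerate every one of its internal species from food.  Detection works in
three steps:

1. expand the food set to its closure (the external subsystem);
2. expand food plus a candidate seed and take the set difference — the
   seed-induced internal subnetwork (S1, R1);
3. certify stoichiometric autocatalysis of the internal block by linear
   programming: does a non-negative flux vector x exist with

       sum_j x_j s_ij >= 1   for every internal species i?

   (The strict form ``> 0`` is equivalent by rescaling.)  External food
   rows are unconstrained because food is assumed freely available.

On top of the certifier this module provides singleton-seed scanning,
composite (pair) seed search with minimality, clique grouping (seeds whose
food-plus-seed closures coincide induce the same SDAS), unsupported-seed
classification, and iterated tier construction in which every detected
SDAS's species become food for the next trophic tier.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import (NetworkError, Reaction, ReactionNetwork, Species,
                   StoichiometricMatrix, build_matrix)
from .expansion import Closure, network_expand, tier0

#: LP feasibility tolerance (HiGHS primal tolerance).
LP_TOL = 1e-7
#: Reported flux entries below this are clipped to zero.
FLUX_CLIP = 1e-9


class DetectionError(NetworkError):
    """Raised for contract violations in the detection pipeline."""


@dataclass(frozen=True)
class SeedSet:
    """A candidate or confirmed seed.

    ``kind`` is ``"singleton"`` or ``"composite"``; ``support`` is
    ``"supported"`` (the induced SDAS produces the seed), ``"unsupported"``
    or ``"not-a-seed"``.
    """

    members: frozenset[str]
    kind: str
    support: str

    def __post_init__(self) -> None:
        if not self.members:
            raise DetectionError("seed set must be non-empty")
        expected = "singleton" if len(self.members) == 1 else "composite"
        if self.kind != expected:
            raise DetectionError(
                f"seed {sorted(self.members)}: kind {self.kind!r} does not "
                f"match cardinality")


@dataclass(frozen=True)
class LPResult:
    """Outcome of the autocatalysis LP.

    ``feasible`` is the verdict; when feasible, ``flux`` maps internal
    reaction ids to a non-negative flux certificate satisfying
    sum_j x_j s_ij >= 1 on every internal row.  ``objective_unbounded`` is
    set when the optional unbounded-objective probe was used.
    """

    feasible: bool
    flux: Mapping[str, float] | None = None
    objective_unbounded: bool = False
    solver_status: str = ""


@dataclass(frozen=True)
class SDAS:
    """A certified seed-dependent autocatalytic system.

    ``species``/``reactions`` are the internal sets (S_k, R_k); ``food`` is
    the external species set it feeds on; ``seeds`` lists seeds known to
    induce it; ``certificate`` the LP flux proof.
    """

    id: str
    species: frozenset[str]
    reactions: frozenset[str]
    tier: int
    food: frozenset[str]
    seeds: tuple[SeedSet, ...]
    certificate: LPResult

    @property
    def fingerprint(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.species, self.reactions)


@dataclass(frozen=True)
class Clique:
    """Singleton supported seeds inducing one and the same SDAS."""

    seeds: frozenset[str]
    sdas: SDAS


# ---------------------------------------------------------------------------
# Partition + LP certification
# ---------------------------------------------------------------------------

def induced_subnetwork(food_closure: Closure, seed: Iterable[str],
                       R: "ReactionNetwork | Iterable[Reaction]"
                       ) -> tuple[Closure, frozenset[str], frozenset[str]]:
    """Expand food + seed and return (closure, internal species, internal
    reactions), the set differences against the food closure."""
    seed = frozenset(seed)
    if seed <= food_closure.species:
        raise DetectionError(
            f"seed {sorted(seed)} is contained in the food closure; "
            "a seed must be disjoint from food")
    closure = network_expand(food_closure.species | seed, R)
    return (closure,
            closure.species - food_closure.species,
            closure.reactions - food_closure.reactions)


def internal_partition(food_closure: Closure, H: Iterable[str],
                       R: ReactionNetwork) -> StoichiometricMatrix:
    """Partitioned stoichiometric matrix for the subnetwork induced by seed
    ``H`` over the given food closure.

    Rows/columns of the food closure are external; the seed-induced
    remainder is internal.  Only species and reactions inside the seeded
    closure appear.
    """
    closure, _s1, r1 = induced_subnetwork(food_closure, H, R)
    sub = ReactionNetwork(
        reactions=[R.reactions[rid] for rid in sorted(closure.reactions)],
        species=[R.species[s] for s in sorted(closure.species) if s in R.species])
    # make sure seed + untouched food species are present as rows
    for sid in sorted(closure.species):
        if sid not in sub.species:
            sub.add_species(R.species.get(sid) or Species(sid))
    return build_matrix(sub,
                        external_species=closure.species - _s1,
                        external_reactions=closure.reactions - r1)


def is_autocatalytic(M: StoichiometricMatrix, *, mode: str = "feasibility",
                     tol: float = LP_TOL) -> LPResult:
    """Certify stoichiometric autocatalysis of the internal block of ``M``.

    Feasible iff a vector x >= 0 over the internal columns exists with
    sum_j x_j s_ij >= 1 for every internal row (external rows are
    unconstrained: food is freely available).

    ``mode="feasibility"`` (default) solves the phase-1 LP with a zero
    objective.  ``mode="objective"`` reproduces the historical probe:
    maximise the net production of the first internal species subject to
    the same constraints; an unbounded objective certifies feasibility.
    """
    A = M.internal_block
    n_rows, n_cols = A.shape
    if n_cols == 0:
        return LPResult(feasible=False, solver_status="empty-internal")
    if n_rows == 0:
        raise DetectionError("partition has internal reactions but no internal species")

    A_ub = -A
    b_ub = -np.ones(n_rows)
    if mode == "feasibility":
        c = np.zeros(n_cols)
    elif mode == "objective":
        c = -A[0, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs",
                  options={"primal_feasibility_tolerance": tol})
    if res.status == 0:
        flux = {rid: (0.0 if x < FLUX_CLIP else float(x))
                for rid, x in zip(M.internal_reactions, res.x)}
        return LPResult(feasible=True, flux=flux,
                        solver_status=res.message.strip() or "optimal")
    if res.status == 3:  # unbounded objective still proves the region non-empty
        return LPResult(feasible=True, flux=None, objective_unbounded=True,
                        solver_status="unbounded-objective")
    if res.status == 2:
        return LPResult(feasible=False, solver_status="infeasible")
    raise DetectionError(f"LP solver failure: status={res.status} {res.message}")


# ---------------------------------------------------------------------------
# Seed scanning
# ---------------------------------------------------------------------------

class _ClosureCache:
    """Per-run cache keyed by closure fingerprint so that seeds inducing the
    same closure share one LP solve and one SDAS record."""

    def __init__(self) -> None:
        self._by_fp: dict[tuple[frozenset[str], frozenset[str]],
                          tuple[LPResult, SDAS | None]] = {}

    def get(self, fp):
        return self._by_fp.get(fp)

    def put(self, fp, value) -> None:
        self._by_fp[fp] = value


def _certify_seed(food_closure: Closure, members: frozenset[str],
                  R: ReactionNetwork, tier: int,
                  cache: _ClosureCache | None = None
                  ) -> tuple[SeedSet, SDAS | None, Closure | None]:
    """Expand + partition + LP-test one candidate seed set."""
    kind = "singleton" if len(members) == 1 else "composite"
    try:
        closure, s1, r1 = induced_subnetwork(food_closure, members, R)
    except DetectionError:
        raise
    if not r1:
        return SeedSet(members, kind, "not-a-seed"), None, closure
    fp = closure.fingerprint
    if cache is not None:
        hit = cache.get(fp)
        if hit is not None:
            lp, sdas = hit
            if sdas is not None:
                seed = SeedSet(members, kind, "supported")
                return seed, sdas, closure
            return SeedSet(members, kind, "not-a-seed"), None, closure
    M = internal_partition(food_closure, members, R)
    lp = is_autocatalytic(M)
    if lp.feasible:
        sdas = SDAS(id="", species=frozenset(s1), reactions=frozenset(r1),
                    tier=tier, food=food_closure.species, seeds=(),
                    certificate=lp)
        seed = SeedSet(members, kind, "supported")
    else:
        sdas = None
        seed = SeedSet(members, kind, "not-a-seed")
    if cache is not None:
        cache.put(fp, (lp, sdas))
    return seed, sdas, closure


def scan_singleton_seeds(food_closure: Closure, R: ReactionNetwork,
                         candidates: Iterable[str] | None = None,
                         tier: int = 1) -> list[tuple[SeedSet, SDAS]]:
    """Scan candidate species one by one for singleton supported seeds.

    ``candidates`` defaults to every species of the network not in the food
    closure.  For each candidate the food-plus-seed closure is expanded,
    partitioned, and LP-tested; outcomes are cached by closure fingerprint,
    so clique members share a single solve.  The result is sorted by
    candidate id and independent of scanning order.
    """
    if candidates is None:
        candidates = set(R.species) - food_closure.species
    else:
        candidates = set(candidates)
        overlap = candidates & food_closure.species
        if overlap:
            raise DetectionError(
                f"candidates {sorted(overlap)} are already food")
    cache = _ClosureCache()
    out: list[tuple[SeedSet, SDAS]] = []
    for cand in sorted(candidates):
        seed, sdas, _ = _certify_seed(food_closure, frozenset({cand}), R,
                                      tier, cache)
        if seed.support == "supported" and sdas is not None:
            out.append((seed, sdas))
    return out


def find_composite_seeds(food_closure: Closure, R: ReactionNetwork,
                         pairs: Iterable[tuple[str, str]] | None = None,
                         failed_singletons: Iterable[str] | None = None,
                         tier: int = 1) -> list[tuple[SeedSet, SDAS]]:
    """Search species pairs for minimal composite supported seeds.

    By default the pairs are all combinations of ``failed_singletons``
    (species whose singleton scan failed); a pair qualifies only if it
    jointly passes the LP test while neither member alone is a seed
    (minimality, re-checked here).
    """
    cache = _ClosureCache()

    def singleton_is_seed(sp: str) -> bool:
        seed, sdas, _ = _certify_seed(food_closure, frozenset({sp}), R, tier, cache)
        return seed.support == "supported"

    if pairs is None:
        if failed_singletons is None:
            failed_singletons = [
                sp for sp in sorted(set(R.species) - food_closure.species)
                if not singleton_is_seed(sp)]
        pairs = itertools.combinations(sorted(set(failed_singletons)), 2)

    out: list[tuple[SeedSet, SDAS]] = []
    for a, b in pairs:
        members = frozenset({a, b})
        if len(members) != 2:
            continue
        if members & food_closure.species:
            raise DetectionError(f"pair {sorted(members)} overlaps the food set")
        if singleton_is_seed(a) or singleton_is_seed(b):
            continue  # non-minimal: a proper subset is already a seed
        seed, sdas, _ = _certify_seed(food_closure, members, R, tier, cache)
        if seed.support == "supported" and sdas is not None:
            out.append((seed, sdas))
    return sorted(out, key=lambda t: tuple(sorted(t[0].members)))


def group_cliques(seed_sdas_pairs: Sequence[tuple[SeedSet, SDAS]],
                  food_closure: Closure | None = None,
                  R: ReactionNetwork | None = None) -> list[Clique]:
    """Partition singleton supported seeds into cliques by exact equality of
    their induced SDAS (species set, reaction set)."""
    groups: dict[tuple[frozenset[str], frozenset[str]],
                 tuple[list[str], SDAS]] = {}
    for seed, sdas in seed_sdas_pairs:
        if seed.kind != "singleton" or seed.support != "supported":
            raise DetectionError(
                "cliques are defined over singleton supported seeds only")
        fp = sdas.fingerprint
        if fp in groups:
            groups[fp][0].extend(seed.members)
        else:
            groups[fp] = (list(seed.members), sdas)
    cliques = []
    for fp, (members, sdas) in groups.items():
        seeds = frozenset(members)
        enriched = SDAS(id=sdas.id, species=sdas.species,
                        reactions=sdas.reactions, tier=sdas.tier,
                        food=sdas.food,
                        seeds=tuple(SeedSet(frozenset({s}), "singleton",
                                            "supported")
                                    for s in sorted(seeds)),
                        certificate=sdas.certificate)
        cliques.append(Clique(seeds=seeds, sdas=enriched))
    # Largest clique first, ties broken by smallest member id.
    return sorted(cliques, key=lambda c: (-len(c.seeds), min(c.seeds)))


def classify_unsupported_seeds(candidates: Iterable[str],
                               known_sdass: Sequence[SDAS],
                               food_closure: Closure,
                               R: ReactionNetwork) -> dict[str, SDAS]:
    """Map candidate species to the SDAS they induce without being produced
    by it.

    ``X`` is an unsupported seed of SDAS ``Y`` iff ``X`` is not one of
    ``Y``'s species and the closure of food + {X} contains all of ``Y``'s
    reactions.  When nested SDASs qualify, ``X`` is assigned to the maximal
    one by reaction-set inclusion.
    """
    ranked = sorted(known_sdass, key=lambda s: -len(s.reactions))
    supported: set[str] = set()
    for s in ranked:
        for seed in s.seeds:
            supported |= seed.members
    out: dict[str, SDAS] = {}
    for cand in sorted(set(candidates)):
        if cand in food_closure.species or cand in supported:
            continue
        closure = network_expand(food_closure.species | {cand}, R)
        for sdas in ranked:
            if cand not in sdas.species and sdas.reactions <= closure.reactions:
                out[cand] = sdas
                break
    return out


# ---------------------------------------------------------------------------
# Tiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierConfig:
    """Policy for iterated tier construction.

    ``max_tier`` bounds the number of scans; ``pair_search`` additionally
    looks for composite pair seeds among failed singletons at each tier;
    ``activate`` chooses which detected SDASs feed the next tier
    ("all" is the default and only built-in policy).
    """

    max_tier: int = 10
    pair_search: bool = False
    candidates: frozenset[str] | None = None
    activate: str = "all"


@dataclass(frozen=True)
class TierLevel:
    tier: int
    food_closure: Closure
    cliques: tuple[Clique, ...]
    sdass: tuple[SDAS, ...]
    composite_seeds: tuple[tuple[SeedSet, SDAS], ...] = ()
    unsupported: Mapping[str, str] = field(default_factory=dict)


def build_tiers(S_U: Iterable[str], R: ReactionNetwork,
                config: TierConfig = TierConfig()) -> list[TierLevel]:
    """Iterated trophic construction.

    Tier 0 is the closure of the ultimate food.  Each subsequent tier scans
    all species outside the current food for singleton supported seeds,
    groups them into cliques, then treats the union of every detected
    SDAS's species as additional food (re-expanded, since SDASs may jointly
    enable further reactions) and repeats, stopping when a scan finds no
    seed or ``max_tier`` is reached.
    """
    t0 = tier0(S_U, R)
    levels = [TierLevel(tier=0, food_closure=t0, cliques=(), sdass=())]
    food = t0
    for t in range(1, config.max_tier + 1):
        cands = config.candidates
        if cands is not None:
            cands = frozenset(cands) - food.species
        pairs = scan_singleton_seeds(food, R, candidates=cands, tier=t)
        cliques = group_cliques(pairs)
        sdass = []
        for i, clique in enumerate(cliques):
            sdas = clique.sdas
            sdass.append(SDAS(id=f"sdas-t{t}-{i}", species=sdas.species,
                              reactions=sdas.reactions, tier=t,
                              food=sdas.food, seeds=sdas.seeds,
                              certificate=sdas.certificate))
        cliques = [Clique(seeds=c.seeds, sdas=s)
                   for c, s in zip(cliques, sdass)]
        composites: tuple[tuple[SeedSet, SDAS], ...] = ()
        if config.pair_search:
            composites = tuple(find_composite_seeds(food, R, tier=t))
        if not cliques and not composites:
            break
        non_food = set(R.species) - food.species
        unsup = classify_unsupported_seeds(non_food, sdass, food, R)
        levels.append(TierLevel(
            tier=t, food_closure=food, cliques=tuple(cliques),
            sdass=tuple(sdass), composite_seeds=composites,
            unsupported={sp: sd.id for sp, sd in unsup.items()}))
        activated = set().union(*(s.species for s in sdass)) if sdass else set()
        for seed, sdas in composites:
            activated |= sdas.species
        food = network_expand(food.species | activated, R)
    return levels
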
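# Methods

This note records the model, the algorithmic and numerical choices, and
the limitations of the `sdas` package in enough detail to reproduce or
audit any result it emits.

## Model and assumptions

The object of study is a *reaction universe*: a finite set of
unidirectional reactions with strictly positive stoichiometric
coefficients, optional explicit catalysts, and a designated *ultimate
food* set of species assumed continuously supplied by an open
environment. The model is purely topological/stoichiometric: no kinetics,
no thermodynamics, no concentrations. Openness is modelled by the
assumptions that (a) food is freely available, and (b) every non-food
species is subject to dilution, so a subnetwork can persist only if it
can net-produce all of its internal species — stoichiometric
autocatalysis.

Conventions baked into the data model:

* Reversible reactions exist only at the input boundary; they are split
  into `.a` (forward) / `.b` (reverse) unidirectional pairs before any
  analysis, with catalysts preserved on both directions.
* A species written with equal coefficients on both sides of an equation
  is explicit catalysis and is normalised into the catalyst set; with
  unequal coefficients only the net difference enters the matrix and the
  species remains an ordinary reactant/product (so `A + F -> 2A` nets +1
  on A while still *requiring* A).
* Catalysts gate both network expansion and motif membership but carry
  zero stoichiometric entries and are never added as products.
* Species identity is by string id; no chemical canonicalisation. Energy
  pseudo-species (light) are ordinary rows; the optional mass-balance
  validator skips any reaction touching a pseudo-species or a species of
  unknown mass.
* Coefficients are floats with a zero tolerance of 1e-9.

## Expansion

Ξ(S₀, R) is computed with a counting/queue scheme: each reaction tracks
how many required species (reactants + catalysts) are still missing and
is indexed by those species, so the closure costs O(total reaction arity)
rather than |R| passes. Reactions fire in waves — products enter the
species set only after a whole wave has been scanned — and the wave index
is recorded per reaction as its *generation*, which is provenance only
and never affects the fixpoint. The fixpoint is unique and
order-independent; this is asserted by seeded-shuffle property tests.

## Detection LP

For a food closure (S₀, R₀) and seed H, the internal subnetwork is the
set difference of Ξ(S₀ ∪ H, R) against (S₀, R₀), and the partitioned
matrix places food rows/columns first. The certifier solves the phase-1
feasibility LP

    find x ≥ 0  with  Σ_j x_j s_ij ≥ 1  for all internal rows i

with HiGHS (`scipy.optimize.linprog`, method `highs`, primal tolerance
1e-7); flux entries below 1e-9 are clipped to zero for reporting. The
`≥ 1` form is used instead of the strict `> 0` form because any strict
solution rescales to it, and feasibility LPs are numerically cleaner than
the historical unbounded-objective probe (maximise net production of the
first internal species and detect unboundedness), which is retained as
`mode="objective"` for cross-checking — the two verdicts are asserted
equal in tests. An internal partition with no internal columns is
infeasible by convention (`empty-internal`): a candidate that fires no
new reaction is not a seed.

A seed whose LP is feasible is *supported* automatically: the constraint
forces net production of every internal species, including the seed
itself. Cliques are grouped by exact closure fingerprint (species set,
reaction set), which also keys a per-scan cache so clique members share
one LP solve. Composite pair search re-checks minimality (both singletons
must individually fail). Unsupported-seed classification is by closure
containment: X is an unsupported seed of a known SDAS Y iff X ∉ Y and
Ξ(S₀ ∪ {X}) ⊇ Y's reactions, assigned to the maximal such Y by
reaction-set inclusion when SDASs are nested — the containment rule is
this package's operationalisation of "triggers a SDAS without being
produced by it", which the source literature defines but does not give an
algorithm for.

Tier construction iterates: scan, group cliques, then re-expand the food
with the union of all detected SDAS species (re-expansion matters —
jointly activated SDASs may enable reactions none enables alone), until a
scan finds nothing or `max_tier` is reached. Candidates at every tier are
all species outside the current food; species belonging to lower-tier
SDASs are food, hence excluded.

## Motif integer program

Within a certified SDAS the minimum-cardinality autocatalytic motifs are
found with a MILP over continuous fluxes x, binary column selectors z and
binary species indicators y:

    min Σ z_j   s.t.   x_j ≤ β_j z_j,
                       Σ_j x_j s_ij ≥ 1 − M_i (1 − y_i),
                       y_i ≥ z_j  for i ∈ Ω_j,
                       Σ z_j ≥ D,  x ≥ 0

with M_i = 1 − Σ_{j: s_ij<0} β_j s_ij, which makes the production
constraint vacuous over the whole flux box when y_i = 0 (asserted
numerically in tests). **Ω_j is the set of internal species the reaction
*requires*: its written reactants plus its catalysts.** Two deliberate
consequences:

* requirements are taken from the written reaction, not from negative net
  entries — a net-autocatalytic column like `A + F -> 2A` requires A;
* internal species that selected reactions only *produce* are not forced
  into the motif; they are reported as the motif's **waste**. Forcing
  them in would cost nothing in feasibility (they are net-produced
  trivially) but would erase the member/waste distinction that the
  ecology layer (mutualism = feeding on waste) depends on.

Numerical choices: backend is HiGHS branch-and-bound via
`scipy.optimize.milp` with `mip_rel_gap = 0`, so optimality is proven;
β_j defaults to 1000 for all reactions (configurable globally or per
reaction) — large enough for every instance exercised here, and a
post-solve warning fires if any certificate flux comes within 1% of β
(the bound may be binding and the motif suspect). An infeasible MILP on a
certified SDAS is reported as "β too small" rather than silently
accepted. Because the MILP's incumbent fluxes are arbitrary feasible
values, each returned motif's certificate is re-solved as a small LP
(minimise total flux over the selected columns subject to the member
production constraints) and then normalised so the smallest member net
production equals 1; the production constraint is re-checked
arithmetically before the motif is returned. Enumeration adds no-good
cuts Σ_{j∈T} z_j ≤ |T|−1 and repeats until the optimum increases,
infeasibility, or `max_solutions`; results are sorted by lexicographic
reaction-id order so solver tie-breaking never shows. A brute-force
subset oracle (all subsets by increasing cardinality, each checked with
the restricted LP) covers instances up to 15 internal reactions and is
asserted to agree with the MILP on every fixture and on random
partitions.

## Ecology and scaffolding

Interaction labels follow fixed witness rules: *competition* = a common
food species consumed by both SDASs' reactions; *predation–parasitism* =
the higher SDAS consumes a motif member of the lower; *mutualism* = the
higher SDAS consumes a motif waste species of the lower. When no motif
list is supplied, all lower-SDAS species are conservatively treated as
members, which suppresses mutualism labels. *Catalytic facilitation* is
reported only as candidate composite paths — a higher-tier species
consumed by one reaction and fully regenerated by another (1:1 flux)
whose combined net conversion equals an existing single reaction not
involving that species — because whether the composite path actually
accelerates the conversion depends on kinetics outside the model; the
heuristic is a stated approximation, not an established algorithm.
Scaffolding is probed by ablation: delete chosen reactions, re-expand,
re-certify; an empty removal set reproduces plain detection exactly.

## Synthetic tiered networks

The generator plants, per tier, autocatalytic cycles
X₁ → X₂ → … → X_k → 2X₁ in which every step consumes one food species
(for tiers above the first, `cross_tier_food_edges` steps consume a
member of the previous tier's cycle, making activation genuinely
tier-dependent) and the closing step doubles X₁. By construction every
cycle member is a supported singleton seed, all members form one clique,
the whole k-cycle is the unique minimal motif, and a `waste_fraction` of
steps emit a byproduct that is provably waste. Waste-emitting steps
consume one extra food unit so that integer pseudo-masses stay exactly
balanced (the mass validator returns no violations on any generated
network). Decoy chains D₁ → D₂ are reachable only by seeding and never
self-sustaining. Defaults (2 tiers, 8 species per tier, motif sizes 2–4,
waste fraction 0.3, 1 cross-tier edge, 2 decoys, 3 food species) give
small, fully checkable universes; identical `rng_seed` reproduces the
identical network.

What the generator does *not* emulate: the right-skewed power-law degree
distributions of real reaction databases, shared intermediates between
planted cycles, nested SDASs, or unsupported seeds. Passing recovery
tests therefore demonstrates correctness of the detection machinery on
known ground truth, not performance claims about real chemistries. Note
also that with `cross_tier_food_edges = 0` an upper-tier cycle feeds on
ultimate food only and is then legitimately detectable at tier 1; tests
and the acceptance script use ≥ 1.

## Problem sizes and scope

All shipped analyses run on embedded toys (≤ 12 species), reconstructed
worked examples and generated networks of a few hundred reactions; a full
acceptance run takes a few seconds. The full published abiotic
(277 species / 717 reactions) and biochemical (4216 / 8402) databases are
journal supplementary files not redistributed here; the loader, scanner
and pipeline accept them directly (tabular dialect, reversible splitting,
catalyst whitelist merged into the food set) and the end-to-end test in
`tests/test_acceptance.py` documents the expected numbers. The expansion
and scan scale near-linearly and the per-candidate LP is polynomial;
only exhaustive composite-seed search beyond pairs and the biochemical
full-database motif MILP are expected to be expensive, and neither is
attempted by default.

Other known limitations: no SBML I/O; no kinetic viability assessment
(a certified SDAS may still be washed out if its reactions are slow); no
checkpoint/resume for interrupted scans (in-memory closure-fingerprint
caching only); composite seeds are searched as pairs only; "same SDAS"
means exact set equality — nested SDASs are distinct records.
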
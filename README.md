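# sdas — seed-dependent autocatalytic systems in reaction networks

`sdas` detects and analyses **seed-dependent autocatalytic systems
(SDASs)** in stoichiometric chemical reaction networks: subnetworks that
cannot arise by network expansion from a food set alone but, once triggered
by a transient chemical *seed*, can stoichiometrically regenerate every one
of their internal species from food. Such systems are central to
metabolism-first accounts of the origin of life, where a food-driven
chemistry complexifies step by step as rare seeding events switch on
successively higher trophic tiers of autocatalysis.

The package is aimed at researchers in systems chemistry, origins-of-life
modelling and metabolic network analysis who work with reaction databases
(tabular TSV/CSV/XLSX or plain-text equations) and want exact,
certificate-backed answers rather than heuristics.

## The model

A reaction universe is a set *R* of unidirectional reactions over species
*S*; reversible reactions are split into `.a`/`.b` direction pairs. Two
primitives drive everything:

1. **Network expansion** Ξ(S₀, R): iteratively add every reaction whose
   reactants *and explicit catalysts* are all available, then add its
   products, until fixpoint. The closure of the *ultimate food* S_U is the
   tier-0 system (S₀, R₀) — everything reachable without a seed.

2. **Stoichiometric autocatalysis.** Adding a candidate seed H and
   re-expanding yields an internal subnetwork (S₁, R₁) = Ξ(S₀ ∪ H, R) \
   (S₀, R₀). Writing s_ij for the net stoichiometric matrix (external food
   rows first, internal rows i ∈ [p, m]; internal reaction columns
   j ∈ [q, n]), H induces a SDAS iff there are fluxes x ≥ 0 with

       Σ_j x_j s_ij ≥ 1   for every internal species i,

   i.e. every internal species is net-produced with excess from freely
   available food. This is a linear-programming feasibility problem
   (HiGHS); the strict form Σ_j x_j s_ij > 0 is equivalent by rescaling.
   Explicit catalysts contribute zero stoichiometry but gate both the
   expansion and motif membership.

On top of the certifier the package provides:

* **seed scanning** — all singleton supported seeds, grouped into
  **cliques** (seeds whose food-plus-seed closures are identical induce
  the same SDAS), plus minimal composite pair seeds and **unsupported
  seeds** (species that trigger a SDAS without being produced by it);
* **trophic tiers** — each detected SDAS's species become food for the
  next scan, yielding a tier hierarchy;
* **minimal autocatalytic motifs** — the smallest reaction subsets T
  inside a SDAS whose required internal species are all net-produced,
  found by a mixed-integer program (binary selection z_j, membership y_i,
  big-M production constraints, objective min Σ z_j, optimality gap 0) and
  enumerated exhaustively with no-good cuts; motif byproducts that no
  selected reaction consumes are reported as **waste**;
* **ecology** — competition / predation–parasitism / mutualism /
  catalytic-facilitation labels for SDAS pairs, and reaction-removal
  ablation to probe **scaffolding** (structures needed to activate, but
  not to maintain, a higher tier).

## Worked example

The registered fixture `fig1_like` is a small tiered universe with
ultimate food {F0, F2} (see `sdas.fixtures`). The tier hierarchy:

```console
$ sdas tiers --db toy:fig1_like
tier	cliques	sdas	species	reactions
0	-	tier0	3	1
1	A1,A2	sdas-t1-0	3	3
2	B1,B2	sdas-t2-0	3	2
3	C1	sdas-t3-0	1	1
```

Tier 0 is the food closure {F0, F1, F2} with the single reaction R0.
Seeding A1 (or A2 — one clique) switches on the three-reaction tier-1
SDAS; its species then feed tier 2, whose waste species B3 in turn feeds
the tier-3 system (a mutualistic interaction). Certifying the tier-1 seed
directly:

```console
$ sdas detect --db toy:fig1_like --seed A1
verdict	SDAS
status	Optimization terminated successfully. (HiGHS Status 7: Optimal)
internal_species	3
internal_reactions	3
flux	R1	4
flux	R2	5
flux	R3	1
```

The flux certificate (4, 5, 1) over (R1, R2, R3) is the net conversion
4 F1 + 5 F2 → A1 + A2 + A3: every internal species is produced with
excess, so the system can out-run dilution once seeded. The smallest
motif inside it:

```console
$ sdas motifs --db toy:fig1_like --seed A1 --enumerate
motif	size	reaction	flux	members	waste
motif-0	2	R1	3	A1;A2	
motif-0	2	R2	4	A1;A2	
```

The two-reaction A1/A2 cycle is the self-amplifying core; A3 is a derived
SDAS species outside the motif.

The same machinery runs on full databases
(`sdas scan-seeds --db reactions.xlsx --food food.txt`), and
`sdas generate` produces random tiered networks with planted cycles and a
ground-truth JSON for benchmarking.

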
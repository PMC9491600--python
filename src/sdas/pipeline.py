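"""End-to-end run orchestration.

A :class:`RunConfig` names the database, the ultimate food, the
always-available catalyst whitelist, the candidate policy and solver
settings.  :func:`run_pipeline` executes food closure -> per-tier seed scan
-> LP certification -> clique grouping -> motif enumeration -> interaction
classification, and writes TSV tables, a machine-readable ``summary.json``
and the resolved config into the output directory.  Re-running the same
config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .core import ReactionNetwork
from .detect import TierConfig, TierLevel, build_tiers
from .ecology import classify_interaction
from .fixtures import toy
from .io import load_database
from .motifs import MotifSearchConfig, enumerate_min_motifs
from .detect import internal_partition

log = logging.getLogger("sdas")


@dataclass
class RunConfig:
    """Serialisable description of one analysis run.

    ``database`` is a file path, or ``toy:<name>`` for a registered toy
    network (in which case ``food`` defaults to the toy's food set).
    ``whitelist`` lists species assumed freely available (environmental
    catalysts such as metals and minerals); they are merged into the food
    set.  ``candidate_policy`` is ``singletons`` or ``singletons+pairs``.
    """

    database: str
    food: list[str] = field(default_factory=list)
    dialect: str | None = None
    species_table: str | None = None
    whitelist: list[str] = field(default_factory=list)
    candidate_policy: str = "singletons"
    max_tier: int = 10
    beta: float = 1000.0
    max_motifs: int = 50
    motif_min_reactions: int = 1
    enumerate_motifs: bool = True
    out_dir: str = "sdas-run"
    rng_seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _load(config: RunConfig) -> tuple[ReactionNetwork, frozenset[str]]:
    if config.database.startswith("toy:"):
        t = toy(config.database[4:])
        food = frozenset(config.food) if config.food else t.food
        return t.network, food
    net = load_database(config.database, dialect=config.dialect,
                        species_path=config.species_table)
    return net, frozenset(config.food)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis described by ``config``.

    Returns the output directory, which contains ``config.json`` (resolved),
    ``tier0.tsv``, ``seeds.tsv``, ``sdas_membership.tsv``, ``motifs.tsv``,
    ``interactions.tsv``, ``summary.json`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.verbosity.upper())
    stderr = logging.StreamHandler(sys.stderr)
    log.addHandler(stderr)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    config.to_json(out / "config.json")
    net, food = _load(config)
    food = food | frozenset(config.whitelist)
    log.info("loaded %d species / %d reactions; food+whitelist = %d species",
             len(net.species), len(net.reactions), len(food))

    tier_cfg = TierConfig(max_tier=config.max_tier,
                          pair_search=(config.candidate_policy
                                       == "singletons+pairs"))
    levels = build_tiers(food, net, tier_cfg)

    t0 = levels[0].food_closure
    _write_tsv(out / "tier0.tsv", ["kind", "id"],
               [["species", s] for s in sorted(t0.species)]
               + [["reaction", r] for r in sorted(t0.reactions)])

    seed_rows, member_rows, motif_rows, interaction_rows = [], [], [], []
    motif_cfg = MotifSearchConfig(beta=config.beta,
                                  min_reactions=config.motif_min_reactions,
                                  max_solutions=config.max_motifs)
    sdas_motifs = {}
    for level in levels[1:]:
        for clique_idx, clique in enumerate(level.cliques):
            sdas = clique.sdas
            for sp in sorted(clique.seeds):
                seed_rows.append([sp, "supported", f"t{level.tier}-c{clique_idx}",
                                  sdas.id])
            for sp in sorted(sdas.species):
                member_rows.append([sdas.id, "species", sp])
            for rid in sorted(sdas.reactions):
                member_rows.append([sdas.id, "reaction", rid])
            if config.enumerate_motifs:
                M = internal_partition(level.food_closure,
                                       [sorted(clique.seeds)[0]], net)
                motifs = enumerate_min_motifs(M, motif_cfg)
                sdas_motifs[sdas.id] = (sdas, motifs)
                for k, m in enumerate(motifs):
                    for rid in sorted(m.reactions):
                        motif_rows.append([sdas.id, f"motif-{k}", m.size, rid,
                                           f"{m.flux.get(rid, 0.0):.6g}",
                                           ";".join(sorted(m.waste))])
        for sp, sid in sorted(level.unsupported.items()):
            seed_rows.append([sp, "unsupported", "", sid])
        for seed, sdas in level.composite_seeds:
            seed_rows.append(["+".join(sorted(seed.members)), "composite",
                              "", sdas.id])

    # pairwise interactions between SDASs of adjacent tiers
    all_sdas = [s for level in levels[1:] for s in (c.sdas for c in level.cliques)]
    for low in all_sdas:
        for high in all_sdas:
            if high.tier <= low.tier:
                continue
            motifs = sdas_motifs.get(low.id, (None, []))[1]
            rep = classify_interaction(low, high, motifs, net)
            if rep.labels:
                interaction_rows.append([low.id, high.id,
                                         ";".join(sorted(rep.labels))])

    _write_tsv(out / "seeds.tsv", ["species", "status", "clique", "sdas"],
               seed_rows)
    _write_tsv(out / "sdas_membership.tsv", ["sdas", "kind", "id"], member_rows)
    _write_tsv(out / "motifs.tsv",
               ["sdas", "motif", "size", "reaction", "flux", "waste"],
               motif_rows)
    _write_tsv(out / "interactions.tsv", ["lower", "higher", "labels"],
               interaction_rows)

    summary = {
        "n_species": len(net.species),
        "n_reactions": len(net.reactions),
        "tier0": {"species": len(t0.species), "reactions": len(t0.reactions)},
        "tiers": [
            {
                "tier": lvl.tier,
                "cliques": [sorted(c.seeds) for c in lvl.cliques],
                "sdas": [
                    {"id": c.sdas.id, "species": len(c.sdas.species),
                     "reactions": len(c.sdas.reactions)}
                    for c in lvl.cliques],
                "unsupported_seeds": len(lvl.unsupported),
                "composite_seeds": len(lvl.composite_seeds),
            }
            for lvl in levels[1:]
        ],
        "motifs": {
            sid: {"count": len(motifs),
                  "min_size": min((m.size for m in motifs), default=0)}
            for sid, (_s, motifs) in sorted(sdas_motifs.items())
        },
        "interactions": [
            {"lower": r[0], "higher": r[1], "labels": r[2].split(";")}
            for r in interaction_rows],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    log.info("run complete: %d tier(s) with seeds, summary at %s",
             len(levels) - 1, out / "summary.json")
    return out
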
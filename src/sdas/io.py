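"""Reading and writing reaction databases.

Two dialects are supported, chosen by file extension or forced with the
``dialect`` argument:

``equations``
    Plain text, one reaction per line, ``#`` comments::

        R1: A + F -> 2 A
        R2: B + C <=> A | cat: U

    The ``id:`` prefix is optional; without it the rendered equation is the
    reaction id.

``table``
    TSV/CSV/XLSX with a header row.  Required columns: ``reaction_id`` and
    either ``equation`` or the pair ``reactants``/``products`` (terms like
    ``2 A + F``).  Optional columns: ``catalysts`` (comma separated),
    ``reversible`` (truthy values: 1/true/yes, or a ``<=>`` arrow in the
    equation), ``origin``.

Reversible rows are split into ``.a``/``.b`` unidirectional pairs on load
by default.  An optional species table (TSV/CSV/XLSX with columns
``species_id`` and optionally ``name``, ``formula``, ``mass``,
``is_pseudo``) attaches masses and pseudo-species flags.  ``load`` after
``write`` is the identity on species ids, reaction stoichiometries and
catalyst sets.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .core import (NetworkError, Reaction, ReactionNetwork, ReactionParseError,
                   Species, format_equation, parse_reaction)

_TABLE_EXT = {".tsv": "\t", ".csv": ","}
_TRUTHY = {"1", "true", "yes", "y", "t"}


def _sniff_dialect(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".txt", ".eq", ".reactions"):
        return "equations"
    if ext in _TABLE_EXT or ext == ".xlsx":
        return "table"
    return "equations"


def _read_table(path: Path) -> pd.DataFrame:
    ext = path.suffix.lower()
    if ext == ".xlsx":
        return pd.read_excel(path, dtype=str)
    sep = _TABLE_EXT.get(ext, "\t")
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _parse_terms(text: str, rid: str, role: str) -> dict[str, float]:
    side = parse_reaction(f"{text} -> __dummy__", id="__side__") \
        if role == "reactants" else \
        parse_reaction(f"__dummy__ -> {text}", id="__side__")
    return dict(side.reactants if role == "reactants" else side.products)


def _is_nan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or \
        (isinstance(v, str) and not v.strip())


def load_database(path: str | Path, dialect: str | None = None,
                  split: bool = True,
                  species_path: str | Path | None = None) -> ReactionNetwork:
    """Load a reaction database.

    ``split=True`` (default) replaces every reversible row with its
    ``.a``/``.b`` unidirectional pair, the form all analyses expect.
    An empty file yields an empty network.
    """
    path = Path(path)
    dialect = dialect or _sniff_dialect(path)
    net = ReactionNetwork()
    if species_path is not None:
        for sp in _load_species(Path(species_path)):
            net.add_species(sp)

    if dialect == "equations":
        for lineno, raw in enumerate(path.read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            rid = None
            if ":" in line and "->" not in line.split(":", 1)[0] \
                    and "|" not in line.split(":", 1)[0]:
                head, _, rest = line.partition(":")
                rid, line = head.strip(), rest.strip()
            try:
                net.add_reaction(parse_reaction(line, id=rid))
            except (ReactionParseError, NetworkError) as e:
                raise type(e)(f"{path.name}:{lineno}: {e}") from None
    elif dialect == "table":
        df = _read_table(path)
        if len(df) > 0:
            cols = {c.lower().strip(): c for c in df.columns}
            if "reaction_id" not in cols:
                raise NetworkError(
                    f"{path.name}: missing required column 'reaction_id' "
                    f"(found: {sorted(cols)})")
            has_eq = "equation" in cols
            if not has_eq and not ("reactants" in cols and "products" in cols):
                raise NetworkError(
                    f"{path.name}: need an 'equation' column or both "
                    "'reactants' and 'products' columns")
            for _, row in df.iterrows():
                rid = row[cols["reaction_id"]]
                if _is_nan(rid):
                    raise NetworkError(f"{path.name}: empty reaction_id")
                rid = str(rid).strip()
                cats = frozenset()
                if "catalysts" in cols and not _is_nan(row[cols["catalysts"]]):
                    cats = frozenset(
                        t.strip() for t in str(row[cols["catalysts"]]).split(",")
                        if t.strip())
                reversible = False
                if "reversible" in cols and not _is_nan(row[cols["reversible"]]):
                    reversible = str(row[cols["reversible"]]).strip().lower() \
                        in _TRUTHY
                origin = None
                if "origin" in cols and not _is_nan(row[cols["origin"]]):
                    origin = str(row[cols["origin"]]).strip()
                if has_eq:
                    r = parse_reaction(str(row[cols["equation"]]), id=rid)
                    reversible = reversible or r.reversible
                    r = Reaction(id=rid, reactants=dict(r.reactants),
                                 products=dict(r.products),
                                 catalysts=r.catalysts | cats,
                                 reversible=reversible, origin=origin)
                else:
                    r = Reaction(
                        id=rid,
                        reactants=_parse_terms(
                            str(row[cols["reactants"]]), rid, "reactants"),
                        products=_parse_terms(
                            str(row[cols["products"]]), rid, "products"),
                        catalysts=cats, reversible=reversible, origin=origin)
                net.add_reaction(r)
    else:
        raise NetworkError(f"unknown dialect {dialect!r}")

    if split:
        net = net.split_all_reversible()
    return net


def _load_species(path: Path) -> list[Species]:
    df = _read_table(path)
    if len(df) == 0:
        return []
    cols = {c.lower().strip(): c for c in df.columns}
    if "species_id" not in cols:
        raise NetworkError(f"{path.name}: missing required column 'species_id'")
    out = []
    for _, row in df.iterrows():
        mass = None
        if "mass" in cols and not _is_nan(row[cols["mass"]]):
            mass = float(row[cols["mass"]])
        pseudo = False
        if "is_pseudo" in cols and not _is_nan(row[cols["is_pseudo"]]):
            pseudo = str(row[cols["is_pseudo"]]).strip().lower() in _TRUTHY
        out.append(Species(
            id=str(row[cols["species_id"]]).strip(),
            name=None if "name" not in cols or _is_nan(row[cols["name"]])
            else str(row[cols["name"]]).strip(),
            formula=None if "formula" not in cols or _is_nan(row[cols["formula"]])
            else str(row[cols["formula"]]).strip(),
            mass=mass, is_pseudo=pseudo))
    return out


def write_database(net: ReactionNetwork, path: str | Path,
                   dialect: str | None = None) -> None:
    """Write a network; the inverse of :func:`load_database` on species ids,
    stoichiometries and catalyst sets."""
    path = Path(path)
    dialect = dialect or _sniff_dialect(path)
    if dialect == "equations":
        lines = [f"{rid}: {format_equation(r)}"
                 for rid, r in sorted(net.reactions.items())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif dialect == "table":
        rows = []
        for rid, r in sorted(net.reactions.items()):
            rows.append({
                "reaction_id": rid,
                "equation": format_equation(r),
                "catalysts": ", ".join(sorted(r.catalysts)),
                "reversible": "1" if r.reversible else "0",
                "origin": r.origin or "",
            })
        df = pd.DataFrame(rows, columns=["reaction_id", "equation",
                                         "catalysts", "reversible", "origin"])
        ext = path.suffix.lower()
        if ext == ".xlsx":
            df.to_excel(path, index=False)
        else:
            df.to_csv(path, sep=_TABLE_EXT.get(ext, "\t"), index=False)
    else:
        raise NetworkError(f"unknown dialect {dialect!r}")


def write_species(net: ReactionNetwork, path: str | Path) -> None:
    """Write the species table (id, name, formula, mass, is_pseudo)."""
    path = Path(path)
    rows = [{
        "species_id": sid,
        "name": sp.name or "",
        "formula": sp.formula or "",
        "mass": "" if sp.mass is None else sp.mass,
        "is_pseudo": "1" if sp.is_pseudo else "0",
    } for sid, sp in sorted(net.species.items())]
    df = pd.DataFrame(rows, columns=["species_id", "name", "formula",
                                     "mass", "is_pseudo"])
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, sep=_TABLE_EXT.get(path.suffix.lower(), "\t"),
                  index=False)
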
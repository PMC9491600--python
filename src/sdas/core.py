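"""Core data model for stoichiometric reaction networks.

This module defines the basic objects everything else is built on:

* :class:`Species` — a chemical entity, optionally carrying a mass and a
  flag for energy pseudo-species (visible light, infrared light, ...) that
  participate in reactions but have no molecular mass.
* :class:`Reaction` — a *unidirectional* stoichiometric transformation with
  an optional set of explicit catalysts.  Reversible reactions exist only
  transiently (as parsed); they are split into ``.a``/``.b`` unidirectional
  pairs before analysis.
* :class:`ReactionNetwork` — a set of species and reactions with referential
  integrity.
* :class:`StoichiometricMatrix` — the four-segment partitioned coefficient
  matrix (external food rows / internal rows x external reactions / internal
  reactions) on which autocatalysis is certified.

Conventions
-----------
Net stoichiometric entries are products minus reactants.  An explicit
catalyst contributes *zero* to the matrix but is recorded per-column in
``catalyst_requirements`` because it gates whether the reaction can run.
A species written with equal coefficients on both sides of an equation is
explicit catalysis and is normalised into the catalyst set; with unequal
coefficients only the net difference matters stoichiometrically and the
species stays an ordinary reactant/product (e.g. ``A + F -> 2 A``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Coefficients smaller than this are treated as zero during validation.
DEFAULT_TOL = 1e-9


class SdasError(Exception):
    """Base class for errors raised by this package."""


class ReactionParseError(SdasError):
    """A reaction-equation string does not match the grammar."""


class NetworkError(SdasError):
    """A network or reaction violates a structural invariant."""


class PartitionError(SdasError):
    """A stoichiometric-matrix partition violates the external/internal layout."""


@dataclass(frozen=True)
class Species:
    """A chemical species (or an energy pseudo-species).

    Parameters
    ----------
    id : str
        Unique identifier within a network.  Identity is purely by string;
        no chemical canonicalisation is attempted.
    name : str, optional
        Human-readable name; defaults to ``id``.
    formula : str, optional
        Free-form formula annotation.
    mass : float, optional
        Mass in atomic mass units.  ``None`` means unknown or, for
        pseudo-species, not applicable.
    is_pseudo : bool
        True for energy carriers such as visible or infrared light.
    """

    id: str
    name: str | None = None
    formula: str | None = None
    mass: float | None = None
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("species id must be a non-empty string")
        if self.name is None:
            object.__setattr__(self, "name", self.id)
        if self.mass is not None and self.mass < 0:
            raise NetworkError(f"species {self.id!r}: mass must be non-negative")


def _clean_coeffs(side: Mapping[str, float], rid: str, role: str,
                  tol: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for sp, coef in side.items():
        if not sp:
            raise NetworkError(f"reaction {rid!r}: empty species id in {role}")
        if coef <= tol:
            raise NetworkError(
                f"reaction {rid!r}: non-positive coefficient {coef!r} for "
                f"{role} {sp!r}")
        out[sp] = float(coef)
    return out


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric transformation.

    ``reactants`` and ``products`` map species id to a strictly positive
    coefficient.  ``catalysts`` are species required for the reaction to run
    but not consumed by it.  A species appearing on both sides with equal
    coefficients is moved into ``catalysts`` at construction time (it is
    explicit catalysis); unequal coefficients are kept as written and only
    the difference enters the stoichiometric matrix.

    ``reversible`` may only be True before :func:`split_reversible`; all
    stored reactions in an analysed network are unidirectional.
    """

    id: str
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    catalysts: frozenset[str] = frozenset()
    reversible: bool = False
    origin: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be a non-empty string")
        tol = DEFAULT_TOL
        reac = _clean_coeffs(self.reactants, self.id, "reactant", tol)
        prod = _clean_coeffs(self.products, self.id, "product", tol)
        cats = set(self.catalysts)
        # Equal coefficients on both sides == explicit catalysis.
        for sp in sorted(set(reac) & set(prod)):
            if abs(reac[sp] - prod[sp]) <= tol:
                del reac[sp]
                del prod[sp]
                cats.add(sp)
        if not reac:
            raise NetworkError(
                f"reaction {self.id!r}: no net reactants (identity or "
                "catalyst-only left-hand side)")
        if not prod:
            raise NetworkError(
                f"reaction {self.id!r}: no net products (identity or "
                "catalyst-only right-hand side)")
        overlap = cats & set(reac)
        if overlap:
            raise NetworkError(
                f"reaction {self.id!r}: catalysts {sorted(overlap)} also "
                "appear as net reactants; a catalyst is a requirement, not a "
                "consumed input")
        object.__setattr__(self, "reactants", dict(reac))
        object.__setattr__(self, "products", dict(prod))
        object.__setattr__(self, "catalysts", frozenset(cats))

    # -- convenience views -------------------------------------------------
    @property
    def required(self) -> frozenset[str]:
        """Species that must be present for the reaction to fire
        (reactants and catalysts alike)."""
        return frozenset(self.reactants) | self.catalysts

    @property
    def touched(self) -> frozenset[str]:
        """All species referenced by the reaction."""
        return frozenset(self.reactants) | frozenset(self.products) | self.catalysts

    def net(self) -> dict[str, float]:
        """Net stoichiometry: products minus reactants (catalysts excluded)."""
        out: dict[str, float] = {}
        for sp, c in self.products.items():
            out[sp] = out.get(sp, 0.0) + c
        for sp, c in self.reactants.items():
            out[sp] = out.get(sp, 0.0) - c
        return {sp: v for sp, v in out.items() if abs(v) > DEFAULT_TOL}

    def reversed(self, new_id: str | None = None) -> "Reaction":
        return Reaction(
            id=new_id or self.id,
            reactants=dict(self.products),
            products=dict(self.reactants),
            catalysts=self.catalysts,
            reversible=False,
            origin=self.origin,
        )


# ---------------------------------------------------------------------------
# Equation grammar
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "->")
# split terms on '+' surrounded by whitespace so ids like NAD+ survive
_TERM_SPLIT = re.compile(r"\s\+\s")


def _parse_side(text: str, side: str) -> dict[str, float]:
    text = text.strip()
    if not text:
        raise ReactionParseError(f"empty {side} side")
    out: dict[str, float] = {}
    for term in _TERM_SPLIT.split(text):
        toks = term.split()
        if not toks:
            raise ReactionParseError(f"empty term on {side} side")
        coef = 1.0
        if len(toks) == 2:
            try:
                coef = float(toks[0])
            except ValueError:
                raise ReactionParseError(
                    f"bad coefficient token {toks[0]!r} in term {term!r}") from None
            sp = toks[1]
        elif len(toks) == 1:
            sp = toks[0]
        else:
            raise ReactionParseError(f"cannot parse term {term!r}")
        if coef <= 0:
            raise ReactionParseError(
                f"non-positive coefficient {coef!r} for species {sp!r}")
        out[sp] = out.get(sp, 0.0) + coef
    return out


def parse_reaction(text: str, id: str | None = None) -> Reaction:
    """Parse a reaction-equation string into a :class:`Reaction`.

    Grammar::

        [coef] species [+ [coef] species ...] (-> | <=>) ...  [| cat: A, B]

    Coefficients default to 1 and must be positive.  ``<=>`` marks the
    reaction reversible (to be split before analysis).  Examples::

        parse_reaction("A + F -> 2 A")
        parse_reaction("B + C <=> A")
        parse_reaction("F -> A | cat: U")

    Raises :class:`ReactionParseError` naming the offending token, and
    :class:`NetworkError` for degenerate equations such as ``A -> A``
    (no net transformation).
    """
    eq = text.strip()
    cats: frozenset[str] = frozenset()
    if "|" in eq:
        eq, _, tail = eq.partition("|")
        tail = tail.strip()
        if not tail.lower().startswith("cat:"):
            raise ReactionParseError(
                f"expected catalyst annotation 'cat: ...', got {tail!r}")
        names = [t.strip() for t in tail[4:].split(",") if t.strip()]
        if not names:
            raise ReactionParseError("empty catalyst list after 'cat:'")
        cats = frozenset(names)
    n_rev = eq.count("<=>")
    n_fwd = eq.count("->")
    if n_rev + n_fwd == 0:
        raise ReactionParseError(f"no reaction arrow ('->' or '<=>') in {text!r}")
    if n_rev + n_fwd > 1:
        raise ReactionParseError(f"multiple reaction arrows in {text!r}")
    arrow = "<=>" if n_rev else "->"
    lhs, _, rhs = eq.partition(arrow)
    reactants = _parse_side(lhs, "reactant")
    products = _parse_side(rhs, "product")
    rid = id if id is not None else format_equation_parts(
        reactants, products, cats, arrow == "<=>")
    return Reaction(id=rid, reactants=reactants, products=products,
                    catalysts=cats, reversible=(arrow == "<=>"))


def _fmt_coef(c: float) -> str:
    if abs(c - round(c)) < DEFAULT_TOL:
        c = int(round(c))
        return "" if c == 1 else f"{c} "
    return f"{c:g} "


def format_equation_parts(reactants: Mapping[str, float],
                          products: Mapping[str, float],
                          catalysts: Iterable[str],
                          reversible: bool) -> str:
    lhs = " + ".join(f"{_fmt_coef(c)}{sp}" for sp, c in sorted(reactants.items()))
    rhs = " + ".join(f"{_fmt_coef(c)}{sp}" for sp, c in sorted(products.items()))
    arrow = "<=>" if reversible else "->"
    eq = f"{lhs} {arrow} {rhs}"
    cats = sorted(catalysts)
    if cats:
        eq += " | cat: " + ", ".join(cats)
    return eq


def format_equation(r: Reaction) -> str:
    """Render a reaction back to its equation-string form (round-trip safe)."""
    return format_equation_parts(r.reactants, r.products, r.catalysts, r.reversible)


def split_reversible(r: Reaction) -> tuple[Reaction, Reaction]:
    """Split a reversible reaction into ``<id>.a`` (forward) and ``<id>.b``
    (reverse, with reactants and products swapped).  Catalysts are preserved
    on both directions."""
    if not r.reversible:
        raise NetworkError(f"reaction {r.id!r} is not reversible; nothing to split")
    fwd = Reaction(id=f"{r.id}.a", reactants=dict(r.reactants),
                   products=dict(r.products), catalysts=r.catalysts,
                   reversible=False, origin=r.origin or r.id)
    rev = Reaction(id=f"{r.id}.b", reactants=dict(r.products),
                   products=dict(r.reactants), catalysts=r.catalysts,
                   reversible=False, origin=r.origin or r.id)
    return fwd, rev


def merge_split_pair(fwd: Reaction, rev: Reaction) -> Reaction:
    """Inverse of :func:`split_reversible`: recover the reversible original
    from a ``.a``/``.b`` pair."""
    if not (fwd.id.endswith(".a") and rev.id.endswith(".b")
            and fwd.id[:-2] == rev.id[:-2]):
        raise NetworkError("not a matching .a/.b pair")
    if dict(fwd.reactants) != dict(rev.products) or \
            dict(fwd.products) != dict(rev.reactants):
        raise NetworkError("pair sides do not mirror each other")
    return Reaction(id=fwd.id[:-2], reactants=dict(fwd.reactants),
                    products=dict(fwd.products), catalysts=fwd.catalysts,
                    reversible=True, origin=fwd.origin)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class ReactionNetwork:
    """A set of species and unidirectional reactions.

    The species set is the union of all species referenced by any reaction
    (as reactant, product, or catalyst) plus any explicitly declared species
    (e.g. declared food that no reaction touches).  Metadata (masses, pseudo
    flags) can be attached by passing :class:`Species` objects.
    """

    def __init__(self, reactions: Iterable[Reaction] = (),
                 species: Iterable[Species] = ()) -> None:
        self.reactions: dict[str, Reaction] = {}
        self.species: dict[str, Species] = {}
        for sp in species:
            if sp.id in self.species:
                raise NetworkError(f"duplicate species id {sp.id!r}")
            self.species[sp.id] = sp
        for r in reactions:
            self.add_reaction(r)

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {r.id!r}")
        self.reactions[r.id] = r
        for sid in r.touched:
            self.species.setdefault(sid, Species(sid))

    def add_species(self, sp: Species) -> None:
        self.species[sp.id] = sp

    @property
    def species_ids(self) -> frozenset[str]:
        return frozenset(self.species)

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<ReactionNetwork {len(self.species)} species, "
                f"{len(self.reactions)} reactions>")

    def split_all_reversible(self) -> "ReactionNetwork":
        """Return a network where every reversible reaction is replaced by
        its ``.a``/``.b`` unidirectional pair."""
        out = ReactionNetwork(species=self.species.values())
        for r in self.reactions.values():
            if r.reversible:
                fwd, rev = split_reversible(r)
                out.add_reaction(fwd)
                out.add_reaction(rev)
            else:
                out.add_reaction(r)
        return out

    def subnetwork(self, reaction_ids: Iterable[str]) -> "ReactionNetwork":
        rids = set(reaction_ids)
        missing = rids - set(self.reactions)
        if missing:
            raise NetworkError(f"unknown reaction ids: {sorted(missing)}")
        reactions = [self.reactions[rid] for rid in sorted(rids)]
        touched = set().union(*(r.touched for r in reactions)) if reactions else set()
        return ReactionNetwork(
            reactions=reactions,
            species=[self.species[s] for s in sorted(touched)])


def validate_mass_balance(net: ReactionNetwork, tol: float = 1e-6) -> list[str]:
    """Optional mass-balance check.

    Returns the ids of reactions whose net mass change exceeds ``tol``.
    Reactions touching pseudo-species or species of unknown mass are skipped
    (energy carriers such as light legitimately unbalance mass books).
    """
    bad: list[str] = []
    for r in net.reactions.values():
        masses = {}
        skip = False
        for sid in r.touched:
            sp = net.species[sid]
            if sp.is_pseudo or sp.mass is None:
                skip = True
                break
            masses[sid] = sp.mass
        if skip:
            continue
        delta = sum(c * masses[s] for s, c in r.products.items()) - \
            sum(c * masses[s] for s, c in r.reactants.items())
        if abs(delta) > tol:
            bad.append(r.id)
    return bad


# ---------------------------------------------------------------------------
# Partitioned stoichiometric matrix
# ---------------------------------------------------------------------------

@dataclass
class StoichiometricMatrix:
    """Four-segment partitioned stoichiometric matrix.

    Rows are species (external food first, then internal), columns are
    reactions (external first, then internal).  ``entries[i, j]`` is the net
    coefficient of species ``row_ids[i]`` in reaction ``col_ids[j]``;
    catalysts contribute zero but are listed per column in
    ``catalyst_requirements``.

    In the field's 1-based index convention the first internal row is ``p``,
    the first internal column ``q``, the last row ``m`` and the last column
    ``n``; these are exposed as properties.  Internally the zero-based
    counts ``n_external_rows`` / ``n_external_cols`` are stored.
    """

    entries: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    n_external_rows: int
    n_external_cols: int
    catalyst_requirements: dict[str, frozenset[str]] = field(default_factory=dict)
    #: per-column gating requirements: the reaction's written reactants plus
    #: catalysts.  Distinct from net-negative entries — an autocatalytic
    #: column like A + F -> 2A requires A while netting +1 on it.
    column_requirements: dict[str, frozenset[str]] = field(default_factory=dict)

    # 1-based convenience indices (p, q, m, n)
    @property
    def p(self) -> int:
        return self.n_external_rows + 1

    @property
    def q(self) -> int:
        return self.n_external_cols + 1

    @property
    def m(self) -> int:
        return len(self.row_ids)

    @property
    def n(self) -> int:
        return len(self.col_ids)

    @property
    def external_species(self) -> list[str]:
        return self.row_ids[: self.n_external_rows]

    @property
    def internal_species(self) -> list[str]:
        return self.row_ids[self.n_external_rows:]

    @property
    def external_reactions(self) -> list[str]:
        return self.col_ids[: self.n_external_cols]

    @property
    def internal_reactions(self) -> list[str]:
        return self.col_ids[self.n_external_cols:]

    @property
    def internal_block(self) -> np.ndarray:
        """Internal rows x internal columns submatrix (the LP operand)."""
        return self.entries[self.n_external_rows:, self.n_external_cols:]

    def internal_requirements(self, col_id: str) -> frozenset[str]:
        """Internal species whose sustained presence reaction ``col_id``
        needs: its written reactants plus catalysts, restricted to internal
        rows.  Falls back to net-negative entries when the matrix was built
        without per-column requirement bookkeeping."""
        internal = set(self.internal_species)
        req = self.column_requirements.get(col_id)
        if req is None:
            j = self.col_ids.index(col_id)
            req = {self.row_ids[i]
                   for i in np.nonzero(self.entries[:, j] < -DEFAULT_TOL)[0]}
            req |= self.catalyst_requirements.get(col_id, frozenset())
        return frozenset(req & internal)

    def restrict(self, col_ids: Sequence[str],
                 row_ids: Sequence[str] | None = None) -> "StoichiometricMatrix":
        """Submatrix over the given internal columns (and optionally internal
        rows); external rows/columns are dropped."""
        cols = [self.col_ids.index(c) for c in col_ids]
        if row_ids is None:
            row_ids = self.internal_species
        rows = [self.row_ids.index(r) for r in row_ids]
        sub = self.entries[np.ix_(rows, cols)]
        return StoichiometricMatrix(
            entries=sub,
            row_ids=list(row_ids),
            col_ids=list(col_ids),
            n_external_rows=0,
            n_external_cols=0,
            catalyst_requirements={c: self.catalyst_requirements.get(c, frozenset())
                                   for c in col_ids},
            column_requirements={c: self.column_requirements[c]
                                 for c in col_ids
                                 if c in self.column_requirements},
        )


def build_matrix(net: ReactionNetwork,
                 external_species: Iterable[str],
                 external_reactions: Iterable[str]) -> StoichiometricMatrix:
    """Build the partitioned stoichiometric matrix of a network.

    External species rows come first, then internal rows; likewise for
    reaction columns.  Orderings are sorted for determinism.  The structural
    invariant that external reactions touch no internal species (the
    internal-rows x external-columns block is identically zero) is verified
    and a :class:`PartitionError` raised on violation.
    """
    ext_sp = set(external_species)
    ext_rx = set(external_reactions)
    unknown_sp = ext_sp - set(net.species)
    if unknown_sp:
        raise PartitionError(f"external species not in network: {sorted(unknown_sp)}")
    unknown_rx = ext_rx - set(net.reactions)
    if unknown_rx:
        raise PartitionError(f"external reactions not in network: {sorted(unknown_rx)}")

    row_ids = sorted(ext_sp) + sorted(set(net.species) - ext_sp)
    col_ids = sorted(ext_rx) + sorted(set(net.reactions) - ext_rx)
    row_index = {s: i for i, s in enumerate(row_ids)}

    for rid in ext_rx:
        bad = net.reactions[rid].touched - ext_sp
        if bad:
            raise PartitionError(
                f"external reaction {rid!r} touches internal species "
                f"{sorted(bad)}; violates the four-segment partition")

    entries = np.zeros((len(row_ids), len(col_ids)))
    cat_req: dict[str, frozenset[str]] = {}
    col_req: dict[str, frozenset[str]] = {}
    for j, rid in enumerate(col_ids):
        r = net.reactions[rid]
        for sp, c in r.products.items():
            entries[row_index[sp], j] += c
        for sp, c in r.reactants.items():
            entries[row_index[sp], j] -= c
        cat_req[rid] = r.catalysts
        col_req[rid] = r.required

    return StoichiometricMatrix(
        entries=entries,
        row_ids=row_ids,
        col_ids=col_ids,
        n_external_rows=len(ext_sp),
        n_external_cols=len(ext_rx),
        catalyst_requirements=cat_req,
        column_requirements=col_req,
    )
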
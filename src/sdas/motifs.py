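"""Minimum-cardinality autocatalytic motifs by integer programming.

Within a certified SDAS, an *autocatalytic motif* is a subset T of the
internal reaction columns whose required internal species are all net
produced with excess by fluxes supported on T alone.  The smallest such
subsets are found with a mixed-integer program (HiGHS branch-and-bound via
:func:`scipy.optimize.milp`, optimality gap 0):

    min  sum_j z_j
    s.t. x_j <= beta_j z_j                       (selection gating)
         sum_j x_j s_ij >= 1 - M_i (1 - y_i)     (big-M production)
         y_i >= z_j   for i in Omega_j           (species coupling)
         sum_j z_j >= D,  x >= 0,  z, y binary

with big-M constant  M_i = 1 - sum_{j: s_ij<0} beta_j s_ij,  which makes
the production constraint vacuous over the whole flux box [0, beta] when
y_i = 0.  Omega_j contains the *internal requirements* of reaction j: its
internal net reactants and internal catalysts — the species whose sustained
supply the reaction depends on.  Internal species that selected reactions
only produce are byproducts; they are reported as the motif's *waste*, not
as members.

All motifs of the optimal cardinality are enumerated by iterating no-good
cuts  sum_{j in T} z_j <= |T| - 1  until the optimum increases.  A
brute-force subset oracle for small instances backs the solver in tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .core import DEFAULT_TOL, SdasError, StoichiometricMatrix
from .detect import is_autocatalytic

#: Numerical slack used when re-checking the returned motif arithmetically.
CHECK_TOL = 1e-6


class MotifError(SdasError):
    """Raised when motif search fails or returns an inconsistent result."""


@dataclass(frozen=True)
class MotifSearchConfig:
    """Knobs of the motif integer program.

    ``beta`` is the per-reaction flux upper bound (a constant for all
    reactions, or a per-reaction mapping); it must comfortably exceed any
    flux level a motif needs — a warning is issued if a solution presses
    against it.  ``min_reactions`` (D) asks for motifs with at least D
    reactions; ``max_solutions`` caps enumeration; ``time_limit`` is in
    seconds (None = none); the MIP gap is fixed at 0 so optimality is
    proven.
    """

    beta: float | Mapping[str, float] = 1000.0
    min_reactions: int = 1
    max_solutions: int = 1000
    time_limit: float | None = None

    def __post_init__(self) -> None:
        if self.min_reactions < 1:
            raise MotifError("min_reactions (D) must be >= 1")
        if isinstance(self.beta, (int, float)):
            if self.beta <= 0:
                raise MotifError("beta must be positive")
        else:
            if any(b <= 0 for b in self.beta.values()):
                raise MotifError("all beta_j must be positive")

    def beta_vector(self, col_ids: Sequence[str]) -> np.ndarray:
        if isinstance(self.beta, (int, float)):
            return np.full(len(col_ids), float(self.beta))
        try:
            return np.array([float(self.beta[c]) for c in col_ids])
        except KeyError as e:
            raise MotifError(f"no beta bound for reaction {e.args[0]!r}") from None


@dataclass(frozen=True)
class Motif:
    """A minimum-cardinality autocatalytic motif.

    ``reactions`` is the selected set T; ``members`` the internal species
    the motif must sustain (union of internal requirements over T);
    ``flux`` the certificate levels over T, normalised so that the smallest
    member net production equals 1; ``waste`` the internal species produced
    by T's reactions that are not members.
    """

    reactions: frozenset[str]
    members: frozenset[str]
    flux: Mapping[str, float] = field(compare=False, default_factory=dict)
    waste: frozenset[str] = frozenset()
    optimal: bool = True

    @property
    def size(self) -> int:
        return len(self.reactions)

    def sort_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.reactions))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _internal_requirement_rows(M: StoichiometricMatrix
                               ) -> tuple[np.ndarray, list[list[int]]]:
    """Internal block + per-internal-column list of required internal row
    indices (the reaction's written reactants and catalysts)."""
    A = M.internal_block
    row_of = {s: i for i, s in enumerate(M.internal_species)}
    omega: list[list[int]] = []
    for rid in M.internal_reactions:
        omega.append(sorted(row_of[s] for s in M.internal_requirements(rid)))
    return A, omega


def _certificate_flux(A: np.ndarray, member_rows: list[int],
                      sel: Sequence[int], beta: np.ndarray) -> np.ndarray:
    """Minimum-total-flux certificate for a selected reaction set: solve
    min sum(x) s.t. net >= 1 on the member rows, 0 <= x <= beta over T.
    Cleaner than the raw MILP incumbent, whose flux levels are arbitrary
    feasible values."""
    from scipy.optimize import linprog

    sub = A[np.ix_(member_rows, list(sel))]
    res = linprog(np.ones(len(sel)), A_ub=-sub, b_ub=-np.ones(len(member_rows)),
                  bounds=[(0, beta[j]) for j in sel], method="highs")
    if res.status != 0:
        raise MotifError(
            "selected reaction set lost feasibility on re-solve "
            f"(status {res.status}); beta may be binding — raise beta")
    x = np.zeros(A.shape[1])
    x[list(sel)] = res.x
    return x


def _motif_from_selection(M: StoichiometricMatrix, A: np.ndarray,
                          omega: list[list[int]], sel: Sequence[int],
                          x: np.ndarray, optimal: bool = True) -> Motif:
    int_species = M.internal_species
    int_reactions = M.internal_reactions
    member_rows = sorted(set(itertools.chain.from_iterable(omega[j] for j in sel)))
    members = frozenset(int_species[i] for i in member_rows)
    # Arithmetic re-check of the production constraint on the returned motif.
    if member_rows:
        net = A[np.ix_(member_rows, list(sel))] @ x[list(sel)]
        if np.min(net) < 1 - CHECK_TOL:
            raise MotifError(
                "solver returned a motif whose flux certificate fails the "
                f"production re-check (min net {np.min(net):.3g} < 1)")
        scale = 1.0 / float(np.min(net))
    else:
        scale = 1.0
    produced = set()
    for j in sel:
        produced |= {int_species[i] for i in np.nonzero(A[:, j] > DEFAULT_TOL)[0]}
    waste = frozenset(produced - members)
    flux = {int_reactions[j]: float(x[j]) * scale for j in sel}
    return Motif(reactions=frozenset(int_reactions[j] for j in sel),
                 members=members, flux=flux, waste=waste, optimal=optimal)


# ---------------------------------------------------------------------------
# ILP
# ---------------------------------------------------------------------------

def _solve_ilp(A: np.ndarray, omega: list[list[int]], beta: np.ndarray,
               D: int, cuts: list[list[int]], time_limit: float | None
               ) -> tuple[str, np.ndarray | None, np.ndarray | None, float]:
    """One MILP solve.  Variables are [x (cont), z (bin), y (bin)].

    Returns (status, x, z, objective)."""
    m, n = A.shape
    nx, nz, ny = n, n, m
    N = nx + nz + ny

    def col(kind: str, k: int) -> int:
        if kind == "x":
            return k
        if kind == "z":
            return nx + k
        return nx + nz + k

    rows_A: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []

    # sum z_j >= D
    row = np.zeros(N)
    row[nx:nx + nz] = 1.0
    rows_A.append(row)
    lb.append(float(D))
    ub.append(np.inf)

    # x_j - beta_j z_j <= 0
    for j in range(n):
        row = np.zeros(N)
        row[col("x", j)] = 1.0
        row[col("z", j)] = -beta[j]
        rows_A.append(row)
        lb.append(-np.inf)
        ub.append(0.0)

    # sum_j s_ij x_j - M_i y_i >= 1 - M_i
    neg = np.where(A < 0, A, 0.0)
    M_i = 1.0 - neg @ beta  # 1 - sum_{j: s_ij<0} beta_j s_ij  (>= 1)
    for i in range(m):
        row = np.zeros(N)
        row[:nx] = A[i, :]
        row[col("y", i)] = -M_i[i]
        rows_A.append(row)
        lb.append(1.0 - M_i[i])
        ub.append(np.inf)

    # y_i >= z_j for i in Omega_j
    for j in range(n):
        for i in omega[j]:
            row = np.zeros(N)
            row[col("z", j)] = 1.0
            row[col("y", i)] = -1.0
            rows_A.append(row)
            lb.append(-np.inf)
            ub.append(0.0)

    # no-good cuts: sum_{j in T} z_j <= |T| - 1
    for T in cuts:
        row = np.zeros(N)
        for j in T:
            row[col("z", j)] = 1.0
        rows_A.append(row)
        lb.append(-np.inf)
        ub.append(len(T) - 1.0)

    c = np.zeros(N)
    c[nx:nx + nz] = 1.0
    integrality = np.concatenate([np.zeros(nx), np.ones(nz), np.ones(ny)])
    bounds = Bounds(lb=np.zeros(N),
                    ub=np.concatenate([beta, np.ones(nz + ny)]))
    constraints = LinearConstraint(csr_matrix(np.vstack(rows_A)),
                                   np.array(lb), np.array(ub))
    options: dict = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=bounds, options=options)
    if res.status == 0:
        x = res.x[:nx]
        z = res.x[nx:nx + nz]
        return "optimal", x, z, float(res.fun)
    if res.status == 2:
        return "infeasible", None, None, np.inf
    if res.status == 1:
        return "time_limit", (res.x[:nx] if res.x is not None else None), \
            (res.x[nx:nx + nz] if res.x is not None else None), \
            float(res.fun) if res.fun is not None else np.inf
    raise MotifError(f"MILP solver failure: status={res.status} {res.message}")


def find_min_motif(M: StoichiometricMatrix,
                   cfg: MotifSearchConfig = MotifSearchConfig()) -> Motif:
    """Find one minimum-cardinality autocatalytic motif in a certified SDAS.

    ``M`` must be a partition whose internal block passed
    :func:`sdas.detect.is_autocatalytic`; an infeasible integer program on
    such input indicates the flux bound ``beta`` is too small and raises
    :class:`MotifError` suggesting to raise it.  A direct arithmetic
    re-check of the production constraint on the returned motif is
    performed before returning.
    """
    A, omega = _internal_requirement_rows(M)
    if A.shape[1] == 0:
        raise MotifError("matrix has no internal reactions")
    beta = cfg.beta_vector(M.internal_reactions)
    status, x, z, obj = _solve_ilp(A, omega, beta, cfg.min_reactions, [],
                                   cfg.time_limit)
    if status == "infeasible":
        raise MotifError(
            "integer program infeasible on a certified SDAS; the flux "
            "bound beta is likely too small — raise beta and retry")
    optimal = status == "optimal"
    if x is None or z is None:
        raise MotifError("solver hit the time limit before any solution")
    sel = [j for j in range(A.shape[1]) if z[j] > 0.5]
    return _finalize(M, A, omega, sel, beta, optimal)


def _finalize(M: StoichiometricMatrix, A: np.ndarray, omega: list[list[int]],
              sel: list[int], beta: np.ndarray, optimal: bool) -> Motif:
    """Re-solve a clean flux certificate for the selected set, warn if it
    presses against the beta bound, and assemble the Motif."""
    member_rows = sorted(set(itertools.chain.from_iterable(
        omega[j] for j in sel)))
    if member_rows:
        x = _certificate_flux(A, member_rows, sel, beta)
    else:
        x = np.zeros(A.shape[1])
    for j in sel:
        if x[j] > 0.99 * beta[j]:
            warnings.warn(
                f"flux of reaction {M.internal_reactions[j]!r} is within 1% "
                f"of its bound beta={beta[j]:g}; the bound may be binding "
                "and the motif suspect — consider raising beta", stacklevel=3)
    return _motif_from_selection(M, A, omega, sel, x, optimal=optimal)


def enumerate_min_motifs(M: StoichiometricMatrix,
                         cfg: MotifSearchConfig = MotifSearchConfig()
                         ) -> list[Motif]:
    """Enumerate all autocatalytic motifs of the optimal cardinality.

    Solves a sequence of integer programs, each excluding the previously
    found reaction sets through no-good cuts, until the optimum increases
    or ``max_solutions`` is reached.  The result is sorted by lexicographic
    reaction-id order, independent of solver tie-breaking.
    """
    A, omega = _internal_requirement_rows(M)
    if A.shape[1] == 0:
        raise MotifError("matrix has no internal reactions")
    beta = cfg.beta_vector(M.internal_reactions)
    cuts: list[list[int]] = []
    motifs: list[Motif] = []
    optimum: int | None = None
    while len(motifs) < cfg.max_solutions:
        status, x, z, obj = _solve_ilp(A, omega, beta, cfg.min_reactions,
                                       cuts, cfg.time_limit)
        if status == "infeasible":
            if optimum is None:
                raise MotifError(
                    "integer program infeasible on a certified SDAS; the "
                    "flux bound beta is likely too small — raise beta")
            break
        if status == "time_limit" and x is None:
            break
        sel = [j for j in range(A.shape[1]) if z[j] > 0.5]
        if optimum is None:
            optimum = len(sel)
        elif len(sel) > optimum:
            break
        motifs.append(_finalize(M, A, omega, sel, beta,
                                optimal=(status == "optimal")))
        cuts.append(sel)
    return sorted(motifs, key=Motif.sort_key)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_motifs(M: StoichiometricMatrix, max_size: int | None = None,
                       size_guard: int = 15) -> list[Motif]:
    """Exhaustive small-instance motif search (testing oracle).

    Enumerates reaction subsets by increasing cardinality and keeps a
    subset if the LP restricted to it (rows = its required internal
    species, columns = the subset) is feasible; all subsets of the first
    feasible cardinality are returned.  Guarded to at most ``size_guard``
    internal columns.
    """
    n = len(M.internal_reactions)
    if n > size_guard:
        raise MotifError(
            f"{n} internal reactions exceed the brute-force guard "
            f"({size_guard})")
    A, omega = _internal_requirement_rows(M)
    int_reactions = M.internal_reactions
    if max_size is None:
        max_size = n
    for size in range(1, max_size + 1):
        found: list[Motif] = []
        for combo in itertools.combinations(range(n), size):
            rows = sorted(set(itertools.chain.from_iterable(
                omega[j] for j in combo)))
            sub = M.restrict([int_reactions[j] for j in combo],
                             [M.internal_species[i] for i in rows])
            lp = is_autocatalytic(sub) if rows else None
            feasible = lp.feasible if lp is not None else True
            if feasible:
                x = np.zeros(n)
                if lp is not None and lp.flux:
                    for rid, v in lp.flux.items():
                        x[int_reactions.index(rid)] = v
                found.append(_motif_from_selection(M, A, omega, list(combo), x))
        if found:
            return sorted(found, key=Motif.sort_key)
    return []
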
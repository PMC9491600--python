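"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sdas import (ReactionNetwork, Reaction, StoichiometricMatrix,
                  build_matrix, toy, toy_names)


# ---------------------------------------------------------------------------
# Independent integer-grid oracle for the autocatalysis LP
# ---------------------------------------------------------------------------

def integer_flux_certificate(A: np.ndarray, bound: int = 12,
                             chunk: int = 200_000) -> np.ndarray | None:
    """Exhaustively search non-negative integer flux vectors with entries
    <= ``bound`` for strictly positive net production on every row of ``A``
    (rows = internal species, columns = internal reactions).

    A strict certificate rescales to the >=1 form, so finding one proves
    LP feasibility; for small systems the converse search is exhaustive up
    to the bound.  Returns a certificate or None.  Pure enumeration —
    independent of any LP machinery.
    """
    m, n = A.shape
    total = (bound + 1) ** n
    radix = np.array([(bound + 1) ** (n - 1 - k) for k in range(n)])
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        X = (idx[:, None] // radix[None, :]) % (bound + 1)
        nets = X @ A.T
        ok = np.all(nets > 1e-12, axis=1)
        hits = np.nonzero(ok)[0]
        if hits.size:
            return X[hits[0]].astype(float)
    return None


def verify_flux_certificate(A: np.ndarray, x, tol: float = 1e-6) -> bool:
    """Arithmetic check that a flux vector nets >= 1 on every row."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -tol):
        return False
    return bool(np.all(A @ x >= 1 - tol))


# ---------------------------------------------------------------------------
# Random partitioned networks (for property/agreement tests)
# ---------------------------------------------------------------------------

def random_partition(rng: np.random.Generator, max_reactions: int = 6
                     ) -> StoichiometricMatrix:
    """A random small internal partition: 1-2 food species, 2-4 internal
    species, up to ``max_reactions`` internal reactions with coefficients
    in {1, 2}.  Every reaction consumes at least one internal species, as
    holds for any seed-induced internal subnetwork."""
    while True:
        n_food = int(rng.integers(1, 3))
        n_int = int(rng.integers(2, 5))
        n_rx = int(rng.integers(2, max_reactions + 1))
        food = [f"F{i}" for i in range(n_food)]
        internal = [f"X{i}" for i in range(n_int)]
        reactions = []
        try:
            for j in range(n_rx):
                r_int = rng.choice(internal, size=int(rng.integers(1, 3)),
                                   replace=False)
                reactants = {str(s): float(rng.integers(1, 3)) for s in r_int}
                if rng.random() < 0.5:
                    reactants[str(rng.choice(food))] = float(rng.integers(1, 3))
                prods = rng.choice(internal + food,
                                   size=int(rng.integers(1, 3)), replace=False)
                products = {str(s): float(rng.integers(1, 3)) for s in prods}
                reactions.append(Reaction(id=f"R{j}", reactants=reactants,
                                          products=products))
            net = ReactionNetwork(reactions)
            return build_matrix(net, external_species=set(food) & set(net.species),
                                external_reactions=set())
        except Exception:
            continue  # degenerate draw (e.g. identity reaction); redraw


@pytest.fixture(params=sorted(toy_names()))
def toy_case(request):
    return toy(request.param)
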
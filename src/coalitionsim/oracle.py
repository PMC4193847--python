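"""Brute-force ground truth on small networks (test support).

Exhaustive enumeration of the 2^N state space gives the exact global optima
of the original utility, and deterministic sequential best-response sweeps
from every state give a well-defined attractor census with basin sizes.
Better attractors having larger basins is the lever the self-optimization
process exploits, so the census doubles as a check of that mechanism.
Guards refuse networks too large to enumerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .topology import CoalitionNetwork

__all__ = ["AttractorCensus", "enumerate_optima", "attractor_census"]

_MAX_ENUMERATE = 20
_MAX_CENSUS = 16


@dataclass(frozen=True)
class AttractorCensus:
    """Fixed points of deterministic sweep descent, with basin sizes.

    ``attractors`` has one row per fixed point (entries +/-1); ``basin_sizes``
    counts, for each attractor, the initial states descending to it
    (summing to 2^N); ``utilities`` are the original-topology utilities;
    ``global_optima`` flags the attractors attaining the enumerated maximum.
    """

    attractors: np.ndarray
    basin_sizes: np.ndarray
    utilities: np.ndarray
    global_optima: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "attractors": self.attractors.tolist(),
            "basin_sizes": self.basin_sizes.tolist(),
            "utilities": self.utilities.tolist(),
            "global_optima": self.global_optima.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _all_states(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def enumerate_optima(network: CoalitionNetwork) -> tuple[float, np.ndarray]:
    """Exact maximum of the original utility over all 2^N states.

    Returns ``(max_utility, states)`` where ``states`` stacks every
    maximizing state as a row.  Refuses N > 20.
    """
    n = network.n_agents
    if n > _MAX_ENUMERATE:
        raise ValueError(f"exhaustive enumeration limited to N <= {_MAX_ENUMERATE}")
    w = network.original_weights
    states = _all_states(n).astype(np.float64)
    utilities = np.einsum("ki,ij,kj->k", states, w, states)
    best = utilities.max()
    # exact arithmetic on these scales; tolerance only guards float summation order
    optima = states[utilities >= best - 1e-9 * max(1.0, abs(best))]
    return float(best), optima.astype(np.int8)


def _sweep_descend(w: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Deterministic descent: repeatedly sweep agents 0..N-1, each adopting
    the sign of its local field (keep-on-tie), until no sweep changes
    anything.  Vectorized over all start states."""
    s = states.astype(np.float64).copy()
    n = s.shape[1]
    while True:
        changed = False
        for i in range(n):
            h = s @ w[:, i]
            new = np.where(h > 0.0, 1.0, np.where(h < 0.0, -1.0, s[:, i]))
            if not np.array_equal(new, s[:, i]):
                changed = True
                s[:, i] = new
        if not changed:
            return s.astype(np.int8)


def attractor_census(network: CoalitionNetwork) -> AttractorCensus:
    """Attractors and basin sizes under deterministic sequential sweeps from
    every one of the 2^N initial states.  Refuses N > 16."""
    n = network.n_agents
    if n > _MAX_CENSUS:
        raise ValueError(f"attractor census limited to N <= {_MAX_CENSUS}")
    w = network.original_weights
    finals = _sweep_descend(w, _all_states(n))
    attractors, inverse = np.unique(finals, axis=0, return_inverse=True)
    basin_sizes = np.bincount(inverse, minlength=attractors.shape[0])
    s = attractors.astype(np.float64)
    utilities = np.einsum("ki,ij,kj->k", s, w, s)
    # verify stability: no improving single flip at any listed attractor
    fields = s @ w.T  # field felt by agent i in attractor k is fields[k, i]
    if np.any(fields * s < 0.0):
        raise AssertionError("census produced an unstable attractor")
    best, _ = enumerate_optima(network)
    global_optima = utilities >= best - 1e-9 * max(1.0, abs(best))
    return AttractorCensus(
        attractors=attractors,
        basin_sizes=basin_sizes,
        utilities=utilities,
        global_optima=global_optima,
    )
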
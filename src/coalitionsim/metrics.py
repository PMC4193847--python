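"""Outcome measures, always evaluated on the original constraint topology.

Three statistics summarize a convergence: the total utility U on the
original weights, the number of satisfied ordered constraints
("agreements": pairs with s_i*s_j*w_ij > 0), and the number of behavior
updates taken to reach the final traced utility value.  Even after weight
adaptation the reported numbers refer to the original problem, which is
what self-optimization is supposed to solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .dynamics import UtilityTrace
from .topology import CoalitionNetwork

__all__ = [
    "ConvergenceRecord",
    "total_original_utility",
    "count_agreements",
    "max_agreements",
    "steps_to_convergence",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class ConvergenceRecord:
    """Outcome of one relaxation epoch."""

    final_state: np.ndarray
    original_utility: float
    agreements: int
    steps_to_convergence: int
    epoch_index: int
    phase_label: str  # "pre", "learning" or "post"
    run_id: int = 0


def _check_pair(network: CoalitionNetwork, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s)
    if s.shape != (network.n_agents,):
        raise ValueError(
            f"state length {s.shape} does not match network of {network.n_agents} agents"
        )
    return s


def total_original_utility(network: CoalitionNetwork, s: np.ndarray) -> float:
    """U = sum_i sum_{j != i} w_O[i, j] * s[i] * s[j] (zero diagonal)."""
    s = _check_pair(network, s).astype(float)
    return float(s @ network.original_weights @ s)


def count_agreements(network: CoalitionNetwork, s: np.ndarray) -> int:
    """Ordered pairs (i, j), i != j, with s[i]*s[j]*w_O[i, j] strictly positive."""
    s = _check_pair(network, s).astype(float)
    satisfied = network.original_weights * np.outer(s, s)
    return int(np.count_nonzero(satisfied > 0.0))


def max_agreements(network: CoalitionNetwork) -> int:
    """Ceiling N*(N-1): every ordered pair satisfied (4290 for N=66)."""
    n = network.n_agents
    return n * (n - 1)


def steps_to_convergence(trace: UtilityTrace | np.ndarray) -> int:
    """Smallest index k such that the traced utility is constant from k on.

    A constant trace gives 0; ``[1, 2, 3, 3, 3]`` gives 2.  Equality is
    exact: after the last state change the trace is carried over bitwise.
    """
    u = trace.per_update_utility if isinstance(trace, UtilityTrace) else np.asarray(trace)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("trace must be a non-empty 1-d sequence")
    changed = np.nonzero(u != u[-1])[0]
    return int(changed[-1]) + 1 if changed.size else 0


def records_to_dataframe(records: Iterable[ConvergenceRecord]) -> pd.DataFrame:
    """Tabulate records (phase, run_id, epoch_index, utility, agreements,
    steps_to_convergence) — the package's primary tabular output."""
    rows = [
        {
            "phase": rec.phase_label,
            "run_id": rec.run_id,
            "epoch_index": rec.epoch_index,
            "utility": rec.original_utility,
            "agreements": rec.agreements,
            "steps_to_convergence": rec.steps_to_convergence,
        }
        for rec in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "phase",
            "run_id",
            "epoch_index",
            "utility",
            "agreements",
            "steps_to_convergence",
        ],
    )
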
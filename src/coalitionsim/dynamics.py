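"""Fast timescale: asynchronous selfish behavior updates.

At each time step one agent, chosen uniformly at random, adopts the
behavioral state (+1 or -1) that maximizes its own utility

    u_i = sum_{j != i} w[i, j] * s[i] * s[j],

i.e. the sign of its local field h_i = sum_j w[i, j] * s[j]; on an exactly
zero field the agent keeps its current state.  With symmetric weights and
zero diagonal every accepted flip strictly increases the total utility on
the weights driving the dynamics, so each relaxation epoch settles into a
fixed-point attractor.  Epochs are separated by "ritual" randomizations of
the full state vector; the epoch length is tau = round(e * N * ln N)
updates, long enough that convergence is essentially always reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .topology import _as_rng

__all__ = [
    "SimulationConfig",
    "UtilityTrace",
    "agent_utility",
    "best_response",
    "relax_epoch",
    "ritual_interval",
]


@dataclass(frozen=True)
class UtilityTrace:
    """Total utility after every behavior update of one epoch, measured on a
    stated weight matrix (by convention the original weights for reporting)."""

    per_update_utility: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.per_update_utility, dtype=float)
        if u.ndim != 1 or u.size == 0:
            raise ValueError("trace must be a non-empty 1-d sequence")
        object.__setattr__(self, "per_update_utility", u)

    @property
    def epoch_length(self) -> int:
        return self.per_update_utility.size

    @property
    def final_utility(self) -> float:
        return float(self.per_update_utility[-1])

    def to_csv(self, path) -> None:
        table = np.column_stack(
            [np.arange(self.epoch_length), self.per_update_utility]
        )
        np.savetxt(
            path, table, delimiter=",", fmt=("%d", "%.17g"),
            header="update_index,utility", comments="",
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters.

    learning_rate
        Per-convergence weight increment r (dimensionless, default 0.0015).
    epoch_length
        Updates per epoch; ``None`` means ``ritual_interval(N)``.
    n_rituals
        Number of ritual randomization/relaxation/learning cycles.
    probe_convergences
        Learning-free epochs per phase in the pre/post comparison.
    seed
        Master seed; all randomness derives from it.
    """

    learning_rate: float = 0.0015
    epoch_length: int | None = None
    n_rituals: int = 200
    probe_convergences: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.learning_rate >= 0.0 and math.isfinite(self.learning_rate)):
            raise ValueError("learning_rate must be finite and non-negative")
        if self.epoch_length is not None and self.epoch_length < 1:
            raise ValueError("epoch_length must be a positive count")
        if self.n_rituals < 0 or self.probe_convergences < 0:
            raise ValueError("counts must be non-negative")

    def resolve_epoch_length(self, n_agents: int) -> int:
        if self.epoch_length is not None:
            return int(self.epoch_length)
        return ritual_interval(n_agents)


def ritual_interval(n_agents: int) -> int:
    """Epoch length between ritual randomizations: round(e * N * ln N)."""
    if n_agents < 2:
        raise ValueError("ritual interval needs at least 2 agents")
    return int(round(math.e * n_agents * math.log(n_agents)))


def _check_state(w: np.ndarray, s: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    s = np.asarray(s)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must form a square matrix")
    if s.shape != (w.shape[0],):
        raise ValueError(
            f"state length {s.shape} does not match weights {w.shape}"
        )
    return s


def agent_utility(network_weights: np.ndarray, s: np.ndarray, i: int) -> float:
    """u_i = sum_{j != i} w[i, j] * s[i] * s[j]."""
    w = np.asarray(network_weights, dtype=float)
    s = _check_state(w, s)
    if not 0 <= i < w.shape[0]:
        raise IndexError(f"agent index {i} out of range")
    h = float(w[i] @ s) - float(w[i, i] * s[i])
    return float(s[i]) * h


def best_response(network_weights: np.ndarray, s: np.ndarray, i: int) -> int:
    """State in {-1, +1} maximizing agent i's utility; keeps s[i] on a tie."""
    w = np.asarray(network_weights, dtype=float)
    s = _check_state(w, s)
    if not 0 <= i < w.shape[0]:
        raise IndexError(f"agent index {i} out of range")
    h = float(w[i] @ s) - float(w[i, i] * s[i])
    if h > 0.0:
        return 1
    if h < 0.0:
        return -1
    return int(s[i])


def relax_epoch(
    network_weights: np.ndarray,
    s: np.ndarray,
    n_steps: int,
    rng: np.random.Generator | int | None,
    trace_weights: np.ndarray | None = None,
    early_stop: bool = False,
) -> tuple[np.ndarray, UtilityTrace]:
    """One relaxation epoch of ``n_steps`` asynchronous best-response updates.

    Agents are selected uniformly at random with replacement.  The dynamics
    run on ``network_weights`` (in the learning protocols, the combined
    original+learned matrix); the returned trace records the total utility
    after every update on ``trace_weights`` (default: the dynamics matrix).
    The input state is never modified; a fresh final state is returned.
    """
    w_dyn = np.ascontiguousarray(network_weights, dtype=np.float64)
    s = _check_state(w_dyn, s)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if trace_weights is None:
        w_trace = w_dyn
    else:
        w_trace = np.ascontiguousarray(trace_weights, dtype=np.float64)
        if w_trace.shape != w_dyn.shape:
            raise ValueError("trace_weights shape mismatch")
    rng = _as_rng(rng)
    order = rng.integers(0, w_dyn.shape[0], size=n_steps)
    s_out = np.asarray(s, dtype=np.int8).copy()
    trace = _kernels.relax(w_dyn, w_trace, s_out, order, early_stop)
    return s_out, UtilityTrace(trace)
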
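"""Slow timescale: selfish weight adaptation at the end of each convergence.

After the network has settled, every agent considers, for each of its
connections, whether nudging the weight up or down by the learning rate r
would increase its own utility, and applies the strictly improving change.
Because the utility contribution of connection (i, j) is w[i, j]*s[i]*s[j],
this decision reduces to the Hebbian rule delta = r*s[i]*s[j] away from the
bounds.  The combined weight (original + learned) is clamped to [-1, 1]; at
a saturated bound neither change improves and the entry stays put.  Learned
changes are stored as the residual on top of the immutable original matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import CoalitionNetwork

__all__ = ["AdaptedWeights", "combined_weights", "selfish_weight_update"]


@dataclass(frozen=True)
class AdaptedWeights:
    """Accumulated learned weight changes omega_L (symmetric, zero diagonal)."""

    learned_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.learned_weights, dtype=float)
        object.__setattr__(self, "learned_weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("learned weights must form a square matrix")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("learned self-connections must stay zero")
        if not np.array_equal(w, w.T):
            raise ValueError("learned weights must be symmetric")

    @classmethod
    def zeros(cls, n_agents: int) -> "AdaptedWeights":
        return cls(np.zeros((n_agents, n_agents)))


def combined_weights(network: CoalitionNetwork, adapted: AdaptedWeights) -> np.ndarray:
    """Entrywise sum omega_O + omega_L — the matrix the dynamics run on."""
    if adapted.learned_weights.shape != network.original_weights.shape:
        raise ValueError("learned weights do not match the network size")
    return network.original_weights + adapted.learned_weights


def selfish_weight_update(
    network: CoalitionNetwork,
    adapted: AdaptedWeights,
    s: np.ndarray,
    r: float,
) -> AdaptedWeights:
    """One round of selfish weight changes at the converged state ``s``.

    For every ordered pair (i, j) both candidate changes +r and -r to the
    combined weight are evaluated against agent i's utility (after clamping
    to [-1, 1]); the strictly improving one is applied, otherwise the entry
    is unchanged.  Agent i's verdict on (i, j) and agent j's on (j, i)
    coincide (both depend only on s[i]*s[j]), so symmetry is preserved.
    Returns a new :class:`AdaptedWeights`; inputs are untouched.
    """
    s = np.asarray(s)
    if s.shape != (network.n_agents,):
        raise ValueError("state length does not match the network")
    if r < 0:
        raise ValueError("learning rate must be non-negative")
    c = combined_weights(network, adapted)
    alignment = np.outer(s, s).astype(float)
    up = np.clip(c + r, -1.0, 1.0)
    down = np.clip(c - r, -1.0, 1.0)
    gain_up = (up - c) * alignment
    gain_down = (down - c) * alignment
    candidate = np.where(gain_up > gain_down, up, down)
    new_c = np.where(np.maximum(gain_up, gain_down) > 0.0, candidate, c)
    np.fill_diagonal(new_c, 0.0)
    return AdaptedWeights(new_c - network.original_weights)
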
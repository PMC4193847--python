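"""Constraint-network topologies and random behavioral states.

The model's "problem space" is a static symmetric weight matrix over agents
(three representatives per neighborhood group).  Two study structures are
provided as presets: a purely modular *neighborhoods* network (22 groups of
3 agents; within-group weight 1, between-group 0.01) and a *districts*
network in which the same 22 groups are nested into four districts of
10/2/5/5 groups (weights 1 within a group, 0.02 within a district, 0.006
across districts).  The two presets share the same total weight mass so
their utility scales are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CoalitionNetwork",
    "build_modular_topology",
    "build_hierarchical_topology",
    "teotihuacan_preset",
    "random_state",
    "save_topology",
    "load_topology",
]

#: district composition of the 22 neighborhood groups (NW, NE, SW, SE)
DISTRICT_COMPOSITION = (10, 2, 5, 5)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class CoalitionNetwork:
    """Static problem definition: original weights plus memberships.

    Parameters
    ----------
    original_weights
        Symmetric ``(n, n)`` float matrix with zero diagonal and entries in
        ``[-1, 1]``; entry ``w[i, j]`` is how important it is for agent *i*
        to agree with agent *j*.
    group_of
        Integer array mapping each agent to its neighborhood group.
    district_of
        Integer array mapping each agent to its district, or ``None`` for
        topologies without a district level.
    scenario_label
        Free-text tag, e.g. ``"neighborhoods"``.
    """

    original_weights: np.ndarray
    group_of: np.ndarray
    district_of: np.ndarray | None = None
    scenario_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.original_weights, dtype=float)
        object.__setattr__(self, "original_weights", w)
        object.__setattr__(self, "group_of", np.asarray(self.group_of, dtype=np.int64))
        if self.district_of is not None:
            object.__setattr__(
                self, "district_of", np.asarray(self.district_of, dtype=np.int64)
            )
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 1:
            raise ValueError("network needs at least one agent")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.abs(w).max(initial=0.0) > 1.0:
            raise ValueError("weights must lie in [-1, 1]")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("self-connections must be zero")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if self.group_of.shape != (n,):
            raise ValueError("group_of must have one entry per agent")
        if self.district_of is not None and self.district_of.shape != (n,):
            raise ValueError("district_of must have one entry per agent")

    @property
    def n_agents(self) -> int:
        return self.original_weights.shape[0]

    @property
    def weight_mass(self) -> float:
        """Total weight mass sum_ij w[i, j]; equals the consensus utility for
        all-positive weights."""
        return float(self.original_weights.sum())


def _check_weight(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or abs(value) > 1.0:
        raise ValueError(f"{name} must be a finite weight in [-1, 1], got {value}")
    return value


def _check_count(name: str, value: int) -> int:
    if int(value) != value or value < 1:
        raise ValueError(f"{name} must be a positive integer, got {value}")
    return int(value)


def build_modular_topology(
    group_count: int,
    group_size: int,
    w_within: float,
    w_between: float,
    scenario_label: str = "modular",
) -> CoalitionNetwork:
    """Fully connected modular network: ``w_within`` inside each group of
    ``group_size`` agents, ``w_between`` across groups, zero diagonal.

    Agent ``i`` belongs to group ``i // group_size`` (0-based throughout).
    """
    group_count = _check_count("group_count", group_count)
    group_size = _check_count("group_size", group_size)
    w_within = _check_weight("w_within", w_within)
    w_between = _check_weight("w_between", w_between)

    n = group_count * group_size
    group_of = np.arange(n) // group_size
    same_group = group_of[:, None] == group_of[None, :]
    w = np.where(same_group, w_within, w_between)
    np.fill_diagonal(w, 0.0)
    return CoalitionNetwork(w, group_of, None, scenario_label)


def build_hierarchical_topology(
    district_composition: Sequence[int],
    group_size: int,
    w_group: float,
    w_district: float,
    w_between: float,
    scenario_label: str = "hierarchical",
) -> CoalitionNetwork:
    """Three-level network: groups nested in districts.

    ``district_composition[d]`` gives the number of groups in district ``d``;
    districts are contiguous blocks of group indices.  Weights: ``w_group``
    within a group, ``w_district`` between groups of the same district,
    ``w_between`` across districts.
    """
    if len(district_composition) == 0:
        raise ValueError("district_composition must be non-empty")
    composition = [_check_count("district size", k) for k in district_composition]
    group_size = _check_count("group_size", group_size)
    w_group = _check_weight("w_group", w_group)
    w_district = _check_weight("w_district", w_district)
    w_between = _check_weight("w_between", w_between)

    group_count = sum(composition)
    n = group_count * group_size
    group_of = np.arange(n) // group_size
    district_of_group = np.repeat(np.arange(len(composition)), composition)
    district_of = district_of_group[group_of]

    same_group = group_of[:, None] == group_of[None, :]
    same_district = district_of[:, None] == district_of[None, :]
    w = np.where(same_group, w_group, np.where(same_district, w_district, w_between))
    np.fill_diagonal(w, 0.0)
    return CoalitionNetwork(w, group_of, district_of, scenario_label)


def teotihuacan_preset(
    scenario: str,
    *,
    w_within: float = 1.0,
    w_district: float | None = None,
    w_between: float | None = None,
) -> CoalitionNetwork:
    """The study's two 66-agent networks (22 groups of 3 representatives).

    ``scenario`` is ``"neighborhoods"`` (weights 1 / 0.01) or ``"districts"``
    (weights 1 / 0.02 / 0.006, district composition 10/2/5/5 groups).  The
    non-unit weights are illustrative defaults and may be overridden.
    """
    if scenario == "neighborhoods":
        wb = 0.01 if w_between is None else w_between
        return build_modular_topology(22, 3, w_within, wb, scenario_label=scenario)
    if scenario == "districts":
        wd = 0.02 if w_district is None else w_district
        wb = 0.006 if w_between is None else w_between
        return build_hierarchical_topology(
            DISTRICT_COMPOSITION, 3, w_within, wd, wb, scenario_label=scenario
        )
    raise ValueError(
        f"unknown scenario {scenario!r}; expected 'neighborhoods' or 'districts'"
    )


def random_state(n_agents: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniform random vector of +/-1 behavioral states (dtype int8)."""
    n_agents = _check_count("n_agents", n_agents)
    rng = _as_rng(rng)
    return (2 * rng.integers(0, 2, size=n_agents) - 1).astype(np.int8)


def save_topology(network: CoalitionNetwork, matrix_path, membership_path) -> None:
    """Write the weight matrix as header-free CSV and memberships as TSV
    (columns agent_id, group_id, district_id; district -1 when absent)."""
    np.savetxt(matrix_path, network.original_weights, delimiter=",", fmt="%.17g")
    district = (
        network.district_of
        if network.district_of is not None
        else np.full(network.n_agents, -1, dtype=np.int64)
    )
    table = np.column_stack([np.arange(network.n_agents), network.group_of, district])
    np.savetxt(membership_path, table, delimiter="\t", fmt="%d")


def load_topology(matrix_path, membership_path, scenario_label: str = "") -> CoalitionNetwork:
    """Inverse of :func:`save_topology`."""
    w = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    table = np.loadtxt(membership_path, delimiter="\t", dtype=np.int64, ndmin=2)
    order = np.argsort(table[:, 0])
    table = table[order]
    district = table[:, 2]
    district_of = None if np.all(district == -1) else district
    return CoalitionNetwork(w, table[:, 1], district_of, scenario_label)
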
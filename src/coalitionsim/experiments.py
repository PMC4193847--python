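"""Study protocols: baseline convergences, ritual self-optimization, and the
pre/post comparison.

Three protocols are provided.  *Baseline*: independent relaxations of the
original network from random states, learning disabled.  *Self-
optimization*: a sequence of ritual cycles — randomize the full behavioral
state, relax on the combined (original + learned) weights for a full epoch,
then apply one selfish weight update at the converged state; learned
changes persist across rituals.  *Comparison*: for each of many independent
runs, probe the original network before learning, run self-optimization,
then probe again from fresh random states with the learned weights frozen;
all reported utilities and agreements refer to the original topology.  At
the study scale (100 runs x 200 rituals and 200 probes per phase, N = 66)
the comparison pools 20,000 convergences per phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .adaptation import AdaptedWeights, combined_weights, selfish_weight_update
from .dynamics import SimulationConfig, relax_epoch
from .metrics import (
    ConvergenceRecord,
    count_agreements,
    max_agreements,
    steps_to_convergence,
    total_original_utility,
)
from .topology import CoalitionNetwork, random_state, teotihuacan_preset

__all__ = [
    "ExperimentSummary",
    "ComparisonResult",
    "run_baseline",
    "run_self_optimization",
    "run_comparison",
    "summarize_records",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentSummary:
    """Aggregates over a pool of convergences (one phase of one experiment)."""

    scenario_label: str
    phase_label: str
    n_convergences: int
    mean_agreements: float
    sd_agreements: float
    consensus_count: int
    mean_utility: float
    sd_utility: float
    max_utility: float
    mean_steps: float
    sd_steps: float
    seeds: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["seeds"] = list(self.seeds)
        return out


@dataclass(frozen=True)
class ComparisonResult:
    """Pre/post summaries plus the pooled per-convergence records."""

    pre: ExperimentSummary
    post: ExperimentSummary
    pre_records: list[ConvergenceRecord]
    post_records: list[ConvergenceRecord]


def summarize_records(
    records: list[ConvergenceRecord],
    network: CoalitionNetwork,
    phase_label: str,
    seeds: list[int] | None = None,
) -> ExperimentSummary:
    """Pool records into means/SDs and a consensus count (records attaining
    the maximum agreement count).  SDs are NaN for a single record."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    agreements = np.array([r.agreements for r in records], dtype=float)
    utility = np.array([r.original_utility for r in records], dtype=float)
    steps = np.array([r.steps_to_convergence for r in records], dtype=float)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")

    return ExperimentSummary(
        scenario_label=network.scenario_label,
        phase_label=phase_label,
        n_convergences=len(records),
        mean_agreements=float(agreements.mean()),
        sd_agreements=_sd(agreements),
        consensus_count=int(np.count_nonzero(agreements == max_agreements(network))),
        mean_utility=float(utility.mean()),
        sd_utility=_sd(utility),
        max_utility=float(utility.max()),
        mean_steps=float(steps.mean()),
        sd_steps=_sd(steps),
        seeds=list(seeds) if seeds is not None else [],
    )


def _probe_epoch(
    network: CoalitionNetwork,
    dynamics_weights: np.ndarray,
    epoch_length: int,
    rng: np.random.Generator,
    phase_label: str,
    epoch_index: int,
    run_id: int,
) -> tuple[ConvergenceRecord, np.ndarray]:
    s0 = random_state(network.n_agents, rng)
    s, trace = relax_epoch(
        dynamics_weights, s0, epoch_length, rng,
        trace_weights=network.original_weights,
    )
    record = ConvergenceRecord(
        final_state=s,
        original_utility=total_original_utility(network, s),
        agreements=count_agreements(network, s),
        steps_to_convergence=steps_to_convergence(trace),
        epoch_index=epoch_index,
        phase_label=phase_label,
        run_id=run_id,
    )
    return record, s


def run_baseline(
    network: CoalitionNetwork,
    n_convergences: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    phase_label: str = "pre",
    run_id: int = 0,
) -> list[ConvergenceRecord]:
    """Independent convergences of the original network, learning disabled."""
    if n_convergences < 1:
        raise ValueError("n_convergences must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    epoch_length = config.resolve_epoch_length(network.n_agents)
    w = network.original_weights
    records = []
    for k in range(n_convergences):
        record, _ = _probe_epoch(network, w, epoch_length, rng, phase_label, k, run_id)
        records.append(record)
    return records


def run_self_optimization(
    network: CoalitionNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    run_id: int = 0,
) -> tuple[list[ConvergenceRecord], AdaptedWeights]:
    """Sequential ritual cycles with persistent selfish weight adaptation.

    Each cycle randomizes the full state, relaxes for one epoch on the
    combined weights, records the outcome on the original topology, and
    applies one weight update at the converged state.  Returns the
    per-cycle records (the per-epoch utility series) and the final learned
    weights.
    """
    if config.n_rituals < 1:
        raise ValueError("n_rituals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    epoch_length = config.resolve_epoch_length(network.n_agents)
    adapted = AdaptedWeights.zeros(network.n_agents)
    records = []
    for k in range(config.n_rituals):
        w_dyn = combined_weights(network, adapted)
        record, s = _probe_epoch(
            network, w_dyn, epoch_length, rng, "learning", k, run_id
        )
        records.append(record)
        adapted = selfish_weight_update(network, adapted, s, config.learning_rate)
    return records, adapted


def _phase_rng(master_seed: int, run: int, phase: int) -> np.random.Generator:
    # independent, reproducible substream per (run, phase)
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(run, phase))
    )


def run_comparison(
    scenario: str | CoalitionNetwork,
    n_runs: int,
    config: SimulationConfig,
) -> ComparisonResult:
    """Pre/post comparison pooled over ``n_runs`` independent runs.

    Per run: (a) *pre* — ``probe_convergences`` learning-free epochs on the
    original weights; (b) *learning* — ``n_rituals`` self-optimization
    cycles; (c) *post* — ``probe_convergences`` fresh-random-state epochs on
    the final combined weights with learning frozen.  Agreements, utility
    and steps are always measured on the original topology.  The whole
    comparison is a pure function of (scenario, n_runs, config).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config.probe_convergences < 1:
        raise ValueError("probe_convergences must be >= 1")
    network = (
        teotihuacan_preset(scenario) if isinstance(scenario, str) else scenario
    )
    epoch_length = config.resolve_epoch_length(network.n_agents)
    pre_records: list[ConvergenceRecord] = []
    post_records: list[ConvergenceRecord] = []
    run_seeds = []
    for run in range(n_runs):
        run_seeds.append(
            int(np.random.SeedSequence(config.seed, spawn_key=(run,)).generate_state(1)[0])
        )
        pre_records.extend(
            run_baseline(
                network,
                config.probe_convergences,
                config,
                rng=_phase_rng(config.seed, run, 0),
                phase_label="pre",
                run_id=run,
            )
        )
        _, adapted = run_self_optimization(
            network, config, rng=_phase_rng(config.seed, run, 1), run_id=run
        )
        w_post = combined_weights(network, adapted)
        rng_post = _phase_rng(config.seed, run, 2)
        for k in range(config.probe_convergences):
            record, _ = _probe_epoch(
                network, w_post, epoch_length, rng_post, "post", k, run
            )
            post_records.append(record)
        if (run + 1) % 10 == 0 or run + 1 == n_runs:
            logger.info(
                "%s: finished run %d/%d", network.scenario_label or "comparison",
                run + 1, n_runs,
            )
    pre = summarize_records(pre_records, network, "pre", run_seeds)
    post = summarize_records(post_records, network, "post", run_seeds)
    return ComparisonResult(pre, post, pre_records, post_records)
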
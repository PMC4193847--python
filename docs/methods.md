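# Methods

## Model

The system is a fully connected Hopfield-type network of `N` agents with
binary states `s_i ∈ {−1, +1}` and symmetric, zero-diagonal weights.
Agent *i*'s utility is `u_i = Σ_{j≠i} ω_ij s_i s_j`; the effective weights
are `ω = ω^O + ω^L`, the static original topology plus accumulated learned
changes. All outcome measures (total utility `U = Σ_i u_i`, agreements =
ordered pairs with `s_i s_j ω^O_ij > 0`, updates-to-convergence) are
computed on `ω^O` only, since the scientific question is how well the
*original* constraints end up satisfied.

**Behavior updates** are asynchronous: one agent per time step, chosen
uniformly at random *with replacement*, adopts the sign of its local field
`h_i = Σ_j ω_ij s_j`. At `h_i = 0` the agent keeps its current state.
This tie rule is a design choice (keeping preserves the Lyapunov argument
and prevents utility-neutral oscillation); empirically it is immaterial —
in the districts preset exact zero fields occur in about 1 in 2×10⁵
updates, and in the neighborhoods preset they are impossible by a parity
argument (the cross-group field is 0.01 times an odd sum).

**Epochs and rituals.** Every `τ = round(e·N·ln N)` updates (752 for
N = 66; rounding to nearest is a design choice, the schedule is defined
only up to real-valued `τ`) the full state vector is replaced by fresh
uniform ±1 values. `τ` is several times the observed convergence time
(mean ≈ 224 updates on the presets), and a fixed-point is reached within
`τ` in ≥ 99% of epochs. Epochs always run the full `τ` updates so that
update-count bookkeeping is comparable across phases; `relax_epoch` has an
`early_stop` flag that detects the fixed point and pads the trace — output
is bitwise identical because agent selections are pre-drawn — but it is
off by default.

**Weight adaptation** happens once per epoch, at the converged state, just
before the next ritual. Each ordered pair evaluates `Δω_ij = ±r` against
agent *i*'s utility and applies the strictly improving change; away from
bounds this is exactly `Δω_ij = r·s_i s_j` (Hebbian), and both agents make
the same decision about their shared connection, so `ω^L` stays symmetric.
The bound `|ω^O + ω^L| ≤ 1` is enforced on the *combined* weight, with
`ω^L` stored as the residual after clamping; at a saturated bound neither
change improves and the entry is untouched. Clamping the combined weight
rather than `ω^L` alone is a design choice; at the default scale
(`200 × r = 0.3` maximum drift) the two readings differ only for
within-group entries that start at the ceiling of 1, which under
combined-clamping simply never move. `ω^L` starts at zero in every run.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` | 0.0015 | per-convergence weight step; small enough that ~10² convergences shape `ω^L`, the slow/fast separation the mechanism needs |
| `τ` | `round(e·N·ln N)` = 752 | updates per epoch; coupon-collector-scale so every agent updates several times |
| `n_rituals` | 200 | learning cycles per run; enough for self-optimization to complete on the presets |
| `probe_convergences` | 200 | learning-free epochs per phase of the comparison |
| weights | 1 / 0.01 (neighborhoods); 1 / 0.02 / 0.006 (districts) | within-group / between-group (/ within-district) importances; chosen so both presets have weight mass 173.58. Illustrative, overridable |

Seeding: all experiments are pure functions of a master seed; per-run and
per-phase generators are derived with `SeedSequence(seed, spawn_key=(run,
phase))` so pre, learning and post phases use independent reproducible
substreams.

## Protocols

* **Baseline** — independent epochs from fresh random states on `ω^O`,
  learning disabled.
* **Self-optimization** — sequential ritual cycles; dynamics on
  `ω^O + ω^L`, per-epoch reporting on `ω^O`, one weight update per epoch.
* **Comparison** — per run: pre probes, learning, then post probes from
  fresh random states on the final combined weights with learning frozen
  (the post phase probes the *product* of self-optimization, not the
  process; an alternative reading that keeps learning on during the post
  epochs gives indistinguishable aggregates once learning has converged).
  Full scale is 100 runs × 200 probes per phase = 20,000 convergences.

`steps_to_convergence` is the smallest trace index after which the
`ω^O`-utility trace is constant. Tracing on `ω^O` while dynamics run on
combined weights can make the trace locally non-monotone; the final
segment is still exactly constant because unchanged states carry the value
over bitwise.

## What the generator does and does not emulate

The topology module *is* the data layer: the study has no empirical data
beyond the two weight structures and uniform random initial states. The
presets encode idealized, perfectly regular modularity — equal group
sizes, exactly two (or three) weight tiers, full connectivity, no spatial
weight modulation, no asymmetric influence, no noise in the update rule.
Passing tests therefore demonstrate properties of this idealized
constraint network, not of any empirically measured social network; in
particular nothing here validates the historical interpretation, only the
formal feasibility claim (distributed selfish dynamics + rituals can
produce reliable global consensus).

## Numerical choices

* Weights are dense float64 matrices (N ≤ a few hundred); states are int8.
* The relaxation loop is numba-compiled; per-update utility is maintained
  incrementally (`ΔU = −4·s_i·h_i` on a flip), so the trace costs one
  extra dot product per accepted flip.
* Agreement counting uses a strict inequality, so zero-weight pairs never
  count.
* Exhaustive oracles: global optima by full 2^N scan (guard N ≤ 20);
  attractor census by deterministic sequential sweeps (agents 0…N−1
  repeatedly, keep-on-tie) from every state (guard N ≤ 16). Deterministic
  sweeps make basins well-defined; random-order basins are random
  variables and are estimated by sampling instead.
* Comparisons to the exact enumerated maximum use a relative 1e-9 guard
  for float summation order only.

## Known limitations and discrepancies

* **Districts statistics.** With the stated districts parameterization
  (1 / 0.02 / 0.006, composition 10/2/5/5) the learning-free phase — a
  pure function of topology and dynamics — yields a mean of ≈ 2828
  agreements and ≈ 110/20,000 consensus convergences, and post-learning
  probes essentially always reach consensus. The reference statistics for
  this scenario (2563 agreements, 53/20,000 pre; 7544/20,000 and 3478
  post) are not reproducible from these parameter values, although the
  same code reproduces every neighborhoods-scenario statistic to within
  sampling error and the districts updates-to-convergence ordering and
  values (≈ 224 pre vs ≈ 264 post). A mass-preserving steeper split
  (0.03 / 0.002) does reproduce the reference pre-phase districts numbers,
  which suggests a parameter provenance issue upstream; the presets
  nevertheless keep the stated values, and the qualitative conclusions
  (districts improve less than neighborhoods is then *not* observed at
  0.02/0.006, where both scenarios self-optimize fully) should be read
  with this caveat. The corresponding full-scale districts test is
  expected to fail and is left failing deliberately.
* The continuous small-learning-rate variant, asymmetric weights,
  habitual (non-rational) adaptation, synchronous updates and
  spatially modulated weights are out of scope.
* Single-trajectory milestones (at which ritual a given run first reaches
  consensus) are seed-specific and only checked qualitatively: ≥ 90% of
  seeds reach and hold the optimum within 200 rituals.
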
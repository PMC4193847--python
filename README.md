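# coalitionsim

A simulator for studying whether a fully distributed coalition — no leader,
no central planner — can reach globally optimal consensus through purely
selfish local behavior. The motivating system is a hypothetical city
government of 22 neighborhood councils with three representatives each
(N = 66 agents), but the machinery is a general self-optimizing
constraint network and all structures are parameterizable.

## The model

Agents carry binary behavioral states `s_i ∈ {−1, +1}` (two choices of
social action, e.g. two vote options) and are coupled by a symmetric weight
matrix `ω` with zero diagonal: `ω_ij > 0` means agent *i* benefits from
matching agent *j*. This is a Hopfield/Ising attractor network read as a
constraint-satisfaction system. Dynamics run on three timescales:

* **Fast — selfish behavior.** At each step a uniformly random agent adopts
  the state maximizing its own utility
  `u_i = Σ_{j≠i} ω_ij s_i s_j`,
  i.e. the sign of its local field (current state kept on an exact tie).
  With symmetric weights this is a Lyapunov dynamic: total utility never
  decreases and the network settles in a fixed-point attractor — usually a
  *suboptimal* one.
* **Slow — selfish weight adaptation.** Once per convergence every agent
  tests, for each connection, whether `Δω_ij = +r` or `−r` would raise its
  own utility and applies the improving change (`r = 0.0015`). Away from
  the `[−1, 1]` bound on the combined weight this is exactly Hebbian
  learning, `Δω_ij = r·s_i·s_j`; learned changes `ω^L` accumulate on top of
  the immutable original topology `ω^O`.
* **Ritual interruptions.** Every `τ = round(e·N·ln N)` updates (752 for
  N = 66) the entire state vector is re-randomized — a model of
  community-wide ritual events that suspend normal social constraints.
  Because better attractors have larger basins, repeated randomize →
  converge → reinforce cycles generalize the learned weights until
  relaxations reliably land on the global optimum of the *original*
  problem: self-optimization.

Two preset topologies are provided: `neighborhoods` (22 groups of 3;
weights 1 within a group, 0.01 between) and `districts` (the same groups
nested into four districts of 10/2/5/5 groups; weights 1 / 0.02 / 0.006).
Both have total weight mass 173.58, so the consensus utility is identical.
All reporting (utility `U`, agreement count, updates-to-convergence) is
evaluated on `ω^O`, even after learning.

## Worked example

```sh
$ coalition-sim baseline --scenario neighborhoods --probes 200 --seed 1
neighborhoods baseline: n=200 mean U=146.77 (SD 7.71) max U=173.58 consensus=1

$ coalition-sim selfopt --scenario neighborhoods --rituals 200 --seed 1
neighborhoods self-optimization: 200 rituals, final-epoch U=173.58, optimum reached in 50/50 of the last epochs
max |combined weight| = 1.0000
```

The baseline shows the collective-action problem: 200 independent
relaxations of the original network average `U = 146.77` against a
consensus optimum of 173.58, and only one run reached consensus — selfish
rational agents get stuck in local equilibria. The second command runs 200
ritual cycles with weight learning on a single network: by the end, every
post-ritual convergence attains the global optimum of the original
constraints (all 50 of the last 50 epochs), even though the weights that
produced it were modified purely selfishly.

The same is available as a library:

```python
import coalitionsim as cs

net = cs.teotihuacan_preset("neighborhoods")
result = cs.run_comparison(net, n_runs=100, config=cs.SimulationConfig(seed=0))
print(result.pre.mean_agreements, result.post.consensus_count)
```

`run_comparison` interleaves, per run, 200 learning-free probe
convergences (pre), 200 ritual-learning cycles, and 200 probes on the
frozen learned weights (post); summaries pool 20,000 convergences per
phase.

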
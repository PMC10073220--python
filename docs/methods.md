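# Methods

## Model overview

`habitnet` simulates free-operant behavior as movement on a network of
response categories.  A simulated experiment has four stages:

1. **Training** (`habitnet.qlearn.train`): the agent emits one response per
   time step, chosen by a softmax over the transition values out of its
   previous response; reinforcement schedules decide deliveries; a one-step
   tabular TD rule updates the value of the completed transition.
2. **Network generation** (`habitnet.network.build_network`): each node
   samples `edges_per_node` distinct targets from a softmax over its
   transition values; the union is an undirected simple graph.
3. **Baseline phase** (`habitnet.traversal.run_phase`): with values and
   network frozen, the agent loops goal choice → shortest path → engagement.
4. **Devaluation and test**: the operant's goal value is set to 0.0 with no
   relearning, and the baseline procedure repeats.

The habit readout is *resistance to devaluation*.  Because its defining
formula is a design choice, the package reports both a ratio
(post / baseline operant proportion; scale-free across conditions, the
default) and a difference (baseline − post).  All directional claims in
the test-suite hold under either.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `alpha` | TD learning rate | 0.1 | per-update step size |
| `gamma` | discount of future transitions | 0.5 | keeps Q ≤ R_max/(1−γ) |
| `beta_c` | choice inverse temperature | 3.0 | training softmax |
| `beta_n` | edge inverse temperature | 50.0 | network softmax |
| `edges_per_node` | sampled targets per node | 2 | min degree by construction |
| `n_nodes` | responses in the environment | 50 | 25/75/100 variants supported |
| operant reward | magnitude per delivery | 1.0 | per schedule |
| other reward | magnitude per other response | 0.001 | FR 1 unless configured |
| `n_loops` | goal choices per phase | 500 | phase length |
| `n_agents` | replicates per condition | 20 | experiment runners |

Q is initialized to zeros; every reported effect is relative, so the
initialization only sets the early exploration regime.

## Schedules

One agent response advances the session clock by exactly one step; there is
no other clock.  Ratio schedules count target responses; interval schedules
count steps.  Variable requirements and intervals are drawn by *stratified
inverse-CDF sampling*: quantiles of the geometric (success probability
1/ratio) or exponential distribution evaluated at the interior midpoints
(k − ½)/n of the unit interval, then randomly permuted.  Midpoints avoid
the infinite endpoint quantiles; permutation randomizes order while keeping
the session's marginal distribution essentially exact (sorted draws are
deterministic given n).  Long sessions extend their sequences chunkwise
with fresh stratified blocks.

Per-kind semantics (see `habitnet/schedules.py` for the full contract):

* **FR k / VR r** deliver when the current requirement is met by target
  responses; VR advances through its pregenerated requirement sequence.
* **VI t** runs an interval timer every step regardless of the response;
  when the interval elapses the reward is *armed* and held until the first
  target response.  Arming is single-capacity: the timer freezes while a
  reward is held (no stacking) and advances again on the collection step
  (no dead time).  Fractional remainders carry over, so realized arming
  times track the exponential draws exactly.
* **VT t** delivers when each interval elapses, independent of responding.
* **tandem** runs components in unsignalled succession and delivers only
  when the final component completes.  A ratio component with value 0 is a
  degenerate, instantly-completing pad: `tandem(X, vr(0))` is step-identical
  to `X`, which is also how the state machine is cross-checked.
* **concurrent** steps all arms independently each time step; contingent
  arms deliver only for their own response id.

Training stops on a *reward-count* criterion (the amount of training is a
number of rewards, not steps).  In the no-choice control (concurrent VI +
VT), VT deliveries count toward that criterion so total reward amounts
match the choice condition.  Non-contingent (VT) rewards are credited to
whatever transition the agent just completed — one-step TD needs a carrier
transition.

## Rate-matching (yoked) VI

The VR-versus-VI comparison uses a VI whose mean interval is matched to the
paired VR session.  Two clocks could define that match:

* *session time*: the realized mean inter-reward interval in steps
  (`yoke_vi_to_vr`, provided and tested); and
* *schedule time*: mean operant responses per reward, ≈ the VR ratio
  (`TrainingLog.mean_responses_per_reward`).

The experiment runners use **schedule time**.  The reason is a property of
the model itself: with β_c = 3 over 50 responses and per-response reward
probability 1/ratio, the training policy stays near-uniform, so the
operant is a small fraction of all responses and a session-time-yoked
interval becomes very long (hundreds of steps).  Under a static policy one
can show the per-response reward probability of an other→operant
transition under such a VI equals the VR's 1/ratio exactly — the
schedule contrast the comparison is meant to probe cancels, and the
residual bootstrap effect runs opposite to the intended manipulation.
Matching on the schedule's own clock preserves the defining difference
between the two rules (time-based versus response-based availability) at
equal programmed cost per reward, and produces the expected dissociation:
the VI selectively rewards transitions *into* the operant from other
responses, the VR rewards all operant responses alike.

## Network generation

Edge probabilities use the **positive** softmax sign,
p_{i,j} ∝ exp(+β_n·Q(i,j)): higher-valued transitions are more likely to
become edges, which is the only sign under which learned value can
concentrate edges on the operant response.  The negative-sign variant is
retained behind `SoftmaxSign.AS_PRINTED_NEGATIVE` for auditability; a unit
test documents that it makes the high-value target the least likely.

Hypothetical matrices for the structure sweep expand the value vector
(q_operant, q_other, …, q_other) by **row replication** (Q[i,j] = q_j).
The literal outer product q_i·q_j is available (`expansion="outer"`) but
its off-diagonal contrasts are of order q_other·q_operant ≈ 10⁻³, far too
weak to move a β_n = 50 softmax; row replication expresses the intended
manipulation (every node values the operant at q_operant).

The graph is undirected: with two sampled out-edges per node, a directed
reading would leave ≈ e⁻² of nodes with in-degree 0 and unreachable as
goals, breaking the traversal loop.  Self-loops are excluded from sampling
(shortest paths cannot contain them) but self-transition values are still
learned and reported.  Disconnected outputs are permitted; metrics flag
them and average path length falls back to the largest component.

## Traversal

Shortest paths are found on the unweighted graph (Dijkstra and BFS
coincide); when several minimal paths exist one is chosen **exactly
uniformly**: a BFS records the number of minimal paths reaching each node,
and the path is sampled backwards from the goal choosing predecessors
proportionally to their path counts.  This avoids the first-found bias of
deterministic tie-breaking and is validated against brute-force
enumeration on small graphs.

Engagement counting: the initial (uniformly random) response counts once;
each loop engages every path node after the current one; a goal equal to
the current response counts as a single re-engagement (paths contain no
self-loops, so this is the only route to self-repetition during phases).
Unreachable goals are resampled with a retry bound.  Conservation
(Σ counts = 1 + Σ engaged path lengths) is a tested invariant.

## What the generators emulate — and what they do not

The schedule samplers and hypothetical-Q generator reproduce the
*programmed* statistics of operant procedures: geometric response
requirements, exponential inter-reward intervals, reward-magnitude
asymmetries, and graded edge concentration.  They do not emulate
bout-and-pause microstructure, innate response-response couplings,
schedule-induced behavior, satiety, or motor constraints.  Passing tests
therefore show that the *network mechanism* produces devaluation
(in)sensitivity under these idealized contingencies — not that real
animals' response topographies follow these distributions.

## Numerical choices

* Softmax probabilities use max-shifted exponentials in the public API;
  the training loop exploits the contraction bound |Q| ≤ R_max/(1−γ) to
  cache unshifted exponentials and update them entrywise (β_c·Q stays
  far below overflow).
* Goal/edge/choice sampling uses cumulative-sum inversion of a single
  uniform draw; all randomness flows through `numpy.random.Generator`
  instances spawned per (condition, agent) via `SeedSequence` keys, so
  every cell of an experiment is independently reproducible and full runs
  are byte-identical for identical (config, seed).
* SARSA updates are one choice late by construction (the bootstrap needs
  the actually chosen next response); the final transition of a session is
  never updated.
* Degenerate inputs: ratio 1 requirements skip the sampler (all ones);
  ratio/interval 0 yield zero sequences without consuming random draws so
  padded tandems stay stream-identical to their simple schedule.

## Problem sizes

Experiment runners default to 20 agents per condition, 50 nodes, 500 goal
choices per phase, and 500 training rewards; the training-amount sweep in
the acceptance suite uses the sub-grid {5, 50, 500} of the configurable
default grid {5, 25, 50, 100, 250, 500}.  These sizes give the directional
statistics comfortable power (rank-test p ≪ 0.05 for the passing effects)
at desk-scale runtimes.

## Known limitations

* **Response-rate regime.**  With β_c = 3.0 over 50 responses and rewards
  of 1.0 per ~15 operant responses, transition values stay ≤ ~0.5 and the
  training softmax stays near-uniform: operant response probability is a
  few percent.  Consequences are documented above (rate-matching) and in
  two deliberately-red end-to-end checks: the self-transition value under
  a schedule-time-yoked VI is *inflated* by the TD max-bootstrap (the value
  of re-entering a hub operant) rather than suppressed below the VR's; and
  in the tandem comparison the two compound schedules differ strongly in
  operant responses per reward (≈ 4 versus ≈ 11), so per-response reward
  richness dominates the contiguity contrast for hub metrics.  The
  contiguity signature itself (self-transition value elevated under
  ratio-terminated tandems) does hold.  Regimes with burst-like operant
  responding would require a sharper policy than these parameters produce.
* Self-transitions never occur during traversal (shortest paths exclude
  them), so bout-and-pause structure is outside the model.
* Only free-operant procedures are covered; multi-stage decision tasks and
  innate constraints (e.g., a prior over edges) are out of scope.
* Wall-clock "required time" is hardware-dependent and intentionally not a
  reported metric; average path length carries the efficiency claim.
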
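# habitnet

A simulator for studying **habit formation as a structural property of a
behavioral network**.  Instead of positing separate goal-directed and
habit systems, the model treats an animal's behavior as a network whose
nodes are response categories (lever press, grooming, rearing, ...) and
whose edges are learned transitions between them.  Habit — operationally,
persistence of an operant response after its reward is devalued — emerges
when edges from other responses concentrate on the operant response, making
it a hub that shortest paths cannot avoid.

The package is aimed at computational behavioral neuroscientists who want
to simulate free-operant experiments (variable-ratio / variable-interval /
variable-time / tandem / concurrent schedules, reward devaluation assays)
and analyze the resulting behavioral networks.

## Model

1. **Transition learning.**  During training the previous response serves
   as the state, and a tabular TD rule learns transition values

   Q(a_{t−1}, a_t) ← Q(a_{t−1}, a_t) + α·δ,
   δ = R(a_t) + γ·max_{a_{t+1}} Q(a_t, a_{t+1}) − Q(a_{t−1}, a_t)

   with α = 0.1, γ = 0.5 (SARSA available as an option).  Responses are
   chosen by a softmax with inverse temperature β_c = 3.0.  The operant
   response earns reward 1.0 under the programmed schedule; every other
   response earns 0.001 on FR 1.

2. **Network generation.**  For every node i, two distinct targets are
   sampled without replacement from p_{i,j} ∝ exp(β_n·Q(i, j)), j ≠ i,
   with β_n = 50; the union of sampled pairs forms an undirected simple
   graph, so every node has at least two edges and no self-loops.

3. **Traversal and devaluation.**  With Q and the network frozen, the agent
   repeatedly (i) picks a goal with probability r_i / Σ_j r_j (operant
   r = 1.0, others 0.001), (ii) finds a shortest path to it — ties broken
   uniformly at random among all minimal paths — and (iii) engages every
   response on the path.  Devaluation sets the operant's r to 0.0 with no
   relearning.  **Resistance to devaluation** is the post/baseline ratio of
   operant response proportions; degree, normalized betweenness centrality
   of the operant node, and average shortest-path length summarize the
   network structure behind it.

## Worked example

```python
import habitnet as hn

cfg = hn.ExperimentConfig(simulation="sim1", n_agents=5,
                          q_operant_grid=(0.0, 0.5, 1.0), seed=7)
df = hn.run_sim1(cfg)
print(df.pivot_table(index=["sweep_value", "agent_id"],
                     columns="metric", values="value")
        .groupby("sweep_value")[["resistance_ratio", "operant_degree",
                                 "betweenness", "avg_path_length"]]
        .mean().round(3))
```

prints

```
metric       resistance_ratio  operant_degree  betweenness  avg_path_length
sweep_value
0.0                     0.010             3.6        0.026            2.927
0.5                     0.490            49.0        0.929            1.920
1.0                     0.495            49.0        0.928            1.920
```

With a flat transition matrix (operant value 0.0) the operant node is an
ordinary node (degree ≈ 3.6 of 49 possible) and devaluation almost
abolishes responding (resistance ≈ 0.01): the behavior is goal-directed.
Raising the hypothetical operant transition value concentrates nearly all
edges on the operant (degree 49, betweenness ≈ 0.93), shortens paths, and
responding persists at half its baseline rate after devaluation — a habit
produced purely by network structure.

The same pipeline runs with *learned* values: `run_sim2` trains agents
under VR 15 versus a rate-matched VI and under choice (concurrent VI 60
VI 60) versus no-choice (concurrent VI 60 VT 60) conditions; `run_sim3`
contrasts tandem VI 15 VR 3 with tandem VR 10 VI 5.  A command-line
interface wraps each pipeline:

```bash
habitnet sim1 --seed 7 --agents 20 --out results/sim1.csv
habitnet sim2 --config myrun.yaml
habitnet sim3 --nodes 25            # network-size variant
```

Each run writes a tidy CSV (one row per agent × condition × metric) and a
JSON manifest with the configuration, seed, and library versions; results
are byte-identical for identical (config, seed).

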
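"""Baseline / post-devaluation phases: goal choice, travel, and resistance.

During a phase the agent repeats three steps with Q and the network frozen:
(1) choose a goal response with probability proportional to its reward
value, (2) find a shortest path from the currently engaged response to the
goal, breaking ties uniformly at random among all minimal paths, and
(3) engage every response along the path.  Habit is read out as the
persistence of the operant response after its reward value is devalued from
1.0 to 0.0: resistance to devaluation is the post/baseline ratio of operant
response proportions (the absolute difference is reported alongside).

Tie-breaking is exactly uniform: a BFS records, for every node, the number
of distinct minimal paths reaching it; the path is then sampled backwards
from the goal choosing each predecessor proportionally to its path count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BehavioralNetwork

__all__ = [
    "RewardValues",
    "PhaseResult",
    "UnreachableGoalError",
    "DisconnectedNetworkError",
    "goal_probabilities",
    "choose_goal",
    "shortest_path",
    "run_phase",
    "devalue",
    "resistance_to_devaluation",
]


class UnreachableGoalError(RuntimeError):
    """No path exists from the current response to the chosen goal."""


class DisconnectedNetworkError(RuntimeError):
    """Goal resampling kept hitting unreachable nodes."""


@dataclass
class RewardValues:
    """Per-response goal values r_i (operant 1.0, others 0.001)."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if (self.r < 0).any():
            raise ValueError("reward values must be >= 0")

    @classmethod
    def standard(
        cls,
        n_responses: int,
        operant_ids: tuple[int, ...] = (0,),
        operant_value: float = 1.0,
        other_value: float = 0.001,
    ) -> "RewardValues":
        r = np.full(n_responses, other_value)
        for i in operant_ids:
            r[i] = operant_value
        return cls(r)


def devalue(values: RewardValues, target: int) -> RewardValues:
    """Set the target's reward value to 0.0; all other entries unchanged.

    Returns a new RewardValues (no learning occurs: the agent never updates
    Q or the network in response to devaluation).  Idempotent.
    """
    r = values.r.copy()
    r[target] = 0.0
    return RewardValues(r)


def goal_probabilities(values: RewardValues) -> np.ndarray:
    """Proportional allocation of reward value: p_i = r_i / sum_j r_j."""
    total = values.r.sum()
    if total <= 0:
        raise ValueError("all reward values are zero; no goal can be chosen")
    return values.r / total


def choose_goal(values: RewardValues, rng: np.random.Generator) -> int:
    p = goal_probabilities(values)
    return int(np.searchsorted(np.cumsum(p), rng.random() * p.sum()))


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, BehavioralNetwork) else net


def shortest_path(net, src: int, goal: int, rng: np.random.Generator) -> list[int]:
    """One minimal-edge-count path from src to goal, uniform among ties.

    ``src == goal`` returns the single-node path.  Raises
    UnreachableGoalError when the goal lies in another component.
    """
    if src == goal:
        return [src]
    adj = _graph(net).adj
    dist: dict[int, int] = {src: 0}
    sigma: dict[int, float] = {src: 1.0}  # minimal-path counts
    frontier = [src]
    while frontier and goal not in dist:
        nxt: list[int] = []
        for u in frontier:
            du1 = dist[u] + 1
            for v in adj[u]:
                if v not in dist:
                    dist[v] = du1
                    sigma[v] = 0.0
                    nxt.append(v)
                if dist[v] == du1:
                    sigma[v] += sigma[u]
        frontier = nxt
    if goal not in dist:
        raise UnreachableGoalError(f"node {goal} unreachable from {src}")
    # sample backwards proportionally to path counts -> exactly uniform
    path = [goal]
    v = goal
    while v != src:
        dv = dist[v] - 1
        preds = [u for u in adj[v] if dist.get(u, -1) == dv]
        w = np.array([sigma[u] for u in preds])
        c = np.cumsum(w)
        v = preds[int(np.searchsorted(c, rng.random() * c[-1]))]
        path.append(v)
    path.reverse()
    return path


@dataclass
class PhaseResult:
    """Engagement counts and traversal record for one phase of one agent."""

    counts: np.ndarray
    n_loops: int
    operant_proportion: float
    path_log: list[list[int]] | None = None

    @property
    def total_engagements(self) -> int:
        return int(self.counts.sum())


def run_phase(
    net: BehavioralNetwork,
    values: RewardValues,
    n_loops: int,
    rng: np.random.Generator,
    operant: int = 0,
    max_goal_retries: int = 100,
    record_paths: bool = False,
) -> PhaseResult:
    """Traverse the network for ``n_loops`` goal choices.

    The first engaged response is uniform random and counts as one
    engagement.  Each loop engages every node on the chosen path after the
    current one; a goal equal to the current response counts as a single
    re-engagement.  Unreachable goals are resampled up to
    ``max_goal_retries`` times before DisconnectedNetworkError.
    """
    g = net.graph
    n = net.n_nodes
    counts = np.zeros(n)
    current = int(rng.integers(n))
    counts[current] += 1
    path_log: list[list[int]] | None = [] if record_paths else None
    for _ in range(n_loops):
        path: list[int] | None = None
        for _attempt in range(max_goal_retries):
            goal = choose_goal(values, rng)
            if goal == current:
                path = [current]
                break
            try:
                path = shortest_path(g, current, goal, rng)
                break
            except UnreachableGoalError:
                continue
        if path is None:
            raise DisconnectedNetworkError(
                f"no reachable goal from node {current} after {max_goal_retries} draws"
            )
        if len(path) == 1:
            counts[current] += 1
        else:
            for node in path[1:]:
                counts[node] += 1
            current = path[-1]
        if path_log is not None:
            path_log.append(path)
    return PhaseResult(
        counts=counts,
        n_loops=n_loops,
        operant_proportion=float(counts[operant] / counts.sum()),
        path_log=path_log,
    )


def resistance_to_devaluation(baseline, post, kind: str = "ratio") -> float:
    """Persistence of the operant response after devaluation.

    ``kind="ratio"`` (default) returns post/baseline operant proportions —
    1.0 means fully habitual, 0.0 fully goal-directed; ``kind="difference"``
    returns baseline - post.  Accepts PhaseResults or bare proportions.
    A zero baseline proportion makes the ratio undefined (NaN, warning).
    """
    b = getattr(baseline, "operant_proportion", baseline)
    p = getattr(post, "operant_proportion", post)
    if kind == "difference":
        return float(b - p)
    if kind != "ratio":
        raise ValueError(f"unknown kind {kind!r}")
    if b == 0:
        warnings.warn("baseline operant proportion is zero; resistance undefined")
        return float("nan")
    return float(p / b)
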
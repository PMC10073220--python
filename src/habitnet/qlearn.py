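"""Tabular TD learning over response-to-response transitions.

The agent's "state" is the response it emitted one step earlier, so the
learned table Q(a_prev, a_cur) holds the value of *transitions* between
responses rather than of responses in a situation.  Defaults follow the
study conditions: learning rate alpha = 0.1, discount gamma = 0.5, choice
inverse temperature beta_c = 3.0, Q initialized to zeros.  Rewards are 1.0
for the operant response (per its schedule) and 0.001 for every other
response (FR 1 on other responses unless configured otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .schedules import (
    ScheduleExhaustedError,
    ScheduleKind,
    ScheduleSpec,
    extend_sequence,
    init_state,
    leaf_sequences,
    step,
)

__all__ = [
    "LearningRule",
    "LearningParams",
    "QMatrix",
    "TrainingLog",
    "Arrangement",
    "softmax_probabilities",
    "choose_training_response",
    "td_error",
    "apply_update",
    "train",
]


class LearningRule(str, Enum):
    Q_LEARNING = "Q_LEARNING"
    SARSA = "SARSA"


@dataclass(frozen=True)
class LearningParams:
    alpha: float = 0.1
    gamma: float = 0.5
    beta_c: float = 3.0
    rule: LearningRule = LearningRule.Q_LEARNING

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if self.beta_c <= 0:
            raise ValueError("beta_c must be > 0")


@dataclass
class QMatrix:
    """N x N transition-value table; row = previous response, column = next."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("QMatrix must be square")

    @classmethod
    def zeros(cls, n_responses: int) -> "QMatrix":
        return cls(np.zeros((n_responses, n_responses)))

    @property
    def n_responses(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "QMatrix":
        return QMatrix(self.values.copy())

    def save(self, path) -> None:
        """Plain-text matrix with a one-line header comment."""
        np.savetxt(path, self.values, header=f"n_responses={self.n_responses}")

    @classmethod
    def load(cls, path) -> "QMatrix":
        return cls(np.loadtxt(path))


@dataclass
class TrainingLog:
    """Per-session record: counted reward times plus optional per-step rows."""

    n_responses: int
    n_steps: int = 0
    n_operant_responses: int = 0
    reward_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    steps: np.ndarray | None = None
    prev: np.ndarray | None = None
    response: np.ndarray | None = None
    reward: np.ndarray | None = None
    delta: np.ndarray | None = None

    @property
    def n_rewards(self) -> int:
        return int(self.reward_steps.size)

    @property
    def mean_responses_per_reward(self) -> float:
        """Mean inter-reward interval on the schedule's own clock, i.e. in
        operant responses rather than session steps (~= the VR ratio)."""
        if self.n_rewards == 0:
            raise ValueError("no rewards delivered")
        return self.n_operant_responses / self.n_rewards

    def to_dataframe(self) -> pd.DataFrame:
        if self.steps is None:
            raise ValueError("training was run without per-step recording")
        return pd.DataFrame(
            {
                "step": self.steps,
                "prev": self.prev,
                "response": self.response,
                "reward": self.reward,
                "delta": self.delta,
            }
        )


@dataclass(frozen=True)
class Arrangement:
    """A free-operant environment: scheduled arms plus background responses.

    ``arms`` are the explicitly scheduled arms (operant schedules and any
    response-independent VT source).  Responses not covered by a contingent
    arm are "other" responses on FR 1 with ``other_magnitude`` reward, or on
    a per-response copy of ``others`` when given (re-targeted to each id).
    ``counted_arms`` lists the arm indices whose deliveries count toward the
    training-amount criterion; by default all arms count.
    """

    arms: tuple[ScheduleSpec, ...]
    n_responses: int = 50
    other_magnitude: float = 0.001
    others: ScheduleSpec | None = None
    counted_arms: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_responses < 2:
            raise ValueError("need at least 2 responses")
        if not self.arms:
            raise ValueError("arrangement needs at least one scheduled arm")
        for a in self.arms:
            if a.kind is not ScheduleKind.VT and not 0 <= a.response < self.n_responses:
                raise ValueError(f"arm response id {a.response} out of range")

    @property
    def operant_ids(self) -> tuple[int, ...]:
        seen: list[int] = []
        for a in self.arms:
            if a.kind is not ScheduleKind.VT and a.response not in seen:
                seen.append(a.response)
        return tuple(seen)


def softmax_probabilities(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax with max-subtraction; invariant to adding a constant."""
    v = np.asarray(values, dtype=float)
    z = np.exp(beta * (v - v.max()))
    return z / z.sum()


def choose_training_response(
    Q: QMatrix, prev: int, beta_c: float, rng: np.random.Generator
) -> int:
    """Sample the next response from softmax(beta_c * Q[prev, :])."""
    p = softmax_probabilities(Q.values[prev], beta_c)
    return int(rng.choice(Q.n_responses, p=p))


def td_error(
    Q: QMatrix,
    a_prev: int,
    a_cur: int,
    reward: float,
    gamma: float,
    rule: LearningRule = LearningRule.Q_LEARNING,
    a_next: int | None = None,
) -> float:
    """Reward-prediction error for the (a_prev -> a_cur) transition.

    Q-learning bootstraps on max_j Q[a_cur, j]; SARSA on Q[a_cur, a_next]
    and therefore requires the actually chosen next response.
    """
    q = Q.values
    if rule is LearningRule.SARSA:
        if a_next is None:
            raise ValueError("SARSA requires a_next")
        bootstrap = q[a_cur, a_next]
    else:
        bootstrap = q[a_cur].max()
    return float(reward + gamma * bootstrap - q[a_prev, a_cur])


def apply_update(Q: QMatrix, a_prev: int, a_cur: int, delta: float, alpha: float) -> QMatrix:
    """In-place update of the single entry (a_prev, a_cur) by alpha * delta."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    Q.values[a_prev, a_cur] += alpha * delta
    return Q


def train(
    arrangement: Arrangement,
    params: LearningParams,
    stop_after_rewards: int,
    rng: np.random.Generator,
    record: bool = False,
    max_steps: int = 5_000_000,
) -> tuple[QMatrix, TrainingLog]:
    """Run choose -> schedule step -> TD update until the reward criterion.

    The amount of training is exactly ``stop_after_rewards`` counted
    deliveries.  ``stop_after_rewards == 0`` returns an untouched zero Q.
    Raises ScheduleExhaustedError if the criterion is unreachable within
    ``max_steps`` time steps.
    """
    if stop_after_rewards < 0:
        raise ValueError("stop_after_rewards must be >= 0")
    n = arrangement.n_responses
    Q = QMatrix.zeros(n)
    q = Q.values
    log = TrainingLog(n_responses=n)
    if stop_after_rewards == 0:
        return Q, log

    arm_specs = arrangement.arms
    arm_states = [init_state(s, stop_after_rewards + 2, rng) for s in arm_specs]
    counted = (
        set(arrangement.counted_arms)
        if arrangement.counted_arms is not None
        else set(range(len(arm_specs)))
    )
    leaves = [
        p for s, st in zip(arm_specs, arm_states) for p in leaf_sequences(s, st)
    ]
    operant = set(arrangement.operant_ids)

    others_specs: dict[int, ScheduleSpec] = {}
    others_states: dict[int, object] = {}
    if arrangement.others is not None:
        for j in range(n):
            if j in operant:
                continue
            sp = ScheduleSpec(
                arrangement.others.kind,
                arrangement.others.value,
                response=j,
                reward_magnitude=arrangement.other_magnitude,
            )
            others_specs[j] = sp
            st = init_state(sp, 64, rng)
            others_states[j] = st
            leaves.extend(leaf_sequences(sp, st))

    alpha, gamma, beta = params.alpha, params.gamma, params.beta_c
    sarsa = params.rule is LearningRule.SARSA

    # Q entries stay within R_max / (1 - gamma) of zero (contraction bound),
    # so beta_c * Q never overflows and the softmax needs no max shift.
    # E caches exp(beta_c * Q) and is patched entrywise after each update.
    E = np.exp(beta * q)

    a_prev = int(rng.integers(n))
    pending: tuple[int, int, float, int] | None = None  # (prev, cur, reward, row_idx)
    reward_steps: list[int] = []
    rows_step: list[int] = []
    rows_prev: list[int] = []
    rows_resp: list[int] = []
    rows_rew: list[float] = []
    rows_delta: list[float] = []

    t = 0
    rewards = 0
    n_operant = 0
    while rewards < stop_after_rewards:
        t += 1
        if t > max_steps:
            raise ScheduleExhaustedError(
                f"reward criterion not reached within {max_steps} steps"
            )
        if t % 32 == 1:
            for lspec, lstate in leaves:
                if len(lstate.pregenerated_sequence) - lstate.sequence_index < 40:
                    extend_sequence(lspec, lstate, rng)

        # softmax choice over the previous response's row
        c = E[a_prev].cumsum()
        a = int(c.searchsorted(rng.random() * c[-1]))
        if a >= n:  # numerical guard
            a = n - 1

        magnitude = 0.0
        for k, (sp, st) in enumerate(zip(arm_specs, arm_states)):
            res = step(sp, st, a)
            if res.delivered:
                magnitude += res.magnitude
                if k in counted:
                    rewards += res.count
                    reward_steps.extend([t] * res.count)
        if a in operant:
            n_operant += 1
        elif arrangement.others is None:
            magnitude += arrangement.other_magnitude
        else:
            res = step(others_specs[a], others_states[a], a)
            if res.delivered:
                magnitude += res.magnitude

        if sarsa:
            if pending is not None:
                pp, pc, pm, pi = pending
                d = pm + gamma * q[pc, a] - q[pp, pc]
                q[pp, pc] += alpha * d
                E[pp, pc] = math.exp(beta * q[pp, pc])
                if record and pi >= 0:
                    rows_delta[pi] = d
            pending = (a_prev, a, magnitude, len(rows_step) if record else -1)
            d_logged = np.nan
        else:
            d_logged = magnitude + gamma * q[a].max() - q[a_prev, a]
            q[a_prev, a] += alpha * d_logged
            E[a_prev, a] = math.exp(beta * q[a_prev, a])

        if record:
            rows_step.append(t)
            rows_prev.append(a_prev)
            rows_resp.append(a)
            rows_rew.append(magnitude)
            rows_delta.append(d_logged)
        a_prev = a

    log.n_steps = t
    log.n_operant_responses = n_operant
    log.reward_steps = np.asarray(reward_steps, dtype=np.int64)
    if record:
        log.steps = np.asarray(rows_step, dtype=np.int64)
        log.prev = np.asarray(rows_prev, dtype=np.int64)
        log.response = np.asarray(rows_resp, dtype=np.int64)
        log.reward = np.asarray(rows_rew)
        log.delta = np.asarray(rows_delta)
    return Q, log
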
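"""Reinforcement-schedule state machines on a discrete response clock.

Time is measured in agent responses: every emitted response advances the
session clock by exactly one step, so ratio schedules (FR/VR) count target
responses while interval schedules (VI/VT) count elapsed steps.

Variable schedules draw their requirement/interval sequences up front by
*stratified* inverse-CDF sampling: the unit interval is divided into equal
bins, the distribution's quantile is evaluated at each bin midpoint, and the
resulting values are randomly permuted.  A session therefore matches the
nominal geometric/exponential distribution almost exactly while the order in
which requirements occur remains random.

Schedule semantics
------------------
FR k      delivers on every k-th target response.
VR r      target responses work off a pregenerated geometric requirement;
          delivery advances to the next requirement.
VI t      an exponential interval elapses (one step per response, regardless
          of which response is emitted), after which the reward is *armed*
          and held until the first target response collects it.  Arming is
          single-capacity: the interval timer is frozen while a reward is
          held, and advances again on the collection step (no dead time).
VT t      delivers as soon as each interval elapses, independent of the
          response stream.
tandem    components run in unsignalled succession; only completion of the
          final component delivers, after which the cycle restarts.
          A degenerate ratio component with value 0 completes instantly and
          is skipped (so ``tandem(X, vr(0))`` is step-identical to ``X``).
concurrent  independent arms stepped in parallel; each contingent arm
          delivers only for its own response id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "ScheduleKind",
    "ScheduleSpec",
    "ScheduleState",
    "StepResult",
    "ScheduleError",
    "ScheduleExhaustedError",
    "InsufficientDataError",
    "fr",
    "vr",
    "vi",
    "vt",
    "tandem",
    "concurrent",
    "sample_vr_requirements",
    "sample_vi_intervals",
    "init_state",
    "step",
    "leaf_sequences",
    "extend_sequence",
    "yoke_vi_to_vr",
]


class ScheduleKind(str, Enum):
    FR = "FR"
    VR = "VR"
    VI = "VI"
    VT = "VT"
    TANDEM = "TANDEM"
    CONCURRENT = "CONCURRENT"


class ScheduleError(ValueError):
    """Invalid schedule parameterization."""


class ScheduleExhaustedError(RuntimeError):
    """A session outran its pregenerated requirements (session end)."""


class InsufficientDataError(ValueError):
    """Too few observed events to compute the requested statistic."""


_SIMPLE_KINDS = (ScheduleKind.FR, ScheduleKind.VR, ScheduleKind.VI, ScheduleKind.VT)


@dataclass(frozen=True)
class ScheduleSpec:
    """Declarative description of one reinforcement schedule.

    ``value`` is the ratio for FR/VR and the mean interval (in steps) for
    VI/VT.  ``response`` is the response id that satisfies a contingent
    schedule (ignored by VT).  Ratio values must be >= 1, except that
    exactly 0 is allowed as a degenerate component inside a tandem.
    """

    kind: ScheduleKind
    value: float | None = None
    components: tuple["ScheduleSpec", ...] = ()
    arms: tuple["ScheduleSpec", ...] = ()
    reward_magnitude: float = 1.0
    response: int = 0

    def __post_init__(self) -> None:
        if self.reward_magnitude < 0:
            raise ScheduleError("reward_magnitude must be >= 0")
        if self.kind in (ScheduleKind.FR, ScheduleKind.VR):
            if self.value is None or not (self.value == 0 or self.value >= 1):
                raise ScheduleError(
                    f"{self.kind.value} value must be >= 1 (or exactly 0 for a "
                    f"degenerate tandem component); got {self.value!r}"
                )
        elif self.kind in (ScheduleKind.VI, ScheduleKind.VT):
            if self.value is None or self.value < 0:
                raise ScheduleError(
                    f"{self.kind.value} value must be >= 0; got {self.value!r}"
                )
        elif self.kind is ScheduleKind.TANDEM:
            if len(self.components) < 2:
                raise ScheduleError("tandem requires at least 2 components")
            if any(c.kind not in _SIMPLE_KINDS for c in self.components):
                raise ScheduleError("tandem components must be FR/VR/VI/VT")
        elif self.kind is ScheduleKind.CONCURRENT:
            if len(self.arms) < 2:
                raise ScheduleError("concurrent requires at least 2 arms")
            contingent = [a.response for a in self.arms if a.kind is not ScheduleKind.VT]
            if len(set(contingent)) != len(contingent):
                raise ScheduleError("concurrent arms must map distinct response ids")


def fr(value: float, *, response: int = 0, reward_magnitude: float = 1.0) -> ScheduleSpec:
    return ScheduleSpec(ScheduleKind.FR, value, response=response, reward_magnitude=reward_magnitude)


def vr(value: float, *, response: int = 0, reward_magnitude: float = 1.0) -> ScheduleSpec:
    return ScheduleSpec(ScheduleKind.VR, value, response=response, reward_magnitude=reward_magnitude)


def vi(value: float, *, response: int = 0, reward_magnitude: float = 1.0) -> ScheduleSpec:
    return ScheduleSpec(ScheduleKind.VI, value, response=response, reward_magnitude=reward_magnitude)


def vt(value: float, *, reward_magnitude: float = 1.0) -> ScheduleSpec:
    return ScheduleSpec(ScheduleKind.VT, value, reward_magnitude=reward_magnitude)


def tandem(
    *components: ScheduleSpec, response: int | None = None, reward_magnitude: float = 1.0
) -> ScheduleSpec:
    """Tandem of ``components`` run in succession; only the last delivers.

    If ``response`` is given, every component is re-targeted to it.
    """
    if response is not None:
        components = tuple(
            ScheduleSpec(c.kind, c.value, response=response, reward_magnitude=c.reward_magnitude)
            for c in components
        )
    return ScheduleSpec(
        ScheduleKind.TANDEM, components=tuple(components), reward_magnitude=reward_magnitude
    )


def concurrent(*arms: ScheduleSpec) -> ScheduleSpec:
    return ScheduleSpec(ScheduleKind.CONCURRENT, arms=tuple(arms))


# ---------------------------------------------------------------------------
# Stratified inverse-CDF samplers
# ---------------------------------------------------------------------------

def _stratified_grid(n: int) -> np.ndarray:
    # interior midpoints (k - 0.5)/n, k = 1..n: excludes 0 and 1 so the
    # exponential/geometric quantiles stay finite
    return (np.arange(1, n + 1) - 0.5) / n


def sample_vr_requirements(ratio: float, n_rewards: int, rng: np.random.Generator) -> np.ndarray:
    """Response requirements for a VR ``ratio`` schedule.

    Quantiles of the geometric distribution (success probability 1/ratio,
    support {1, 2, ...}) on a stratified midpoint grid, randomly permuted.
    """
    if n_rewards < 1:
        raise ScheduleError("n_rewards must be >= 1")
    if ratio < 1:
        raise ScheduleError("ratio must be >= 1")
    if ratio == 1:
        return np.ones(n_rewards, dtype=np.int64)
    req = stats.geom.ppf(_stratified_grid(n_rewards), 1.0 / ratio).astype(np.int64)
    return rng.permutation(req)


def sample_vi_intervals(
    mean_interval: float, n_rewards: int, rng: np.random.Generator
) -> np.ndarray:
    """Inter-reward intervals for a VI/VT schedule with the given mean.

    Quantiles of the exponential distribution on a stratified midpoint grid,
    randomly permuted.
    """
    if n_rewards < 1:
        raise ScheduleError("n_rewards must be >= 1")
    if mean_interval <= 0:
        raise ScheduleError("mean_interval must be > 0")
    iv = stats.expon.ppf(_stratified_grid(n_rewards), scale=mean_interval)
    return rng.permutation(iv)


# ---------------------------------------------------------------------------
# Session state
# ---------------------------------------------------------------------------

@dataclass
class ScheduleState:
    """Mutable run state for one schedule (see module docstring)."""

    pregenerated_sequence: np.ndarray = field(default_factory=lambda: np.empty(0))
    sequence_index: int = 0
    progress_counter: float = 0.0
    armed: bool = False
    component_index: int = 0
    component_states: list["ScheduleState"] | None = None
    arm_states: list["ScheduleState"] | None = None

    @property
    def exhausted(self) -> bool:
        return self.sequence_index >= len(self.pregenerated_sequence)


@dataclass(frozen=True)
class StepResult:
    delivered: bool
    magnitude: float = 0.0
    count: int = 0  # number of component deliveries (concurrent arms may sum)


_NO_REWARD = StepResult(False)  # shared no-delivery result (hot path)


def _draw_sequence(spec: ScheduleSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind is ScheduleKind.VR:
        if spec.value == 0:
            return np.zeros(n, dtype=np.int64)  # degenerate: no rng draw
        return sample_vr_requirements(spec.value, n, rng)
    if spec.kind in (ScheduleKind.VI, ScheduleKind.VT):
        if spec.value == 0:
            return np.zeros(n)
        return sample_vi_intervals(spec.value, n, rng)
    return np.empty(0)


def init_state(spec: ScheduleSpec, n_rewards: int, rng: np.random.Generator) -> ScheduleState:
    """Pregenerate sequences for roughly ``n_rewards`` deliveries."""
    n = max(int(n_rewards), 1)
    if spec.kind is ScheduleKind.TANDEM:
        return ScheduleState(component_states=[init_state(c, n, rng) for c in spec.components])
    if spec.kind is ScheduleKind.CONCURRENT:
        return ScheduleState(arm_states=[init_state(a, n, rng) for a in spec.arms])
    return ScheduleState(pregenerated_sequence=_draw_sequence(spec, n, rng))


def leaf_sequences(
    spec: ScheduleSpec, state: ScheduleState
) -> list[tuple[ScheduleSpec, ScheduleState]]:
    """All (spec, state) pairs holding a pregenerated sequence."""
    if spec.kind is ScheduleKind.TANDEM:
        return [
            p for c, cs in zip(spec.components, state.component_states)
            for p in leaf_sequences(c, cs)
        ]
    if spec.kind is ScheduleKind.CONCURRENT:
        return [
            p for a, ast in zip(spec.arms, state.arm_states) for p in leaf_sequences(a, ast)
        ]
    if spec.kind is ScheduleKind.FR:
        return []
    return [(spec, state)]


def extend_sequence(
    spec: ScheduleSpec, state: ScheduleState, rng: np.random.Generator, n: int = 512
) -> None:
    """Append a fresh stratified chunk so long sessions never run dry."""
    state.pregenerated_sequence = np.concatenate(
        [state.pregenerated_sequence, _draw_sequence(spec, n, rng)]
    )


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def step(
    spec: ScheduleSpec, state: ScheduleState, response: int, dt: float = 1.0
) -> StepResult:
    """Advance the schedule by one time step in which ``response`` was emitted.

    Mutates ``state`` in place and reports whether a reward was delivered.
    """
    kind = spec.kind
    if kind in (ScheduleKind.FR, ScheduleKind.VR):
        return _step_ratio(spec, state, response)
    if kind is ScheduleKind.VI:
        return _step_vi(spec, state, response, dt)
    if kind is ScheduleKind.VT:
        return _step_vt(spec, state, dt)
    if kind is ScheduleKind.TANDEM:
        return _step_tandem(spec, state, response, dt)
    return _step_concurrent(spec, state, response, dt)


def _current_requirement(spec: ScheduleSpec, state: ScheduleState) -> float | None:
    if spec.kind is ScheduleKind.FR:
        return spec.value
    if state.sequence_index >= len(state.pregenerated_sequence):
        return None  # exhausted: schedule goes silent
    return float(state.pregenerated_sequence[state.sequence_index])


def _step_ratio(spec: ScheduleSpec, state: ScheduleState, response: int) -> StepResult:
    req = _current_requirement(spec, state)
    if req is None:
        return _NO_REWARD
    if response == spec.response:
        state.progress_counter += 1.0
    if state.progress_counter >= req:
        state.progress_counter = 0.0
        if spec.kind is ScheduleKind.VR:
            state.sequence_index += 1
        return StepResult(True, spec.reward_magnitude, 1)
    return _NO_REWARD


def _advance_vi_timer(state: ScheduleState, dt: float) -> None:
    state.progress_counter += dt
    seq = state.pregenerated_sequence
    i = state.sequence_index
    if i < len(seq) and state.progress_counter >= seq[i]:
        state.armed = True
        state.progress_counter -= float(seq[i])
        state.sequence_index = i + 1


def _step_vi(spec: ScheduleSpec, state: ScheduleState, response: int, dt: float) -> StepResult:
    if state.armed:
        if response == spec.response:
            state.armed = False
            _advance_vi_timer(state, dt)  # the collection step still counts
            return StepResult(True, spec.reward_magnitude, 1)
        return _NO_REWARD  # held reward; timer frozen (single capacity)
    _advance_vi_timer(state, dt)
    if state.armed and response == spec.response:
        state.armed = False
        return StepResult(True, spec.reward_magnitude, 1)
    return _NO_REWARD


def _step_vt(spec: ScheduleSpec, state: ScheduleState, dt: float) -> StepResult:
    state.progress_counter += dt
    seq = state.pregenerated_sequence
    i = state.sequence_index
    if i < len(seq) and state.progress_counter >= seq[i]:
        state.progress_counter -= float(seq[i])
        state.sequence_index = i + 1
        return StepResult(True, spec.reward_magnitude, 1)
    return _NO_REWARD


def _is_zero_ratio(comp: ScheduleSpec, cstate: ScheduleState) -> bool:
    if comp.kind is ScheduleKind.FR:
        return comp.value == 0
    if comp.kind is ScheduleKind.VR:
        seq = cstate.pregenerated_sequence
        return cstate.sequence_index < len(seq) and seq[cstate.sequence_index] == 0
    return False


def _tandem_advance(spec: ScheduleSpec, state: ScheduleState) -> bool:
    """Move past the just-completed component; True when the cycle delivered.

    Degenerate (zero-requirement) ratio components complete instantly and
    are skipped, which makes a trailing ``vr(0)`` component transparent.
    """
    n = len(spec.components)
    delivered = False
    i = state.component_index
    hops = 0
    while True:
        if i == n - 1:
            if delivered:
                raise ScheduleError("tandem consists solely of zero-requirement components")
            delivered = True
            i = 0
        else:
            i += 1
        comp = spec.components[i]
        cstate = state.component_states[i]
        if _is_zero_ratio(comp, cstate):
            if comp.kind is ScheduleKind.VR:
                cstate.sequence_index += 1
            hops += 1
            if hops > 2 * n:
                raise ScheduleError("tandem consists solely of zero-requirement components")
            continue
        break
    state.component_index = i
    return delivered


def _step_tandem(
    spec: ScheduleSpec, state: ScheduleState, response: int, dt: float
) -> StepResult:
    i = state.component_index
    cres = step(spec.components[i], state.component_states[i], response, dt)
    if not cres.delivered:
        return _NO_REWARD
    if _tandem_advance(spec, state):
        return StepResult(True, spec.reward_magnitude, 1)
    return _NO_REWARD


def _step_concurrent(
    spec: ScheduleSpec, state: ScheduleState, response: int, dt: float
) -> StepResult:
    delivered = False
    magnitude = 0.0
    count = 0
    for arm, ast in zip(spec.arms, state.arm_states):
        r = step(arm, ast, response, dt)
        if r.delivered:
            delivered = True
            magnitude += r.magnitude
            count += r.count
    return StepResult(delivered, magnitude, count)


# ---------------------------------------------------------------------------
# Yoking
# ---------------------------------------------------------------------------

def yoke_vi_to_vr(vr_training_log) -> float:
    """Mean inter-reward interval (in steps) of a completed VR session.

    Accepts a ``TrainingLog`` (uses its ``reward_steps``) or any sequence of
    reward step times.  Used to parameterize a VI schedule matched in reward
    rate to a VR session.
    """
    steps = getattr(vr_training_log, "reward_steps", vr_training_log)
    steps = np.asarray(steps, dtype=float)
    if steps.size < 2:
        raise InsufficientDataError("need at least 2 reward events to yoke a VI schedule")
    return float(np.mean(np.diff(steps)))
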
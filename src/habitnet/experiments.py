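"""End-to-end devaluation experiments: train, build network, assay habit.

Three study designs are provided:

* ``run_sim1`` — structure sweep: hypothetical Q-matrices with the operant
  column swept over a grid; measures how edge concentration on the operant
  response produces resistance to devaluation.
* ``run_sim2`` — learned Q-values: VR vs. rate-matched (yoked) VI across
  training amounts, plus choice (concurrent VI VI, two operants) vs.
  no-choice (concurrent VI VT, one operant) conditions.
* ``run_sim3`` — tandem schedules: VI, VR, tandem VI 15 VR 3 and tandem
  VR 10 VI 5, separating response-reward correlation from contiguity.

Every run is reproducible from (config, seed): per-agent generators are
spawned from the master seed with a counter-based key, so each condition is
independently reproducible.  Results come back as a tidy DataFrame with one
row per (agent, condition, metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .network import NetworkParams, build_network, hypothetical_q, network_metrics
from .qlearn import Arrangement, LearningParams, LearningRule, QMatrix, train
from .schedules import tandem, vi, vr, vt
from .traversal import RewardValues, devalue, resistance_to_devaluation, run_phase

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "run_simulation",
    "agent_rng",
]

RESULT_COLUMNS = [
    "simulation",
    "condition",
    "sweep_value",
    "agent_id",
    "seed",
    "metric",
    "value",
]


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the field."""


@dataclass(frozen=True)
class ExperimentConfig:
    simulation: str = "sim1"
    n_agents: int = 20
    n_nodes: int = 50
    n_loops: int = 500
    seed: int = 0
    learning: LearningParams = field(default_factory=LearningParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    # sim1
    q_operant_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    q_other: float = 0.001
    q_expansion: str = "replicate"
    # sim2 / sim3
    training_amounts: tuple[int, ...] = (5, 25, 50, 100, 250, 500)
    n_training_rewards: int = 500
    vr_ratio: float = 15.0
    choice_vi_mean: float = 60.0
    tandem_vi_vr: tuple[float, float] = (15.0, 3.0)
    tandem_vr_vi: tuple[float, float] = (10.0, 5.0)

    def __post_init__(self) -> None:
        if self.simulation not in ("sim1", "sim2", "sim3"):
            raise ConfigError(f"simulation must be sim1/sim2/sim3, got {self.simulation!r}")
        if self.n_agents < 1:
            raise ConfigError("n_agents must be >= 1")
        if self.n_nodes < 3:
            raise ConfigError("n_nodes must be >= 3")
        if self.n_loops < 1:
            raise ConfigError("n_loops must be >= 1")
        if not self.q_operant_grid:
            raise ConfigError("q_operant_grid must be non-empty")
        if any(not 0.0 <= q <= 1.0 for q in self.q_operant_grid):
            raise ConfigError("q_operant_grid values must lie in [0, 1]")
        if not self.training_amounts or any(a < 2 for a in self.training_amounts):
            raise ConfigError("training_amounts must all be >= 2 (yoking needs 2 rewards)")
        if self.n_training_rewards < 2:
            raise ConfigError("n_training_rewards must be >= 2")
        if self.vr_ratio < 1:
            raise ConfigError("vr_ratio must be >= 1")
        if self.choice_vi_mean <= 0:
            raise ConfigError("choice_vi_mean must be > 0")
        for name in ("tandem_vi_vr", "tandem_vr_vi"):
            pair = getattr(self, name)
            if len(pair) != 2 or any(v is None for v in pair):
                raise ConfigError(f"{name} must give two schedule values")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        kw = dict(raw)
        try:
            if isinstance(kw.get("learning"), dict):
                if "rule" in kw["learning"]:
                    kw["learning"]["rule"] = LearningRule(kw["learning"]["rule"])
                kw["learning"] = LearningParams(**kw["learning"])
            if isinstance(kw.get("network"), dict):
                kw["network"] = NetworkParams(**kw["network"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"learning/network: {exc}") from exc
        for name in ("q_operant_grid", "training_amounts", "tandem_vi_vr", "tandem_vr_vi"):
            if name in kw:
                if kw[name] is None:
                    raise ConfigError(f"{name} must not be null")
                kw[name] = tuple(kw[name])
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def agent_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one (condition, agent) cell of a run."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def devaluation_assay(
    Q: QMatrix,
    operant_ids: tuple[int, ...],
    cfg: ExperimentConfig,
    rng: np.random.Generator,
    devalued: int = 0,
) -> dict[str, float]:
    """Network generation + baseline + post-devaluation readout for one agent."""
    net = build_network(Q, cfg.network, operant_ids, rng)
    values = RewardValues.standard(cfg.n_nodes, operant_ids)
    baseline = run_phase(net, values, cfg.n_loops, rng, operant=devalued)
    post = run_phase(net, devalue(values, devalued), cfg.n_loops, rng, operant=devalued)
    m = network_metrics(net, devalued)
    return {
        "baseline_proportion": baseline.operant_proportion,
        "post_proportion": post.operant_proportion,
        "resistance_ratio": resistance_to_devaluation(baseline, post),
        "resistance_diff": resistance_to_devaluation(baseline, post, kind="difference"),
        "operant_degree": float(m.degree),
        "betweenness": m.betweenness,
        "avg_path_length": m.avg_path_length,
        "connected": float(m.connected),
        "q_self": float(Q.values[devalued, devalued]),
    }


def _rows(cfg, condition, sweep_value, agent_id, metrics: dict[str, float]) -> list[dict]:
    return [
        {
            "simulation": cfg.simulation,
            "condition": condition,
            "sweep_value": sweep_value,
            "agent_id": agent_id,
            "seed": cfg.seed,
            "metric": k,
            "value": v,
        }
        for k, v in metrics.items()
    ]


def run_sim1(cfg: ExperimentConfig) -> pd.DataFrame:
    """Structure sweep over the hypothetical operant Q-value grid."""
    rows: list[dict] = []
    for li, q_op in enumerate(cfg.q_operant_grid):
        Q = hypothetical_q(q_op, cfg.q_other, cfg.n_nodes, cfg.q_expansion)
        for a in range(cfg.n_agents):
            rng = agent_rng(cfg.seed, 1, li, a)
            metrics = devaluation_assay(Q, (0,), cfg, rng)
            rows += _rows(cfg, "q_operant", q_op, a, metrics)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _train_and_assay(
    cfg: ExperimentConfig,
    arrangement: Arrangement,
    amount: int,
    rng: np.random.Generator,
    devalued: int = 0,
):
    Q, log = train(arrangement, cfg.learning, amount, rng)
    metrics = devaluation_assay(Q, arrangement.operant_ids, cfg, rng, devalued=devalued)
    return metrics, log


def run_sim2(cfg: ExperimentConfig) -> pd.DataFrame:
    """VR vs. yoked VI across training amounts, plus choice vs. no-choice."""
    rows: list[dict] = []
    n = cfg.n_nodes
    for ai, amount in enumerate(cfg.training_amounts):
        for a in range(cfg.n_agents):
            arr_vr = Arrangement(arms=(vr(cfg.vr_ratio),), n_responses=n)
            m_vr, log_vr = _train_and_assay(cfg, arr_vr, amount, agent_rng(cfg.seed, 2, 0, ai, a))
            rows += _rows(cfg, "VR", amount, a, m_vr)
            # VI matched to the VR schedule's mean inter-reward interval on
            # the schedule's own clock (operant responses per reward)
            yoked = log_vr.mean_responses_per_reward
            arr_vi = Arrangement(arms=(vi(yoked),), n_responses=n)
            m_vi, _ = _train_and_assay(cfg, arr_vi, amount, agent_rng(cfg.seed, 2, 1, ai, a))
            rows += _rows(cfg, "VI", amount, a, m_vi)
    amount = cfg.n_training_rewards
    for a in range(cfg.n_agents):
        arr_choice = Arrangement(
            arms=(vi(cfg.choice_vi_mean, response=0), vi(cfg.choice_vi_mean, response=1)),
            n_responses=n,
        )
        m_c, _ = _train_and_assay(cfg, arr_choice, amount, agent_rng(cfg.seed, 2, 2, 0, a))
        rows += _rows(cfg, "choice", amount, a, m_c)
        arr_nochoice = Arrangement(
            arms=(vi(cfg.choice_vi_mean, response=0), vt(cfg.choice_vi_mean)),
            n_responses=n,
        )
        m_n, _ = _train_and_assay(cfg, arr_nochoice, amount, agent_rng(cfg.seed, 2, 3, 0, a))
        rows += _rows(cfg, "no_choice", amount, a, m_n)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_sim3(cfg: ExperimentConfig) -> pd.DataFrame:
    """VI, VR, tandem VI VR, and tandem VR VI at a fixed training amount."""
    rows: list[dict] = []
    n = cfg.n_nodes
    amount = cfg.n_training_rewards
    t_vivr = cfg.tandem_vi_vr
    t_vrvi = cfg.tandem_vr_vi
    for a in range(cfg.n_agents):
        arr_vr = Arrangement(arms=(vr(cfg.vr_ratio),), n_responses=n)
        m_vr, log_vr = _train_and_assay(cfg, arr_vr, amount, agent_rng(cfg.seed, 3, 0, 0, a))
        rows += _rows(cfg, "VR", amount, a, m_vr)
        yoked = log_vr.mean_responses_per_reward
        arr_vi = Arrangement(arms=(vi(yoked),), n_responses=n)
        m_vi, _ = _train_and_assay(cfg, arr_vi, amount, agent_rng(cfg.seed, 3, 1, 0, a))
        rows += _rows(cfg, "VI", amount, a, m_vi)
        arr_t1 = Arrangement(
            arms=(tandem(vi(t_vivr[0]), vr(t_vivr[1])),), n_responses=n
        )
        m_t1, _ = _train_and_assay(cfg, arr_t1, amount, agent_rng(cfg.seed, 3, 2, 0, a))
        rows += _rows(cfg, "tandem_VI_VR", amount, a, m_t1)
        arr_t2 = Arrangement(
            arms=(tandem(vr(t_vrvi[0]), vi(t_vrvi[1])),), n_responses=n
        )
        m_t2, _ = _train_and_assay(cfg, arr_t2, amount, agent_rng(cfg.seed, 3, 3, 0, a))
        rows += _rows(cfg, "tandem_VR_VI", amount, a, m_t2)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_simulation(cfg: ExperimentConfig) -> pd.DataFrame:
    return {"sim1": run_sim1, "sim2": run_sim2, "sim3": run_sim3}[cfg.simulation](cfg)
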
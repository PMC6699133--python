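"""The five simulated intervention conditions.

Four strategies select *influence agents* — the top 15% of a class by
in-degree, betweenness or closeness centrality, or a uniform random 15% —
whose initial PAL is boosted by 17% before a 365-day simulation; a control
condition runs the bare dynamics.  The outcome per class and condition is
the *success rate*: the percent change of the class mean PAL from day 0
(post-boost) to day 364.  The random condition is replicated 100 times with
fresh selections and its success rates averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import abm
from .abm import AgentStates, SimConfig, Trajectory  # noqa: F401 (Trajectory re-exported)
from .metrics import CENTRALITY_MEASURES, centralities

__all__ = [
    "Condition",
    "ConditionResult",
    "ClassData",
    "CONDITION_NAMES",
    "default_conditions",
    "selection_size",
    "select_influence_agents",
    "apply_boost",
    "success_rate",
    "run_condition",
    "prepare_classes",
    "run_experiment",
]

CONDITION_NAMES = ("control", "random", "in_degree", "betweenness", "closeness")


@dataclass(frozen=True)
class Condition:
    """One intervention arm."""

    name: str
    fraction: float = 0.15
    boost: float = 0.17
    random_replicates: int = 100

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {self.name!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        if self.boost < 0:
            raise ValueError("boost must be >= 0")
        if self.random_replicates < 1:
            raise ValueError("random_replicates must be >= 1")


def default_conditions(fraction: float = 0.15, boost: float = 0.17,
                       random_replicates: int = 100) -> list[Condition]:
    return [Condition(name, fraction, boost, random_replicates)
            for name in CONDITION_NAMES]


@dataclass
class ConditionResult:
    class_id: str
    condition: str
    success_rate: float
    selected_agents: list
    mean_trajectory: np.ndarray  # class mean PAL per day (random: replicate avg)
    seed: int


@dataclass
class ClassData:
    """Everything one class contributes to the experiment."""

    class_id: str
    graph: nx.DiGraph
    centralities: pd.DataFrame
    states: AgentStates


def selection_size(n: int, fraction: float) -> int:
    """Number of influence agents: round-half-up of fraction*n, at least 1."""
    if n < 1:
        raise ValueError("empty class")
    return max(1, int(math.floor(fraction * n + 0.5)))


def select_influence_agents(network: nx.DiGraph,
                            table: pd.DataFrame,
                            condition: Condition,
                            rng: np.random.Generator) -> list:
    """Choose the influence agents for one class under one condition.

    Centrality conditions take the top-k pupils on the named measure; when
    several pupils tie at the cutoff score, the remaining slots are filled
    by a uniform random draw among the tied pupils.  The random condition
    samples k pupils uniformly without replacement; control selects nobody.
    """
    nodes = list(network.nodes)
    if condition.name == "control":
        return []
    k = selection_size(len(nodes), condition.fraction)
    if condition.name == "random":
        idx = rng.choice(len(nodes), size=k, replace=False)
        return [nodes[i] for i in sorted(idx)]
    scores = table.loc[nodes, condition.name].to_numpy(float)
    order = np.argsort(-scores, kind="stable")
    cutoff = scores[order[k - 1]]
    above = [nodes[i] for i in order if scores[i] > cutoff]
    tied = [nodes[i] for i in order if scores[i] == cutoff]
    need = k - len(above)
    chosen_tied = [tied[i] for i in sorted(rng.choice(len(tied), size=need, replace=False))]
    return above + chosen_tied


def apply_boost(states: AgentStates, agents, boost: float,
                pal_bounds: tuple[float, float] = SimConfig().pal_bounds) -> AgentStates:
    """Raise the initial PAL of the selected agents by ``boost`` (relative),
    clamped to ``pal_bounds``; all other pupils are untouched."""
    new = states.copy()
    index = {a: i for i, a in enumerate(states.ids)}
    for a in agents:
        if a not in index:
            raise KeyError(f"unknown agent id {a!r}")
        i = index[a]
        new.pal[i] = np.clip(new.pal[i] * (1.0 + boost), *pal_bounds)
    return new


def success_rate(trajectory: Trajectory) -> float:
    """Percent change of class mean PAL between the first and last day."""
    mean = trajectory.mean_pal
    if np.any(mean[0] == 0):
        raise ValueError("day-0 mean PAL is zero")
    value = 100.0 * (mean[-1] - mean[0]) / mean[0]
    return float(value) if np.ndim(value) == 0 else float(np.mean(value))


def run_condition(network: nx.DiGraph,
                  baseline: AgentStates,
                  condition: Condition,
                  config: SimConfig,
                  rng: np.random.Generator,
                  table: pd.DataFrame | None = None) -> ConditionResult:
    """Run one condition on one class.

    Control and centrality conditions are single deterministic runs (the rng
    only breaks centrality ties); the random condition repeats the
    select-boost-run cycle ``condition.random_replicates`` times in lockstep
    and averages the success rates.
    """
    if table is None:
        table = centralities(network)
    class_id = network.graph.get("class_id", "")
    seed = int(rng.integers(0, 2**31 - 1))
    if condition.name == "random":
        m = condition.random_replicates
        n = len(baseline.ids)
        pal0 = np.repeat(baseline.pal[:, None], m, axis=1)
        k = selection_size(n, condition.fraction)
        selections = []
        for r in range(m):
            idx = rng.choice(n, size=k, replace=False)
            selections.append([baseline.ids[i] for i in sorted(idx)])
            pal0[idx, r] *= 1.0 + condition.boost
        states = AgentStates(list(baseline.ids), np.clip(pal0, *config.pal_bounds),
                             baseline.env.copy(),
                             None if baseline.threshold is None else baseline.threshold.copy())
        traj = abm.run(network, states, config)
        # per-replicate success through the same contiguous 1-run path, then a
        # shifted mean (exact when all replicates coincide, e.g. zero boost)
        rates = np.array([
            success_rate(Trajectory(traj.ids, np.ascontiguousarray(traj.pal[:, :, r])))
            for r in range(m)
        ])
        avg = float(rates[0] + np.mean(rates - rates[0]))
        return ConditionResult(class_id, condition.name, avg,
                               sorted(set(a for sel in selections for a in sel)),
                               traj.mean_pal.mean(axis=1), seed)
    agents = select_influence_agents(network, table, condition, rng)
    states = apply_boost(baseline, agents, condition.boost, config.pal_bounds)
    traj = abm.run(network, states, config)
    return ConditionResult(class_id, condition.name, success_rate(traj),
                           list(agents), traj.mean_pal, seed)


def prepare_classes(participants: pd.DataFrame,
                    networks: dict[str, nx.DiGraph],
                    threshold: float | None = None) -> list[ClassData]:
    """Bundle network, centralities and baseline agent states per class."""
    out = []
    for class_id in sorted(networks):
        g = networks[class_id]
        sub = participants.set_index("participant_id").loc[list(g.nodes)]
        states = AgentStates(
            ids=list(g.nodes),
            pal=sub["baseline_pal"].to_numpy(float),
            env=sub["env"].to_numpy(float),
            threshold=None if threshold is None else np.full(len(g), threshold),
        )
        out.append(ClassData(class_id, g, centralities(g), states))
    return out


def run_experiment(classes: list[ClassData],
                   config: SimConfig,
                   conditions: list[Condition] | None = None,
                   master_seed: int = 0,
                   collect_trajectories: bool = False):
    """All conditions on all classes; long-format results table.

    Per class and condition a child rng is derived deterministically from
    the master seed, so the whole table is reproducible and any single cell
    can be replayed from the logged seed.  With ``collect_trajectories`` a
    second long-format frame (class_id, condition, day, mean_pal) is
    returned as well.
    """
    if conditions is None:
        conditions = default_conditions()
    rows = []
    traj_frames = []
    for ci, cls in enumerate(classes):
        for cj, cond in enumerate(conditions):
            rng = np.random.default_rng(np.random.SeedSequence([master_seed, ci, cj]))
            res = run_condition(cls.graph, cls.states, cond, config, rng,
                                table=cls.centralities)
            rows.append(
                {
                    "class_id": cls.class_id,
                    "condition": cond.name,
                    "success_rate": res.success_rate,
                    "n_agents": len(res.selected_agents),
                    "seed": res.seed,
                }
            )
            if collect_trajectories:
                traj_frames.append(pd.DataFrame(
                    {
                        "class_id": cls.class_id,
                        "condition": cond.name,
                        "day": np.arange(len(res.mean_trajectory)),
                        "mean_pal": res.mean_trajectory,
                    }
                ))
    results = pd.DataFrame(rows)
    if collect_trajectories:
        return results, pd.concat(traj_frames, ignore_index=True)
    return results
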
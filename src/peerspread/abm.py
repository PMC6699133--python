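"""Deterministic three-phase diffusion model of physical activity.

Each simulated day every pupil's physical activity level (PAL) is updated in
three phases, applied synchronously to the whole class:

1. *Social influence*: the weighted mean PAL of the classmates the pupil
   nominated (out-neighbours), S_i = sum_j w_ij PAL_j / sum_j w_ij.  A pupil
   with no nominations feels no social pull (S_i = PAL_i).
2. *Socio-environmental combination*: the social signal is mixed with an
   environment anchor, T_i = (1 - lambda) S_i + lambda * a(env_i) with
   a(env) = pal_ref (2 - env)/2, and the discrepancy Delta_i = T_i - PAL_i
   is the socio-environmental influence.
3. *Threshold comparison*: only influences exceeding the pupil's change
   threshold act: if |Delta_i| > theta_i then
   PAL_i <- clamp(PAL_i + eta Delta_i), else PAL_i is unchanged.

The model has no randomness: trajectories are fully determined by the
network, the initial states and the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SimConfig",
    "AgentStates",
    "Trajectory",
    "pal_anchor",
    "social_influence",
    "socioenvironmental_influence",
    "threshold_gate",
    "weight_matrix",
    "step",
    "run",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    days
        Number of simulated days recorded, day 0 .. days-1 (default 365,
        i.e. day 0-364); day 0 is the initial (post-intervention) state.
    eta
        Fraction of the socio-environmental influence applied per day.
    lambda_env
        Mixing weight of the environment anchor against the social signal.
    threshold
        Default change threshold theta (per-agent values may override).
    pal_bounds
        Hard clamp on PAL.
    pal_ref
        PAL anchored by the most affluent environment (env = 0); the anchor
        falls linearly to 0 at env = 2.
    """

    days: int = 365
    eta: float = 0.05
    lambda_env: float = 0.15
    threshold: float = 0.2
    pal_bounds: tuple[float, float] = (0.1, 4.27)
    pal_ref: float = 7.0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must be in (0, 1]")
        if not 0.0 <= self.lambda_env <= 1.0:
            raise ValueError("lambda_env must be in [0, 1]")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.pal_bounds[0] >= self.pal_bounds[1]:
            raise ValueError("pal_bounds must be increasing")


@dataclass
class AgentStates:
    """Per-pupil simulation state for one class.

    ``pal`` may be a vector (n,) or a matrix (n, m) to run m independent
    replicates of the same class in lockstep; ``env`` and ``threshold``
    are per-pupil and broadcast across replicates.
    """

    ids: list
    pal: np.ndarray
    env: np.ndarray
    threshold: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pal = np.asarray(self.pal, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        if self.pal.shape[0] != len(self.ids) or self.env.shape != (len(self.ids),):
            raise ValueError("pal/env shapes inconsistent with ids")
        if np.any(self.pal < 0):
            raise ValueError("pal must be >= 0")
        if np.any((self.env < 0) | (self.env > 2)):
            raise ValueError("env must lie in [0, 2]")
        if self.threshold is not None:
            self.threshold = np.asarray(self.threshold, dtype=float)
            if np.any(self.threshold < 0):
                raise ValueError("thresholds must be >= 0")

    def thresholds(self, config: SimConfig) -> np.ndarray:
        if self.threshold is None:
            return np.full(len(self.ids), config.threshold)
        return self.threshold

    def copy(self) -> "AgentStates":
        return AgentStates(list(self.ids), self.pal.copy(), self.env.copy(),
                           None if self.threshold is None else self.threshold.copy())


@dataclass
class Trajectory:
    """Daily PAL of one simulated class (day 0 = initial state)."""

    ids: list
    pal: np.ndarray  # (days, n) or (days, n, m)

    @property
    def mean_pal(self) -> np.ndarray:
        """Class mean PAL per day, (days,) or (days, m)."""
        return self.pal.mean(axis=1)

    def __len__(self) -> int:
        return self.pal.shape[0]


def pal_anchor(env, pal_ref: float):
    """Environment anchor: pal_ref at env=0 falling linearly to 0 at env=2."""
    return pal_ref * (2.0 - np.asarray(env, dtype=float)) / 2.0


def weight_matrix(network: nx.DiGraph, ids: list | None = None) -> np.ndarray:
    """Dense weight matrix W with W[i, j] = weight of edge i -> j."""
    ids = list(network.nodes) if ids is None else list(ids)
    return nx.to_numpy_array(network, nodelist=ids, weight="weight")


def _social_field(w: np.ndarray, pal: np.ndarray) -> np.ndarray:
    """Weighted mean PAL of nominated peers; own PAL where there are none.

    The weighted sum accumulates peer by peer in a fixed order rather than
    through a matrix product, so a column of a replicate batch is bit-for-bit
    identical to the same class simulated on its own.
    """
    out_strength = w.sum(axis=1)
    s = np.zeros_like(pal)
    if pal.ndim == 2:
        for k in range(w.shape[1]):
            s += w[:, k, None] * pal[k]
        has_peers = out_strength > 0
        s /= np.where(has_peers, out_strength, 1.0)[:, None]
        return np.where(has_peers[:, None], s, pal)
    for k in range(w.shape[1]):
        s += w[:, k] * pal[k]
    has_peers = out_strength > 0
    s /= np.where(has_peers, out_strength, 1.0)
    return np.where(has_peers, s, pal)


def social_influence(agent, network: nx.DiGraph, states: AgentStates) -> float:
    """Phase 1 for a single pupil: weighted mean PAL of nominated peers."""
    ids = states.ids
    i = ids.index(agent)
    w = weight_matrix(network, ids)
    return float(_social_field(w, states.pal)[i])


def socioenvironmental_influence(s, env, pal, config: SimConfig):
    """Phase 2: signed influence Delta = (1-lambda) S + lambda a(env) - PAL."""
    lam = config.lambda_env
    target = (1.0 - lam) * np.asarray(s, float) + lam * pal_anchor(env, config.pal_ref)
    return target - np.asarray(pal, float)


def threshold_gate(delta, pal, threshold, config: SimConfig):
    """Phase 3: apply eta * Delta only where |Delta| exceeds the threshold."""
    delta = np.asarray(delta, float)
    pal = np.asarray(pal, float)
    moved = np.clip(pal + config.eta * delta, *config.pal_bounds)
    return np.where(np.abs(delta) > threshold, moved, pal)


def _step_arrays(w: np.ndarray, pal: np.ndarray, env: np.ndarray,
                 theta: np.ndarray, config: SimConfig) -> np.ndarray:
    s = _social_field(w, pal)
    if pal.ndim == 2:
        delta = socioenvironmental_influence(s, env[:, None], pal, config)
        return threshold_gate(delta, pal, theta[:, None], config)
    delta = socioenvironmental_influence(s, env, pal, config)
    return threshold_gate(delta, pal, theta, config)


def step(network: nx.DiGraph, states: AgentStates, config: SimConfig) -> AgentStates:
    """One synchronous day: all influences from day-t states, then applied."""
    w = weight_matrix(network, states.ids)
    new = states.copy()
    new.pal = _step_arrays(w, states.pal, states.env, states.thresholds(config), config)
    return new


def run(network: nx.DiGraph, states: AgentStates, config: SimConfig) -> Trajectory:
    """Simulate ``config.days`` days; day 0 is the initial state."""
    w = weight_matrix(network, states.ids)
    theta = states.thresholds(config)
    pal = states.pal
    out = np.empty((config.days,) + pal.shape)
    out[0] = pal
    for d in range(1, config.days):
        pal = _step_arrays(w, pal, states.env, theta, config)
        out[d] = pal
    return Trajectory(list(states.ids), out)
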
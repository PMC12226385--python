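"""Scheduler, initialization, and full-run execution of the networked CPR model.

One global step: (1) draw one agent uniformly at random, (2) run its decision
pipeline, (3) recompute the impact-weighted extraction level z, (4) advance
the resource state, (5) relax every agent's perceived resource state toward
its current local observation.  A *generation* is P steps (one expected
action per agent); the default horizon of T = 40000 steps with P = 1000
agents is 40 generations, enough for the model to settle on a branch.

All randomness in a run — the network, the initial strategies and heuristics,
the schedule, and every decision — is drawn from a single seeded generator,
so (config, seed) reproduces a trajectory exactly.  Ensembles use seeds
``base_seed + run_index``, which vary both the network realization and the
dynamical noise between runs.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .agent_decision import AgentState, DecisionParams, DecisionRecord, decide
from .expectation_hsm import N_HEURISTICS, HeuristicState, HsmParams, SnapshotHistory
from .network_gen import NetworkModel, complete_network, generate_ba, impact_weights
from .payoff_model import IncentiveParams, Params, default_incentives
from .resource_dynamics import EnvironmentState

__all__ = ["SimConfig", "SimState", "Trajectory", "init_state", "step", "run", "run_ensemble"]

_Z_REFRESH = 4096  # steps between exact recomputations of z (drift control)


@dataclass
class SimConfig:
    """Full run specification; defaults are the model's reference configuration."""

    P: int = 1000
    T: int = 40000
    lam: int = 250
    nu: float = 0.0
    epsilon: float = 0.25
    sigma: float = 0.1
    hsm: HsmParams = field(default_factory=HsmParams)
    payoffs: Params = field(default_factory=default_incentives)
    n0: float = 0.5
    p_low0: float = 0.5
    seed: int = 0
    record_stride: int = 10
    trailing_window: int = 100
    topology: str = "ba"  # "ba" | "complete"
    diagnostics: bool = False
    diagnostics_from: int = 0
    ah_window_generations: int = 10
    strategy_record_steps: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.P < 2:
            raise ValueError("P must be >= 2")
        if not 0.0 <= self.n0 <= 1.0:
            raise ValueError(f"n0 must lie in [0, 1], got {self.n0}")
        if not 0.0 <= self.p_low0 <= 1.0:
            raise ValueError(f"p_low0 must lie in [0, 1], got {self.p_low0}")
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if self.topology not in ("ba", "complete"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "ba" and not (1 <= self.lam < self.P):
            raise ValueError(f"need 1 <= lam < P, got lam={self.lam}, P={self.P}")
        if not 0.0 < self.epsilon / self.P < 1.0:
            raise ValueError("epsilon / P must lie in (0, 1)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimState:
    """Mutable state of a running simulation (struct-of-arrays internals)."""

    config: SimConfig
    net: NetworkModel
    agents: list[AgentState]
    env: EnvironmentState
    params: DecisionParams
    S: np.ndarray          # float 0/1 low-effort indicators
    c: np.ndarray          # per-node impact-weighted sum of low-effort neighbors
    inv_den: np.ndarray    # 1 / (sum of neighbor impact factors); 1/degree when nu = 0
    obs_w: np.ndarray      # per-node observation impact factor d^nu
    n_hat: np.ndarray      # per-node perceived resource state
    W: np.ndarray          # normalized impact weights (environment update)
    z: float
    _snap_buf: np.ndarray = field(default=None, repr=False)

    @property
    def t(self) -> int:
        return self.env.t


@dataclass
class Trajectory:
    """Recorded output of one run."""

    t: np.ndarray
    n: np.ndarray
    z: np.ndarray
    trailing_n: np.ndarray  # un-strided final `trailing_window` resource states
    final_strategies: np.ndarray
    degrees: np.ndarray
    is_hub: np.ndarray
    ah_mean: np.ndarray     # per-agent mean perceived A_H over the trailing window
    seed: int
    config: SimConfig
    wall_clock: float = 0.0
    diagnostics: Optional[pd.DataFrame] = None
    strategy_snapshots: Optional[dict[int, np.ndarray]] = None

    def trailing_mean_n(self, window: Optional[int] = None) -> float:
        w = window if window is not None else self.trailing_n.size
        if w > self.trailing_n.size:
            raise ValueError(f"window {w} exceeds recorded trailing buffer {self.trailing_n.size}")
        return float(self.trailing_n[-w:].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "n": self.n, "z": self.z})


def _build_network(config: SimConfig, rng: np.random.Generator,
                   net: Optional[NetworkModel]) -> NetworkModel:
    if net is not None:
        return net
    if config.topology == "complete":
        return complete_network(config.P)
    return generate_ba(config.P, config.lam, seed=int(rng.integers(2**31)))


def init_state(config: SimConfig, net: Optional[NetworkModel] = None,
               rng: Optional[np.random.Generator] = None) -> SimState:
    """Build the initial simulation state.

    Strategies are iid Bernoulli(p_low0); the resource and every agent's
    perception start at n0; snapshot histories, forecasts, and fitnesses are
    cold-started from each agent's initial local observation; heuristics are
    drawn uniformly.  Graphs with isolated nodes are rejected (an isolated
    agent cannot form a snapshot).  When ``rng`` is omitted a fresh generator
    is seeded from ``config.seed``; :func:`run` passes its own stream so the
    whole run consumes a single seeded sequence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    net = _build_network(config, rng, net)
    if net.node_count != config.P:
        raise ValueError(f"network has {net.node_count} nodes but config.P = {config.P}")
    if np.any(net.degrees == 0):
        raise ValueError("graph has isolated nodes: agents there could never observe peers")

    S = (rng.random(config.P) < config.p_low0).astype(np.float64)
    heuristic_draws = rng.integers(1, N_HEURISTICS + 1, size=config.P)

    # agents observe the effective extraction of their neighborhoods: each
    # peer counts in proportion to its environmental impact factor d^nu
    # (uniform when nu = 0); one CSR pass builds the weighted ledger sums
    obs_w = net.degrees.astype(np.float64) ** config.nu
    c = np.add.reduceat((S * obs_w)[net.indices], net.indptr[:-1]).astype(np.float64)
    inv_den = 1.0 / np.add.reduceat(obs_w[net.indices], net.indptr[:-1])
    snap0 = c * inv_den

    agents = []
    for i in range(config.P):
        agents.append(
            AgentState(
                id=i,
                degree=int(net.degrees[i]),
                strategy=int(S[i]),
                perceived_n=config.n0,
                history=SnapshotHistory.cold_start(float(snap0[i])),
                heuristics=HeuristicState.cold_start(float(snap0[i]), int(heuristic_draws[i])),
            )
        )

    W = impact_weights(net.degrees, config.nu).W
    params = DecisionParams(
        sigma=config.sigma, payoffs=config.payoffs,
        epsilon=config.epsilon, P=config.P, hsm=config.hsm,
    )
    state = SimState(
        config=config, net=net, agents=agents,
        env=EnvironmentState(n=config.n0, t=0), params=params,
        S=S, c=c, inv_den=inv_den, obs_w=obs_w,
        n_hat=np.full(config.P, config.n0, dtype=np.float64),
        W=W, z=float(S @ W),
    )
    state._snap_buf = np.empty(config.P)
    return state


def step(state: SimState, rng: np.random.Generator) -> tuple[int, DecisionRecord]:
    """Advance the simulation by one global step; returns (agent id, record)."""
    i = int(rng.integers(state.config.P))
    agent = state.agents[i]
    agent.perceived_n = float(state.n_hat[i])
    agent.last_action_step = state.env.t
    old = agent.strategy
    snap = float(state.c[i]) * state.inv_den[i]
    snap = 0.0 if snap < 0.0 else (1.0 if snap > 1.0 else snap)  # guard fp drift
    rec = decide(agent, state.params, rng, snapshot=snap)
    if agent.strategy != old:
        ds = agent.strategy - old
        state.S[i] = agent.strategy
        nb = state.net.indices[state.net.indptr[i]: state.net.indptr[i + 1]]
        state.c[nb] += ds * state.obs_w[i]
        state.z += ds * float(state.W[i])

    # resource law of motion
    rate = state.config.epsilon / state.config.P
    state.env.n += rate * (state.z - state.env.n)
    state.env.t += 1

    # all agents relax their perception toward their current local observation
    buf = state._snap_buf
    np.multiply(state.c, state.inv_den, out=buf)
    buf -= state.n_hat
    buf *= rate
    state.n_hat += buf
    return i, rec


def run(config: SimConfig, net: Optional[NetworkModel] = None) -> Trajectory:
    """Execute a full run of T steps and record the trajectory."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)  # single stream for init and dynamics
    state = init_state(config, net=net, rng=rng)

    T = config.T
    n_series = np.empty(T)
    z_series = np.empty(T)
    ah_sum = np.zeros(config.P)
    ah_cnt = np.zeros(config.P, dtype=np.int64)
    ah_from = max(0, T - config.ah_window_generations * config.P)
    diag_rows: list[tuple] = []
    snapshots: dict[int, np.ndarray] = {}
    record_steps = set(config.strategy_record_steps or ())

    for t in range(T):
        i, rec = step(state, rng)
        if t % _Z_REFRESH == 0:  # counter incremental fp drift in z and c
            state.z = float(state.S @ state.W)
            np.add.reduceat(
                (state.S * state.obs_w)[state.net.indices], state.net.indptr[:-1],
                out=state.c,
            )
        n_series[t] = state.env.n
        z_series[t] = state.z
        if t >= ah_from:
            ah_sum[i] += rec.advantage_high
            ah_cnt[i] += 1
        if config.diagnostics and t >= config.diagnostics_from:
            diag_rows.append(
                (t, i, state.agents[i].degree, rec.advantage_high,
                 rec.forecast, rec.heuristic, rec.strategy)
            )
        if (t + 1) in record_steps:
            snapshots[t + 1] = state.S.astype(np.int8).copy()

    stride = config.record_stride
    rec_idx = np.arange(stride - 1, T, stride)
    with np.errstate(invalid="ignore"):
        ah_mean = np.where(ah_cnt > 0, ah_sum / np.maximum(ah_cnt, 1), np.nan)
    diagnostics = None
    if config.diagnostics:
        diagnostics = pd.DataFrame(
            diag_rows,
            columns=["step", "id", "degree", "advantage_high", "forecast", "heuristic", "strategy"],
        )
    return Trajectory(
        t=rec_idx,
        n=n_series[rec_idx].copy(),
        z=z_series[rec_idx].copy(),
        trailing_n=n_series[-config.trailing_window:].copy(),
        final_strategies=state.S.astype(np.int8),
        degrees=state.net.degrees.copy(),
        is_hub=state.net.is_hub.copy(),
        ah_mean=ah_mean,
        seed=config.seed,
        config=config,
        wall_clock=time.perf_counter() - t0,
        diagnostics=diagnostics,
        strategy_snapshots=snapshots or None,
    )


def run_ensemble(config: SimConfig, n_runs: int, base_seed: Optional[int] = None,
                 net: Optional[NetworkModel] = None) -> list[Trajectory]:
    """Run ``n_runs`` independent simulations with seeds base_seed + 0..n-1."""
    base = config.seed if base_seed is None else base_seed
    return [run(config.replace(seed=base + k), net=net) for k in range(n_runs)]
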
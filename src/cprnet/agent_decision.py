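"""Single-agent decision pipeline: observe, perceive, forecast, choose.

At its action event an agent (i) snapshots its ledger — the fraction of its
neighbors currently on the low-effort strategy, (ii) scores and refreshes its
forecasting rules against that snapshot, (iii) draws a rule and issues a
forecast z^e of the low-effort fraction, (iv) evaluates the payoff advantage
of high effort A_H = piH(z^e, n_hat) - piL(z^e, n_hat) at its own perceived
resource state n_hat, and (v) picks high effort with logistic probability

    P_H = 1 / (1 + exp(-d * sigma * A_H)),

so better-connected agents (larger degree d) respond more sharply to the same
perceived advantage.  Between action events, every agent's perceived resource
state relaxes toward its current local observation at the environmental rate
eps / P, mirroring the resource law of motion with local information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .expectation_hsm import (
    HeuristicState,
    HsmParams,
    SnapshotHistory,
    sample_heuristic,
    selection_probabilities,
    update_fitness,
)
from .payoff_model import Params, advantage_coefficients

__all__ = [
    "AgentState",
    "DecisionParams",
    "DecisionRecord",
    "local_snapshot",
    "update_perception",
    "choice_prob_high",
    "decide",
]

_EXP_CLIP = 500.0  # hub degrees times large advantages overflow exp otherwise

LOW, HIGH = 1, 0  # strategy coding: S = 1 means low effort


@dataclass
class AgentState:
    """One resource user: strategy, observation state, and forecasting state."""

    id: int
    degree: int
    strategy: int  # 1 = low effort, 0 = high effort
    perceived_n: float
    history: SnapshotHistory
    heuristics: HeuristicState
    ledger: Optional[dict[int, int]] = None  # neighbor id -> last seen strategy
    last_action_step: int = -1


@dataclass
class DecisionParams:
    """Decision-rule inputs: logistic slope, payoffs, and perception rate."""

    sigma: float
    payoffs: Params
    epsilon: float
    P: int
    hsm: HsmParams = field(default_factory=HsmParams)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        # bilinear advantage coefficients, cached for the hot path
        self.adv_coeffs = advantage_coefficients(self.payoffs)

    def advantage_high(self, z: float, n: float) -> float:
        a0, az, an, azn = self.adv_coeffs
        return -(a0 + az * z + an * n + azn * z * n)


@dataclass
class DecisionRecord:
    """Diagnostics of one action event."""

    strategy: int
    advantage_high: float
    forecast: float
    heuristic: int
    snapshot: float


def local_snapshot(agent: AgentState, weights: Optional[dict[int, float]] = None) -> float:
    """The agent's local estimate of the effective low-effort fraction.

    The mean of the ledger entries (the agent itself excluded), optionally
    weighted by the neighbors' environmental impact weights.  Impact
    weighting matters under impact inequality (nu > 0): the quantity agents
    observe and forecast is the *effective* extraction level, in which
    high-impact peers count proportionally more; with homogeneous impact the
    weights are uniform and this is the plain fraction of low-effort
    neighbors.
    """
    if not agent.ledger:
        raise ValueError(f"agent {agent.id} has no ledger entries (isolated node?)")
    if weights is None:
        return sum(agent.ledger.values()) / len(agent.ledger)
    num = sum(s * weights[j] for j, s in agent.ledger.items())
    den = sum(weights[j] for j in agent.ledger)
    if den <= 0:
        raise ValueError("neighbor impact weights sum to zero")
    return num / den


def update_perception(agent: AgentState, snapshot: float, epsilon: float, P: int) -> float:
    """Relax the agent's perceived resource state toward its local observation.

    Applies ``n_hat <- n_hat + (eps/P) (snapshot - n_hat)`` — the resource law
    of motion driven by local information.  Runs for every agent at every
    global step; convexity keeps n_hat in [0, 1].
    """
    agent.perceived_n += (epsilon / P) * (snapshot - agent.perceived_n)
    return agent.perceived_n


def choice_prob_high(d: int, sigma: float, advantage_high: float) -> float:
    """Logistic probability of choosing high effort.

    Monotone increasing in the perceived advantage of high effort and, away
    from indifference, sharper for better-connected agents.
    """
    x = d * sigma * advantage_high
    x = -_EXP_CLIP if x < -_EXP_CLIP else (_EXP_CLIP if x > _EXP_CLIP else x)
    return 1.0 / (1.0 + math.exp(-x))


def decide(
    agent: AgentState,
    params: DecisionParams,
    rng: np.random.Generator,
    snapshot: float | None = None,
) -> DecisionRecord:
    """Run one full action event and update the agent in place.

    Order: snapshot -> fitness update of all rules against the snapshot ->
    rule draw -> forecast z^e -> advantage A_H at the agent's perceived
    resource state -> Bernoulli(P_H) strategy choice.  ``snapshot`` may be
    supplied by the caller (the engine maintains neighbor counts); otherwise
    it is computed from the agent's ledger.
    """
    if snapshot is None:
        snapshot = local_snapshot(agent)
    update_fitness(agent.heuristics, agent.history, snapshot, params.hsm)
    probs = selection_probabilities(agent.heuristics, params.hsm)
    agent.heuristics.current = sample_heuristic(probs, rng)
    z_e = agent.heuristics.forecasts[agent.heuristics.current - 1]
    a_high = params.advantage_high(z_e, agent.perceived_n)
    p_high = choice_prob_high(agent.degree, params.sigma, a_high)
    agent.strategy = HIGH if rng.random() < p_high else LOW
    return DecisionRecord(
        strategy=agent.strategy,
        advantage_high=a_high,
        forecast=z_e,
        heuristic=agent.heuristics.current,
        snapshot=snapshot,
    )
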
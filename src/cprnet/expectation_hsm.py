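"""Heuristics Switching Model: forecasting rules, fitness, and rule selection.

Agents forecast the fraction of low-effort extractors among their neighbors
from the snapshots they took at their own past action events.  Four rules are
available (1-based indices, following the standard menu of this literature):

1. **Adaptive**:      z^e = beta1 * z_{t-1} + (1 - beta1) * z^e_{prev}
2. **Trend-chasing**: z^e = z_{t-1} + beta2 * (z_{t-1} - z_{t-2})
3. **Contrarian**:    z^e = z_{t-1} + beta3 * (z_{t-1} - z_{t-2}), beta3 < 0
4. **Anchoring**:     z^e = 0.5 * (z_ave + z_{t-1}) + (z_{t-1} - z_{t-2})

where z_{t-1}, z_{t-2} are the agent's two most recent snapshots, z_ave the
running mean of all its snapshots, and z^e_prev the adaptive rule's own
previous forecast.  Every rule's fitness is a discounted sum of its negated
squared forecast errors; the rule actually used is re-drawn at every action
event from an inertia-plus-softmax distribution.

Timing convention: the lags t-1, t-2 index the agent's *own* successive
action events (an agent acts on average once every P global steps), because
snapshots are only taken when the agent acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_HEURISTICS",
    "HEURISTIC_NAMES",
    "SnapshotHistory",
    "HeuristicState",
    "HsmParams",
    "forecast",
    "all_forecasts",
    "update_fitness",
    "selection_probabilities",
    "sample_heuristic",
]

N_HEURISTICS = 4
HEURISTIC_NAMES = ("adaptive", "trend", "contrarian", "anchoring")


@dataclass
class HsmParams:
    """Rule coefficients and selection parameters.

    beta1: adaptive blending weight; beta2: trend extrapolation; beta3:
    contrarian extrapolation (negative); rho: probability of retaining the
    incumbent rule (inertia); eta: fitness memory in [0, 1]; phi: choice
    intensity of the softmax (>= 0; large phi approaches argmax selection).
    """

    beta1: float = 0.63
    beta2: float = 0.44
    beta3: float = -0.44
    rho: float = 0.9
    eta: float = 0.7
    phi: float = 100.0
    #: lag convention of the adaptive rule: by default it blends the newest
    #: snapshot with its own most recent forecast; set True to blend with the
    #: forecast issued one event earlier instead (a two-lag reading).
    adaptive_two_lag: bool = False

    def __post_init__(self) -> None:
        if self.beta3 >= 0:
            raise ValueError(f"beta3 must be negative (contrarian rule), got {self.beta3}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")


@dataclass
class SnapshotHistory:
    """An agent's ledger snapshots, indexed by its own action events."""

    z_prev: float
    z_prev2: float
    z_sum: float
    count: int

    @classmethod
    def cold_start(cls, z0: float) -> "SnapshotHistory":
        """Initialize from the agent's first local observation."""
        return cls(z_prev=z0, z_prev2=z0, z_sum=z0, count=1)

    @property
    def z_ave(self) -> float:
        return self.z_sum / self.count

    def push(self, z: float) -> None:
        self.z_prev2 = self.z_prev
        self.z_prev = z
        self.z_sum += z
        self.count += 1


@dataclass
class HeuristicState:
    """Per-heuristic forecasts and fitnesses, plus the rule currently in use."""

    forecasts: list[float]
    fitness: list[float] = field(default_factory=lambda: [0.0] * N_HEURISTICS)
    current: int = 1  # 1-based heuristic index
    adaptive_prev2: float = 0.0  # adaptive rule's forecast from one event earlier

    @classmethod
    def cold_start(cls, z0: float, current: int = 1) -> "HeuristicState":
        return cls(forecasts=[z0] * N_HEURISTICS, current=current, adaptive_prev2=z0)


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def forecast(h: int, hist: SnapshotHistory, prev_forecast: float, params: HsmParams) -> float:
    """Forecast of heuristic ``h`` (1..4), clipped to [0, 1].

    ``prev_forecast`` is that heuristic's previously issued forecast (used by
    the adaptive rule only).  Forecasts are clipped because z is a population
    fraction while the extrapolating rules can leave the unit interval.
    """
    z1, z2 = hist.z_prev, hist.z_prev2
    if h == 1:
        value = params.beta1 * z1 + (1 - params.beta1) * prev_forecast
    elif h == 2:
        value = z1 + params.beta2 * (z1 - z2)
    elif h == 3:
        value = z1 + params.beta3 * (z1 - z2)
    elif h == 4:
        value = 0.5 * (hist.z_ave + z1) + (z1 - z2)
    else:
        raise ValueError(f"unknown heuristic index {h} (valid: 1..{N_HEURISTICS})")
    return _clip01(value)


def all_forecasts(state: HeuristicState, hist: SnapshotHistory, params: HsmParams) -> list[float]:
    """Refresh every rule's forecast from the (already updated) history."""
    prev1 = state.adaptive_prev2 if params.adaptive_two_lag else state.forecasts[0]
    prevs = [prev1] + [state.forecasts[k] for k in range(1, N_HEURISTICS)]
    return [forecast(h, hist, prevs[h - 1], params) for h in range(1, N_HEURISTICS + 1)]


def update_fitness(state: HeuristicState, hist: SnapshotHistory, z_observed: float,
                   params: HsmParams) -> None:
    """Score all four rules against a new snapshot and refresh their forecasts.

    In place: pushes ``z_observed`` onto the history, sets every rule's
    fitness to ``-(z_observed - forecast)^2 + eta * fitness`` (all rules are
    tracked, not just the incumbent), then re-issues all four forecasts for
    the next event.
    """
    if not 0.0 <= z_observed <= 1.0:
        raise ValueError(f"observed fraction must lie in [0, 1], got {z_observed}")
    for k in range(N_HEURISTICS):
        err = z_observed - state.forecasts[k]
        state.fitness[k] = -err * err + params.eta * state.fitness[k]
    hist.push(z_observed)
    old_adaptive = state.forecasts[0]
    state.forecasts = all_forecasts(state, hist, params)
    state.adaptive_prev2 = old_adaptive


def selection_probabilities(state: HeuristicState, params: HsmParams) -> np.ndarray:
    """Inertia-plus-softmax distribution over the four rules.

    ``P(h) = rho * [h == incumbent] + (1 - rho) * softmax(phi * fitness)_h``.
    The softmax is max-shifted: with phi = 100 raw exponentials overflow.
    """
    f = state.fitness
    m = max(f)
    w = [math.exp(params.phi * (x - m)) for x in f]
    s = sum(w)
    probs = np.array([(1 - params.rho) * x / s for x in w])
    probs[state.current - 1] += params.rho
    return probs


def sample_heuristic(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Inverse-CDF draw of a 1-based heuristic index, in fixed rule order."""
    u = rng.random()
    acc = 0.0
    for k, p in enumerate(probs):
        acc += p
        if u < acc:
            return k + 1
    return len(probs)
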
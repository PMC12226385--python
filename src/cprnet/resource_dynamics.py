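"""Effective population extraction and the resource law of motion.

The resource state n in [0, 1] relaxes toward the impact-weighted fraction of
low-effort extractors z, closing a share eps/P of the gap every step::

    n_t = n_{t-1} + (eps/P) (z_t - n_{t-1})

so low-effort extraction lets the resource recover while high effort depletes
it.  ``eps`` sets the speed of environmental relative to strategic dynamics;
dividing by the population size P makes one *generation* (P scheduler steps,
one expected action per agent) advance the resource by a fraction eps of the
remaining gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnvironmentState", "effective_extraction", "step_environment"]


@dataclass
class EnvironmentState:
    """Resource state n in [0, 1] and the global step counter."""

    n: float
    t: int = 0


def effective_extraction(strategies: np.ndarray, weights: np.ndarray) -> float:
    """Impact-weighted low-effort fraction z = sum_i S_i W_i.

    ``strategies`` is the 0/1 low-effort indicator vector; ``weights`` must be
    normalized.  With uniform weights this is the plain low-effort fraction.
    """
    S = np.asarray(strategies)
    W = np.asarray(weights)
    if S.shape != W.shape:
        raise ValueError(f"strategies and weights length mismatch: {S.shape} vs {W.shape}")
    return float(S @ W)


def step_environment(env: EnvironmentState, z: float, epsilon: float, P: int) -> EnvironmentState:
    """Advance the resource one step toward z; fixed point at n = z."""
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z}")
    rate = epsilon / P
    if not 0.0 < rate < 1.0:
        raise ValueError(f"eps/P must lie in (0, 1), got {rate}")
    env.n += rate * (z - env.n)
    env.t += 1
    return env
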
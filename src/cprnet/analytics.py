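"""Downstream analysis: outcome classification, sweeps, diagnostics, and the
replicator-dynamics companion.

A run is classified relative to the full-information equilibrium (FIE) by the
mean resource state over its trailing window (the final 100 un-strided steps
under the default recording configuration):
*scarce* if that trailing mean lies strictly below n*, *abundant* otherwise.
Ensembles of such classifications quantify bistability (the split between the
two branches), and sweeps over the attachment count (degree skewness) or the
impact-inequality exponent nu map where bistability appears and collapses.

The replicator system is the analytical well-mixed, full-information limit::

    dz/dt = z (1 - z) (piL(z, n) - piH(z, n))
    dn/dt = eps * alpha * (z - n)

whose interior fixed point is the FIE.  ``alpha`` plays the role of the 1/P
factor of the discrete law of motion; use ``alpha = 1/P`` to compare time
scales with the agent-based model.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network_gen import NetworkModel, degree_skewness
from .payoff_model import FiePoint, Params, advantage_coefficients, solve_fie
from .sim_engine import SimConfig, Trajectory, run

__all__ = [
    "ABUNDANT",
    "SCARCE",
    "classify_outcome",
    "ensemble_split",
    "summarize_ensemble",
    "sweep_skewness",
    "sweep_impact",
    "degree_advantage_table",
    "effort_degree_correlation",
    "majority_illusion_index",
    "replicator_field",
    "integrate_replicator",
]

ABUNDANT = "abundant"
SCARCE = "scarce"


def classify_outcome(traj: Trajectory, fie: FiePoint,
                     window: int | None = None) -> str:
    """Classify a run as abundant or scarce relative to the FIE.

    Uses the mean resource state over the final ``window`` un-strided steps
    (the full recorded trailing buffer when ``window`` is None).
    Exact ties go to *abundant* (documented convention).
    """
    if not fie.exists:
        raise ValueError("cannot classify outcomes without a full-information equilibrium")
    return SCARCE if traj.trailing_mean_n(window) < fie.n_star else ABUNDANT


def ensemble_split(runs: Sequence[Trajectory], fie: FiePoint,
                   window: int | None = None) -> float:
    """Fraction of runs whose trailing resource mean lies below the FIE."""
    if not runs:
        raise ValueError("ensemble_split needs at least one run")
    scarce = sum(classify_outcome(tr, fie, window) == SCARCE for tr in runs)
    return scarce / len(runs)


def summarize_ensemble(runs: Sequence[Trajectory], fie: FiePoint,
                       window: int | None = None) -> pd.DataFrame:
    """Per-run summary table: seed, trailing mean, class, effort-degree correlation."""
    rows = []
    for tr in runs:
        rows.append(
            {
                "seed": tr.seed,
                "mean_n_last": tr.trailing_mean_n(window),
                "outcome_class": classify_outcome(tr, fie, window),
                "effort_degree_correlation": effort_degree_correlation(
                    tr.final_strategies, tr.degrees
                ),
            }
        )
    return pd.DataFrame(rows)


def _sweep(base: SimConfig, coord_name: str, values: Iterable, configure,
           runs_per_level: int, window: int | None) -> pd.DataFrame:
    fie = solve_fie(base.payoffs)
    rows = []
    for v in values:
        cfg = configure(base, v)
        for k in range(runs_per_level):
            tr = run(cfg.replace(seed=base.seed + k))
            rows.append(
                {
                    coord_name: v,
                    "seed": tr.seed,
                    "skewness": _traj_skewness(tr),
                    "mean_n_last": tr.trailing_mean_n(window),
                    "outcome_class": classify_outcome(tr, fie, window),
                }
            )
    return pd.DataFrame(rows)


def _traj_skewness(tr: Trajectory) -> float:
    d = tr.degrees.astype(float)
    m2 = np.mean((d - d.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((d - d.mean()) ** 3) / m2**1.5)


def sweep_skewness(base: SimConfig, lam_grid: Sequence[int] | None = None,
                   runs_per_level: int = 30, window: int | None = None) -> pd.DataFrame:
    """Long-run outcomes across degree-distribution skewness levels.

    The sweep is keyed by the attachment count lam (the generator knob); the
    realized Fisher-Pearson degree skewness of each run's network is recorded
    alongside so outcomes can be plotted against either axis.
    """
    if lam_grid is None:
        lam_grid = [50, 150, 250, 350, 450, 550, 650, 750, 850, 950]
        lam_grid = [l for l in lam_grid if l < base.P]
    return _sweep(base, "lam", lam_grid, lambda c, v: c.replace(lam=int(v)),
                  runs_per_level, window)


def sweep_impact(base: SimConfig, nu_grid: Sequence[float] | None = None,
                 runs_per_level: int = 30, window: int | None = None) -> pd.DataFrame:
    """Long-run outcomes across impact-inequality exponents nu."""
    if nu_grid is None:
        nu_grid = list(np.arange(0.0, 3.0 + 1e-9, 0.25))
    return _sweep(base, "nu", nu_grid, lambda c, v: c.replace(nu=float(v)),
                  runs_per_level, window)


def degree_advantage_table(records: pd.DataFrame, last_k: int | None = None,
                           bins: int = 20) -> pd.DataFrame:
    """Bin perceived high-effort advantages and report mean degree per bin.

    ``records`` is a per-event diagnostics frame with columns ``step``,
    ``degree`` and ``advantage_high``.  Returns one row per non-empty bin:
    bin center, mean degree, and frequency (fractions sum to 1).
    """
    req = {"step", "degree", "advantage_high"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must contain columns {sorted(req)}")
    df = records
    if last_k is not None:
        df = df[df["step"] >= df["step"].max() - last_k + 1]
    a = df["advantage_high"].to_numpy()
    lo, hi = a.min(), a.max()
    if lo == hi:  # single degenerate bin
        return pd.DataFrame(
            {"advantage_mid": [lo], "mean_degree": [df["degree"].mean()], "frequency": [1.0]}
        )
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.digitize(a, edges) - 1, 0, bins - 1)
    out = (
        pd.DataFrame({"bin": idx, "degree": df["degree"].to_numpy()})
        .groupby("bin")
        .agg(mean_degree=("degree", "mean"), count=("degree", "size"))
        .reset_index()
    )
    out["advantage_mid"] = 0.5 * (edges[out["bin"]] + edges[out["bin"] + 1])
    out["frequency"] = out["count"] / out["count"].sum()
    return out[["advantage_mid", "mean_degree", "frequency"]]


def effort_degree_correlation(strategies: np.ndarray, degrees: np.ndarray) -> float:
    """Pearson correlation between the high-effort indicator and degree.

    Positive values mean hubs extract with high effort (the abundant-branch
    configuration).  Constant strategy or degree vectors return 0.
    """
    s = np.asarray(strategies, dtype=float)
    d = np.asarray(degrees, dtype=float)
    if s.size != d.size or s.size < 2:
        raise ValueError("need matching strategy/degree vectors of length >= 2")
    high = 1.0 - s
    if high.std() == 0 or d.std() == 0:
        return 0.0
    return float(np.corrcoef(high, d)[0, 1])


def majority_illusion_index(net: NetworkModel, strategies: np.ndarray) -> float:
    """Fraction of agents whose local majority differs from the global one.

    The global majority is the strategy held by more than half the agents
    (exact global ties resolve to low effort).  Neighborhood ties are
    resolved *toward* the global majority, so they never count as illusion.
    """
    s = np.asarray(strategies, dtype=float)
    if s.size != net.node_count:
        raise ValueError("strategy vector length must equal node count")
    if np.any(net.degrees == 0):
        raise ValueError("majority illusion undefined with isolated nodes")
    global_major_low = s.mean() >= 0.5
    low_counts = np.add.reduceat(s[net.indices], net.indptr[:-1])
    frac_low = low_counts / net.degrees
    if global_major_low:
        illusion = frac_low < 0.5
    else:
        illusion = frac_low > 0.5
    return float(illusion.mean())


def replicator_field(z: float, n: float, params: Params, epsilon: float,
                     alpha: float = 1.0) -> tuple[float, float]:
    """Right-hand side (dz/dt, dn/dt) of the well-mixed replicator system."""
    if not (0.0 <= z <= 1.0 and 0.0 <= n <= 1.0):
        raise ValueError("z and n must lie in [0, 1]")
    a0, az, an, azn = advantage_coefficients(params)
    adv_low = a0 + az * z + an * n + azn * z * n
    return z * (1.0 - z) * adv_low, epsilon * alpha * (z - n)


def integrate_replicator(z0: float, n0: float, horizon: float, params: Params,
                         epsilon: float, alpha: float = 1.0,
                         max_step: float | None = None) -> pd.DataFrame:
    """Integrate the replicator system with an adaptive 4th/5th-order scheme.

    Returns a tidy path (t, z, n).  The state is clipped to the unit square
    after integration only to guard against round-off; the field itself
    vanishes on the z boundaries.
    """
    a0, az, an, azn = advantage_coefficients(params)

    def rhs(_t, y):
        z, n = y
        adv_low = a0 + az * z + an * n + azn * z * n
        return (z * (1.0 - z) * adv_low, epsilon * alpha * (z - n))

    sol = solve_ivp(
        rhs, (0.0, horizon), (z0, n0), method="RK45", dense_output=False,
        max_step=max_step or horizon / 100.0, rtol=1e-8, atol=1e-10,
    )
    z = np.clip(sol.y[0], 0.0, 1.0)
    n = np.clip(sol.y[1], 0.0, 1.0)
    return pd.DataFrame({"t": sol.t, "z": z, "n": n})
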
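"""Environment-dependent two-strategy game and its full-information equilibrium.

Resource users choose between low-effort (L) and high-effort (H) extraction.
Payoffs depend on the resource state ``n`` (0 = fully degraded, 1 = fully
prosperous) and on the fraction ``z`` of the population extracting with low
effort.  The game interpolates linearly between a "degraded" payoff matrix
(weight ``1 - n``) and a "prosperous" one (weight ``n``)::

    Pi(n) = (1 - n) [[R0, S0], [T0, P0]] + n [[R1, S1], [T1, P1]]

with the first row/column the low-effort strategy.  Three equivalent
parameterizations are supported:

* :class:`CornerPayoffs` -- the eight matrix entries above;
* :class:`IncentiveParams` -- the four corner payoff differences
  (delta_H^0, delta_L^0, Delta_L^1, Delta_H^1) that fully determine the
  advantage of one strategy over the other;
* :class:`AffineParams` -- coefficients of the affine surfaces
  ``pi^s(n, z) = alpha^s + g1^s z + g2^s n + g3^s n z``.

The default configuration creates incentives *against* coordination: when the
resource is depleted, early adopters of low effort gain, and when it is
prosperous, opportunistic high effort gains.  Under those incentives a
well-mixed, perfectly informed population settles at the full-information
equilibrium (FIE) where the advantage vanishes and the resource fixed point
equals the low-effort fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "CornerPayoffs",
    "IncentiveParams",
    "AffineParams",
    "FiePoint",
    "default_incentives",
    "default_affine",
    "payoffs",
    "advantage_low",
    "advantage_high",
    "corner_incentives",
    "affine_from_corners",
    "corners_from_affine",
    "corners_from_incentives",
    "advantage_coefficients",
    "solve_fie",
]


@dataclass(frozen=True)
class CornerPayoffs:
    """The eight entries of the environment-dependent payoff matrix.

    Subscript 0 refers to the fully degraded environment (n = 0), subscript 1
    to the fully prosperous one (n = 1).  R/S are low-effort payoffs against
    low/high-effort co-players; T/P the high-effort analogues.
    """

    R0: float
    S0: float
    T0: float
    P0: float
    R1: float
    S1: float
    T1: float
    P1: float


@dataclass(frozen=True)
class IncentiveParams:
    """Corner payoff differences driving strategy switching.

    ``deltaH0 = S0 - P0`` : advantage of being an early adopter of low effort
    in a depleted environment; ``deltaL0 = R0 - T0`` : late adopter of low
    effort, depleted environment; ``DeltaL1 = T1 - R1`` : early adopter of
    high effort, bountiful environment; ``DeltaH1 = P1 - S1`` : late adopter
    of high effort, bountiful environment.  Lowercase deltas are incentives
    toward low effort, capital Deltas toward high effort.
    """

    deltaH0: float
    deltaL0: float
    DeltaL1: float
    DeltaH1: float


@dataclass(frozen=True)
class AffineParams:
    """Coefficients of the affine payoff surfaces pi^s(n, z), s in {L, H}."""

    alphaL: float
    alphaH: float
    g1L: float
    g2L: float
    g3L: float
    g1H: float
    g2H: float
    g3H: float


@dataclass(frozen=True)
class FiePoint:
    """Full-information equilibrium: resource state n* (= low-effort share z*)."""

    n_star: float
    exists: bool


Params = Union[CornerPayoffs, IncentiveParams, AffineParams]

#: Default incentive configuration.  deltaH0 is stored with its effective
#: positive sign (see :func:`default_incentives`).
_DEFAULT_SIGN_RESOLVED = IncentiveParams(
    deltaH0=0.3, deltaL0=0.05, DeltaL1=0.7, DeltaH1=0.45
)
_DEFAULT_AS_PRINTED = IncentiveParams(
    deltaH0=-0.3, deltaL0=0.05, DeltaL1=0.7, DeltaH1=0.45
)


def default_incentives(as_printed: bool = False) -> IncentiveParams:
    """Return the default incentive parameters.

    The default uses ``deltaH0 = +0.3``.  The source table of this model
    family prints -0.3 for this entry, but the accompanying analysis requires
    ``S0 - P0 > 0`` (a positive incentive toward low effort in a depleted
    environment) and an interior equilibrium, both of which force the
    positive sign; with -0.3 the advantage is negative on the whole state
    space and no interior equilibrium exists.  Pass ``as_printed=True`` to
    get the literal tabled value.
    """
    return _DEFAULT_AS_PRINTED if as_printed else _DEFAULT_SIGN_RESOLVED


def default_affine(as_printed: bool = False) -> AffineParams:
    """Default affine parameterization (gauge alphaH = 0, g3 terms zero)."""
    a_diff = -0.3 if as_printed else 0.3
    return AffineParams(
        alphaL=a_diff, alphaH=0.0, g1L=0.5, g2L=1.5, g3L=0.0,
        g1H=0.75, g2H=2.25, g3H=0.0,
    )


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


def payoffs(params: Params, z: float, n: float) -> tuple[float, float]:
    """Evaluate (piL, piH) at low-effort fraction ``z`` and resource state ``n``.

    Accepts corner or affine parameters (incentive parameters do not fix the
    absolute payoff level; convert them with :func:`corners_from_incentives`
    first).  Both forms agree for equivalent parameter sets.
    """
    _check_unit("z", z)
    _check_unit("n", n)
    if isinstance(params, IncentiveParams):
        params = corners_from_incentives(params)
    if isinstance(params, CornerPayoffs):
        m = params
        piL = (1 - n) * (m.R0 * z + m.S0 * (1 - z)) + n * (m.R1 * z + m.S1 * (1 - z))
        piH = (1 - n) * (m.T0 * z + m.P0 * (1 - z)) + n * (m.T1 * z + m.P1 * (1 - z))
        return piL, piH
    if isinstance(params, AffineParams):
        a = params
        piL = a.alphaL + a.g1L * z + a.g2L * n + a.g3L * n * z
        piH = a.alphaH + a.g1H * z + a.g2H * n + a.g3H * n * z
        return piL, piH
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def advantage_low(params: Params, z: float, n: float) -> float:
    """Payoff advantage of low effort, piL - piH, at (z, n).

    For :class:`IncentiveParams` this is evaluated directly from the corner
    differences::

        piL - piH = (1-n) (deltaL0 z + deltaH0 (1-z)) - n (DeltaL1 z + DeltaH1 (1-z))
    """
    if isinstance(params, IncentiveParams):
        _check_unit("z", z)
        _check_unit("n", n)
        p = params
        return (1 - n) * (p.deltaL0 * z + p.deltaH0 * (1 - z)) - n * (
            p.DeltaL1 * z + p.DeltaH1 * (1 - z)
        )
    piL, piH = payoffs(params, z, n)
    return piL - piH


def advantage_high(params: Params, z: float, n: float) -> float:
    """Payoff advantage of high effort, piH - piL (the decision-rule input)."""
    return -advantage_low(params, z, n)


def corner_incentives(m: CornerPayoffs) -> IncentiveParams:
    """Corner payoff differences of a payoff matrix pair."""
    return IncentiveParams(
        deltaH0=m.S0 - m.P0,
        deltaL0=m.R0 - m.T0,
        DeltaL1=m.T1 - m.R1,
        DeltaH1=m.P1 - m.S1,
    )


def affine_from_corners(m: CornerPayoffs) -> AffineParams:
    """Convert matrix corners to affine surface coefficients."""
    return AffineParams(
        alphaL=m.S0,
        alphaH=m.P0,
        g1L=m.R0 - m.S0,
        g2L=m.S1 - m.S0,
        g3L=m.R1 - m.R0 + m.S0 - m.S1,
        g1H=m.T0 - m.P0,
        g2H=m.P1 - m.P0,
        g3H=m.P0 - m.P1 + m.T1 - m.T0,
    )


def corners_from_affine(a: AffineParams) -> CornerPayoffs:
    """Invert :func:`affine_from_corners` exactly."""
    S0 = a.alphaL
    P0 = a.alphaH
    R0 = a.g1L + S0
    S1 = a.g2L + S0
    R1 = a.g3L + R0 + S1 - S0
    T0 = a.g1H + P0
    P1 = a.g2H + P0
    T1 = a.g3H + P1 + T0 - P0
    return CornerPayoffs(R0=R0, S0=S0, T0=T0, P0=P0, R1=R1, S1=S1, T1=T1, P1=P1)


def corners_from_incentives(p: IncentiveParams) -> CornerPayoffs:
    """Canonical payoff matrices for a set of corner incentives.

    Incentives determine payoffs only up to the absolute payoff levels, which
    never enter the advantage.  The gauge fixes the high-effort payoffs in
    the degraded environment and the low-effort payoffs in the prosperous one
    to zero (in particular P0 = S1 = 0), so the four corners equal the
    incentives directly.
    """
    return CornerPayoffs(
        R0=p.deltaL0, S0=p.deltaH0, T0=0.0, P0=0.0,
        R1=0.0, S1=0.0, T1=p.DeltaL1, P1=p.DeltaH1,
    )


def _as_incentives(params: Params) -> IncentiveParams:
    if isinstance(params, IncentiveParams):
        return params
    if isinstance(params, AffineParams):
        params = corners_from_affine(params)
    return corner_incentives(params)


def advantage_coefficients(params: Params) -> tuple[float, float, float, float]:
    """Coefficients (a0, az, an, azn) of piL - piH = a0 + az z + an n + azn z n.

    Useful for hot loops: the advantage is bilinear in (z, n).
    """
    p = _as_incentives(params)
    a0 = p.deltaH0
    az = p.deltaL0 - p.deltaH0
    an = -(p.deltaH0 + p.DeltaH1)
    azn = p.deltaH0 - p.deltaL0 - p.DeltaL1 + p.DeltaH1
    return a0, az, an, azn


_TOL = 1e-12


def solve_fie(params: Params) -> FiePoint:
    """Solve for the full-information equilibrium n* in [0, 1].

    The FIE is the state a well-mixed, perfectly informed population attains:
    the resource fixed point equals the low-effort fraction (n = z) and the
    payoff advantage vanishes.  Substituting z = n in the bilinear advantage
    gives a quadratic in n; among roots in [0, 1] the dynamically stable one
    under anti-coordination feedback (advantage of low effort decreasing in
    n) is returned.  If no root lies in [0, 1], ``exists`` is False.

    Raises
    ------
    ValueError
        If the advantage is identically zero (every state is an equilibrium).
    """
    a0, az, an, azn = advantage_coefficients(params)
    # advantage_low(n, n) = a0 + (az + an) n + azn n^2
    c2, c1, c0 = azn, az + an, a0
    if abs(c2) < _TOL and abs(c1) < _TOL and abs(c0) < _TOL:
        raise ValueError("degenerate payoffs: advantage is identically zero")

    if abs(c2) < _TOL:
        roots = [] if abs(c1) < _TOL else [-c0 / c1]
    else:
        disc = c1 * c1 - 4 * c2 * c0
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)]

    candidates = [r for r in roots if -_TOL <= r <= 1 + _TOL]
    if not candidates:
        return FiePoint(n_star=math.nan, exists=False)

    def slope(n: float) -> float:
        return c1 + 2 * c2 * n

    # prefer the stabilizing root: d/dn advantage_low(n, n) < 0
    stable = [r for r in candidates if slope(r) < 0]
    root = min(stable or candidates, key=slope)
    return FiePoint(n_star=min(1.0, max(0.0, root)), exists=True)
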
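"""Closed-form analysis of symmetric solutions.

A symmetric solution has M equal follicles at relative size 1/M (all
others at zero).  Substituting into the growth law gives a constant
velocity per follicle

    v = (alpha / M) * phi(1/M + A_ex),

so the M follicles grow linearly in time.  The solution *grows* iff
v > 0, i.e. (at A_ex = 0) iff M1 < M < M2.  It is *stable* iff 1/M lies
on the declining branch of phi (right of the maximum), which for the
parabola means

    M1 < M < M_max = 2*M1*M2/(M1 + M2),

the harmonic mean of the zero-crossing parameters; in the limit
M2 >> M1 this is M1 < M < 2*M1.  The stable integers are the achievable
ovulation numbers.  M2 = inf is accepted as a sentinel for that limit.

External androgen A_ex shifts phi's argument, which moves both the
growth window and the maximum in u-space; all criteria here apply the
shift consistently and reduce to the formulas above at A_ex = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Set, Tuple

from scipy import optimize

from .core import BiphasicParams, ParameterError, phi

__all__ = [
    "SymmetricSolution",
    "StabilityCriteria",
    "M1Interval",
    "symmetric_velocity",
    "m_max",
    "is_stable",
    "symmetric_solution",
    "stable_set",
    "stability_criteria",
    "m1_interval_for",
]


@dataclass(frozen=True)
class SymmetricSolution:
    """One candidate ovulation number with its velocity and verdicts."""

    M: int
    velocity: float
    grows: bool
    stable: bool


@dataclass(frozen=True)
class StabilityCriteria:
    """Parameter-level intervals: which M grow, which are stable."""

    m_max: float
    growth_interval: Tuple[float, float]  # open (M1, M2)
    stable_interval: Tuple[float, float]  # open (M1, M_max)


@dataclass(frozen=True)
class M1Interval:
    """Open interval of M1 values making a given M stable; may be empty."""

    low: float
    high: float

    @property
    def empty(self) -> bool:
        return not self.low < self.high

    def contains(self, m1: float) -> bool:
        return self.low < m1 < self.high


def _check_m(M: int) -> int:
    if M < 1 or int(M) != M:
        raise ParameterError(f"M must be a positive integer, got {M}")
    return int(M)


def symmetric_velocity(M: int, params: BiphasicParams) -> float:
    """Velocity (alpha/M)*phi(1/M + A_ex) of the M-follicle symmetric state."""
    M = _check_m(M)
    return params.alpha / M * float(phi(1.0 / M + params.a_ex, params))


def _phi_argmax(params: BiphasicParams) -> float:
    """Location of phi's maximum in u (unshifted argument)."""
    if params.is_parabola:
        return 0.5 * (1.0 / params.m1 + 1.0 / params.m2)
    res = optimize.minimize_scalar(
        lambda u: -params.phi_fn(u),
        bounds=(1.0 / params.m2, 1.0 / params.m1),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def m_max(params: BiphasicParams) -> float:
    """Upper stability bound on M: 2*M1*M2/(M1+M2) for the parabola.

    For a pluggable phi the bound is 1/argmax(phi), found numerically
    on the bracket (1/M2, 1/M1).  M2 = inf gives the limit 2*M1.
    """
    if params.is_parabola and math.isinf(params.m2):
        return 2.0 * params.m1
    return 1.0 / _phi_argmax(params)


def _growth_window(params: BiphasicParams) -> Tuple[float, float]:
    """Open window of u where phi(u + A_ex) > 0, clipped to u >= 0."""
    lo = 1.0 / params.m2 - params.a_ex if not math.isinf(params.m2) else -params.a_ex
    hi = 1.0 / params.m1 - params.a_ex
    return max(lo, 0.0), hi


def is_stable(M: int, params: BiphasicParams) -> bool:
    """Is the M-follicle symmetric solution a stable growing solution?

    For M >= 2: grows (phi positive at u = 1/M + A_ex) *and* sits on
    the declining branch of phi (1/M + A_ex past the maximum), i.e.
    M1 < M < M_max at A_ex = 0.  Boundaries are excluded (strict
    inequalities).

    For M = 1 the symmetric-perturbation criterion does not apply: a
    lone follicle has relative size exactly 1, larger perturbations are
    impossible, and an infinitesimal competitor at u ~ 0 has phi < 0
    and shrinks.  M = 1 is therefore stable iff it grows at all:
    phi(1 + A_ex) > 0.
    """
    M = _check_m(M)
    lo, hi = _growth_window(params)
    u = 1.0 / M
    grows = lo < u < hi
    if M == 1:
        return grows
    if not grows:
        return False
    if params.is_parabola:
        if math.isinf(params.m2):
            # maximum of the limit shape sits at (1/m1)/2 (parabola midpoint
            # with 1/m2 -> 0)
            u_star = 0.5 / params.m1
        else:
            u_star = _phi_argmax(params)
    else:
        u_star = _phi_argmax(params)
    # declining branch of the shifted curve: u + a_ex > u_star
    return u + params.a_ex > u_star


def symmetric_solution(M: int, params: BiphasicParams) -> SymmetricSolution:
    """Assemble velocity + verdicts for one M (finite M2 required)."""
    M = _check_m(M)
    v = symmetric_velocity(M, params)
    return SymmetricSolution(M=M, velocity=v, grows=v > 0.0, stable=is_stable(M, params))


def stable_set(params: BiphasicParams, m_cap: int = 20) -> Set[int]:
    """All stable integer ovulation numbers up to ``m_cap``.

    Whenever M = 1 is stable it is the only element: M = 1 stable
    requires M1 < 1 (at A_ex = 0), and then M_max < 2*M1 < 2 excludes
    every M >= 2.
    """
    if m_cap < 1:
        raise ParameterError(f"m_cap must be >= 1, got {m_cap}")
    return {M for M in range(1, m_cap + 1) if is_stable(M, params)}


def stability_criteria(params: BiphasicParams) -> StabilityCriteria:
    mm = m_max(params)
    return StabilityCriteria(
        m_max=mm,
        growth_interval=(params.m1, params.m2),
        stable_interval=(params.m1, mm),
    )


def m1_interval_for(M: int, m2: float) -> M1Interval:
    """Open interval of M1 values for which M is a stable ovulation number.

    Solves M1 < M < 2*M1*m2/(M1 + m2) for M1: the stability bound gives
    M1 > M*m2/(2*m2 - M), intersected with M1 < M.  In the m2 -> inf
    limit this is (M/2, M).  If 2*m2 <= M the interval is empty
    (stability impossible at that m2).
    """
    M = _check_m(M)
    if M < 2:
        # M = 1 is governed by the growth condition alone: M1 < 1.
        return M1Interval(0.0, 1.0)
    if math.isinf(m2):
        return M1Interval(M / 2.0, float(M))
    if not m2 > 0:
        raise ParameterError(f"M2 must be positive, got {m2}")
    if 2.0 * m2 <= M:
        return M1Interval(float(M), float(M))  # empty
    low = M * m2 / (2.0 * m2 - M)
    return M1Interval(low, float(M))
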
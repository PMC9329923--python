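"""Reference implementation of Lacker's follicle-competition model.

In its rescaled form, follicle i obeys

    dx_i/dt = x_i * g(x_i, x_T),
    g(x_i, x_T) = 1 - (x_T - M1*x_i) * (x_T - M2*x_i),

with x_T the total size.  The symmetric solution (M equal follicles)
collapses to the scalar ODE

    dx_T/dt = x_T + mu * x_T**3,     mu = -(1 - M1/M) * (1 - M2/M).

For mu > 0 the total size diverges at a finite blow-up time
t* = 0.5 * ln(1 + 1/(mu * x0**2)) (super-exponential growth); for
mu < 0 it settles at the growth-arrest steady state
x_T* = 1/sqrt(|mu|) (per follicle x_T*/M); mu = 0 is marginal (pure
exponential).

Dropping the constant 1 from g and transforming time by
d(tau)/dt = x_T**3 turns Lacker's model into the relative-size law
du_i/d(tau) = u_i * phi(u_i) with the parabolic phi — the same flow as
:mod:`follisim.core` on a different clock.  :func:`time_transform_check`
verifies this numerically by comparing relative-size vectors of the two
systems at matched values of x_T (the common monotone clock along an
orbit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import BiphasicParams, ParameterError, growth_rhs

__all__ = [
    "LackerParams",
    "SymmetricLackerSolution",
    "TransformAgreement",
    "lacker_rhs",
    "mu",
    "blowup_time_closed_form",
    "symmetric_fate",
    "time_transform_check",
]

BLOWUP_FACTOR = 1e12  # x_T this many times above x0 counts as blown up


@dataclass(frozen=True)
class LackerParams:
    """Zero-crossing parameters of Lacker's g, same roles as M1/M2."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if not (0 < self.m1 < self.m2):
            raise ParameterError(f"require 0 < M1 < M2, got {self.m1}, {self.m2}")


@dataclass(frozen=True)
class SymmetricLackerSolution:
    """Fate of the M-follicle symmetric solution of Lacker's model."""

    M: int
    mu: float
    regime: str  # "blow-up" | "arrest" | "marginal"
    blow_up_time: Optional[float] = None
    arrest_size: Optional[float] = None  # steady-state x_T
    arrest_size_per_follicle: Optional[float] = None


@dataclass(frozen=True)
class TransformAgreement:
    """Result of matching the de-constanted Lacker flow to the biphasic flow."""

    max_discrepancy: float
    n_points: int
    xt_range: tuple
    monotone_restricted: bool


def lacker_rhs(sizes, params: LackerParams) -> np.ndarray:
    """dx_i/dt = x_i * (1 - (x_T - M1*x_i)(x_T - M2*x_i))."""
    x = np.asarray(sizes, dtype=float)
    total = x.sum()
    return x * (1.0 - (total - params.m1 * x) * (total - params.m2 * x))


def _deconstanted_rhs(sizes, params: LackerParams) -> np.ndarray:
    """Lacker's law without the constant 1 in g (pure parabolic part)."""
    x = np.asarray(sizes, dtype=float)
    total = x.sum()
    return -x * (total - params.m1 * x) * (total - params.m2 * x)


def mu(M: int, params: LackerParams) -> float:
    """Symmetric-solution coefficient mu = -(1 - M1/M)(1 - M2/M)."""
    if M < 1 or int(M) != M:
        raise ParameterError(f"M must be a positive integer, got {M}")
    return -(1.0 - params.m1 / M) * (1.0 - params.m2 / M)


def blowup_time_closed_form(mu_val: float, x0: float) -> float:
    """Separable-ODE blow-up time of dx/dt = x + mu*x^3 for mu > 0."""
    if mu_val <= 0:
        raise ParameterError("closed-form blow-up time requires mu > 0")
    return 0.5 * math.log(1.0 + 1.0 / (mu_val * x0 * x0))


def symmetric_fate(
    M: int, x0: float, params: LackerParams, rtol: float = 1e-10
) -> SymmetricLackerSolution:
    """Integrate dx_T/dt = x_T + mu*x_T^3 and classify the outcome.

    Blow-up (mu > 0) is detected when x_T exceeds ``BLOWUP_FACTOR * x0``;
    beyond that point the remaining time to the singularity is
    ~ 1/(2*mu*x_T^2), far below any reported precision, so the event
    time is reported as the blow-up time.  To keep the event resolvable,
    the integration runs in the reciprocal-square variable
    w = x_T**(-2), which obeys the equivalent (and non-stiff) ODE
    dw/dt = -2*w - 2*mu and reaches the threshold with w still of
    moderate size; integrating x_T directly stalls, since past
    x_T ~ 1e8 the remaining time to the singularity is smaller than the
    floating-point spacing of t.  Arrest (mu < 0) reports the fixed
    point 1/sqrt(|mu|) (confirmed by the integration approaching it).
    mu = 0 exactly is flagged marginal.
    """
    if x0 <= 0:
        raise ParameterError("x0 must be positive")
    m = mu(M, params)
    if m == 0.0:
        return SymmetricLackerSolution(M=M, mu=m, regime="marginal")

    if m > 0.0:
        w0 = x0**-2
        w_cap = w0 / BLOWUP_FACTOR**2

        def rhs_w(t, w):
            return -2.0 * w - 2.0 * m

        def blown(t, w):
            return w[0] - w_cap

        blown.terminal = True
        blown.direction = -1.0
        horizon = 10.0 * blowup_time_closed_form(m, x0)
        sol = solve_ivp(
            rhs_w, (0.0, horizon), [w0], rtol=rtol, atol=1e-300, events=[blown]
        )
        if len(sol.t_events[0]) == 0:
            raise RuntimeError("blow-up event not reached; horizon too short")
        return SymmetricLackerSolution(
            M=M, mu=m, regime="blow-up", blow_up_time=float(sol.t_events[0][0])
        )

    arrest = 1.0 / math.sqrt(-m)
    return SymmetricLackerSolution(
        M=M,
        mu=m,
        regime="arrest",
        arrest_size=arrest,
        arrest_size_per_follicle=arrest / M,
    )


def _monotone_prefix(ts: np.ndarray, xt: np.ndarray) -> int:
    """Index of the last point before x_T's first change of direction."""
    d = np.diff(xt)
    if len(d) == 0:
        return 0
    sign0 = np.sign(d[0]) or 1.0
    turn = np.nonzero(np.sign(d) != sign0)[0]
    return int(turn[0]) if len(turn) else len(xt) - 1


def time_transform_check(
    initial: Sequence[float],
    params: LackerParams,
    horizon: float = 50.0,
    xt_cap_factor: float = 50.0,
    n_points: int = 100,
    rtol: float = 1e-10,
) -> TransformAgreement:
    """Compare the de-constanted Lacker flow with the biphasic flow.

    Both systems are integrated from the same initial sizes; because
    they share orbits (one is a time rescaling of the other by the
    positive factor x_T^3), their relative-size vectors must agree when
    compared at equal values of x_T.  x_T serves as the common clock on
    its first strictly monotone stretch; if x_T turns around inside the
    horizon, the comparison is restricted to that prefix and flagged.
    """
    x0 = np.asarray(initial, dtype=float)
    if x0.sum() <= 0:
        raise ParameterError("cohort must have positive total size")
    bip = BiphasicParams(m1=params.m1, m2=params.m2, alpha=1.0, a_ex=0.0)

    cap = xt_cap_factor * x0.sum()

    def capped(t, x):
        return np.maximum(x, 0.0).sum() - cap

    capped.terminal = True
    capped.direction = 1.0

    floor = 1e-6 * x0.sum()

    def floored(t, x):
        return np.maximum(x, 0.0).sum() - floor

    floored.terminal = True
    floored.direction = -1.0

    def run(rhs):
        def guarded(t, x):
            xp = np.maximum(x, 0.0)
            if xp.sum() <= 0.0:
                return np.zeros_like(xp)
            return rhs(xp)

        sol = solve_ivp(
            guarded,
            (0.0, horizon),
            x0,
            rtol=rtol,
            atol=1e-12,
            dense_output=True,
            events=[capped, floored],
        )
        return sol

    sol_a = run(lambda x: _deconstanted_rhs(x, params))
    sol_b = run(lambda x: growth_rhs(x, bip))

    restricted = False
    grids = []
    for sol in (sol_a, sol_b):
        ts = np.linspace(sol.t[0], sol.t[-1], 4000)
        xt = np.maximum(sol.sol(ts), 0.0).sum(axis=0)
        k = _monotone_prefix(ts, xt)
        if k < len(ts) - 1:
            restricted = True
        grids.append((sol, ts[: k + 1], xt[: k + 1]))

    # overlapping x_T range on the monotone prefixes
    lo = max(min(g[2][0], g[2][-1]) for g in grids)
    hi = min(max(g[2][0], g[2][-1]) for g in grids)
    if not hi > lo:
        raise RuntimeError("no overlapping monotone x_T range to compare on")
    targets = np.linspace(lo, hi, n_points + 2)[1:-1]

    def u_at_xt(sol, ts, xt, target):
        f = lambda t: np.maximum(sol.sol(t), 0.0).sum() - target
        # bracket on the stored monotone grid
        idx = np.searchsorted(xt if xt[-1] > xt[0] else -xt,
                              target if xt[-1] > xt[0] else -target)
        idx = min(max(idx, 1), len(ts) - 1)
        a, b = ts[idx - 1], ts[idx]
        fa, fb = f(a), f(b)
        if fa == 0.0:
            t_star = a
        elif fb == 0.0:
            t_star = b
        elif fa * fb > 0:  # target slightly off-bracket; widen to full prefix
            t_star = brentq(f, ts[0], ts[-1], xtol=1e-14)
        else:
            t_star = brentq(f, a, b, xtol=1e-14)
        x = np.maximum(sol.sol(t_star), 0.0)
        return x / x.sum()

    worst = 0.0
    for target in targets:
        ua = u_at_xt(*grids[0], target)
        ub = u_at_xt(*grids[1], target)
        worst = max(worst, float(np.abs(ua - ub).max()))
    return TransformAgreement(
        max_discrepancy=worst,
        n_points=len(targets),
        xt_range=(float(lo), float(hi)),
        monotone_restricted=restricted,
    )
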
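"""Numerical integration of follicle cohorts.

Two protocols are supported:

fixed-cohort
    N follicles start together with random sizes (uniform between
    ``init_low`` and ``init_high``) and compete from t = 0.  The run
    ends at the simulated LH surge — the first time the total follicle
    size reaches ``surge_multiplier`` times its initial value (total
    size standing in for circulating estradiol) — or at ``t_max``.

continual-entry
    Follicles enter the cycle at random times.  Before entry a follicle
    grows independently and exponentially at rate ``gamma``
    (dx/dt = gamma*x) from the initial size ``x_c * exp(-gamma*t_i)``,
    so it reaches the critical size ``x_c`` exactly at its entry time
    ``t_i``; from then on it permanently obeys the competition law,
    even if it later shrinks below ``x_c``.  The total size ``x_T``
    sums over all follicles at all times (a config flag can restrict it
    to competing follicles for sensitivity analyses).  No surge by
    default; the run covers a fixed horizon.

Integration uses an adaptive Runge-Kutta solver (rtol 1e-8, atol
1e-10); the surge is localized by the solver's event root-finding.
Sizes are clamped at zero: a follicle that regresses to zero size stays
there (atresia is absorbing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    BiphasicParams,
    DegenerateCohortError,
    ParameterError,
    growth_rhs,
    phi,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "OvulationOutcome",
    "SolverError",
    "sample_initial_sizes",
    "integrate_cohort",
    "simulate_continual_entry",
    "classify_ovulating",
    "twin_scenario",
    "normalize_time",
]

FIXED_COHORT = "fixed-cohort"
CONTINUAL_ENTRY = "continual-entry"

# a cohort whose total size falls below this fraction of its initial total
# is treated as fully atretic (run terminated, no ovulation); kept well
# above the solver's absolute tolerance so the collapse is still resolved
EXTINCTION_FLOOR = 1e-6


class SolverError(RuntimeError):
    """The ODE solver failed to produce a trajectory."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run, except the model params.

    Defaults encode the standard protocol: initial sizes uniform on
    [0.05, 0.15], surge at 4.6x the initial total size, and (for
    continual entry) gamma = 1, x_c = 1.
    """

    n_follicles: int = 5
    init_low: float = 0.05
    init_high: float = 0.15
    seed: int = 0
    surge_multiplier: Optional[float] = 4.6
    t_max: float = 1000.0
    mode: str = FIXED_COHORT
    gamma: float = 1.0
    x_c: float = 1.0
    n_entries: int = 25
    entry_window: float = 40.0
    explicit_initial_sizes: Optional[Tuple[float, ...]] = None
    include_precompetition_in_total: bool = True
    surge_in_continual_entry: bool = False
    rtol: float = 1e-8
    atol: float = 1e-10
    n_report: int = 400

    def __post_init__(self) -> None:
        if self.n_follicles < 1:
            raise ParameterError("n_follicles must be >= 1")
        if not (0 < self.init_low < self.init_high):
            raise ParameterError(
                f"require 0 < init_low < init_high, got [{self.init_low}, {self.init_high}]"
            )
        if self.surge_multiplier is not None and not self.surge_multiplier > 1:
            raise ParameterError("surge_multiplier must exceed 1")
        if self.mode not in (FIXED_COHORT, CONTINUAL_ENTRY):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.gamma <= 0 or self.x_c <= 0:
            raise ParameterError("gamma and x_c must be positive")
        if self.n_entries < 1:
            raise ParameterError("n_entries must be >= 1")
        if self.t_max <= 0 or self.entry_window <= 0:
            raise ParameterError("t_max and entry_window must be positive")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_follicles init_low init_high seed surge_multiplier t_max mode "
                "gamma x_c n_entries entry_window include_precompetition_in_total "
                "surge_in_continual_entry rtol atol n_report"
            ).split()
        }
        d["explicit_initial_sizes"] = (
            list(self.explicit_initial_sizes)
            if self.explicit_initial_sizes is not None
            else None
        )
        return d


@dataclass
class Trajectory:
    """Dense record of one run on a uniform reporting grid.

    ``sizes`` has one row per time point and one column per follicle.
    ``entry_times`` is None for fixed cohorts; in continual-entry mode
    follicle i is pre-competition while ``times < entry_times[i]``.
    """

    times: np.ndarray
    sizes: np.ndarray
    total_size: np.ndarray
    surge_time: Optional[float]
    params: BiphasicParams
    config: SimulationConfig
    entry_times: Optional[np.ndarray] = None

    @property
    def n_follicles(self) -> int:
        return self.sizes.shape[1]

    @property
    def final_sizes(self) -> np.ndarray:
        return self.sizes[-1]

    def relative(self) -> np.ndarray:
        return self.sizes / self.total_size[:, None]

    def phase_matrix(self) -> np.ndarray:
        """Boolean (time x follicle): True where the follicle competes."""
        if self.entry_times is None:
            return np.ones_like(self.sizes, dtype=bool)
        return self.times[:, None] >= self.entry_times[None, :]


@dataclass(frozen=True)
class OvulationOutcome:
    """Which follicles ovulate at the surge (or horizon)."""

    ovulating_indices: frozenset
    count: int
    surge_time: Optional[float]
    classification_rule: str


def sample_initial_sizes(config: SimulationConfig) -> np.ndarray:
    """Initial follicle sizes: uniform draws, or the explicit override."""
    if config.explicit_initial_sizes is not None:
        return np.asarray(config.explicit_initial_sizes, dtype=float)
    rng = np.random.default_rng(config.seed)
    return rng.uniform(config.init_low, config.init_high, size=config.n_follicles)


def _report_grid(t_end: float, n_report: int) -> np.ndarray:
    return np.linspace(0.0, t_end, n_report)


def integrate_cohort(
    initial: Sequence[float],
    params: BiphasicParams,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate a fixed cohort from t = 0 to the surge or ``t_max``.

    The surge fires the first time ``x_T`` rises through
    ``surge_multiplier * x_T(0)``; the event time is localized by the
    solver's root-finder.  Output is evaluated on a uniform grid whose
    last point is exactly the surge time (or ``t_max``).
    """
    x0 = np.asarray(initial, dtype=float)
    if x0.sum() <= 0.0:
        raise DegenerateCohortError("cohort must contain positive total size")
    if np.any(x0 < 0.0):
        raise ParameterError("initial sizes must be non-negative")

    def rhs(t, x):
        xp = np.maximum(x, 0.0)
        if xp.sum() <= 0.0:  # fully extinct (or a transient trial step)
            return np.zeros_like(xp)
        return growth_rhs(xp, params)

    # total extinction: symmetric states below the growth window shrink at
    # constant negative velocity and hit zero in finite time (full atresia)
    floor = EXTINCTION_FLOOR * x0.sum()

    def extinct(t, x):
        return np.maximum(x, 0.0).sum() - floor

    extinct.terminal = True
    extinct.direction = -1.0

    events = [extinct]
    if config.surge_multiplier is not None:
        threshold = config.surge_multiplier * x0.sum()

        def surge(t, x):
            return np.maximum(x, 0.0).sum() - threshold

        surge.terminal = True
        surge.direction = 1.0
        events.append(surge)

    sol = solve_ivp(
        rhs,
        (0.0, config.t_max),
        x0,
        method="RK45",
        rtol=config.rtol,
        atol=config.atol,
        dense_output=True,
        events=events,
    )
    if not sol.success and sol.status != 1:
        raise SolverError(f"integration failed: {sol.message}")

    surge_time = None
    if config.surge_multiplier is not None and len(sol.t_events[1]) > 0:
        surge_time = float(sol.t_events[1][0])
    t_end = surge_time if surge_time is not None else float(sol.t[-1])

    times = _report_grid(t_end, config.n_report)
    sizes = np.maximum(sol.sol(times).T, 0.0)
    return Trajectory(
        times=times,
        sizes=sizes,
        total_size=sizes.sum(axis=1),
        surge_time=surge_time,
        params=params,
        config=config,
    )


def simulate_continual_entry(
    params: BiphasicParams, config: SimulationConfig
) -> Trajectory:
    """Continual-entry run: exponential pre-growth, then competition.

    Entry times are uniform on [0, entry_window]; every follicle exists
    from t = 0 at size ``x_c * exp(-gamma * t_i)`` and switches to the
    competition law exactly at its entry time (the pre-entry exponential
    is autonomous, so the switch schedule is known in advance and the
    integration proceeds piecewise between switches).
    """
    if config.mode != CONTINUAL_ENTRY:
        raise ParameterError("config.mode must be 'continual-entry'")
    rng = np.random.default_rng(config.seed)
    entry_times = np.sort(rng.uniform(0.0, config.entry_window, size=config.n_entries))
    x0 = config.x_c * np.exp(-config.gamma * entry_times)
    n = config.n_entries

    def make_rhs(competing: np.ndarray):
        def rhs(t, x):
            xp = np.maximum(x, 0.0)
            total = xp.sum() if config.include_precompetition_in_total else xp[competing].sum()
            d = config.gamma * xp  # pre-competition follicles
            if total > 0.0 and competing.any():
                u = xp[competing] / total
                d[competing] = params.alpha * u * np.asarray(
                    phi(u + params.a_ex, params)
                )
            return d

        return rhs

    # segment boundaries: each entry time (follicles switch there), then t_max
    boundaries = [t for t in entry_times if t < config.t_max] + [config.t_max]
    segments: List = []  # (t0, t1, dense solution)
    surge_time = None
    threshold = None
    state = x0.copy()
    t0 = 0.0
    competing = entry_times <= 0.0
    for t1 in boundaries:
        if t1 > t0:
            events = None
            if (
                config.surge_in_continual_entry
                and config.surge_multiplier is not None
                and threshold is not None
            ):
                def surge(t, x, thr=threshold):
                    return np.maximum(x, 0.0).sum() - thr

                surge.terminal = True
                surge.direction = 1.0
                events = [surge]
            sol = solve_ivp(
                make_rhs(competing.copy()),
                (t0, t1),
                state,
                method="RK45",
                rtol=config.rtol,
                atol=config.atol,
                dense_output=True,
                events=events,
            )
            if not sol.success and sol.status != 1:
                raise SolverError(f"integration failed on [{t0}, {t1}]: {sol.message}")
            segments.append((t0, float(sol.t[-1]), sol.sol))
            state = sol.y[:, -1].copy()
            if events and sol.t_events and len(sol.t_events[0]) > 0:
                surge_time = float(sol.t_events[0][0])
                break
            t0 = t1
        newly = np.isclose(entry_times, t1) & ~competing
        competing |= newly
        if newly.any() and threshold is None and config.surge_multiplier is not None:
            # surge threshold anchored at x_T when competition first starts
            threshold = config.surge_multiplier * np.maximum(state, 0.0).sum()

    t_end = surge_time if surge_time is not None else min(config.t_max, segments[-1][1])
    times = _report_grid(t_end, config.n_report)
    sizes = np.empty((len(times), n))
    for i, t in enumerate(times):
        for s0, s1, dense in segments:
            if s0 <= t <= s1:
                sizes[i] = dense(t)
                break
        else:  # t beyond last segment end (numerical edge); use final state
            sizes[i] = segments[-1][2](segments[-1][1])
    sizes = np.maximum(sizes, 0.0)
    return Trajectory(
        times=times,
        sizes=sizes,
        total_size=sizes.sum(axis=1),
        surge_time=surge_time,
        params=params,
        config=config,
        entry_times=entry_times,
    )


def classify_ovulating(
    traj: Trajectory,
    params: Optional[BiphasicParams] = None,
    rule: str = "growth+size",
    leader_fraction: Optional[float] = None,
) -> OvulationOutcome:
    """Decide which follicles ovulate at the surge (else at the horizon).

    Default rule ("growth+size"): follicle i ovulates iff it is
    instantaneously growing at the evaluation time (phi(u_i + A_ex) > 0
    with u_i > 0) *and* has reached a size comparable to the dominant
    follicle (at least ``leader_fraction`` of the largest, default 0.5).
    The growth condition alone leaves stragglers in: when 1/M2 is small,
    a follicle far behind the leader can still sit just inside the
    positive window and grow slowly at the surge even though it has
    already lost the race in relative size; the size condition removes
    those, while co-dominant winners (near-equal by construction of the
    symmetric attractor) always satisfy it.

    Alternative rules: "growth" (growth condition only) and "fraction"
    (size within ``leader_fraction`` of the largest, default 0.8).

    Pre-competition follicles (continual-entry mode, not yet past the
    developmental switch) are never classified as ovulating.
    """
    if traj.sizes.size == 0:
        raise ValueError("empty trajectory")
    params = params or traj.params
    x = traj.final_sizes.copy()
    if traj.entry_times is not None:
        x[traj.entry_times > traj.times[-1]] = 0.0  # pre-competition: ineligible
    total = traj.final_sizes.sum()
    if total <= 0.0 or x.max() <= 0.0:
        idx: frozenset = frozenset()
    else:
        u = x / total
        growing = (u > 0.0) & (np.asarray(phi(u + params.a_ex, params)) > 0.0)
        if rule == "growth":
            ok = growing
        elif rule == "fraction":
            f = 0.8 if leader_fraction is None else leader_fraction
            ok = x >= f * x.max()
        elif rule == "growth+size":
            f = 0.5 if leader_fraction is None else leader_fraction
            ok = growing & (x >= f * x.max())
        else:
            raise ParameterError(f"unknown classification rule {rule!r}")
        idx = frozenset(int(i) for i in np.nonzero(ok)[0])
    return OvulationOutcome(
        ovulating_indices=idx,
        count=len(idx),
        surge_time=traj.surge_time,
        classification_rule=rule,
    )


def twin_scenario(
    delta: float,
    params: BiphasicParams,
    config: SimulationConfig,
    surge: bool = True,
    return_trajectory: bool = False,
):
    """Race whose two leading follicles differ by relative gap ``delta``.

    The leaders start at ``init_high`` and ``init_high * (1 - delta)``;
    the remaining ``n_follicles - 2`` competitors are sampled strictly
    below both.  With the surge on, near-identical leaders can reach the
    surge together and both ovulate even when only one follicle is a
    stable outcome; with the surge off and a long horizon, the smaller
    twin eventually shrinks.  ``delta = 0`` gives exactly equal twins
    (identical for all time, by uniqueness of ODE solutions).
    """
    if delta < 0.0:
        raise ParameterError("delta must be non-negative")
    if delta >= 0.05:
        raise ParameterError("delta must be a small gap (< 0.05 relative)")
    if config.n_follicles < 2:
        raise ParameterError("twin scenario needs at least 2 follicles")
    rng = np.random.default_rng(config.seed)
    leader = config.init_high
    second = leader * (1.0 - delta)
    n_small = config.n_follicles - 2
    hi_small = min(0.95 * second, 0.5 * (config.init_low + config.init_high))
    small = rng.uniform(config.init_low, hi_small, size=n_small)
    initial = np.concatenate([[leader, second], small])
    run_cfg = replace(
        config,
        explicit_initial_sizes=tuple(initial),
        surge_multiplier=config.surge_multiplier if surge else None,
    )
    traj = integrate_cohort(initial, params, run_cfg)
    outcome = classify_ovulating(traj, params)
    if return_trajectory:
        return outcome, traj
    return outcome


def normalize_time(traj: Trajectory, target_duration: float = 14.0) -> Trajectory:
    """Rescale the time axis so the surge (or horizon) lands at ``target_duration``.

    A pure relabeling — model time units are arbitrary (alpha sets the
    scale), so runs are conventionally displayed on a 14-day follicular
    phase.  Sizes are unchanged; idempotent for a fixed target.
    """
    if target_duration <= 0:
        raise ParameterError("target_duration must be positive")
    anchor = traj.surge_time if traj.surge_time is not None else float(traj.times[-1])
    if anchor <= 0:
        raise ValueError("nothing to rescale: trajectory has zero duration")
    scale = target_duration / anchor
    return Trajectory(
        times=traj.times * scale,
        sizes=traj.sizes,
        total_size=traj.total_size,
        surge_time=None if traj.surge_time is None else traj.surge_time * scale,
        params=traj.params,
        config=traj.config,
        entry_times=None if traj.entry_times is None else traj.entry_times * scale,
    )
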
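import numpy as np
import pytest

from follisim import BiphasicParams, SimulationConfig


@pytest.fixture
def params_single():
    """Regime where a single follicle is the only stable ovulation number."""
    return BiphasicParams(m1=0.9, m2=3.5)


@pytest.fixture
def params_triple():
    """Regime where three (or four) co-dominant follicles are stable."""
    return BiphasicParams(m1=2.9, m2=7.5)


@pytest.fixture
def five_follicle_config():
    return SimulationConfig(n_follicles=5, seed=0, t_max=400.0)


def integrate_rk4(rhs, x0, t_end, dt):
    """Fixed-step classical Runge-Kutta reference integrator."""
    x = np.asarray(x0, dtype=float).copy()
    t = 0.0
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(x)
        k2 = rhs(x + 0.5 * dt * k1)
        k3 = rhs(x + 0.5 * dt * k2)
        k4 = rhs(x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return t, x
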
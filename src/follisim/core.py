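"""Core growth law of the follicle-competition model.

Each follicle of size ``x_i`` grows according to

    dx_i/dt = alpha * u_i * phi(u_i + A_ex),      u_i = x_i / x_T,

where ``x_T = sum_j x_j`` is the total follicle size and ``phi`` is a
biphasic (inverse-U) function of the follicle's *relative* size: negative
below ``1/M2`` and above ``1/M1``, positive in between.  The relative size
enters because the local (intra-follicular) androgen concentration, the
growth-controlling signal, is proportional to ``x_i / x_T``.  ``A_ex``
models chronic external androgen, which shifts the biphasic curve to the
left and can abolish the positive-growth window entirely (the model's
picture of anovulatory PCOS).

The default ``phi`` is the parabola ``(1 - M1*u) * (M2*u - 1)``; any other
biphasic shape with the same zero crossings can be plugged in via
:attr:`BiphasicParams.phi_fn`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BiphasicParams",
    "AndrogenParams",
    "ParameterError",
    "DegenerateCohortError",
    "phi",
    "growth_rhs",
    "local_androgen",
    "relative_sizes",
]


class ParameterError(ValueError):
    """Model parameters violate their invariants (e.g. M1 >= M2)."""


class DegenerateCohortError(ValueError):
    """Operation undefined because the total follicle size x_T is zero."""


@dataclass(frozen=True)
class BiphasicParams:
    """Control parameters of the biphasic growth law.

    Parameters
    ----------
    m1, m2
        Dimensionless zero-crossing parameters: ``phi`` is positive for
        relative sizes in the open window ``(1/m2, 1/m1)``.  Requires
        ``0 < m1 < m2``.  ``m2 = inf`` is accepted as a sentinel for
        limit analyses in :mod:`follisim.symmetric`; the pointwise
        functions :func:`phi` and :func:`growth_rhs` need finite ``m2``.
    alpha
        Velocity constant (size per unit model time); pure time rescale.
    a_ex
        External androgen, in relative-size units, added to ``phi``'s
        argument.  ``a_ex >= 1/m1`` closes the growth window completely.
    phi_fn
        Optional replacement biphasic function ``phi(u) -> float`` (must
        be vectorized over numpy arrays).  When given, it overrides the
        parabola; analytic shortcuts that assume the parabola fall back
        to numerical root/extremum finding.
    """

    m1: float
    m2: float
    alpha: float = 1.0
    a_ex: float = 0.0
    phi_fn: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ParameterError(f"M1 and M2 must be positive, got {self.m1}, {self.m2}")
        if not self.m1 < self.m2:
            raise ParameterError(f"require M1 < M2, got M1={self.m1}, M2={self.m2}")
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if self.a_ex < 0:
            raise ParameterError(f"A_ex must be non-negative, got {self.a_ex}")

    @property
    def is_parabola(self) -> bool:
        return self.phi_fn is None

    def to_dict(self) -> dict:
        return {
            "m1": self.m1,
            "m2": self.m2,
            "alpha": self.alpha,
            "a_ex": self.a_ex,
        }


@dataclass(frozen=True)
class AndrogenParams:
    """Circulating-androgen bookkeeping.

    ``a_total`` is the (approximately constant) total circulating
    androgen; ``eta`` the fraction of follicle-produced androgen that
    leaves the ovary.  The intra-follicular concentration of follicle
    *i* is then ``A_i = (a_total / eta) * x_i / x_T``: a function of
    relative, not absolute, size.
    """

    a_total: float
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not self.a_total > 0:
            raise ParameterError(f"A_T must be positive, got {self.a_total}")
        if not (0.0 < self.eta <= 1.0):
            raise ParameterError(f"eta must be in (0, 1], got {self.eta}")


def phi(u, params: BiphasicParams):
    """Evaluate the biphasic function at relative size(s) ``u``.

    Default parabola: ``(1 - M1*u) * (M2*u - 1)``, with zeros at
    ``1/M2`` and ``1/M1`` and maximum midway between them.
    """
    if params.phi_fn is not None:
        return params.phi_fn(np.asarray(u, dtype=float)) if np.ndim(u) else float(
            params.phi_fn(u)
        )
    if math.isinf(params.m2):
        raise ParameterError("phi requires finite M2; M2=inf is an analysis-only sentinel")
    u = np.asarray(u, dtype=float)
    out = (1.0 - params.m1 * u) * (params.m2 * u - 1.0)
    return float(out) if out.ndim == 0 else out


def relative_sizes(sizes) -> np.ndarray:
    """Fractions ``u_i = x_i / x_T``; requires ``x_T > 0``."""
    sizes = np.asarray(sizes, dtype=float)
    total = sizes.sum()
    if total <= 0.0:
        raise DegenerateCohortError("total follicle size x_T must be positive")
    return sizes / total


def growth_rhs(sizes, params: BiphasicParams) -> np.ndarray:
    """Time derivative of every follicle size under the competition law.

    ``dx_i/dt = alpha * u_i * phi(u_i + A_ex)`` with ``u_i = x_i/x_T``;
    the total ``x_T`` sums over *all* follicles.  A zero-size follicle
    has zero derivative (atresia is absorbing).  Depends on relative
    sizes only: rescaling the whole cohort leaves the derivative vector
    unchanged.
    """
    u = relative_sizes(sizes)
    return params.alpha * u * np.asarray(phi(u + params.a_ex, params))


def local_androgen(sizes, andr: AndrogenParams) -> np.ndarray:
    """Intra-follicular androgen concentrations ``A_i = beta * x_i``.

    ``beta = A_T / (eta * x_T)``, so ``eta * sum(A_i) = A_T`` exactly
    (total circulating androgen is conserved) and each ``A_i`` is
    proportional to the follicle's relative size.
    """
    sizes = np.asarray(sizes, dtype=float)
    total = sizes.sum()
    if total <= 0.0:
        raise DegenerateCohortError("total follicle size x_T must be positive")
    beta = andr.a_total / (andr.eta * total)
    return beta * sizes
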
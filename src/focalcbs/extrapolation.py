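"""Two- and three-point complete-basis-set extrapolation kernels.

Three convergence models are used, one per energy component:

* mean-field (HF):        E(X) = E_CBS + A * exp(alpha * sqrt(X)), alpha < 0
* correlation:            E(X) = E_CBS + A * X**(-beta),           beta  > 0
* mixed Gaussian/exp.:    E(X) = E_CBS + B * exp(-(X-1)) + C * exp(-(X-1)**2)

The two-point kernels eliminate (E_CBS, A) exactly from two basis cardinal
numbers; the three-point form is an exact 3x3 linear solve in
(E_CBS, B, C).  All kernels are pure functions of their inputs and are
exact (machine precision) on data generated from their own model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import IllConditionedExtrapolationError, InvalidRecordError

#: Relative weight-separation threshold below which a two-point
#: extrapolation is a catastrophic cancellation.
_WEIGHT_RTOL = 1e-12


@dataclass(frozen=True)
class ExtrapolationParams:
    """Exponents of the component-wise convergence models.

    alpha (< 0) governs the mean-field model ``E_CBS + A*exp(alpha*sqrt(X))``,
    beta (> 0) the correlation power law ``E_CBS + A*X**(-beta)``, and
    gamma (> 0) the CCSD(T)-correlation power law used inside the post-MP2
    extrapolation.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha < 0):
            raise InvalidRecordError(f"alpha must be < 0, got {self.alpha}")
        if not (self.beta > 0):
            raise InvalidRecordError(f"beta must be > 0, got {self.beta}")
        if not (self.gamma > 0):
            raise InvalidRecordError(f"gamma must be > 0, got {self.gamma}")


#: Exponents refit against quintuple-zeta reference data for the
#: (aDZ, aTZ) basis pair; the package default for the cheap composite.
REFIT_ADZ_ATZ = ExtrapolationParams(alpha=-4.473, beta=2.796, gamma=2.741)

#: The conventional cubic exponent of the standard two-point correlation
#: extrapolation.
CUBIC_BETA = 3.0


def _check_pair(x_lo: int, x_hi: int) -> None:
    if x_lo >= x_hi:
        raise InvalidRecordError(
            f"cardinal pair must satisfy x_lo < x_hi, got ({x_lo}, {x_hi})"
        )


def _two_point(e_lo: float, e_hi: float, w_lo: float, w_hi: float) -> float:
    # E_CBS = (w_hi*e_lo - w_lo*e_hi) / (w_hi - w_lo) for E = E_CBS + A*w
    denom = w_hi - w_lo
    if abs(denom) <= _WEIGHT_RTOL * max(abs(w_hi), abs(w_lo)) or denom == 0.0:
        raise IllConditionedExtrapolationError(
            f"extrapolation weights {w_lo!r} and {w_hi!r} are numerically "
            "indistinguishable"
        )
    return (w_hi * e_lo - w_lo * e_hi) / denom


def hf_two_point(
    e_lo: float, e_hi: float, x_lo: int, x_hi: int, alpha: float
) -> float:
    """CBS limit of the mean-field model through two points.

    Solves ``E(X) = E_CBS + A*exp(alpha*sqrt(X))`` for ``E_CBS`` given
    energies at cardinals ``x_lo < x_hi``; ``alpha`` must be negative.
    """
    _check_pair(x_lo, x_hi)
    if not (alpha < 0):
        raise InvalidRecordError(f"alpha must be < 0, got {alpha}")
    w_lo = math.exp(alpha * math.sqrt(x_lo))
    w_hi = math.exp(alpha * math.sqrt(x_hi))
    if w_lo == 0.0 and w_hi == 0.0:
        raise IllConditionedExtrapolationError(
            f"both weights underflow for alpha={alpha}"
        )
    return _two_point(e_lo, e_hi, w_lo, w_hi)


def corr_two_point(
    e_lo: float, e_hi: float, x_lo: int, x_hi: int, beta: float
) -> float:
    """CBS limit of the correlation power law through two points.

    Solves ``E(X) = E_CBS + A*X**(-beta)``; with ``beta = 3`` this is the
    standard cubic two-point rule.
    """
    _check_pair(x_lo, x_hi)
    if not (beta > 0):
        raise InvalidRecordError(f"beta must be > 0, got {beta}")
    return _two_point(e_lo, e_hi, float(x_lo) ** -beta, float(x_hi) ** -beta)


def post_mp2_two_point(
    e_ccsdt_lo: float,
    e_ccsdt_hi: float,
    e_mp2_lo: float,
    e_mp2_hi: float,
    x_lo: int,
    x_hi: int,
    beta: float,
    gamma: float,
) -> float:
    """CBS limit of the post-MP2 correction (CCSD(T) minus MP2 correlation).

    The CCSD(T)-correlation pair is extrapolated with exponent ``gamma`` and
    the MP2-correlation pair with ``beta``; the result is the difference of
    the two limits.  With ``beta == gamma`` this reduces algebraically to
    extrapolating the (CCSD(T) - MP2) differences directly.
    """
    return corr_two_point(e_ccsdt_lo, e_ccsdt_hi, x_lo, x_hi, gamma) - (
        corr_two_point(e_mp2_lo, e_mp2_hi, x_lo, x_hi, beta)
    )


@dataclass(frozen=True)
class ThreePointSolution:
    """Exact solution of the mixed Gaussian/exponential three-point model
    ``E(X) = e_cbs + b_coef*exp(-(X-1)) + c_coef*exp(-(X-1)**2)``."""

    e_cbs: float
    b_coef: float
    c_coef: float
    x_start: int

    def energy(self, x: float) -> float:
        """Evaluate the forward model at cardinal ``x``."""
        return (
            self.e_cbs
            + self.b_coef * math.exp(-(x - 1))
            + self.c_coef * math.exp(-((x - 1) ** 2))
        )


def mixed_three_point(
    e_x: float, e_x1: float, e_x2: float, x_start: int
) -> ThreePointSolution:
    """Analytic CBS limit from three consecutive cardinals.

    Solves the 3x3 linear system of the mixed Gaussian/exponential form at
    cardinals ``x_start, x_start+1, x_start+2``.  The system is nonsingular
    for any ``x_start >= 2``, so no iteration is needed; the forward model
    reproduces the inputs to better than 1e-10 hartree.
    """
    if x_start < 2:
        raise InvalidRecordError(f"x_start must be >= 2, got {x_start}")
    xs = np.array([x_start, x_start + 1, x_start + 2], dtype=float)
    design = np.column_stack(
        [
            np.ones(3),
            np.exp(-(xs - 1.0)),
            np.exp(-((xs - 1.0) ** 2)),
        ]
    )
    e_cbs, b, c = np.linalg.solve(design, np.array([e_x, e_x1, e_x2]))
    return ThreePointSolution(
        e_cbs=float(e_cbs), b_coef=float(b), c_coef=float(c), x_start=x_start
    )
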
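"""Nonlinear least-squares refitting of the extrapolation exponents.

Each fit adjusts a single exponent so that a two-point extrapolation from
two small-basis energies best reproduces a reference value, summed over a
set of observations:

* ``HF`` target:       hf_two_point(e2, e3, alpha)  vs. a quintuple-zeta HF
  reference (residuals in hartree for absolute energies);
* ``MP2_CORR`` target: corr_two_point(e2, e3, beta) vs. a quintuple-zeta
  MP2-correlation reference;
* ``POST_MP2`` target: post_mp2_two_point(cc2, cc3, mp2_2, mp2_3, beta,
  gamma) with ``beta`` held fixed, vs. a triple-zeta post-MP2 reference.

The kernels are linear in the energies, so the same objective applies
unchanged whether observations carry absolute fragment energies or
counterpoise-corrected interaction components (the difference of the
extrapolations equals the extrapolation of the differences); the
interaction-level reading is the default interpretation for the post-MP2
target.  The objective is unweighted least squares and contains no
randomness: results are deterministic given the fixed starting points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InvalidRecordError
from .extrapolation import corr_two_point, hf_two_point, post_mp2_two_point


class FitTarget(str, Enum):
    HF = "hf"
    MP2_CORR = "mp2"
    POST_MP2 = "postmp2"


#: Conventional starting exponents; each basin was verified against a
#: dense grid search.
_START = {FitTarget.HF: -4.0, FitTarget.MP2_CORR: 3.0, FitTarget.POST_MP2: 3.0}

#: Number of energies one observation carries per target.
_ARITY = {FitTarget.HF: 2, FitTarget.MP2_CORR: 2, FitTarget.POST_MP2: 4}


@dataclass(frozen=True)
class FitObservation:
    """One training point: low-cardinal energies plus a reference value.

    ``energies`` is ``(e_lo, e_hi)`` for the HF and MP2 targets and
    ``(e_ccsdt_lo, e_ccsdt_hi, e_mp2_lo, e_mp2_hi)`` for the post-MP2
    target.  Units must simply be consistent with ``reference``.
    """

    system_id: str
    energies: tuple[float, ...]
    reference: float
    fragment: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", tuple(map(float, self.energies)))
        if not all(math.isfinite(e) for e in self.energies) or not math.isfinite(
            self.reference
        ):
            raise InvalidRecordError(
                f"observation {self.system_id!r} has non-finite values"
            )


@dataclass(frozen=True)
class FitProblem:
    """A single-exponent fitting problem over >= 1 observations."""

    target: FitTarget
    observations: tuple[FitObservation, ...]
    cardinals: tuple[int, int] = (2, 3)
    fixed_beta: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", FitTarget(self.target))
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.observations:
            raise InvalidRecordError("fit problem needs >= 1 observation")
        arity = _ARITY[self.target]
        for obs in self.observations:
            if len(obs.energies) != arity:
                raise InvalidRecordError(
                    f"{self.target.value} observations need {arity} energies, "
                    f"{obs.system_id!r} has {len(obs.energies)}"
                )
        if self.target is FitTarget.POST_MP2:
            if self.fixed_beta is None or not (self.fixed_beta > 0):
                raise InvalidRecordError(
                    "post-MP2 fits require fixed_beta > 0, got "
                    f"{self.fixed_beta!r}"
                )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one exponent fit.

    ``value_rounded`` carries four significant digits, the precision at
    which refit exponents are customarily quoted.  ``rank_deficient`` marks
    problems whose residuals do not depend on the exponent (e.g. already
    converged, constant-energy observations), where any value fits.
    """

    value: float
    value_rounded: float
    rss: float
    n_obs: int
    converged: bool
    rank_deficient: bool = False


def _round_sig(x: float, digits: int = 4) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


def _predictor(problem: FitProblem) -> Callable[[float, FitObservation], float]:
    x_lo, x_hi = problem.cardinals
    if problem.target is FitTarget.HF:
        return lambda a, o: hf_two_point(*o.energies, x_lo, x_hi, a)
    if problem.target is FitTarget.MP2_CORR:
        return lambda b, o: corr_two_point(*o.energies, x_lo, x_hi, b)
    beta = problem.fixed_beta
    return lambda g, o: post_mp2_two_point(
        *o.energies, x_lo, x_hi, beta, g
    )


def fit_exponent(problem: FitProblem) -> FitResult:
    """Minimize the sum of squared extrapolation residuals over one exponent.

    A Levenberg-Marquardt minimizer is run from the conventional starting
    point; convergence is a relative parameter change below 1e-12 within
    200 iterations.  Non-convergence is reported via ``converged=False``
    with the best value still returned.
    """
    predict = _predictor(problem)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = float(x[0])
        return np.array(
            [predict(p, o) - o.reference for o in problem.observations]
        )

    res = least_squares(
        residuals,
        x0=[_START[problem.target]],
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=200 * 3,
    )
    jac_norm = float(np.linalg.norm(res.jac))
    rank_deficient = jac_norm < 1e-8 * math.sqrt(len(problem.observations))
    value = float(res.x[0])
    return FitResult(
        value=value,
        value_rounded=_round_sig(value),
        rss=float(2.0 * res.cost),
        n_obs=len(problem.observations),
        converged=bool(res.success),
        rank_deficient=rank_deficient,
    )


def fit_alpha(problem: FitProblem) -> FitResult:
    """Fit the mean-field exponent alpha (target ``hf``)."""
    if problem.target is not FitTarget.HF:
        raise InvalidRecordError("fit_alpha expects a problem with target 'hf'")
    return fit_exponent(problem)


def fit_beta(problem: FitProblem) -> FitResult:
    """Fit the MP2-correlation exponent beta (target ``mp2``)."""
    if problem.target is not FitTarget.MP2_CORR:
        raise InvalidRecordError("fit_beta expects a problem with target 'mp2'")
    return fit_exponent(problem)


def fit_gamma(problem: FitProblem) -> FitResult:
    """Fit the post-MP2 exponent gamma with beta held fixed
    (target ``postmp2``)."""
    if problem.target is not FitTarget.POST_MP2:
        raise InvalidRecordError(
            "fit_gamma expects a problem with target 'postmp2'"
        )
    return fit_exponent(problem)


# ---------------------------------------------------------------------------
# Training-table IO.  Wide schema, one row per observation:
#   hf/mp2 targets:  system_id[, fragment], e_lo, e_hi, e_ref
#   postmp2 target:  system_id, e_ccsdt_lo, e_ccsdt_hi, e_mp2_lo, e_mp2_hi, e_ref

def read_fit_csv(
    path,
    target: FitTarget | str,
    cardinals: tuple[int, int] = (2, 3),
    fixed_beta: float | None = None,
) -> FitProblem:
    """Load a training table into a :class:`FitProblem`."""
    target = FitTarget(target)
    df = pd.read_csv(path)
    if target is FitTarget.POST_MP2:
        cols = ["e_ccsdt_lo", "e_ccsdt_hi", "e_mp2_lo", "e_mp2_hi"]
    else:
        cols = ["e_lo", "e_hi"]
    missing = {*cols, "system_id", "e_ref"} - set(df.columns)
    if missing:
        raise InvalidRecordError(
            f"fit table is missing columns {sorted(missing)}"
        )
    obs = tuple(
        FitObservation(
            system_id=str(row["system_id"]),
            energies=tuple(float(row[c]) for c in cols),
            reference=float(row["e_ref"]),
            fragment=str(row["fragment"]) if "fragment" in df.columns else None,
        )
        for _, row in df.iterrows()
    )
    return FitProblem(
        target=target, observations=obs, cardinals=cardinals,
        fixed_beta=fixed_beta,
    )
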
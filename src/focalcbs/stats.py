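"""Validation statistics for comparing two interaction-energy vectors.

Agreement between a reference ΔE vector ``x`` and a candidate vector ``y``
is certified with ordinary least squares (slope, intercept, adjusted R²,
residual standard deviation with n-2 degrees of freedom) together with the
mean absolute deviation, root-mean-square deviation and the worst absolute
and relative offenders.  Relative deviations are reported against the
reference vector.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import DegenerateRegressionError, InvalidRecordError


@dataclass(frozen=True)
class DeviationReport:
    """Regression and deviation statistics (kJ/mol unless dimensionless).

    Fields not computed by the producing operation are ``None``.
    ``max_abs_dev`` and ``max_rel_dev`` carry (value, system label) pairs;
    the relative part is a percentage of the reference value.
    """

    n: int
    slope: float | None = None
    intercept: float | None = None
    adj_r2: float | None = None
    resid_sd: float | None = None
    mad: float | None = None
    rmsd: float | None = None
    max_abs_dev: tuple[float, str] | None = None
    max_rel_dev: tuple[float, str] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _columns(xs, ys) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InvalidRecordError("inputs must be 1-d vectors of equal length")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise InvalidRecordError("inputs must be finite")
    return xs, ys


def regress(xs: Sequence[float], ys: Sequence[float]) -> DeviationReport:
    """Ordinary least squares y = slope*x + intercept.

    Requires >= 3 points and non-constant x.  ``adj_r2`` uses the
    two-parameter formula 1 - (1 - R²)(n-1)/(n-2); ``resid_sd`` is
    sqrt(RSS/(n-2)).
    """
    xs, ys = _columns(xs, ys)
    n = xs.size
    if n < 3:
        raise InvalidRecordError(f"regression needs >= 3 points, got {n}")
    if np.ptp(xs) == 0:
        raise DegenerateRegressionError("predictor vector is constant")
    fit = _sps.linregress(xs, ys)
    resid = ys - (fit.slope * xs + fit.intercept)
    rss = float(resid @ resid)
    r2 = fit.rvalue**2
    return DeviationReport(
        n=int(n),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        adj_r2=float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
        resid_sd=float(np.sqrt(rss / (n - 2))),
    )


def deviations(
    xs: Sequence[float],
    ys: Sequence[float],
    ids: Sequence[str] | None = None,
) -> DeviationReport:
    """Deviation statistics of ``ys`` against the reference ``xs``.

    ``mad`` is mean |y - x|, ``rmsd`` the root of the mean squared
    deviation; the worst absolute and relative offenders are returned with
    their labels.  Entries with ``x == 0`` are skipped for the relative
    part; if no entry qualifies, ``max_rel_dev`` is ``None``.
    """
    xs, ys = _columns(xs, ys)
    n = xs.size
    if n == 0:
        raise InvalidRecordError("deviation statistics need >= 1 point")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = [str(s) for s in ids]
    if len(ids) != n:
        raise InvalidRecordError("ids must match the vectors in length")

    diff = np.abs(ys - xs)
    i_abs = int(np.argmax(diff))
    nonzero = xs != 0
    max_rel = None
    if nonzero.any():
        rel = np.where(nonzero, 100.0 * diff / np.abs(np.where(nonzero, xs, 1.0)), -np.inf)
        i_rel = int(np.argmax(rel))
        max_rel = (float(rel[i_rel]), ids[i_rel])
    return DeviationReport(
        n=int(n),
        mad=float(diff.mean()),
        rmsd=float(np.sqrt(np.mean((ys - xs) ** 2))),
        max_abs_dev=(float(diff[i_abs]), ids[i_abs]),
        max_rel_dev=max_rel,
    )


def full_report(
    xs: Sequence[float],
    ys: Sequence[float],
    ids: Sequence[str] | None = None,
) -> DeviationReport:
    """Regression plus deviation statistics in one report."""
    reg = regress(xs, ys)
    dev = deviations(xs, ys, ids)
    return DeviationReport(
        n=reg.n,
        slope=reg.slope,
        intercept=reg.intercept,
        adj_r2=reg.adj_r2,
        resid_sd=reg.resid_sd,
        mad=dev.mad,
        rmsd=dev.rmsd,
        max_abs_dev=dev.max_abs_dev,
        max_rel_dev=dev.max_rel_dev,
    )
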
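"""Bookkeeping over DFT-SAPT interaction-energy decompositions.

DFT-SAPT splits the interaction energy of a dimer into an
electrostatic/polarization component (``e_pol``), first-order exchange
repulsion (``e_exch``), induction (``e_ind``) and dispersion (``e_disp``),
all in kJ/mol.  The dispersion-to-polarization ratio |Edisp|/|Epol| sorts
dimers into electrostatics-dominated, mixed and dispersion-dominated
classes; the default thresholds (0.5, 1.5) cleanly separate the three
groups of the bundled benchmark table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .exceptions import (
    InvalidRecordError,
    UndefinedRatioError,
    ZeroReferenceError,
)

#: (lower, upper) bounds on |Edisp|/|Epol|: below the lower bound a dimer is
#: electrostatics-dominated, above the upper bound dispersion-dominated.
DEFAULT_THRESHOLDS = (0.5, 1.5)

#: Reported totals may disagree with the component sum by accumulated
#: rounding of the printed components; beyond this the record is rejected.
_TOTAL_ROUNDING_GUARD = 0.25


class InteractionClass(str, Enum):
    ELECTROSTATICS_DOMINATED = "electrostatics_dominated"
    MIXED = "mixed"
    DISPERSION_DOMINATED = "dispersion_dominated"


@dataclass(frozen=True)
class SaptDecomposition:
    """One dimer's DFT-SAPT components and reported total (kJ/mol)."""

    system_id: str
    e_pol: float
    e_exch: float
    e_ind: float
    e_disp: float
    e_total: float

    def __post_init__(self) -> None:
        comps = (self.e_pol, self.e_exch, self.e_ind, self.e_disp, self.e_total)
        if not all(math.isfinite(c) for c in comps):
            raise InvalidRecordError(
                f"{self.system_id!r}: non-finite SAPT component"
            )
        if self.e_exch < 0:
            warnings.warn(
                f"{self.system_id!r}: negative exchange component "
                f"({self.e_exch} kJ/mol) is unphysical at equilibrium "
                "separations",
                stacklevel=2,
            )
        resid = self.e_total - (
            self.e_pol + self.e_exch + self.e_ind + self.e_disp
        )
        if abs(resid) > _TOTAL_ROUNDING_GUARD:
            raise InvalidRecordError(
                f"{self.system_id!r}: reported total differs from the "
                f"component sum by {resid:.3f} kJ/mol"
            )


def sapt_total(d: SaptDecomposition) -> float:
    """Exact component sum e_pol + e_exch + e_ind + e_disp (kJ/mol)."""
    return d.e_pol + d.e_exch + d.e_ind + d.e_disp


def disp_pol_ratio(d: SaptDecomposition) -> float:
    """Dispersion-to-polarization ratio |Edisp| / |Epol|.

    Invariant under an overall sign flip of the components.  Undefined
    (raises) for zero polarization.
    """
    if d.e_pol == 0:
        raise UndefinedRatioError(
            f"{d.system_id!r}: dispersion-to-polarization ratio is "
            "undefined for e_pol = 0"
        )
    return abs(d.e_disp) / abs(d.e_pol)


def classify(
    d: SaptDecomposition,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> InteractionClass:
    """Assign the interaction class from the dispersion-to-polarization
    ratio: below ``thresholds[0]`` electrostatics-dominated, above
    ``thresholds[1]`` dispersion-dominated, otherwise mixed."""
    lo, hi = thresholds
    if not (0 < lo < hi):
        raise InvalidRecordError(f"invalid thresholds {thresholds!r}")
    r = disp_pol_ratio(d)
    if r < lo:
        return InteractionClass.ELECTROSTATICS_DOMINATED
    if r > hi:
        return InteractionClass.DISPERSION_DOMINATED
    return InteractionClass.MIXED


def compare_to_supermolecular(
    sapt: SaptDecomposition, de_ref: float
) -> tuple[float, float]:
    """Absolute (kJ/mol) and relative (%) deviation of the SAPT component
    sum from a supermolecular reference interaction energy."""
    abs_dev = abs(sapt_total(sapt) - de_ref)
    if de_ref == 0:
        raise ZeroReferenceError(
            f"{sapt.system_id!r}: relative deviation undefined for a zero "
            "reference"
        )
    return abs_dev, 100.0 * abs_dev / abs(de_ref)


# ---------------------------------------------------------------------------
# CSV schema: system_id, e_pol, e_exch, e_ind, e_disp, e_total
#             [, group_label, ...extra columns pass through]

SAPT_CSV_COLUMNS = ["system_id", "e_pol", "e_exch", "e_ind", "e_disp", "e_total"]


def read_sapt_csv(path) -> list[SaptDecomposition]:
    """Read a SAPT component table (kJ/mol)."""
    df = pd.read_csv(path)
    missing = set(SAPT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidRecordError(f"SAPT CSV is missing columns {sorted(missing)}")
    return [
        SaptDecomposition(
            system_id=str(r.system_id),
            e_pol=float(r.e_pol),
            e_exch=float(r.e_exch),
            e_ind=float(r.e_ind),
            e_disp=float(r.e_disp),
            e_total=float(r.e_total),
        )
        for r in df.itertuples(index=False)
    ]


def write_sapt_csv(
    decomps: Sequence[SaptDecomposition], path, group_labels=None
) -> None:
    df = pd.DataFrame(
        {
            "system_id": [d.system_id for d in decomps],
            "e_pol": [d.e_pol for d in decomps],
            "e_exch": [d.e_exch for d in decomps],
            "e_ind": [d.e_ind for d in decomps],
            "e_disp": [d.e_disp for d in decomps],
            "e_total": [d.e_total for d in decomps],
        }
    )
    if group_labels is not None:
        df["group_label"] = [
            g.value if isinstance(g, InteractionClass) else g
            for g in group_labels
        ]
    df.to_csv(path, index=False)
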
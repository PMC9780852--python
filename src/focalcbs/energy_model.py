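"""Normalized data model for absolute electronic energies and
counterpoise-corrected interaction-energy components.

Absolute energies are stored in hartree, one record per
(system, fragment, method component, basis cardinal number).  Interaction
components are kept in kJ/mol with the convention that a negative value
means attractive (binding) interaction.  The counterpoise correction is
applied by evaluating each monomer in the full dimer basis, so that the
supermolecular difference cancels the basis-set superposition error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import (
    IncompleteDataError,
    InvalidRecordError,
    MismatchedRecordsError,
)

#: 1 hartree in kJ/mol (CODATA-derived).
HARTREE_TO_KJMOL = 2625.499639

#: Basis cardinal number X of the aug-cc-pVXZ series.
CARDINAL_LABELS = {2: "aDZ", 3: "aTZ", 4: "aQZ", 5: "a5Z"}
VALID_CARDINALS = frozenset(CARDINAL_LABELS)


class Fragment(str, Enum):
    """Role of a fragment in the supermolecular calculation."""

    DIMER = "dimer"
    MONOMER_A = "monomer_A"
    MONOMER_B = "monomer_B"


class Component(str, Enum):
    """Method component of the total electronic energy.

    ``HF`` is the mean-field energy; ``MP2_CORR`` and ``CCSDT_CORR`` are the
    MP2 and CCSD(T) correlation energies (total minus HF in the same basis).
    The post-MP2 correction is the difference CCSDT_CORR - MP2_CORR.
    """

    HF = "HF"
    MP2_CORR = "MP2_corr"
    CCSDT_CORR = "CCSDT_corr"


class BasisContext(str, Enum):
    """Whether a monomer was evaluated in the dimer basis (counterpoise) or
    in its own basis."""

    DIMER_BASIS = "dimer_basis"
    OWN_BASIS = "own_basis"


@dataclass(frozen=True)
class EnergyRecord:
    """One absolute electronic energy in hartree."""

    system_id: str
    fragment: Fragment
    component: Component
    cardinal: int
    basis_context: BasisContext
    energy: float
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment", Fragment(self.fragment))
        object.__setattr__(self, "component", Component(self.component))
        object.__setattr__(
            self, "basis_context", BasisContext(self.basis_context)
        )
        if self.cardinal not in VALID_CARDINALS:
            raise InvalidRecordError(
                f"cardinal must be one of {sorted(VALID_CARDINALS)}, "
                f"got {self.cardinal!r}"
            )
        if not math.isfinite(self.energy):
            raise InvalidRecordError(
                f"energy must be finite, got {self.energy!r}"
            )


@dataclass(frozen=True)
class ComponentInteraction:
    """Counterpoise-corrected interaction-energy components (kJ/mol) of one
    system at one basis cardinal number.

    ``de_post_mp2`` is defined as the CCSD(T)-correlation interaction
    component minus the MP2-correlation one; when ``de_ccsdt_corr`` is
    stored the identity is enforced to 1e-9 kJ/mol.
    """

    system_id: str
    cardinal: int
    de_hf: float
    de_mp2_corr: float
    de_post_mp2: float
    de_ccsdt_corr: float | None = None

    def __post_init__(self) -> None:
        if self.cardinal not in VALID_CARDINALS:
            raise InvalidRecordError(f"invalid cardinal {self.cardinal!r}")
        if self.de_ccsdt_corr is not None:
            resid = self.de_post_mp2 - (self.de_ccsdt_corr - self.de_mp2_corr)
            if abs(resid) > 1e-9:
                raise InvalidRecordError(
                    "de_post_mp2 must equal de_ccsdt_corr - de_mp2_corr "
                    f"(residual {resid:.3e} kJ/mol)"
                )

    @property
    def total(self) -> float:
        """CP-corrected CCSD(T) interaction energy at this cardinal."""
        return self.de_hf + self.de_mp2_corr + self.de_post_mp2


def hartree_to_kjmol(e: float) -> float:
    """Convert an energy from hartree to kJ/mol (exactly linear)."""
    if not math.isfinite(e):
        raise InvalidRecordError(f"energy must be finite, got {e!r}")
    return e * HARTREE_TO_KJMOL


def _as_energy(x) -> float:
    return x.energy if isinstance(x, EnergyRecord) else float(x)


def cp_interaction(e_dimer, e_mon_a, e_mon_b) -> float:
    """Counterpoise-corrected supermolecular interaction energy in kJ/mol.

    Accepts plain hartree floats or :class:`EnergyRecord` objects.  With
    records, consistency is enforced: one system, one component, one
    cardinal, and both monomers evaluated in the dimer basis.  Negative
    result means attraction.  Symmetric in the two monomers.
    """
    records = [x for x in (e_dimer, e_mon_a, e_mon_b) if isinstance(x, EnergyRecord)]
    if records:
        if len(records) != 3:
            raise MismatchedRecordsError(
                "mixing EnergyRecord and bare floats is ambiguous; "
                "pass three records or three floats"
            )
        dim, mon_a, mon_b = records
        if dim.fragment is not Fragment.DIMER:
            raise MismatchedRecordsError("first record must be the dimer")
        for mon in (mon_a, mon_b):
            if mon.fragment is Fragment.DIMER:
                raise MismatchedRecordsError("monomer record expected")
            if mon.basis_context is not BasisContext.DIMER_BASIS:
                raise MismatchedRecordsError(
                    "counterpoise correction requires monomers evaluated "
                    "in the dimer basis"
                )
        if len({r.system_id for r in records}) != 1:
            raise MismatchedRecordsError("records span multiple systems")
        if len({r.component for r in records}) != 1:
            raise MismatchedRecordsError("records span multiple components")
        if len({r.cardinal for r in records}) != 1:
            raise MismatchedRecordsError("records span multiple cardinals")
    return hartree_to_kjmol(
        _as_energy(e_dimer) - _as_energy(e_mon_a) - _as_energy(e_mon_b)
    )


def assemble_components(
    records: Iterable[EnergyRecord],
) -> list[ComponentInteraction]:
    """Assemble CP-corrected interaction components for one system.

    For every cardinal present in ``records`` the full 3 fragments x 3
    components grid (monomers in the dimer basis) must exist; a missing
    record raises :class:`IncompleteDataError` naming the absent
    (fragment, component, cardinal) triples.  Returns one
    :class:`ComponentInteraction` per cardinal, sorted by cardinal.
    """
    records = list(records)
    if not records:
        raise IncompleteDataError("<empty>", [])
    system_ids = {r.system_id for r in records}
    if len(system_ids) != 1:
        raise MismatchedRecordsError(
            f"assemble_components expects one system, got {sorted(system_ids)}"
        )
    (system_id,) = system_ids

    index: dict[tuple[Fragment, Component, int], EnergyRecord] = {}
    for r in records:
        if (
            r.fragment is not Fragment.DIMER
            and r.basis_context is not BasisContext.DIMER_BASIS
        ):
            continue  # own-basis monomer energies play no role in CP assembly
        index[(r.fragment, r.component, r.cardinal)] = r

    cardinals = sorted({x for (_, _, x) in index})
    missing = [
        (f, c, x)
        for x in cardinals
        for f in Fragment
        for c in Component
        if (f, c, x) not in index
    ]
    if missing:
        raise IncompleteDataError(system_id, missing)

    out = []
    for x in cardinals:
        parts = {
            c: cp_interaction(
                index[(Fragment.DIMER, c, x)],
                index[(Fragment.MONOMER_A, c, x)],
                index[(Fragment.MONOMER_B, c, x)],
            )
            for c in Component
        }
        out.append(
            ComponentInteraction(
                system_id=system_id,
                cardinal=x,
                de_hf=parts[Component.HF],
                de_mp2_corr=parts[Component.MP2_CORR],
                de_post_mp2=parts[Component.CCSDT_CORR]
                - parts[Component.MP2_CORR],
                de_ccsdt_corr=parts[Component.CCSDT_CORR],
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV schema: system_id, fragment, component, cardinal, basis_context,
#             energy_hartree, provenance  (UTF-8, header required)

ENERGY_CSV_COLUMNS = [
    "system_id",
    "fragment",
    "component",
    "cardinal",
    "basis_context",
    "energy_hartree",
    "provenance",
]


def read_energy_csv(path) -> list[EnergyRecord]:
    """Read an absolute-energy table (see :data:`ENERGY_CSV_COLUMNS`)."""
    df = pd.read_csv(
        path,
        dtype={"provenance": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    required = set(ENERGY_CSV_COLUMNS) - {"provenance"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidRecordError(
            f"energy CSV is missing columns {sorted(missing)}"
        )
    if "provenance" not in df.columns:
        df["provenance"] = ""
    return [
        EnergyRecord(
            system_id=str(row.system_id),
            fragment=Fragment(row.fragment),
            component=Component(row.component),
            cardinal=int(row.cardinal),
            basis_context=BasisContext(row.basis_context),
            energy=float(row.energy_hartree),
            provenance=str(row.provenance),
        )
        for row in df.itertuples(index=False)
    ]


def write_energy_csv(records: Sequence[EnergyRecord], path) -> None:
    """Write energy records using the standard table schema."""
    df = pd.DataFrame(
        {
            "system_id": [r.system_id for r in records],
            "fragment": [r.fragment.value for r in records],
            "component": [r.component.value for r in records],
            "cardinal": [r.cardinal for r in records],
            "basis_context": [r.basis_context.value for r in records],
            "energy_hartree": [repr(r.energy) for r in records],
            "provenance": [r.provenance for r in records],
        }
    )
    df.to_csv(path, index=False)
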
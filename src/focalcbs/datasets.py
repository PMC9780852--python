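"""Loaders for the bundled literature tables.

``dft_sapt_components.csv`` holds published DFT-SAPT/CBS component energies
(kJ/mol) for a curated collection of noncovalent complexes: the 18-dimer
"Set3x6" suite (six complexes in each of the electrostatics-dominated,
mixed and dispersion-dominated classes), seven stacked furan-toluene
configurations, two miscellaneous dimers and five large complexes (PHB
chain-pair models and L7 members).  ``de_ref`` is the best supermolecular
estimate of the interaction energy for each row.  For the large complexes
with two published component sets, the first-listed values are kept.

``cbs_limit_summary.csv`` holds the published magnitudes (negatives of the
interaction energies, kJ/mol) of the CBS-extrapolated results for the five
large complexes under three methods: the cheap fitted (aDZ, aTZ) scheme,
the (aTZ, aQZ) focal-point scheme, and SAPT-DFT.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sapt import SaptDecomposition


def _read(name: str) -> pd.DataFrame:
    with resources.files("focalcbs.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_sapt_reference() -> pd.DataFrame:
    """The DFT-SAPT component table as a DataFrame (kJ/mol)."""
    return _read("dft_sapt_components.csv")


def load_sapt_decompositions(subset: str | None = None) -> list[SaptDecomposition]:
    """The DFT-SAPT table as :class:`SaptDecomposition` objects.

    ``subset`` filters on the ``subset`` column
    (set3x6 / furan_toluene / misc / large).
    """
    df = load_sapt_reference()
    if subset is not None:
        df = df[df["subset"] == subset]
    return [
        SaptDecomposition(
            system_id=r.system_id,
            e_pol=r.e_pol,
            e_exch=r.e_exch,
            e_ind=r.e_ind,
            e_disp=r.e_disp,
            e_total=r.e_total,
        )
        for r in df.itertuples(index=False)
    ]


def load_cbs_summary() -> pd.DataFrame:
    """Published CBS-limit magnitudes for the five large complexes."""
    return _read("cbs_limit_summary.csv")
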
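"""Composite (focal-point) interaction-energy schemes.

A focal-point estimate composes the CCSD(T)/CBS interaction energy from
components converged at different basis levels: the cheap, fast-converging
mean-field part from the largest affordable basis, and the expensive
post-MP2 correction from a small one.  Four schemes are provided:

``A5Z_FOCAL``
    HF and MP2-correlation components taken directly at quintuple-zeta,
    the post-MP2 correction at triple-zeta; no extrapolation.  This is the
    canonical reference composition.
``ATZ_AQZ_FOCAL``
    HF at quadruple-zeta unextrapolated; the MP2-correlation and post-MP2
    components extrapolated aTZ->aQZ with the standard cubic two-point rule.
``ADZ_ATZ_FIT``
    All three components extrapolated from the cheap (aDZ, aTZ) pair using
    refit exponents (alpha, beta, gamma); the package default parameters
    are :data:`focalcbs.extrapolation.REFIT_ADZ_ATZ`.
``THREE_POINT``
    Cross-check scheme: each fragment's components extrapolated with the
    mixed Gaussian/exponential three-point form over three consecutive
    cardinals, then combined by counterpoise.

All composition happens on counterpoise-corrected interaction components in
kJ/mol; by linearity this is identical to composing absolute energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .energy_model import (
    Component,
    ComponentInteraction,
    EnergyRecord,
    Fragment,
    assemble_components,
    hartree_to_kjmol,
)
from .exceptions import IncompleteDataError, MismatchedRecordsError
from .extrapolation import (
    CUBIC_BETA,
    ExtrapolationParams,
    REFIT_ADZ_ATZ,
    corr_two_point,
    hf_two_point,
    mixed_three_point,
    post_mp2_two_point,
)


class Scheme(str, Enum):
    A5Z_FOCAL = "a5z-focal"
    ATZ_AQZ_FOCAL = "atz-aqz-focal"
    ADZ_ATZ_FIT = "adz-atz-fit"
    THREE_POINT = "three-point"


@dataclass(frozen=True)
class CompositeResult:
    """One composite interaction energy and its three parts (kJ/mol)."""

    system_id: str
    scheme: Scheme
    de_total: float
    de_hf_part: float
    de_mp2_part: float
    de_post_mp2_part: float

    def __post_init__(self) -> None:
        parts = self.de_hf_part + self.de_mp2_part + self.de_post_mp2_part
        if abs(self.de_total - parts) > 1e-9:
            raise MismatchedRecordsError(
                "composite total differs from the sum of its parts by "
                f"{self.de_total - parts:.3e} kJ/mol"
            )


def _by_cardinal(
    components: Iterable[ComponentInteraction], needed: tuple[int, ...]
) -> dict[int, ComponentInteraction]:
    comps = list(components)
    ids = {c.system_id for c in comps}
    if len(ids) != 1:
        raise MismatchedRecordsError(
            f"composite schemes act on one system, got {sorted(ids)}"
        )
    (system_id,) = ids
    table = {c.cardinal: c for c in comps}
    missing = [x for x in needed if x not in table]
    if missing:
        raise IncompleteDataError(
            system_id, [("*", "*", x) for x in missing]
        )
    return table


def compose_a5z_focal(
    components: Iterable[ComponentInteraction],
) -> CompositeResult:
    """Reference composition: HF and MP2 correlation at cardinal 5, post-MP2
    correction at cardinal 3, no extrapolation."""
    table = _by_cardinal(components, (3, 5))
    hf = table[5].de_hf
    mp2 = table[5].de_mp2_corr
    post = table[3].de_post_mp2
    return CompositeResult(
        system_id=table[5].system_id,
        scheme=Scheme.A5Z_FOCAL,
        de_total=hf + mp2 + post,
        de_hf_part=hf,
        de_mp2_part=mp2,
        de_post_mp2_part=post,
    )


def compose_atz_aqz_focal(
    components: Iterable[ComponentInteraction],
) -> CompositeResult:
    """Focal-point composition from the (aTZ, aQZ) pair: HF at cardinal 4
    unextrapolated (near-converged at quadruple-zeta), correlation parts
    extrapolated with the cubic two-point rule."""
    table = _by_cardinal(components, (3, 4))
    lo, hi = table[3], table[4]
    hf = hi.de_hf
    mp2 = corr_two_point(lo.de_mp2_corr, hi.de_mp2_corr, 3, 4, CUBIC_BETA)
    post = corr_two_point(lo.de_post_mp2, hi.de_post_mp2, 3, 4, CUBIC_BETA)
    return CompositeResult(
        system_id=hi.system_id,
        scheme=Scheme.ATZ_AQZ_FOCAL,
        de_total=hf + mp2 + post,
        de_hf_part=hf,
        de_mp2_part=mp2,
        de_post_mp2_part=post,
    )


def compose_fitted_adz_atz(
    components: Iterable[ComponentInteraction],
    params: ExtrapolationParams = REFIT_ADZ_ATZ,
) -> CompositeResult:
    """Cheap composition from the (aDZ, aTZ) pair with refit exponents.

    The HF part uses the exponential-in-sqrt(X) model with ``params.alpha``,
    the MP2-correlation part the power law with ``params.beta``, and the
    post-MP2 part the two-exponent difference (``gamma`` for the
    CCSD(T)-correlation pair, ``beta`` for the MP2 pair).  The CCSD(T)
    correlation components must therefore be stored on the inputs.
    """
    table = _by_cardinal(components, (2, 3))
    lo, hi = table[2], table[3]
    if lo.de_ccsdt_corr is None or hi.de_ccsdt_corr is None:
        raise IncompleteDataError(
            lo.system_id, [("*", Component.CCSDT_CORR, x) for x in (2, 3)]
        )
    hf = hf_two_point(lo.de_hf, hi.de_hf, 2, 3, params.alpha)
    mp2 = corr_two_point(lo.de_mp2_corr, hi.de_mp2_corr, 2, 3, params.beta)
    post = post_mp2_two_point(
        lo.de_ccsdt_corr,
        hi.de_ccsdt_corr,
        lo.de_mp2_corr,
        hi.de_mp2_corr,
        2,
        3,
        params.beta,
        params.gamma,
    )
    return CompositeResult(
        system_id=hi.system_id,
        scheme=Scheme.ADZ_ATZ_FIT,
        de_total=hf + mp2 + post,
        de_hf_part=hf,
        de_mp2_part=mp2,
        de_post_mp2_part=post,
    )


def compose_three_point(
    records: Iterable[EnergyRecord], x_start: int = 3
) -> CompositeResult:
    """Cross-check composition: mixed Gaussian/exponential three-point
    extrapolation applied per fragment and component over cardinals
    ``x_start .. x_start+2``, then combined by counterpoise.

    Because the three-point solve is linear in the input energies,
    extrapolating components separately and summing equals extrapolating
    the total fragment energies.
    """
    records = list(records)
    comps = assemble_components(records)
    _by_cardinal(comps, tuple(range(x_start, x_start + 3)))  # completeness
    system_id = comps[0].system_id

    index = {(r.fragment, r.component, r.cardinal): r.energy for r in records
             if r.fragment is Fragment.DIMER or r.basis_context.value == "dimer_basis"}

    def cbs_part(component: Component) -> float:
        limits = {}
        for frag in Fragment:
            es = [index[(frag, component, x)]
                  for x in range(x_start, x_start + 3)]
            limits[frag] = mixed_three_point(*es, x_start=x_start).e_cbs
        return hartree_to_kjmol(
            limits[Fragment.DIMER]
            - limits[Fragment.MONOMER_A]
            - limits[Fragment.MONOMER_B]
        )

    hf = cbs_part(Component.HF)
    mp2 = cbs_part(Component.MP2_CORR)
    post = cbs_part(Component.CCSDT_CORR) - mp2
    return CompositeResult(
        system_id=system_id,
        scheme=Scheme.THREE_POINT,
        de_total=hf + mp2 + post,
        de_hf_part=hf,
        de_mp2_part=mp2,
        de_post_mp2_part=post,
    )


def compose(
    components: Sequence[ComponentInteraction],
    scheme: Scheme | str,
    params: ExtrapolationParams = REFIT_ADZ_ATZ,
) -> CompositeResult:
    """Dispatch on scheme name (three-point excluded: it needs records)."""
    scheme = Scheme(scheme)
    if scheme is Scheme.A5Z_FOCAL:
        return compose_a5z_focal(components)
    if scheme is Scheme.ATZ_AQZ_FOCAL:
        return compose_atz_aqz_focal(components)
    if scheme is Scheme.ADZ_ATZ_FIT:
        return compose_fitted_adz_atz(components, params)
    raise MismatchedRecordsError(
        "the three-point scheme needs absolute-energy records; "
        "call compose_three_point directly"
    )
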
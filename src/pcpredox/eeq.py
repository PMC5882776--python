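"""Stoichiometric electron-equivalent (eeq) balance.

Anaerobic respiration routes electrons from a donor (here lactate) to
whichever terminal electron acceptors are available.  Per mole of acceptor
reduced, the half-reactions transfer

* Fe(III) -> Fe(II):              1 eeq
* NO3- -> N2 (denitrification):   5 eeq
* SO4^2- -> S^2- :                8 eeq
* R-Cl -> R-H (dechlorination):   2 eeq per chlorine removed

while complete oxidation of lactate to CO2 donates 12 eeq per mole.  The
ledger compares electron equivalents added with the donor against those
consumed by each reducing pathway, in mmol per microcosm.

Two accounting modes exist for dechlorination: ``"per_chlorine"``
(default) charges 2 eeq for every C-Cl bond reduced, summed over the whole
congener distribution; ``"per_molecule"`` charges a flat 2 eeq per mole of
the head compound transformed, regardless of how many chlorines were
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from pcpredox.congeners import Congener, parse_name
from pcpredox.errors import InvalidParameterError, MassBalanceError

__all__ = [
    "EeqCoefficients",
    "EeqLedger",
    "eeq_added",
    "pathway_eeq",
    "dechlorination_eeq",
    "build_ledger",
]

PATHWAYS = ("fe3", "no3", "so4", "dechlorination")


@dataclass(frozen=True)
class EeqCoefficients:
    """Electron equivalents per mole for each half-reaction."""

    fe3: int = 1
    no3: int = 5
    so4: int = 8
    per_chlorine_removed: int = 2
    lactate_donor: int = 12

    def __post_init__(self) -> None:
        for name in ("fe3", "no3", "so4", "per_chlorine_removed", "lactate_donor"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise InvalidParameterError(
                    f"eeq coefficient {name} must be a positive integer, got {v!r}"
                )


DEFAULT_COEFFICIENTS = EeqCoefficients()


def eeq_added(
    donor_mM: float,
    volume_L: float,
    coeff: EeqCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Electron equivalents added with the donor, in mmol.

    ``donor_mM * volume_L`` mmol of lactate times the donor equivalence
    (12 eeq/mol for complete oxidation to CO2).  The standard microcosm
    (20 mM lactate in 0.015 L) adds 3.60 mmol eeq.
    """
    if donor_mM < 0 or volume_L <= 0:
        raise InvalidParameterError(
            "donor_mM must be >= 0 and volume_L > 0"
        )
    return donor_mM * volume_L * coeff.lactate_donor


def pathway_eeq(
    moles_reduced_mmol: float,
    pathway: str,
    coeff: EeqCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Electron equivalents consumed by an inorganic reducing pathway (mmol).

    ``pathway`` is one of ``"fe3"``, ``"no3"``, ``"so4"``.
    """
    if moles_reduced_mmol < 0:
        raise InvalidParameterError("moles_reduced_mmol must be >= 0")
    if pathway not in ("fe3", "no3", "so4"):
        raise InvalidParameterError(
            f"unknown pathway {pathway!r}; expected fe3, no3 or so4"
        )
    return moles_reduced_mmol * getattr(coeff, pathway)


def _as_congener(key) -> Congener:
    if isinstance(key, Congener):
        return key
    return Congener(parse_name(key))


def _total_cl_mmol(profile: Mapping) -> tuple[float, float]:
    """(total chlorine mmol, total phenol-skeleton mmol) of a profile."""
    cl = 0.0
    skel = 0.0
    for key, mmol in profile.items():
        if mmol < 0:
            raise InvalidParameterError("congener amounts must be >= 0")
        cong = _as_congener(key)
        cl += cong.n_chlorines * mmol
        skel += mmol
    return cl, skel


def dechlorination_eeq(
    initial_profile: Mapping,
    final_profile: Mapping,
    coeff: EeqCoefficients = DEFAULT_COEFFICIENTS,
    *,
    mode: str = "per_chlorine",
    skeleton_tolerance: float = 1e-6,
) -> float:
    """Electron equivalents consumed by reductive dechlorination (mmol).

    Profiles map congener (name or :class:`Congener`) to mmol.  The phenol
    skeleton is conserved by dechlorination, so the total moles of the two
    profiles must agree within ``skeleton_tolerance`` (relative).

    ``mode="per_chlorine"`` (default): eeq = (Cl atoms removed) * 2.
    ``mode="per_molecule"``: eeq = (mmol of the fully chlorinated head
    compound transformed) * 2, a literal per-mol-acceptor reading.
    """
    cl0, skel0 = _total_cl_mmol(initial_profile)
    cl1, skel1 = _total_cl_mmol(final_profile)
    scale = max(skel0, skel1, 1e-30)
    if abs(skel0 - skel1) > skeleton_tolerance * scale:
        raise MassBalanceError(
            f"phenol-skeleton moles not conserved: {skel0:g} -> {skel1:g} mmol"
        )
    if mode == "per_chlorine":
        removed = cl0 - cl1
        if removed < -skeleton_tolerance * max(cl0, 1e-30):
            raise MassBalanceError(
                "final profile carries more chlorine than initial"
            )
        return max(removed, 0.0) * coeff.per_chlorine_removed
    if mode == "per_molecule":
        head0 = sum(
            mmol for key, mmol in initial_profile.items()
            if _as_congener(key).n_chlorines == 5
        )
        head1 = sum(
            mmol for key, mmol in final_profile.items()
            if _as_congener(key).n_chlorines == 5
        )
        return max(head0 - head1, 0.0) * coeff.per_chlorine_removed
    raise InvalidParameterError(
        f"unknown accounting mode {mode!r}; expected per_chlorine or per_molecule"
    )


@dataclass(frozen=True)
class EeqLedger:
    """Per-treatment electron-equivalent budget (all values mmol eeq)."""

    treatment_id: str
    added_mmol: float
    consumed: dict = field(default_factory=dict)

    @property
    def total_consumed_mmol(self) -> float:
        return sum(self.consumed.values())

    def fraction(self, pathway: str) -> float:
        """Fraction of added eeq consumed by one pathway."""
        if pathway not in self.consumed:
            raise InvalidParameterError(f"unknown pathway {pathway!r}")
        if self.added_mmol == 0:
            raise InvalidParameterError("no eeq added; fraction undefined")
        return self.consumed[pathway] / self.added_mmol


def build_ledger(
    treatment_id: str,
    added_mmol: float,
    per_pathway: Mapping[str, float],
) -> EeqLedger:
    """Assemble a ledger from per-pathway consumptions.

    ``per_pathway`` maps pathway name (``fe3``, ``no3``, ``so4``,
    ``dechlorination``) to mmol eeq consumed.  The total is the exact sum
    of the entries.
    """
    if added_mmol < 0:
        raise InvalidParameterError("added_mmol must be >= 0")
    consumed = {}
    for pathway in PATHWAYS:
        v = float(per_pathway.get(pathway, 0.0))
        if v < 0:
            raise InvalidParameterError(
                f"consumed eeq for {pathway} must be >= 0, got {v}"
            )
        consumed[pathway] = v
    unknown = set(per_pathway) - set(PATHWAYS)
    if unknown:
        raise InvalidParameterError(f"unknown pathways: {sorted(unknown)}")
    return EeqLedger(treatment_id, float(added_mmol), consumed)
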
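"""Unit-safe isotope composition handling.

Isotope compositions arrive from the lab either in delta notation (‰ versus an
international standard) or directly as atom percent.  Internally everything is
an *atom fraction* in [0, 1]: the heavy-isotope share of the element's atoms.
Atom percent and per-mil exist only at I/O boundaries, because the downstream
mass-balance equations (tracer µg = APE x content x biomass x 1e6) are only
dimensionally coherent when enrichment and element content are plain fractions.

Conversions::

    R = R_std * (1 + delta / 1000)      # isotope ratio from delta
    atom_fraction = R / (1 + R)
    delta = (R / R_std - 1) * 1000,  R = af / (1 - af)

Atom percent excess (APE) is the difference between a labelled sample's atom
fraction and the matching unlabelled-control atom fraction.  Negative APE is
retained (clipping would bias means upward) and flagged for downstream logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Element(str, Enum):
    """Tracer element: 13-carbon or 15-nitrogen."""

    C13 = "13C"
    N15 = "15N"


@dataclass(frozen=True)
class IsotopeStandard:
    """An international reference standard for one element.

    ``reference_ratio`` is the heavy/light isotope ratio of the standard
    (dimensionless, > 0).
    """

    element: Element
    name: str
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.reference_ratio <= 0:
            raise InvalidCompositionError(
                f"reference ratio must be positive, got {self.reference_ratio}"
            )


# 13C/12C of Vienna Pee Dee Belemnite; the conventional IRMS calibration value.
VPDB = IsotopeStandard(Element.C13, "VPDB", 0.0111802)
# 15N/14N of atmospheric N2 (AIR), the nitrogen delta-scale anchor.
AIR = IsotopeStandard(Element.N15, "AIR", 0.0036765)

STANDARDS: dict[Element, IsotopeStandard] = {Element.C13: VPDB, Element.N15: AIR}


class InvalidCompositionError(ValueError):
    """A delta or atom fraction outside its physically meaningful range."""


class PairingError(ValueError):
    """Labelled/control compositions that cannot be compared."""


class EnrichmentFlag(str, Enum):
    OK = "ok"
    BELOW_ZERO = "below_zero"
    BELOW_DETECTION = "below_detection"


@dataclass(frozen=True)
class IsotopeComposition:
    """One isotope measurement, stored as an atom fraction in [0, 1].

    ``source_notation`` records how the value arrived ("delta_permil" or
    "atom_percent"); ``analytical_sd_permil`` is the instrument precision in
    delta notation when known.
    """

    element: Element
    atom_fraction: float
    source_notation: Optional[str] = None
    analytical_sd_permil: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_fraction <= 1.0:
            raise InvalidCompositionError(
                f"atom fraction must lie in [0, 1], got {self.atom_fraction}"
            )

    @classmethod
    def from_delta(
        cls,
        element: Element,
        delta_permil: float,
        analytical_sd_permil: Optional[float] = None,
    ) -> "IsotopeComposition":
        af = delta_to_atom_fraction(delta_permil, STANDARDS[element])
        return cls(element, af, "delta_permil", analytical_sd_permil)

    @classmethod
    def from_atom_percent(
        cls,
        element: Element,
        atom_percent: float,
        analytical_sd_permil: Optional[float] = None,
    ) -> "IsotopeComposition":
        return cls(element, atom_percent / 100.0, "atom_percent", analytical_sd_permil)

    @property
    def atom_percent(self) -> float:
        return 100.0 * self.atom_fraction

    @property
    def delta_permil(self) -> float:
        return atom_fraction_to_delta(self.atom_fraction, STANDARDS[self.element])


@dataclass(frozen=True)
class EnrichmentRecord:
    """Atom-fraction excess of a labelled sample over its control baseline."""

    element: Element
    ape: float
    flag: EnrichmentFlag = EnrichmentFlag.OK

    @property
    def ape_atom_percent(self) -> float:
        return 100.0 * self.ape


def delta_to_atom_fraction(delta_permil: float, standard: IsotopeStandard) -> float:
    """Convert delta notation (‰) to atom fraction via the standard's ratio.

    Strictly increasing in delta; delta = −1000‰ maps to atom fraction 0.
    """
    if not math.isfinite(delta_permil):
        raise InvalidCompositionError(f"delta must be finite, got {delta_permil}")
    if delta_permil < -1000.0:
        raise InvalidCompositionError(
            f"delta below -1000 permil implies a negative isotope ratio: {delta_permil}"
        )
    ratio = standard.reference_ratio * (1.0 + delta_permil / 1000.0)
    return ratio / (1.0 + ratio)


def atom_fraction_to_delta(atom_fraction: float, standard: IsotopeStandard) -> float:
    """Exact inverse of :func:`delta_to_atom_fraction` (requires af < 1)."""
    if not 0.0 <= atom_fraction < 1.0:
        raise InvalidCompositionError(
            f"atom fraction must lie in [0, 1) for delta conversion, got {atom_fraction}"
        )
    ratio = atom_fraction / (1.0 - atom_fraction)
    return (ratio / standard.reference_ratio - 1.0) * 1000.0


def atom_percent_excess(
    labelled: IsotopeComposition, control: IsotopeComposition
) -> EnrichmentRecord:
    """Enrichment of a labelled sample over the pooled control baseline.

    The excess is the plain difference of atom fractions.  Negative excess
    (labelled below control, possible under measurement noise) is retained and
    flagged ``below_zero``; significance is decided downstream.
    """
    if labelled.element is not control.element:
        raise PairingError(
            f"cannot compare {labelled.element.value} against {control.element.value}"
        )
    ape = labelled.atom_fraction - control.atom_fraction
    flag = EnrichmentFlag.BELOW_ZERO if ape < 0 else EnrichmentFlag.OK
    return EnrichmentRecord(labelled.element, ape, flag)


def delta_sd_to_atom_fraction_sd(
    sd_permil: float, standard: IsotopeStandard, at_atom_fraction: float
) -> float:
    """Propagate an analytical sd stated in ‰ to atom-fraction units.

    Uses the local derivative of the delta→atom-fraction map at the operating
    composition (e.g. the control baseline), d(af)/dδ = R_std / (1000 (1+R)²).
    """
    if sd_permil < 0:
        raise InvalidCompositionError(f"sd must be non-negative, got {sd_permil}")
    if not 0.0 <= at_atom_fraction < 1.0:
        raise InvalidCompositionError(
            f"operating atom fraction must lie in [0, 1), got {at_atom_fraction}"
        )
    ratio = at_atom_fraction / (1.0 - at_atom_fraction)
    return standard.reference_ratio * (sd_permil / 1000.0) / (1.0 + ratio) ** 2
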
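"""Drug–polymer miscibility screening.

Two complementary screens, both evaluated from tabulated constants alone:

* the Hansen solubility-parameter difference
  ``Δδ = |δ_drug − δ_polymer|`` (MPa^1/2), with the widely used rule of thumb
  that Δδ < 7 MPa^1/2 predicts miscibility and Δδ > 10 MPa^1/2 immiscibility;
* the Flory–Huggins interaction parameter estimated from Δδ,

      χ = V_d · (Δδ)² / (R·T),

  where V_d is the drug's molar volume, R the gas constant and T the absolute
  temperature. χ ≤ 0.5 is read as favourable mixing; χ > 0.5 as limited
  miscibility with a tendency toward phase separation.

Unit note: V_d is held in cm³/mol and Δδ in MPa^1/2. The conversion factors
(1e-6 m³/cm³ for the volume, 1e6 Pa/MPa for the squared parameter difference)
cancel exactly, so χ is computed in base SI units but is numerically equal to
the naive product of the tabulated numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DomainError, ValidationError
from .materials import MaterialRecord

__all__ = [
    "GAS_CONSTANT",
    "MiscibilityAssessment",
    "delta_delta",
    "flory_huggins_chi",
    "classify_delta",
    "classify_chi",
    "assess_pair",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: Hansen-difference thresholds, MPa^1/2
DELTA_MISCIBLE_BELOW = 7.0
DELTA_IMMISCIBLE_ABOVE = 10.0

#: Flory–Huggins threshold above which miscibility is considered limited
CHI_LIMITED_ABOVE = 0.5

DeltaClass = Literal["miscible", "partially_miscible", "immiscible"]
ChiClass = Literal["favourable", "limited"]


@dataclass(frozen=True)
class MiscibilityAssessment:
    """Both screens for one drug–polymer pair (one row of a screening table)."""

    drug: str
    polymer: str
    delta_delta: float
    chi: float
    temperature: float  # K
    delta_class: DeltaClass
    chi_class: ChiClass


def delta_delta(drug: MaterialRecord, polymer: MaterialRecord) -> float:
    """Absolute difference of total solubility parameters, MPa^1/2."""
    return abs(drug.delta - polymer.delta)


def flory_huggins_chi(
    drug: MaterialRecord, polymer: MaterialRecord, temperature: float = 298.0
) -> float:
    """Flory–Huggins interaction parameter at ``temperature`` (K).

    Dimensionless; zero exactly when the two solubility parameters coincide.
    """
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    if drug.molar_mass is None:
        raise ValidationError(
            f"{drug.name}: molar_mass is required to compute the "
            "Flory-Huggins interaction parameter"
        )
    vd_m3 = drug.molar_volume * 1e-6  # cm^3/mol -> m^3/mol
    d_delta_sq_pa = (delta_delta(drug, polymer) ** 2) * 1e6  # MPa -> Pa = J/m^3
    return vd_m3 * d_delta_sq_pa / (GAS_CONSTANT * temperature)


def classify_delta(dd: float) -> DeltaClass:
    """Classify a Hansen-difference value against the 7 / 10 MPa^1/2 thresholds.

    Values falling exactly on a threshold are classed ``partially_miscible``
    (the literature rule is stated with strict inequalities).
    """
    if dd < 0:
        raise DomainError(f"delta_delta must be >= 0, got {dd}")
    if dd < DELTA_MISCIBLE_BELOW:
        return "miscible"
    if dd > DELTA_IMMISCIBLE_ABOVE:
        return "immiscible"
    return "partially_miscible"


def classify_chi(chi: float) -> ChiClass:
    """Classify χ against the 0.5 threshold; exactly 0.5 counts as favourable."""
    if chi < 0:
        raise DomainError(f"chi must be >= 0, got {chi}")
    return "limited" if chi > CHI_LIMITED_ABOVE else "favourable"


def assess_pair(
    drug: MaterialRecord, polymer: MaterialRecord, temperature: float = 298.0
) -> MiscibilityAssessment:
    """Run both screens for one pair and bundle the classified result."""
    dd = delta_delta(drug, polymer)
    chi = flory_huggins_chi(drug, polymer, temperature)
    return MiscibilityAssessment(
        drug=drug.name,
        polymer=polymer.name,
        delta_delta=dd,
        chi=chi,
        temperature=temperature,
        delta_class=classify_delta(dd),
        chi_class=classify_chi(chi),
    )
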
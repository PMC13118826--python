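"""Powder flow metrics and tablet acceptance checks.

Carr's (compressibility) index, CI = (ρ_tapped − ρ_bulk)/ρ_tapped × 100,
summarizes how much a powder consolidates on tapping; USP <1174> maps CI to
seven flow-character classes. The quoted USP band edges leave small gaps
(e.g. 10–11%); here the bands are implemented as contiguous half-open
intervals so every CI in [0, 100) receives exactly one class:

    <=10 excellent | (10,15] good | (15,20] fair | (20,25] passable
    | (25,31] poor | (31,37] very_poor | >37 extremely_poor

Tablet batch acceptance applies the immediate-release targets used when the
compression force was set: friability strictly below 0.5%, disintegration
strictly under 60 s, and drug content within 90–110% of label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DomainError, ValidationError

__all__ = [
    "PowderDensities",
    "TabletBatchQC",
    "TabletAcceptanceReport",
    "carrs_index",
    "classify_flow",
    "tablet_acceptance",
]

FlowClass = Literal[
    "excellent", "good", "fair", "passable", "poor", "very_poor", "extremely_poor"
]

#: (upper CI bound inclusive, class); scanned in order, last band open-ended
_FLOW_BANDS: tuple[tuple[float, FlowClass], ...] = (
    (10.0, "excellent"),
    (15.0, "good"),
    (20.0, "fair"),
    (25.0, "passable"),
    (31.0, "poor"),
    (37.0, "very_poor"),
)

FRIABILITY_LIMIT_PCT = 0.5
DISINTEGRATION_LIMIT_S = 60.0
CONTENT_RANGE_PCT = (90.0, 110.0)


@dataclass(frozen=True)
class PowderDensities:
    """Bulk and tapped density of one granule batch, g/mL."""

    bulk_density: float
    tapped_density: float

    def __post_init__(self) -> None:
        if self.bulk_density <= 0:
            raise DomainError(f"bulk_density must be > 0, got {self.bulk_density}")
        if self.tapped_density < self.bulk_density:
            raise ValidationError(
                f"tapped density {self.tapped_density} below bulk density "
                f"{self.bulk_density}: tapping cannot decrease packing density"
            )


@dataclass(frozen=True)
class TabletBatchQC:
    """Summary quality attributes of one tablet batch."""

    mean_weight_mg: float
    hardness_kp: float
    friability_pct: float
    disintegration_s: float
    content_pct: float
    weight_sd_mg: float = 0.0
    hardness_sd_kp: float = 0.0
    disintegration_sd_s: float = 0.0

    def __post_init__(self) -> None:
        for fname in (
            "mean_weight_mg",
            "hardness_kp",
            "friability_pct",
            "disintegration_s",
            "content_pct",
            "weight_sd_mg",
            "hardness_sd_kp",
            "disintegration_sd_s",
        ):
            if getattr(self, fname) < 0:
                raise DomainError(f"{fname} must be >= 0")


@dataclass(frozen=True)
class TabletAcceptanceReport:
    """Per-criterion booleans for one batch."""

    friability_pass: bool
    disintegration_pass: bool
    content_pass: bool

    @property
    def all_pass(self) -> bool:
        return self.friability_pass and self.disintegration_pass and self.content_pass


def carrs_index(densities: PowderDensities) -> float:
    """Carr's compressibility index, percent. Scale-invariant in the densities."""
    return (
        (densities.tapped_density - densities.bulk_density)
        / densities.tapped_density
        * 100.0
    )


def classify_flow(ci: float) -> FlowClass:
    """USP <1174> flow character for a Carr's index value."""
    if ci < 0:
        raise DomainError(f"Carr's index must be >= 0, got {ci}")
    for upper, label in _FLOW_BANDS:
        if ci <= upper:
            return label
    return "extremely_poor"


def tablet_acceptance(qc: TabletBatchQC) -> TabletAcceptanceReport:
    """Immediate-release acceptance: friability < 0.5%, disintegration < 60 s,
    content within 90–110% of label (boundaries: limits are strict for the
    first two, inclusive for the content range)."""
    lo, hi = CONTENT_RANGE_PCT
    return TabletAcceptanceReport(
        friability_pass=qc.friability_pct < FRIABILITY_LIMIT_PCT,
        disintegration_pass=qc.disintegration_s < DISINTEGRATION_LIMIT_S,
        content_pass=lo <= qc.content_pct <= hi,
    )
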
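"""Material thermophysical records and Hansen solubility-parameter algebra.

A :class:`MaterialRecord` carries the constants every downstream stage needs:
the (total or component-wise) Hansen solubility parameter delta in MPa^1/2,
the amorphous true density in g/cm^3, the glass-transition temperature on a
declared scale, and — for the drug — the molar mass used to form the molar
volume entering the Flory–Huggins interaction parameter.

Temperature-scale handling is centralized here: a record declares whether its
Tg is Celsius or Kelvin, and conversion helpers are the single point of truth
so downstream modules never guess the scale.

The bundled library ships the constants for the glibenclamide (GLB) system
and its three candidate carriers: PVP K25, PVP VA64 and Soluplus (SOL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import pandas as pd

from .errors import DomainError, NotFoundError, ValidationError

__all__ = [
    "MaterialRecord",
    "ParameterLibrary",
    "total_solubility_parameter",
    "molar_volume",
    "load_material_library",
    "read_materials_table",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: tolerance for agreement between a declared total delta and the one
#: recomputed from the Hansen components (MPa^1/2)
DELTA_CONSISTENCY_TOL = 0.05

ABSOLUTE_ZERO_C = -273.15

TgScale = Literal["C", "K"]


def celsius_to_kelvin(t: float) -> float:
    return t - ABSOLUTE_ZERO_C


def kelvin_to_celsius(t: float) -> float:
    return t + ABSOLUTE_ZERO_C


def total_solubility_parameter(
    delta_d: float, delta_p: float, delta_h: float
) -> float:
    """Total Hansen solubility parameter from its three contributions.

    delta_t = sqrt(delta_d^2 + delta_p^2 + delta_h^2), all in MPa^1/2.
    The dispersion, polar and hydrogen-bonding contributions add in
    quadrature because each is the square root of a cohesive energy density.
    """
    for name, v in (("delta_d", delta_d), ("delta_p", delta_p), ("delta_h", delta_h)):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    return math.sqrt(delta_d**2 + delta_p**2 + delta_h**2)


def molar_volume(molar_mass: float, true_density: float) -> float:
    """Molar volume in cm^3/mol from molar mass (g/mol) and density (g/cm^3)."""
    if molar_mass <= 0:
        raise DomainError(f"molar_mass must be > 0, got {molar_mass}")
    if true_density <= 0:
        raise DomainError(f"true_density must be > 0, got {true_density}")
    return molar_mass / true_density


@dataclass(frozen=True)
class MaterialRecord:
    """One substance's thermophysical constants.

    Parameters
    ----------
    name : identifier used for library lookup and reporting.
    role : ``"drug"`` or ``"polymer"``.
    delta_total : total solubility parameter, MPa^1/2. May be omitted when
        the full component triple is given.
    delta_d, delta_p, delta_h : Hansen components, MPa^1/2 (all three or none).
    true_density : amorphous true density, g/cm^3.
    tg : glass-transition temperature on the scale declared by ``tg_scale``.
    tg_scale : ``"C"`` (default; every library constant is quoted in Celsius)
        or ``"K"``.
    molar_mass : g/mol; required on the drug when the Flory–Huggins
        interaction parameter is requested.
    """

    name: str
    role: Literal["drug", "polymer"]
    true_density: float
    tg: float
    delta_total: float | None = None
    delta_d: float | None = None
    delta_p: float | None = None
    delta_h: float | None = None
    tg_scale: TgScale = "C"
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.true_density <= 0:
            raise DomainError(
                f"{self.name}: true_density must be > 0, got {self.true_density}"
            )
        components = (self.delta_d, self.delta_p, self.delta_h)
        has_components = all(c is not None for c in components)
        if any(c is not None for c in components) and not has_components:
            raise ValidationError(
                f"{self.name}: Hansen components must be given as a full "
                "(delta_d, delta_p, delta_h) triple"
            )
        if self.delta_total is None and not has_components:
            raise ValidationError(
                f"{self.name}: need delta_total or the full Hansen component triple"
            )
        if has_components:
            recomputed = total_solubility_parameter(*components)  # type: ignore[arg-type]
            if self.delta_total is not None:
                if abs(self.delta_total - recomputed) > DELTA_CONSISTENCY_TOL:
                    raise ValidationError(
                        f"{self.name}: delta_total {self.delta_total} inconsistent "
                        f"with components (sqrt sum of squares = {recomputed:.4f}, "
                        f"tolerance {DELTA_CONSISTENCY_TOL})"
                    )
            else:
                object.__setattr__(self, "delta_total", recomputed)
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise DomainError(
                f"{self.name}: molar_mass must be > 0, got {self.molar_mass}"
            )
        if self.tg_scale not in ("C", "K"):
            raise ValidationError(
                f"{self.name}: tg_scale must be 'C' or 'K', got {self.tg_scale!r}"
            )

    @property
    def delta(self) -> float:
        """Total solubility parameter (always resolvable after validation)."""
        assert self.delta_total is not None
        return self.delta_total

    def tg_in(self, scale: TgScale) -> float:
        """Tg converted to the requested scale."""
        if scale == self.tg_scale:
            return self.tg
        if scale == "K":
            return celsius_to_kelvin(self.tg)
        return kelvin_to_celsius(self.tg)

    @property
    def molar_volume(self) -> float:
        """Molar volume, cm^3/mol. Requires molar_mass."""
        if self.molar_mass is None:
            raise ValidationError(
                f"{self.name}: molar_mass is required to compute molar volume"
            )
        return molar_volume(self.molar_mass, self.true_density)


@dataclass
class ParameterLibrary:
    """Collection of material records keyed by name."""

    records: dict[str, MaterialRecord] = field(default_factory=dict)

    def add(self, record: MaterialRecord) -> None:
        if record.name in self.records:
            raise ValidationError(f"duplicate material name {record.name!r}")
        self.records[record.name] = record

    def __getitem__(self, name: str) -> MaterialRecord:
        try:
            return self.records[name]
        except KeyError:
            known = ", ".join(sorted(self.records))
            raise NotFoundError(
                f"unknown material {name!r}; known materials: {known}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)


def _records_from_frame(df: pd.DataFrame) -> ParameterLibrary:
    lib = ParameterLibrary()

    def _opt(row, col):
        v = row.get(col)
        return None if v is None or pd.isna(v) else float(v)

    for _, row in df.iterrows():
        lib.add(
            MaterialRecord(
                name=str(row["name"]),
                role=str(row["role"]),  # type: ignore[arg-type]
                delta_total=_opt(row, "delta_total"),
                delta_d=_opt(row, "delta_d"),
                delta_p=_opt(row, "delta_p"),
                delta_h=_opt(row, "delta_h"),
                true_density=float(row["density"]),
                tg=float(row["tg"]),
                tg_scale=str(row.get("tg_scale", "C") or "C"),  # type: ignore[arg-type]
                molar_mass=_opt(row, "molar_mass"),
            )
        )
    return lib


def read_materials_table(path) -> ParameterLibrary:
    """Read a materials table from tab- or comma-delimited text.

    Expected columns: name, role, delta_total, delta_d, delta_p, delta_h,
    density, tg, tg_scale, molar_mass (missing optional cells left blank).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "role", "density", "tg"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"materials table {path} missing required columns: {sorted(missing)}"
        )
    return _records_from_frame(df)


def load_material_library() -> ParameterLibrary:
    """Bundled constants for the glibenclamide / PVP K25 / PVP VA64 / SOL system.

    Literature values: delta_t 23.8 / 22.2 / 23.7 / 22.1 MPa^1/2, amorphous true
    density 1.37 / 1.18 / 1.167 / 0.99 g/cm^3, Tg 62 / 145 / 101 / 71 degC, and
    a glibenclamide molar mass of 494.0 g/mol.
    """
    with resources.files("glasstab.data").joinpath("materials.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return _records_from_frame(df)
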
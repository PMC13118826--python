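"""Dissolution profiles: similarity factor f2 and release-kinetics models.

Similarity factor. Two cumulative dissolution profiles R(t), T(t) sampled on
a common grid of n points are compared with

    f2 = 50 * log10( 100 / sqrt(1 + (1/n) * sum_t (R_t - T_t)^2) )

Identical profiles give f2 = 100; an average point-wise gap of 10% gives
f2 just under 50, the regulatory similarity threshold (profiles are declared
similar when f2 > 50). Profiles are never silently interpolated onto a
common grid — mismatched grids raise.

Rapid-dissolution exemption. When both products dissolve more than 85%
within 15 minutes the f2 test is waived and the profiles are accepted as
similar. The 15-minute value is linearly interpolated (from (0, 0) through
the observed points) when 15 min is not a sampled time — the only place this
module interpolates.

Release kinetics. Four classical models are fitted by ordinary least squares
on their linearizations:

    zero order      Q = k*t                 (Q vs t;        k in %/min)
    first order     ln(100-Q) = ln100 - k*t (ln(100-Q) vs t; k in 1/min)
    Higuchi         Q = k*sqrt(t)           (Q vs sqrt(t);  k in %/min^0.5)
    Hixson-Crowell  100^(1/3)-(100-Q)^(1/3) = k*t            (k in %^(1/3)/min)

and ranked by the coefficient of determination of the linearized fit. The
first-order and Hixson-Crowell transforms are undefined at 100% dissolved;
points at >= 99.95% are excluded from those fits with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DomainError, FitError, ValidationError

__all__ = [
    "DissolutionProfile",
    "SimilarityDecision",
    "KineticModelFit",
    "MODEL_ORDER",
    "f2_similarity",
    "similarity_decision",
    "fit_kinetic_model",
    "select_model",
    "read_dissolution_table",
    "profiles_to_frame",
]

KineticModel = Literal["zero_order", "first_order", "higuchi", "hixson_crowell"]

#: fixed fitting / tie-break order
MODEL_ORDER: tuple[KineticModel, ...] = (
    "zero_order",
    "first_order",
    "higuchi",
    "hixson_crowell",
)

MODEL_RATE_UNITS: dict[KineticModel, str] = {
    "zero_order": "%/min",
    "first_order": "1/min",
    "higuchi": "%/min^0.5",
    "hixson_crowell": "%^(1/3)/min",
}

#: points at or above this % dissolved are unusable for log/cube-root transforms
COMPLETE_DISSOLUTION_CUTOFF = 99.95

#: small assay overshoot above 100% is tolerated in stored profiles
MAX_DISSOLVED_PCT = 110.0


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative dissolution of one formulation on a fixed time grid.

    ``dissolved`` holds the mean cumulative % dissolved at each time; an
    optional ``replicates`` matrix (vessels x times) carries per-vessel data,
    in which case the stored means must equal the vessel means.
    """

    formulation: str
    times: np.ndarray  # minutes
    dissolved: np.ndarray  # cumulative % dissolved
    replicates: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dissolved = np.asarray(self.dissolved, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "dissolved", dissolved)
        if times.ndim != 1 or dissolved.shape != times.shape:
            raise ValidationError(
                f"{self.formulation}: times and dissolved must be 1-D and equal length"
            )
        if times.size == 0:
            raise ValidationError(f"{self.formulation}: empty profile")
        if times[0] < 0 or np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{self.formulation}: times must be non-negative and strictly increasing"
            )
        if np.any(dissolved < 0) or np.any(dissolved > MAX_DISSOLVED_PCT):
            raise ValidationError(
                f"{self.formulation}: dissolved values must lie in "
                f"[0, {MAX_DISSOLVED_PCT}] %"
            )
        if self.replicates is not None:
            reps = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            object.__setattr__(self, "replicates", reps)
            if reps.shape[1] != times.size:
                raise ValidationError(
                    f"{self.formulation}: replicate matrix has {reps.shape[1]} "
                    f"time columns, expected {times.size}"
                )
            if not np.allclose(reps.mean(axis=0), dissolved, atol=1e-9):
                raise ValidationError(
                    f"{self.formulation}: stored means differ from vessel means"
                )

    @property
    def n_vessels(self) -> int:
        return 1 if self.replicates is None else self.replicates.shape[0]

    def dissolved_at(self, t: float) -> float:
        """Linear interpolation through (0, 0) and the observed points."""
        times = np.concatenate(([0.0], self.times)) if self.times[0] > 0 else self.times
        vals = (
            np.concatenate(([0.0], self.dissolved))
            if self.times[0] > 0
            else self.dissolved
        )
        if t < times[0] or t > times[-1]:
            raise DomainError(
                f"{self.formulation}: t={t} outside the observed span "
                f"[{times[0]}, {times[-1]}] min"
            )
        return float(np.interp(t, times, vals))


@dataclass(frozen=True)
class SimilarityDecision:
    """Outcome of the regulatory similarity comparison."""

    rule: Literal["rapid_dissolution_exemption", "f2_test"]
    similar: bool
    f2: float | None = None


@dataclass(frozen=True)
class KineticModelFit:
    """One model's linearized least-squares fit."""

    model: KineticModel
    rate_constant: float
    intercept: float
    r_squared: float
    rate_units: str
    n_points: int


def _common_grid(reference: DissolutionProfile, test: DissolutionProfile) -> None:
    if reference.times.shape != test.times.shape or not np.allclose(
        reference.times, test.times
    ):
        raise AlignmentError(
            "profiles are on different time grids "
            f"({reference.times.tolist()} vs {test.times.tolist()}); "
            "f2 requires shared sampling times and no interpolation is applied"
        )


def f2_similarity(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    truncate_above_85: bool = False,
) -> float:
    """Similarity factor f2 between two profiles on a shared grid.

    With ``truncate_above_85`` the conventional truncation is applied: only
    points up to (and including) the first at which the reference exceeds
    85% dissolved enter the sum. Off by default.
    """
    _common_grid(reference, test)
    r = reference.dissolved
    t = test.dissolved
    if truncate_above_85:
        above = np.nonzero(r > 85.0)[0]
        if above.size:
            r, t = r[: above[0] + 1], t[: above[0] + 1]
    n = r.size
    msd = float(np.sum((r - t) ** 2)) / n
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def similarity_decision(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    t_rapid: float = 15.0,
    cutoff: float = 85.0,
) -> SimilarityDecision:
    """Regulatory decision: rapid-dissolution exemption, else f2 > 50.

    Both profiles dissolving more than ``cutoff``% by ``t_rapid`` minutes
    waives the f2 test and declares the profiles similar.
    """
    _common_grid(reference, test)
    if t_rapid <= 0 or cutoff <= 0:
        raise DomainError("t_rapid and cutoff must be positive")
    try:
        rapid = (
            reference.dissolved_at(t_rapid) > cutoff
            and test.dissolved_at(t_rapid) > cutoff
        )
    except DomainError:
        rapid = False  # grid ends before t_rapid: no exemption possible
    if rapid:
        return SimilarityDecision(rule="rapid_dissolution_exemption", similar=True)
    f2 = f2_similarity(reference, test)
    return SimilarityDecision(rule="f2_test", similar=f2 > 50.0, f2=f2)


def _linearize(
    model: KineticModel, times: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if model == "zero_order":
        return times, q
    if model == "higuchi":
        return np.sqrt(times), q
    remaining = 100.0 - q
    if model == "first_order":
        return times, np.log(remaining)
    # hixson_crowell
    return times, 100.0 ** (1.0 / 3.0) - remaining ** (1.0 / 3.0)


def fit_kinetic_model(
    profile: DissolutionProfile, model: KineticModel
) -> KineticModelFit:
    """Fit one release model by OLS on its linearization.

    Returns the slope-derived rate constant (reported positive for the
    first-order model), the intercept of the linearized regression, and the
    R² of the linearized fit.
    """
    if model not in MODEL_ORDER:
        raise ValidationError(
            f"unknown model {model!r}; choose one of {list(MODEL_ORDER)}"
        )
    times = profile.times
    q = np.minimum(profile.dissolved, 100.0)  # assay overshoot capped for fitting
    if model in ("first_order", "hixson_crowell"):
        usable = q < COMPLETE_DISSOLUTION_CUTOFF
        if not usable.all():
            warnings.warn(
                f"{profile.formulation}: {int((~usable).sum())} point(s) at "
                f">= {COMPLETE_DISSOLUTION_CUTOFF}% dissolved excluded from the "
                f"{model} fit (transform undefined at complete dissolution)",
                stacklevel=2,
            )
        times, q = times[usable], q[usable]
    if times.size < 3:
        raise FitError(
            f"{profile.formulation}: {model} fit needs >= 3 usable points, "
            f"have {times.size}"
        )
    x, y = _linearize(model, times, q)
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    k = -slope if model == "first_order" else slope
    return KineticModelFit(
        model=model,
        rate_constant=k,
        intercept=intercept,
        r_squared=r2,
        rate_units=MODEL_RATE_UNITS[model],
        n_points=int(times.size),
    )


def select_model(
    profile: DissolutionProfile, models: Sequence[KineticModel] = MODEL_ORDER
) -> tuple[KineticModelFit, list[KineticModelFit]]:
    """Fit all requested models and pick the best by R².

    Returns ``(best, fits)`` with ``fits`` in the fixed model order. Exact R²
    ties are broken by that order, with a warning.
    """
    fits = [fit_kinetic_model(profile, m) for m in models]
    best_r2 = max(f.r_squared for f in fits)
    winners = [f for f in fits if f.r_squared == best_r2]
    if len(winners) > 1:
        warnings.warn(
            f"{profile.formulation}: R² tie between "
            f"{[f.model for f in winners]}; keeping first in fixed model order",
            stacklevel=2,
        )
    return winners[0], fits


def read_dissolution_table(path) -> dict[str, DissolutionProfile]:
    """Read long-format delimited text: formulation, time_min, pct_dissolved[, vessel].

    With a vessel column, per-vessel replicates are stored and the profile
    mean is their vessel-wise average.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"formulation", "time_min", "pct_dissolved"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"dissolution table {path} missing columns: {sorted(missing)}"
        )
    profiles: dict[str, DissolutionProfile] = {}
    for name, grp in df.groupby("formulation", sort=False):
        if "vessel" in df.columns and grp["vessel"].notna().any():
            wide = grp.pivot_table(
                index="vessel", columns="time_min", values="pct_dissolved"
            ).sort_index(axis=1)
            times = wide.columns.to_numpy(dtype=float)
            reps = wide.to_numpy(dtype=float)
            profiles[str(name)] = DissolutionProfile(
                formulation=str(name),
                times=times,
                dissolved=reps.mean(axis=0),
                replicates=reps,
            )
        else:
            grp = grp.sort_values("time_min")
            profiles[str(name)] = DissolutionProfile(
                formulation=str(name),
                times=grp["time_min"].to_numpy(dtype=float),
                dissolved=grp["pct_dissolved"].to_numpy(dtype=float),
            )
    return profiles


def profiles_to_frame(profiles: Sequence[DissolutionProfile]) -> pd.DataFrame:
    """Long-format frame in the same schema ``read_dissolution_table`` reads."""
    rows = []
    for p in profiles:
        if p.replicates is not None:
            for v, vessel_vals in enumerate(p.replicates, start=1):
                for t, q in zip(p.times, vessel_vals):
                    rows.append((p.formulation, t, q, v))
        else:
            for t, q in zip(p.times, p.dissolved):
                rows.append((p.formulation, t, q, None))
    return pd.DataFrame(
        rows, columns=["formulation", "time_min", "pct_dissolved", "vessel"]
    )
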
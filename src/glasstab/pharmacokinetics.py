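"""Non-compartmental analysis of plasma concentration–time data.

Per subject: Cmax and Tmax are read directly from the observed
concentrations (no model), and the exposure AUC is the linear-trapezoid
area over the observed span, with a (0, 0) anchor prepended when the first
sample is drawn after dosing (standard for extravascular dosing, where the
pre-dose concentration is zero). No extrapolation beyond the last sample is
performed — the result is AUC(0–tlast).

Per group: arithmetic mean ± sample SD of each parameter over subjects.
Relative bioavailability of a test formulation against a reference given
the same dose is F% = mean AUC_test / mean AUC_ref × 100. Group differences
are screened with a classical one-way ANOVA (between/within mean-square
ratio on k−1 and N−k degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "PlasmaProfile",
    "NCAResult",
    "GroupPK",
    "RelativeBioavailability",
    "AnovaResult",
    "nca",
    "group_summary",
    "relative_bioavailability",
    "one_way_anova",
    "read_plasma_table",
]


@dataclass(frozen=True)
class PlasmaProfile:
    """One subject's plasma concentration–time course after a single dose."""

    group: str
    subject: str
    times: np.ndarray  # hours post-dose
    concentrations: np.ndarray  # ug/mL

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if times.ndim != 1 or conc.shape != times.shape:
            raise ValidationError(
                f"{self.group}/{self.subject}: times and concentrations must be "
                "1-D and equal length"
            )
        if times.size and (times[0] < 0 or np.any(np.diff(times) <= 0)):
            raise ValidationError(
                f"{self.group}/{self.subject}: times must be non-negative and "
                "strictly increasing"
            )
        if np.any(conc < 0):
            raise ValidationError(
                f"{self.group}/{self.subject}: negative concentration"
            )

    def censor_below_loq(self, loq: float) -> "PlasmaProfile":
        """Copy with concentrations below the limit of quantification set to 0."""
        if loq < 0:
            raise DomainError(f"loq must be >= 0, got {loq}")
        conc = np.where(self.concentrations < loq, 0.0, self.concentrations)
        return PlasmaProfile(self.group, self.subject, self.times.copy(), conc)


@dataclass(frozen=True)
class NCAResult:
    cmax: float  # ug/mL
    tmax: float  # h
    auc_0_t: float  # ug*h/mL


@dataclass(frozen=True)
class GroupPK:
    """Mean ± sample SD of each NCA parameter over a group's subjects."""

    group: str
    n: int
    cmax_mean: float
    cmax_sd: float
    tmax_mean: float
    tmax_sd: float
    auc_mean: float
    auc_sd: float


@dataclass(frozen=True)
class RelativeBioavailability:
    test_group: str
    reference_group: str
    f_percent: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False  # zero within-group variance with unequal means


def nca(profile: PlasmaProfile, loq: float | None = None) -> NCAResult:
    """Cmax/Tmax by direct inspection, AUC(0-tlast) by linear trapezoid.

    Tmax ties are broken toward the earliest time. An optional ``loq``
    zeroes unquantifiable concentrations first.
    """
    if loq is not None:
        profile = profile.censor_below_loq(loq)
    if profile.times.size < 2:
        raise FitError(
            f"{profile.group}/{profile.subject}: NCA needs >= 2 samples, "
            f"have {profile.times.size}"
        )
    times, conc = profile.times, profile.concentrations
    imax = int(np.argmax(conc))  # argmax returns the first maximum: earliest Tmax
    if times[0] > 0:
        times = np.concatenate(([0.0], times))
        conc = np.concatenate(([0.0], conc))
    auc = float(np.trapezoid(conc, times))
    return NCAResult(
        cmax=float(profile.concentrations[imax]),
        tmax=float(profile.times[imax]),
        auc_0_t=auc,
    )


def group_summary(
    profiles: Sequence[PlasmaProfile], loq: float | None = None
) -> GroupPK:
    """Per-subject NCA followed by mean ± sample SD (ddof = 1; SD 0 for n = 1)."""
    if not profiles:
        raise FitError("group summary needs at least one subject")
    groups = {p.group for p in profiles}
    if len(groups) > 1:
        raise ValidationError(f"profiles span multiple groups: {sorted(groups)}")
    results = [nca(p, loq=loq) for p in profiles]

    def _mean_sd(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    cmax_m, cmax_s = _mean_sd([r.cmax for r in results])
    tmax_m, tmax_s = _mean_sd([r.tmax for r in results])
    auc_m, auc_s = _mean_sd([r.auc_0_t for r in results])
    return GroupPK(
        group=profiles[0].group,
        n=len(results),
        cmax_mean=cmax_m,
        cmax_sd=cmax_s,
        tmax_mean=tmax_m,
        tmax_sd=tmax_s,
        auc_mean=auc_m,
        auc_sd=auc_s,
    )


def relative_bioavailability(
    test: GroupPK, reference: GroupPK
) -> RelativeBioavailability:
    """F% = mean AUC(test) / mean AUC(reference) × 100 (same dose assumed)."""
    if reference.auc_mean <= 0:
        raise DomainError(
            f"reference group {reference.group} has non-positive mean AUC "
            f"{reference.auc_mean}"
        )
    return RelativeBioavailability(
        test_group=test.group,
        reference_group=reference.group,
        f_percent=test.auc_mean / reference.auc_mean * 100.0,
    )


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on a parameter's per-subject values.

    Computed from the between/within sums-of-squares identity. A pooled
    within-group variance of exactly zero with unequal group means is
    reported as F = inf, p = 0 with ``degenerate=True`` rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} needs >= 2 subjects, has {arr.size}")
    all_values = np.concatenate(list(arrays.values()))
    grand_mean = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(
        arr.size * (arr.mean() - grand_mean) ** 2 for arr in arrays.values()
    )
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    if ss_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w)
        return AnovaResult(math.inf, 0.0, df_b, df_w, degenerate=True)
    f_stat = ms_between / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(float(f_stat), p, df_b, df_w)


def read_plasma_table(path) -> dict[str, list[PlasmaProfile]]:
    """Read long-format delimited text: group, subject, time_h, conc_ug_ml.

    Returns profiles grouped by treatment group, each sorted by time.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"group", "subject", "time_h", "conc_ug_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"plasma table {path} missing columns: {sorted(missing)}")
    out: dict[str, list[PlasmaProfile]] = {}
    for (group, subject), grp in df.groupby(["group", "subject"], sort=False):
        grp = grp.sort_values("time_h")
        out.setdefault(str(group), []).append(
            PlasmaProfile(
                group=str(group),
                subject=str(subject),
                times=grp["time_h"].to_numpy(dtype=float),
                concentrations=grp["conc_ug_ml"].to_numpy(dtype=float),
            )
        )
    return out
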
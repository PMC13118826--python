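"""Synthetic dissolution and plasma data with the structure the pipeline assumes.

Dissolution profiles are drawn from the closed form of one of the four
release models on the standard paddle-test grid (10, 20, 30, 45, 60,
120 min), with independent additive Gaussian noise per vessel (clipped to
[0, 100]% dissolved).

Plasma curves follow the one-compartment oral-absorption (Bateman) form

    C(t) = A * ka/(ka-ke) * (exp(-ke*t) - exp(-ka*t)),   A = F*Dose/V,

sampled on the 0.25, 0.5, 1, 2, 4, 8, 12, 24 h grid, with lognormal
between-subject variability applied multiplicatively to ka, ke and A.
Useful closed forms for validating the downstream estimators:
Tmax = ln(ka/ke)/(ka-ke) and AUC(0-inf) = A/ke.

Randomness is driven by a single integer seed; each simulated object derives
an independent child stream via ``numpy.random.SeedSequence.spawn``, so a
study is reproducible component-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dissolution import DissolutionProfile, KineticModel, MODEL_ORDER
from .errors import DomainError, ValidationError
from .pharmacokinetics import PlasmaProfile

__all__ = [
    "PADDLE_TIME_GRID_MIN",
    "PLASMA_TIME_GRID_H",
    "DissolutionSimSpec",
    "PKSimSpec",
    "dissolution_closed_form",
    "bateman",
    "simulate_dissolution",
    "simulate_plasma",
    "make_paper_like_study",
    "StudyBundle",
]

#: standard paddle-dissolution sampling grid, minutes
PADDLE_TIME_GRID_MIN = (10.0, 20.0, 30.0, 45.0, 60.0, 120.0)

#: plasma sampling grid, hours post-dose
PLASMA_TIME_GRID_H = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass(frozen=True)
class DissolutionSimSpec:
    """Generating model, grid and noise for one simulated formulation."""

    formulation: str
    model: KineticModel
    rate_constant: float
    times: tuple[float, ...] = PADDLE_TIME_GRID_MIN
    noise_sd: float = 2.0  # % dissolved, additive per vessel
    n_vessels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_ORDER:
            raise ValidationError(
                f"unknown model {self.model!r}; choose one of {list(MODEL_ORDER)}"
            )
        if self.rate_constant <= 0:
            raise DomainError(f"rate_constant must be > 0, got {self.rate_constant}")
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_vessels < 1:
            raise DomainError(f"n_vessels must be >= 1, got {self.n_vessels}")


@dataclass(frozen=True)
class PKSimSpec:
    """Bateman parameters and cohort design for one simulated treatment group."""

    group: str
    ka: float  # 1/h
    ke: float  # 1/h
    scale: float  # A = F*Dose/V, ug/mL
    times: tuple[float, ...] = PLASMA_TIME_GRID_H
    n_subjects: int = 5
    cv: float = 0.10  # lognormal between-subject CV on ka, ke, scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0:
            raise DomainError("ka and ke must be > 0")
        if self.ka == self.ke:
            raise DomainError(
                "ka == ke is a degenerate Bateman parameterization; perturb one rate"
            )
        if self.scale <= 0:
            raise DomainError(f"scale must be > 0, got {self.scale}")
        if self.n_subjects < 1:
            raise DomainError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.cv < 0:
            raise DomainError(f"cv must be >= 0, got {self.cv}")


def dissolution_closed_form(
    model: KineticModel, k: float, times: np.ndarray
) -> np.ndarray:
    """Noise-free cumulative % dissolved for one model, clipped to 100%."""
    t = np.asarray(times, dtype=float)
    if model == "zero_order":
        q = k * t
    elif model == "first_order":
        q = 100.0 * (1.0 - np.exp(-k * t))
    elif model == "higuchi":
        q = k * np.sqrt(t)
    elif model == "hixson_crowell":
        root = np.maximum(100.0 ** (1.0 / 3.0) - k * t, 0.0)
        q = 100.0 - root**3
    else:
        raise ValidationError(f"unknown model {model!r}")
    return np.clip(q, 0.0, 100.0)


def bateman(ka: float, ke: float, scale: float, times: np.ndarray) -> np.ndarray:
    """One-compartment oral-absorption concentration curve, ug/mL."""
    t = np.asarray(times, dtype=float)
    return scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def simulate_dissolution(spec: DissolutionSimSpec) -> DissolutionProfile:
    """Simulate one formulation's profile; bit-identical for a fixed spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    times = np.asarray(spec.times, dtype=float)
    truth = dissolution_closed_form(spec.model, spec.rate_constant, times)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_vessels, times.size))
    reps = np.clip(truth[None, :] + noise, 0.0, 100.0)
    return DissolutionProfile(
        formulation=spec.formulation,
        times=times,
        dissolved=reps.mean(axis=0),
        replicates=reps,
    )


def simulate_plasma(spec: PKSimSpec) -> list[PlasmaProfile]:
    """Simulate one treatment group's cohort of plasma profiles.

    Each subject's (ka, ke, scale) is the group value times an independent
    lognormal factor with unit median and coefficient of variation ``cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sigma = np.sqrt(np.log(1.0 + spec.cv**2))
    times = np.asarray(spec.times, dtype=float)
    profiles = []
    for i in range(1, spec.n_subjects + 1):
        factors = rng.lognormal(mean=0.0, sigma=sigma, size=3) if sigma > 0 else np.ones(3)
        ka, ke, scale = spec.ka * factors[0], spec.ke * factors[1], spec.scale * factors[2]
        if ka == ke:  # measure-zero collision from the perturbation
            ka *= 1.0 + 1e-9
        conc = np.maximum(bateman(ka, ke, scale, times), 0.0)
        profiles.append(
            PlasmaProfile(
                group=spec.group, subject=f"{spec.group}-{i:02d}",
                times=times, concentrations=conc,
            )
        )
    return profiles


@dataclass(frozen=True)
class StudyBundle:
    """Synthetic study: four dissolution arms and four PK groups."""

    dissolution: dict[str, DissolutionProfile] = field(default_factory=dict)
    plasma: dict[str, list[PlasmaProfile]] = field(default_factory=dict)
    reference_group: str = "REF"


#: generating kinetics for the four dissolution arms: one slow matrix-release
#: arm (Higuchi), one moderate first-order arm, and two fast first-order arms
_DISSOLUTION_ARMS: tuple[tuple[str, KineticModel, float], ...] = (
    ("REF", "higuchi", 4.5),  # ~49% at 120 min: slow matrix release
    ("SOL", "first_order", 0.04),  # moderate: ~91% at 60 min
    ("K25", "first_order", 0.35),  # fast: ~97% by 10 min
    ("VA64", "first_order", 0.40),  # fast
)

#: group-level Bateman kinetics; AUC(0-inf) = scale/ke
_PK_GROUPS: tuple[tuple[str, float, float], ...] = (
    # (group, ka 1/h, ke 1/h)
    ("REF", 0.8, 0.25),
    ("K25", 1.5, 0.25),
    ("VA64", 3.0, 0.25),
    ("SOL", 1.2, 0.25),
)

#: default group-mean AUC ratios against the reference arm
DEFAULT_AUC_RATIOS = {"REF": 1.0, "K25": 0.95, "VA64": 1.25, "SOL": 2.5}

_REFERENCE_SCALE = 1.2  # ug/mL; reference A = F*Dose/V


def make_paper_like_study(
    seed: int = 0,
    auc_ratios: dict[str, float] | None = None,
    n_subjects: int = 5,
    cv: float = 0.10,
    dissolution_noise_sd: float = 2.0,
) -> StudyBundle:
    """Build a full synthetic study: 4 dissolution arms + 4 PK groups.

    ``auc_ratios`` sets each group's generating mean AUC relative to the
    reference group, so relative-bioavailability analyses can be exercised
    against a known truth.
    """
    ratios = dict(DEFAULT_AUC_RATIOS)
    if auc_ratios:
        unknown = set(auc_ratios) - set(ratios)
        if unknown:
            raise ValidationError(f"unknown PK groups in auc_ratios: {sorted(unknown)}")
        ratios.update(auc_ratios)
    root = np.random.SeedSequence(seed)
    diss_seeds, pk_seeds = root.spawn(2)
    bundle_diss: dict[str, DissolutionProfile] = {}
    for child, (name, model, k) in zip(
        diss_seeds.spawn(len(_DISSOLUTION_ARMS)), _DISSOLUTION_ARMS
    ):
        spec = DissolutionSimSpec(
            formulation=name, model=model, rate_constant=k,
            noise_sd=dissolution_noise_sd,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        bundle_diss[name] = simulate_dissolution(spec)
    bundle_pk: dict[str, list[PlasmaProfile]] = {}
    for child, (group, ka, ke) in zip(pk_seeds.spawn(len(_PK_GROUPS)), _PK_GROUPS):
        scale = _REFERENCE_SCALE * ratios[group]
        spec = PKSimSpec(
            group=group, ka=ka, ke=ke, scale=scale,
            n_subjects=n_subjects, cv=cv,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        bundle_pk[group] = simulate_plasma(spec)
    return StudyBundle(dissolution=bundle_diss, plasma=bundle_pk, reference_group="REF")
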
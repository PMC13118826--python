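"""Gordon–Taylor glass-transition prediction for binary amorphous mixtures.

The Gordon–Taylor equation predicts the single Tg of a miscible binary
amorphous mixture from the pure-component values:

    Tg_mix = (W1·Tg1 + K·W2·Tg2) / (W1 + K·W2)

with component 2 the higher-Tg component and K taken from the Simha–Boyer
rule, K = ρ1·Tg1 / (ρ2·Tg2), which assumes the jump in thermal expansion
coefficient at Tg is roughly universal so K follows from densities and Tg
alone.

Scale convention. Thermodynamic convention evaluates both equations with Tg
in kelvin. Much of the formulation literature, however, tabulates Tg in
Celsius and evaluates the equations directly on that scale; the two
conventions give materially different predictions (several degrees for the
systems bundled here). Both are provided: ``scale_mode="celsius"`` (default,
matching the bundled reference values) and ``scale_mode="kelvin"``. The
prediction is returned on the same scale the equations were evaluated on.

Agreement between the predicted and DSC-measured Tg of a processed mixture
(within a few degrees) is the standard desk criterion for single-phase
glassy-solution formation; ``compare_tg`` applies a 4 degC default window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DomainError, ValidationError
from .materials import MaterialRecord

__all__ = [
    "ScaleMode",
    "GordonTaylorPrediction",
    "TgComparison",
    "simha_boyer_k",
    "gordon_taylor_tg",
    "fox_tg",
    "compare_tg",
]

ScaleMode = Literal["celsius", "kelvin"]

#: default |ΔTg| window (same scale as the inputs) for the single-phase call
SINGLE_PHASE_THRESHOLD = 4.0


@dataclass(frozen=True)
class GordonTaylorPrediction:
    """Predicted mixture Tg with the constants that produced it."""

    drug: str
    polymer: str
    w_drug: float
    k: float
    tg_predicted: float
    scale_mode: ScaleMode


@dataclass(frozen=True)
class TgComparison:
    """Predicted vs experimental Tg and the single-phase consistency call."""

    tg_predicted: float
    tg_experimental: float
    delta_tg: float  # experimental - predicted
    threshold: float
    single_phase_consistent: bool


def _tg_on_scale(record: MaterialRecord, scale_mode: ScaleMode) -> float:
    tg = record.tg_in("C" if scale_mode == "celsius" else "K")
    if tg <= 0:
        raise DomainError(
            f"{record.name}: Tg is {tg} on the {scale_mode} scale; the "
            "Simha-Boyer ratio requires a positive temperature — use kelvin "
            "mode for sub-zero-Celsius glasses"
        )
    return tg


def simha_boyer_k(
    component1: MaterialRecord,
    component2: MaterialRecord,
    scale_mode: ScaleMode = "celsius",
) -> float:
    """Simha–Boyer constant K = ρ1·Tg1/(ρ2·Tg2).

    ``component1`` must be the lower-Tg component (ties allowed).
    """
    tg1 = _tg_on_scale(component1, scale_mode)
    tg2 = _tg_on_scale(component2, scale_mode)
    if tg1 > tg2:
        raise ValidationError(
            f"component ordering: {component1.name} (Tg {tg1}) must not exceed "
            f"{component2.name} (Tg {tg2}); pass the lower-Tg component first"
        )
    return component1.true_density * tg1 / (component2.true_density * tg2)


def gordon_taylor_tg(
    drug: MaterialRecord,
    polymer: MaterialRecord,
    w_drug: float,
    scale_mode: ScaleMode = "celsius",
    k: float | None = None,
) -> GordonTaylorPrediction:
    """Predict the mixture Tg at drug weight fraction ``w_drug``.

    Component ordering (which of drug/polymer is the low-Tg component 1) is
    resolved internally by Tg. ``k`` overrides the Simha–Boyer value; passing
    k = Tg1/Tg2 (in kelvin mode) recovers the Fox equation.
    """
    if not 0.0 <= w_drug <= 1.0:
        raise DomainError(f"w_drug must be in [0, 1], got {w_drug}")
    tg_d = _tg_on_scale(drug, scale_mode)
    tg_p = _tg_on_scale(polymer, scale_mode)
    if tg_d <= tg_p:
        lo, hi, w1 = drug, polymer, w_drug
    else:
        lo, hi, w1 = polymer, drug, 1.0 - w_drug
    if k is None:
        k = simha_boyer_k(lo, hi, scale_mode)
    elif k <= 0:
        raise DomainError(f"k must be > 0, got {k}")
    tg1 = _tg_on_scale(lo, scale_mode)
    tg2 = _tg_on_scale(hi, scale_mode)
    w2 = 1.0 - w1
    tg = (w1 * tg1 + k * w2 * tg2) / (w1 + k * w2)
    return GordonTaylorPrediction(
        drug=drug.name,
        polymer=polymer.name,
        w_drug=w_drug,
        k=k,
        tg_predicted=tg,
        scale_mode=scale_mode,
    )


def fox_tg(drug: MaterialRecord, polymer: MaterialRecord, w_drug: float) -> float:
    """Fox-equation prediction, kelvin scale: 1/Tg = W1/Tg1 + W2/Tg2.

    Returned in kelvin. Equivalent to Gordon-Taylor with K = Tg1/Tg2.
    """
    if not 0.0 <= w_drug <= 1.0:
        raise DomainError(f"w_drug must be in [0, 1], got {w_drug}")
    tg_d = drug.tg_in("K")
    tg_p = polymer.tg_in("K")
    return 1.0 / (w_drug / tg_d + (1.0 - w_drug) / tg_p)


def compare_tg(
    prediction: GordonTaylorPrediction | float,
    tg_experimental: float,
    threshold: float = SINGLE_PHASE_THRESHOLD,
    experimental_scale: ScaleMode | None = None,
) -> TgComparison:
    """Compare a prediction with a measured Tg on the same scale.

    delta_tg is experimental − predicted; |delta_tg| ≤ threshold flags the
    mixture as consistent with a single phase. When ``prediction`` is a
    :class:`GordonTaylorPrediction`, ``experimental_scale`` (if given) must
    match the prediction's scale — mixing scales is refused rather than
    silently converted.
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold}")
    if isinstance(prediction, GordonTaylorPrediction):
        if experimental_scale is not None and experimental_scale != prediction.scale_mode:
            raise ValidationError(
                f"experimental Tg on {experimental_scale} scale cannot be compared "
                f"with a {prediction.scale_mode}-scale prediction"
            )
        predicted = prediction.tg_predicted
    else:
        predicted = float(prediction)
    delta = tg_experimental - predicted
    return TgComparison(
        tg_predicted=predicted,
        tg_experimental=tg_experimental,
        delta_tg=delta,
        threshold=threshold,
        single_phase_consistent=abs(delta) <= threshold,
    )
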
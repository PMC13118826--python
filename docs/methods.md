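# Methods

## Miscibility screening

The Hansen total solubility parameter is δ_t = √(δ_d² + δ_p² + δ_h²), with
dispersion, polar and hydrogen-bonding contributions adding in quadrature.
Records may carry the total directly, the component triple, or both; when
both are present they must agree within 0.05 MPa^1/2 or the record is
rejected (silent preference of one over the other would hide transcription
errors). The bundled library carries literature totals only — no
group-contribution estimation is attempted.

The Flory–Huggins interaction parameter is estimated from the solubility
parameter difference:

    χ = V_d (Δδ)² / (R T)

with V_d the drug's molar volume (molar mass / amorphous true density),
R = 8.314 J mol⁻¹ K⁻¹ and T defaulting to 298 K. Internally the product is
formed in base SI units (V_d in m³/mol, (Δδ)² in J/m³); the cm³·MPa
conversion factors cancel exactly, so the SI route is a correctness check,
not a numerical necessity. The glibenclamide molar mass defaults to
494.0 g/mol, the standard chemical constant; with the bundled density
1.37 g/cm³ this gives V_d ≈ 360.6 cm³/mol, which is also the value
back-solved from every bundled reference χ.

Classification thresholds: Δδ < 7 MPa^1/2 → miscible, Δδ > 10 MPa^1/2 →
immiscible, between → partially miscible; χ > 0.5 → limited, otherwise
favourable. The literature states these rules with strict inequalities and
never evaluates the boundaries, so the boundary convention here is: Δδ
exactly 7 or 10 falls in the middle (partially-miscible) class, and χ
exactly 0.5 is favourable.

## Glass-transition prediction

Gordon–Taylor: Tg = (W₁Tg₁ + K W₂Tg₂)/(W₁ + K W₂), component 2 being the
higher-Tg component (resolved internally, so callers pass drug/polymer in
any order). K comes from the Simha–Boyer rule K = ρ₁Tg₁/(ρ₂Tg₂), which
assumes the thermal-expansion step at Tg is roughly universal. One
denominator form in circulation, (W₂ + K W₂), cannot reproduce the
pure-component limits (at W₁ = 1 it predicts Tg₂·K/(K) ≠ Tg₁); the form
implemented here restores both endpoints and is monotone in composition.

**Temperature scale.** Thermodynamic convention evaluates both equations in
kelvin. The bundled reference predictions for 10% drug load
(129.8 / 95.8 / 70.2 °C for K25 / VA64 / SOL) reproduce only when both
equations are evaluated with Tg in Celsius, a convention common in the
formulation literature; kelvin mode gives materially different numbers
(≈136 °C for the K25 system). Both modes are provided;
`scale_mode="celsius"` is the default to match the reference values, and
the two are never mixed silently — comparisons refuse mismatched scales.
Celsius mode rejects materials with Tg ≤ 0 °C, where the Simha–Boyer ratio
on that scale becomes meaningless; kelvin mode handles them.

Predicted-vs-measured comparison: ΔTg = experimental − predicted;
|ΔTg| ≤ 4 °C (user-overridable) flags the mixture as consistent with a
single phase. The sign convention matches reporting practice (positive when
the measurement exceeds the prediction).

## Powder flow and tablet QC

Carr's index CI = (ρ_tapped − ρ_bulk)/ρ_tapped × 100 is scale-invariant in
the densities and lies in [0, 100). Powder-density inputs are interpreted
as g/mL regardless of the source table's unit label (bulk granule densities
are sometimes mislabelled mg/mL; the numbers are identical in g/mL).
The USP <1174> class edges are quoted in the compendia with one-unit gaps
(10–11, 15–16, …); they are implemented as contiguous half-open bands
≤10, (10,15], (15,20], (20,25], (25,31], (31,37], >37 so classification is
exhaustive and unambiguous; every reference CI value sits well inside a
band, so the gap convention never changes a reported class. One bundled
reference CI (18.9 for the VA64 granules) does not reproduce from its own
printed densities (0.48/0.59 → 18.6, presumably computed from unrounded
replicates); the function returns the computed value.

Tablet acceptance: friability strictly < 0.5%, disintegration strictly
< 60 s, content inclusively within 90–110% of label — the limits applied
when the compression force is chosen during development.

## Dissolution similarity

f₂ = 50·log₁₀(100/√(1 + (1/n)Σ(R_t−T_t)²)) over n shared time points.
Identical profiles give exactly 100; an average 10% point-wise gap gives
≈49.9, just under the f₂ > 50 similarity rule. Profiles on different grids
are refused — regulatory practice requires common time points, and silent
interpolation would manufacture agreement. The conventional truncation
("at most one point above 85% dissolved enters the sum") is available as an
option but off by default, since the bundled reference analyses use the
full profile.

The rapid-dissolution exemption (both products > 85% dissolved within
15 min → similar, no f₂ computed) is the one place linear interpolation is
used: the standard paddle grid (10, 20, 30, 45, 60, 120 min) has no 15-min
sample, so the 15-min value is interpolated through (0, 0) and the observed
points.

## Release kinetics

Four models, fitted by ordinary least squares on their linearizations:

| model          | regression                  | k units     |
|----------------|-----------------------------|-------------|
| zero order     | Q vs t                      | %/min       |
| first order    | ln(100−Q) vs t (k = −slope) | 1/min       |
| Higuchi        | Q vs √t                     | %/min^0.5   |
| Hixson–Crowell | 100^⅓ − (100−Q)^⅓ vs t      | %^⅓/min     |

R² is that of the linearized fit (the convention in dissolution-kinetics
tables; back-transformed R² would rank differently in general). Zero-order
and Higuchi are fitted with a free intercept; strict Higuchi theory forces
the intercept through the origin, and noise-free generated data recovers a
zero intercept anyway. The first-order k uses the natural log; the base-10
variant is k/2.303. Points at ≥ 99.95% dissolved are excluded from the
first-order and Hixson–Crowell fits (the transforms are undefined at
complete dissolution) with a warning; fits need ≥ 3 usable points. Model
selection is argmax R² with exact ties broken by the fixed model order
(zero, first, Higuchi, Hixson–Crowell) and a warning.

## Non-compartmental pharmacokinetics

Cmax and Tmax are read directly from the observations (ties broken to the
earliest time); AUC(0–t_last) is the linear trapezoid with a (0, 0) anchor
prepended when the first sample is post-dose (extravascular dosing, zero
pre-dose concentration). No extrapolation to infinity is performed.
Concentrations below an optional LOQ (e.g. an assay lower bound of
0.01 µg/mL) are zeroed before analysis when the LOQ is supplied; off by
default. Group summaries are arithmetic mean ± sample SD (ddof = 1; SD
reported 0 for n = 1). Relative bioavailability is the ratio of group-mean
AUCs × 100 — per-subject-ratio averaging needs paired designs and
individual data that group summaries do not provide. One-way ANOVA uses the
classical between/within sums-of-squares identity on (k−1, N−k) degrees of
freedom; a pooled within-group variance of exactly zero with unequal means
(possible for discrete parameters such as Tmax on a coarse grid) is
reported as F = ∞, p = 0 with a degeneracy flag rather than an error.

## Synthetic data generator

Dissolution: the chosen model's closed form on the standard paddle grid
(10, 20, 30, 45, 60, 120 min), additive Gaussian noise per vessel (default
SD 2% dissolved, 6 vessels as in a standard USP run), clipped to [0, 100]%.
Plasma: the one-compartment oral-absorption (Bateman) curve on the 0.25,
0.5, 1, 2, 4, 8, 12, 24 h sampling grid, with lognormal unit-median
between-subject factors on ka, ke and the scale A = F·Dose/V (default CV
10%, a typical preclinical between-animal variability; the reference study
reports only means ± SD, so the simplest noise structures matching that
data shape were chosen). Groups of 5 subjects by default. ka = ke is
rejected rather than special-cased (the limit form is a measure-zero
parameterization callers can avoid by perturbing a rate).

The bundled study generator produces one slow matrix-release arm (Higuchi),
one moderate and two fast first-order arms, and four PK groups whose
group-mean AUC ratios against the reference are configurable (defaults 1.0
/ 0.95 / 1.25 / 2.5), since AUC(0–∞) = A/ke makes the generating ratio
exact up to sampling truncation. All randomness derives from one integer
seed via `numpy.random.SeedSequence.spawn`, so each component's stream is
independent and the whole study is reproducible bit-for-bit.

What the generator does **not** emulate: supersaturation/precipitation
kinetics, biphasic release, correlated vessel effects, assay error
structure, enterohepatic recirculation, or any real-data artefact beyond
additive/lognormal noise. Tests passing on synthetic data therefore
demonstrate estimator correctness and pipeline plumbing, not robustness to
real-study pathologies.

## Problem sizes and numerical choices

Stochastic test properties use 200 seeds for kinetic-constant recovery and
50 seeds for the end-to-end F% recovery, sizes at which the Monte-Carlo
standard error is comfortably below the asserted tolerances. Recovery tests
use generating constants that keep profiles inside (0, 100)% on the full
grid, because the [0, 100] clipping censors the noise and visibly biases
the fitted constant otherwise (observed for a Higuchi arm reaching ~99% at
120 min) — estimator unbiasedness is only claimed absent censoring.
Report JSON serializes floats at full precision; rounding happens only in
text rendering.

## Known limitations

- The Hansen screen uses totals only; pairs with compensating component
  differences (equal totals, different δ_p/δ_h balance) screen as ideal.
- χ from (Δδ)² is non-negative by construction and cannot represent
  specific attractive interactions (χ < 0).
- Linearized least squares is not maximum likelihood for additive noise on
  Q under the nonlinear transforms; fitted constants carry small transform
  bias at high noise.
- The f₂ decision uses mean profiles; vessel-to-vessel variability does not
  enter the similarity statistic.
- No bioequivalence confidence intervals, λz/half-life estimation, or
  AUC extrapolation to infinity.
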
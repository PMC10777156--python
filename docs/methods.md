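# Methods

## The experiment being modelled

A single-density replacement series of two co-occurring peat mosses
(*Sphagnum cuspidatum*, *S. medium*): five cover ratios (100/0, 75/25,
50/50, 25/75, 0/100) × two water-table treatments × n replicates
(default 4, i.e. 40 mesocosms). After an acclimation period with the
water table at −1 cm, both arms experience a one-week *mild* drawdown
(−5 cm, no precipitation); the *deep* arm continues with a further
two-week drawdown (−20 cm more). Both arms are then rewetted to the
ambient level and followed for eight weeks. Net ecosystem CO₂ exchange
(NEE, µmol CO₂ m⁻² s⁻¹, ecological sign convention: positive = uptake)
is measured by closed transparent chamber three times during
acclimation (11, 9 and 1 days before drawdown), four times per week
during drawdown and twice per week during recovery.

The default calendar places drawdown start at day 11: acclimation
days 0–11 (measured on days 0, 2, 10), mild drawdown days 11–18
(measured at day offsets 1, 3, 5, 7), deep drawdown days 18–32
(offsets 1, 3, 5, 7, 8, 10, 12, 14), recovery 56 days from day 18
(mild arm) or 32 (deep arm), measured at offsets 3 and 7 of each week.
Measurement days are deterministic given the schedule so runs are
reproducible; day jitter is deliberately not simulated.

## Synthetic NEE model

Per mesocosm, NEE at measurement day *d* inside phase *p* is

    NEE(d) = L_p + s_p · (d − start_p) + ε,   ε ~ N(0, σ²) i.i.d.

where `s_p` is the phase slope for that (mixture, treatment, phase) and
the phase-entry level `L_p` is the previous phase's noiseless end
value — trajectories are continuous across phase boundaries except at
rewetting (below). This is a phenomenological model: no water-table
physics, evaporation or moss physiology is simulated, and the heatwave
events that precede drawdown transitions in such experiments are
treated as calendar annotations only.

Defaults (all overridable through `GeneratorConfig` or the pipeline
YAML config):

- **Baselines** (acclimation level, µmol m⁻² s⁻¹): 1.45, 1.35, 1.25,
  1.15, 1.05 from the pure *S. cuspidatum* to the pure *S. medium*
  mixture — inside the observed acclimation range 0.74–1.71, ordered
  with the higher photosynthetic rates of *S. cuspidatum*-rich stands.
  Acclimation slope is 0 (no pre-drought trend).
- **Drawdown slopes** (µmol m⁻² s⁻¹ per day): mild 0.20, 0.14, 0.21,
  0.14, 0.19 and deep −0.18, −0.11, −0.11, −0.13, −0.09 across the
  five mixtures. These are the reported response slopes of the study
  design this generator emulates and double as generative truth for the
  parameter-recovery tests. Slope units are interpreted as "per day"
  (a 0.20/day slope doubles a ~1.4 baseline over the seven-day mild
  week, consistent with the near-doubling of NEE under mild drawdown).
  Both arms share the mild-week slopes, since the hydrological regime
  is identical through that week.
- **Rewetting step**: the mild arm's NEE returns to its acclimation
  baseline immediately at rewetting (the diffusion advantage of drier
  moss vanishes when pores refill); the deep arm enters recovery
  continuously from its drawdown end level. Both behaviours are
  configurable (`rewet_to_baseline`).
- **Recovery slopes**: mild arm 0.0/day (NEE barely changes once back
  at baseline); deep arm 0.005/day for mixtures with ≥ 75%
  *S. cuspidatum* and 0.002/day otherwise, reflecting the faster
  rewetting recovery of *S. cuspidatum*-rich stands while leaving the
  deep arm well below baseline after eight weeks (≈ 45% below, for the
  monoculture defaults). These are the package's own choices; only the
  drawdown slopes have a reported anchor.
- **Noise**: σ = 0.45 µmol m⁻² s⁻¹, independent per measurement.
  Calibration: with four mild-week measurements at day offsets
  1, 3, 5, 7, the OLS slope SD is σ/√20 and the group-level standard
  error at n = 8 is σ/(√20·√8) = σ/12.65; σ = 0.45 reproduces the
  0.03–0.05 standard-error band of the reported mild-drawdown slope
  table (≈ 0.036). The same σ gives deep-phase slope SD σ/√138 ≈ 0.038,
  i.e. n = 4 group standard errors ≈ 0.019, matching the deep band.
- **Missingness**: the pipeline's default run drops one deep-arm 75/25
  mesocosm (`DD_75-25_r1`), emulating the single leaking-container
  exclusion; all group code tolerates the resulting n = 3 cell.

What the generator does **not** emulate: temporal autocorrelation
within a mesocosm beyond the deterministic trend, heteroscedasticity
across phases, day-to-day environmental fluctuations shared by all
mesocosms, chamber-closure artefacts, or nonlinear (saturating)
drought responses. Passing parameter-recovery tests on this generator
therefore shows the estimators are correct and appropriately powered
under the design's geometry and noise level — not that real moss
responds linearly.

## Chamber traces and flux computation

Raw traces are 1 Hz CO₂ records over 120 s (121 samples, t = 0…120).
The flux fit discards a 30 s dead band (closure artefacts), fits OLS on
the remainder (≥ 10 points required), and converts ppm s⁻¹ to an areal
molar flux:

    NEE = −slope · P·V / (R · T · A),   R = 8.314 J mol⁻¹ K⁻¹

with V the chamber volume (cylinder ∅ 0.29 m × 0.30 m ⇒ 0.01982 m³,
plus an optional `extra_volume` for loop tubing — default 0 since that
volume is rarely known), A the mesocosm (collar) surface area
(∅ 0.225 m ⇒ 0.03976 m²) — the flux originates from the moss surface,
so the collar, not the chamber cross-section, normalises it — and
T, P the climate-room defaults 295.15 K and 101325 Pa. The sign flip
makes declining concentration (uptake) positive. No water-vapour
dilution correction is applied (a limitation; traces are assumed dry or
pre-corrected by the analyzer). Fits with r² < 0.75 are flagged, never
dropped — preserving data while exposing unstable closures.

The synthetic trace generator is the exact algebraic inverse of this
conversion, which yields the round-trip identity used throughout the
tests: noiseless trace → flux recovers the input NEE to < 1e-9.

## Stability statistics

From each mesocosm's series: `NEE_acc` = mean over all acclimation
measurements (≥ 2 required); `NEE_d` = mean of measurements on the
*last* measurement day of the arm's drawdown (mild arm: end of the mild
week; deep arm: end of the deep phase) — the mean, rather than the
single last reading, is robust to accidental duplicate closures;
`NEE_rec` likewise on the last recovery day. Then

    Ω = NEE_acc / (NEE_d − NEE_acc)        (signed resistance)
    Δ = |(NEE_d − NEE_acc) / (NEE_rec − NEE_acc)|   (resilience)

Ω keeps its sign because the drought response of NEE is bidirectional
(mild drawdown raises NEE via better gas diffusion; deep drawdown
lowers it): Ω = 1 is a doubling, Ω = −2 a halving, |Ω| large means high
resistance. Δ ≥ 0 always; both are invariant to rescaling all three
NEE levels. Denominators below 1e-9 µmol m⁻² s⁻¹ (unchanged NEE;
complete return to baseline) produce infinite markers with explicit
flags (`omega_infinite`, `delta_infinite`); flagged values are excluded
listwise from group statistics, with exclusion counts reported, rather
than letting ±∞ propagate into ANOVA. A zero acclimation mean raises an
error (resistance undefined).

Response slopes are per-mesocosm OLS of NEE against day within a
phase (≥ 3 points), with days re-zeroed to the phase's first
measurement so slopes are comparable across arms whose phases start on
different calendar days; the recovery rate uses all recovery
measurements, not endpoints. The deep arm's drawdown slope is the
deep-phase slope (the mild week is analysed separately, pooled across
both arms at n = 8, because the regimes are identical through it).

## Group inference

`oneway_anova` implements the classical equal-variance one-way F test
directly from the sum-of-squares definitions (the SS decomposition
`SS_between + SS_within = SS_total` is property-tested, and the F and p
values are cross-checked against an independent implementation).
Zero within-group variance yields an infinite-F marker unless the
between-group variance is also zero (all data equal ⇒ F = 0). Tukey HSD
contrasts use the studentized-range adjustment via statsmodels.
`fit_repeated_measures` offers a mixed model (random intercept per
mesocosm) as a convenience for repeated-measures questions; it is a
pragmatic specification, documented as such — the package's primary
inference surface is the per-mesocosm slope + ANOVA path, which is
what the slope tables rest on.

## Numerical choices and edge cases

- Degeneracy tolerance for Ω/Δ denominators: 1e-9 on the µmol m⁻² s⁻¹
  scale (measurement noise is ~0.45, so anything below this is exact
  arithmetic cancellation, not data).
- A perfectly constant trace or phase is an exact zero-slope fit
  (stderr 0; trace r² reported as 1 by convention).
- `build_design` randomises treatment assignment within each mixture by
  a seeded permutation; all generator randomness flows from a single
  `numpy.random.default_rng(seed)`.
- Insufficient data always raises structured errors carrying the count
  found and required, or the missing phase; batch flux fitting collects
  per-trace failures instead of aborting.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
the scales the design itself prescribes: 40-mesocosm experiments,
50-mesocosm single-cell samples for slope recovery, 100-draw round-trip
and oracle sweeps, and 200-replicate ANOVA calibration runs (type-I
error and power). These sizes keep every check comfortably below a
minute while leaving Monte-Carlo error far smaller than the tested
tolerances.

## Known limitations

- Phenomenological linear trends; no mechanistic hydrology or
  physiology, no CH₄/H₂O channels, no nonlinear chamber models.
- No water-vapour dilution correction in the flux conversion.
- The mixed-model output documents its own structure; it does not claim
  equivalence to any particular published repeated-measures fit.
- Real-data features absent from the generator (autocorrelation, shared
  environmental fluctuations) mean calibration results transfer to real
  campaigns only approximately.
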
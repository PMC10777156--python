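"""Synthetic mesocosm experiment generator.

Emulates the replacement-series drought experiment: five *Sphagnum*
mixtures x two drawdown treatments x n replicates, measured through
acclimation (water table held at -1 cm), a one-week mild drawdown,
an additional two-week deep drawdown (deep arm only) and an eight-week
rewetting period.  NEE trajectories are piecewise linear in time within
each phase, continuous across phase boundaries (except for a
configurable rewetting step), with independent Gaussian measurement
noise.  Raw 1 Hz chamber concentration traces can be synthesised as the
exact inverse of the flux module's conversion, so trace -> flux -> NEE
round-trips to the configured value on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DESIGN_FRACTIONS,
    PHASE_ORDER,
    MesocosmRecord,
    MixtureComposition,
    NeeSeries,
    Phase,
    PhaseSchedule,
    Treatment,
)
from .errors import ConfigurationError, InvalidArgumentError
from .flux import ChamberSpec, ConcentrationTrace, nee_to_slope

# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

#: Acclimation NEE level per S. cuspidatum fraction (umol CO2 m-2 s-1).
#: Values sit inside the measured acclimation range 0.74-1.71, highest in
#: the S. cuspidatum monoculture and lowest in the S. medium monoculture.
DEFAULT_BASELINE_NEE: dict[float, float] = {
    1.0: 1.45, 0.75: 1.35, 0.5: 1.25, 0.25: 1.15, 0.0: 1.05,
}

#: Mild-drawdown NEE response slopes per mixture (umol m-2 s-1 per day);
#: both arms share the mild week, so both use these.
DEFAULT_MILD_SLOPES: dict[float, float] = {
    1.0: 0.20, 0.75: 0.14, 0.5: 0.21, 0.25: 0.14, 0.0: 0.19,
}

#: Deep-drawdown NEE response slopes per mixture (deep arm only).
DEFAULT_DEEP_SLOPES: dict[float, float] = {
    1.0: -0.18, 0.75: -0.11, 0.5: -0.11, 0.25: -0.13, 0.0: -0.09,
}

#: Recovery-period slopes per (treatment, mixture).  The mild arm returns
#: to baseline at rewetting and then barely changes; the deep arm creeps
#: back up, faster where S. cuspidatum cover is >= 75%.
DEFAULT_RECOVERY_SLOPES: dict[Treatment, dict[float, float]] = {
    Treatment.MILD: {f: 0.0 for f in DESIGN_FRACTIONS},
    Treatment.DEEP: {1.0: 0.005, 0.75: 0.005, 0.5: 0.002, 0.25: 0.002, 0.0: 0.002},
}

#: Measurement-noise SD on NEE (umol m-2 s-1).  Calibrated so that, with
#: four measurements in the mild week (day offsets 1, 3, 5, 7), the
#: group-level standard error of fitted slopes at n = 8 falls in the
#: 0.03-0.05 band of the observed response-slope table:
#: stderr = noise_sd / (sqrt(20) * sqrt(8)) ~= noise_sd / 12.65, so
#: noise_sd = 0.45 gives ~0.036.
DEFAULT_NOISE_SD = 0.45

#: Within-week measurement-day offsets (days after phase start).
DRAWDOWN_WEEKLY_OFFSETS = (1, 3, 5, 7)  # four per week during drawdown
RECOVERY_WEEKLY_OFFSETS = (3, 7)  # two per week during recovery
ACCLIMATION_OFFSETS = (-11, -9, -1)  # days relative to drawdown start


def _weekly_days(start: int, length: int, weekly: Sequence[int]) -> tuple[int, ...]:
    """Measurement days from a repeating weekly offset pattern."""
    days = []
    for week in range(-(-length // 7)):
        for off in weekly:
            d = 7 * week + off
            if d <= length:
                days.append(start + d)
    return tuple(days)


def default_schedule(
    treatment: Treatment,
    *,
    drawdown_start: int = 11,
    mild_days: int = 7,
    deep_days: int = 14,
    recovery_days: int = 56,
) -> PhaseSchedule:
    """Default phase calendar for one treatment arm.

    Acclimation measurements fall 11, 9 and 1 days before drawdown;
    drawdown phases are measured four times per week, recovery twice
    per week.  The mild arm's recovery starts at the end of the mild
    week; the deep arm's after two further drawdown weeks.
    """
    treatment = Treatment(treatment)
    acc = (0, drawdown_start)
    mild = (drawdown_start, drawdown_start + mild_days)
    bounds: dict[Phase, tuple[int, int]] = {Phase.ACCLIMATION: acc, Phase.MILD_DRAWDOWN: mild}
    meas: dict[Phase, tuple[int, ...]] = {
        Phase.ACCLIMATION: tuple(drawdown_start + o for o in ACCLIMATION_OFFSETS),
        Phase.MILD_DRAWDOWN: _weekly_days(mild[0], mild_days, DRAWDOWN_WEEKLY_OFFSETS),
    }
    if treatment is Treatment.DEEP:
        deep = (mild[1], mild[1] + deep_days)
        bounds[Phase.DEEP_DRAWDOWN] = deep
        meas[Phase.DEEP_DRAWDOWN] = _weekly_days(deep[0], deep_days, DRAWDOWN_WEEKLY_OFFSETS)
        rec_start = deep[1]
    else:
        rec_start = mild[1]
    bounds[Phase.RECOVERY] = (rec_start, rec_start + recovery_days)
    meas[Phase.RECOVERY] = _weekly_days(rec_start, recovery_days, RECOVERY_WEEKLY_OFFSETS)
    return PhaseSchedule(bounds, meas)


def default_schedules() -> dict[Treatment, PhaseSchedule]:
    """Per-arm default schedules."""
    return {t: default_schedule(t) for t in Treatment}


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------


def _default_phase_slopes() -> dict[tuple[float, Treatment, Phase], float]:
    slopes: dict[tuple[float, Treatment, Phase], float] = {}
    for f in DESIGN_FRACTIONS:
        for t in Treatment:
            slopes[(f, t, Phase.ACCLIMATION)] = 0.0  # flat pre-drought baseline
            slopes[(f, t, Phase.MILD_DRAWDOWN)] = DEFAULT_MILD_SLOPES[f]
            slopes[(f, t, Phase.RECOVERY)] = DEFAULT_RECOVERY_SLOPES[t][f]
        slopes[(f, Treatment.DEEP, Phase.DEEP_DRAWDOWN)] = DEFAULT_DEEP_SLOPES[f]
    return slopes


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Attributes
    ----------
    baseline_nee
        Acclimation NEE level per S. cuspidatum fraction.
    phase_slope
        Linear NEE trend per (fraction, treatment, phase), in
        umol m-2 s-1 per day.
    noise_sd
        SD of the independent Gaussian measurement noise added to each
        NEE observation (umol m-2 s-1); see :data:`DEFAULT_NOISE_SD`.
    rewet_to_baseline
        Whether the arm's NEE snaps back to its acclimation baseline at
        the start of recovery (the mild arm does; the deep arm stays
        continuous with its drawdown end level).
    drop_mesocosm
        Optional mesocosm id removed after generation, emulating the
        single leaking-container exclusion (pipeline default drops one
        deep-arm 75/25 replicate).
    """

    baseline_nee: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_NEE))
    phase_slope: dict[tuple[float, Treatment, Phase], float] = field(
        default_factory=_default_phase_slopes)
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 4
    seed: int = 0
    drop_mesocosm: str | None = None
    rewet_to_baseline: dict[Treatment, bool] = field(
        default_factory=lambda: {Treatment.MILD: True, Treatment.DEEP: False})

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")

    @classmethod
    def default(cls, **overrides) -> "GeneratorConfig":
        """Config at the default study conditions, with field overrides."""
        return cls(**overrides)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def make_mesocosm_id(composition: MixtureComposition, treatment: Treatment,
                     replicate: int) -> str:
    """Canonical id, e.g. ``'DD_75-25_r1'`` (MD = mild, DD = deep arm)."""
    prefix = "MD" if Treatment(treatment) is Treatment.MILD else "DD"
    return f"{prefix}_{composition.label.replace('/', '-')}_r{replicate}"


def build_design(n_replicates: int = 4, seed: int = 0) -> list[MesocosmRecord]:
    """Randomly assign treatments within each mixture.

    For each of the five replacement-series compositions,
    ``2 * n_replicates`` cores are assigned to the mild or deep arm by
    a seeded permutation (n per arm).  Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[MesocosmRecord] = []
    for frac in DESIGN_FRACTIONS:
        comp = MixtureComposition.from_cuspidatum(frac)
        arms = [Treatment.MILD] * n_replicates + [Treatment.DEEP] * n_replicates
        counts = {Treatment.MILD: 0, Treatment.DEEP: 0}
        for idx in rng.permutation(len(arms)):
            tr = arms[idx]
            counts[tr] += 1
            records.append(
                MesocosmRecord(make_mesocosm_id(comp, tr, counts[tr]), comp, tr, counts[tr])
            )
    return records


def _resolve_schedules(
    schedule: PhaseSchedule | Mapping[Treatment, PhaseSchedule] | None,
) -> dict[Treatment, PhaseSchedule]:
    if schedule is None:
        return default_schedules()
    if isinstance(schedule, PhaseSchedule):
        return {t: schedule for t in Treatment}
    return {Treatment(t): s for t, s in schedule.items()}


def generate_nee_series(
    design: Sequence[MesocosmRecord],
    schedule: PhaseSchedule | Mapping[Treatment, PhaseSchedule] | None = None,
    config: GeneratorConfig | None = None,
) -> list[NeeSeries]:
    """Simulate one NEE trajectory per mesocosm.

    Within each phase, NEE follows the configured linear trend from the
    phase-entry level; entry levels are continuous with the previous
    phase's noiseless end value, except at rewetting where arms flagged
    ``rewet_to_baseline`` drop back to their acclimation baseline.
    Independent Gaussian noise is added per measurement.

    Raises :class:`ConfigurationError` (naming the missing key) before
    producing any output if a required slope or baseline entry is
    absent.
    """
    config = config if config is not None else GeneratorConfig.default()
    schedules = _resolve_schedules(schedule)
    # validate configuration up front so failures happen before any output
    for rec in design:
        frac = rec.composition.cuspidatum_fraction
        if frac not in config.baseline_nee:
            raise ConfigurationError(f"no baseline_nee entry for fraction {frac}")
        for phase in schedules[rec.treatment].phases:
            key = (frac, rec.treatment, phase)
            if key not in config.phase_slope:
                raise ConfigurationError(
                    f"no phase_slope entry for (fraction={frac}, "
                    f"treatment={rec.treatment.value}, phase={phase.value})"
                )
    rng = np.random.default_rng(config.seed)
    out: list[NeeSeries] = []
    for rec in design:
        sched = schedules[rec.treatment]
        frac = rec.composition.cuspidatum_fraction
        baseline = config.baseline_nee[frac]
        level = baseline
        days: list[int] = []
        phases: list[Phase] = []
        values: list[float] = []
        for phase in sched.phases:
            start, end = sched.phase_bounds[phase]
            slope = config.phase_slope[(frac, rec.treatment, phase)]
            if phase is Phase.RECOVERY and config.rewet_to_baseline.get(rec.treatment, False):
                level = baseline  # rewetting step: snap back to pre-drought level
            for d in sched.measurement_days[phase]:
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                days.append(d)
                phases.append(phase)
                values.append(level + slope * (d - start) + noise)
            level = level + slope * (end - start)
        out.append(NeeSeries(rec.mesocosm_id, rec.composition, rec.treatment,
                             days, phases, values))
    return out


def generate_concentration_trace(
    nee: float,
    chamber: ChamberSpec | None = None,
    ambient_co2: float = 420.0,
    duration_s: int = 120,
    noise_sd_ppm: float = 0.0,
    seed: int = 0,
    mesocosm_id: str = "",
    day: int = 0,
) -> ConcentrationTrace:
    """Synthesise the 1 Hz chamber trace a given NEE would produce.

    The noiseless concentration slope is the exact inverse of the flux
    module's ideal-gas conversion, so uptake (positive NEE) gives a
    decreasing trace and ``trace_to_nee`` recovers ``nee`` identically
    on noiseless data.
    """
    if duration_s < 60:
        raise InvalidArgumentError("duration_s must be >= 60")
    chamber = chamber if chamber is not None else ChamberSpec()
    slope = nee_to_slope(nee, chamber)
    t = np.arange(duration_s + 1, dtype=float)  # 1 Hz, t = 0..duration_s
    co2 = ambient_co2 + slope * t
    if noise_sd_ppm > 0:
        co2 = co2 + np.random.default_rng(seed).normal(0.0, noise_sd_ppm, t.size)
    return ConcentrationTrace(t, co2, chamber, mesocosm_id=mesocosm_id, day=day)


def apply_missingness(series: Sequence[NeeSeries], drop_id: str) -> list[NeeSeries]:
    """Remove one mesocosm from the dataset (e.g. a leaking container).

    Raises ``KeyError`` if ``drop_id`` is not present.  Downstream
    group summaries must tolerate the resulting n-1 cell.
    """
    ids = {s.mesocosm_id for s in series}
    if drop_id not in ids:
        raise KeyError(f"mesocosm id {drop_id!r} not present")
    return [s for s in series if s.mesocosm_id != drop_id]


def simulate_experiment(
    config: GeneratorConfig | None = None,
    schedule: PhaseSchedule | Mapping[Treatment, PhaseSchedule] | None = None,
) -> tuple[list[MesocosmRecord], list[NeeSeries]]:
    """Convenience wrapper: design + NEE series (+ configured dropout)."""
    config = config if config is not None else GeneratorConfig.default()
    design = build_design(config.n_replicates, config.seed)
    series = generate_nee_series(design, schedule, config)
    if config.drop_mesocosm:
        series = apply_missingness(series, config.drop_mesocosm)
    return design, series
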
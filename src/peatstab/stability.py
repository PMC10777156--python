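"""Per-mesocosm ecosystem stability statistics.

Following the resistance/resilience framework adapted to a flux whose
drought response can go in either direction, three summary levels are
taken from each mesocosm's NEE series:

* ``NEE_acc``: mean NEE over the acclimation period,
* ``NEE_d``: NEE on the last measurement day of the arm's drawdown
  treatment (mild arm: end of the mild week; deep arm: end of the deep
  phase),
* ``NEE_rec``: NEE on the last measurement day of the recovery period.

Signed resistance keeps the direction of the drought response:

    omega = NEE_acc / (NEE_d - NEE_acc)

so omega = 1 means NEE doubled during drawdown and omega = -2 means it
halved; values near 0 mean low resistance, large |omega| high
resistance.  Resilience is the unsigned ratio

    delta = |(NEE_d - NEE_acc) / (NEE_rec - NEE_acc)|

large when NEE has returned close to its pre-drought level.  Degenerate
denominators (unchanged NEE, or complete return to baseline) yield
infinite markers with explicit flags instead of propagating division
blow-ups into group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .core import MixtureComposition, NeeSeries, Phase, PhaseSchedule, Treatment
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingPhaseError,
    UndefinedBaselineError,
)

#: Denominators smaller than this (umol m-2 s-1) are treated as zero.
DEGENERACY_TOL = 1e-9

#: Flag names used in StabilityResult.degenerate_flags.
OMEGA_INFINITE = "omega_infinite"
DELTA_INFINITE = "delta_infinite"


def resistance_omega(nee_acc_mean: float, nee_d: float, tol: float = DEGENERACY_TOL) -> float:
    """Signed resistance of NEE to drawdown.

    Returns ``math.inf`` (the infinite-resistance marker) when NEE is
    unchanged within ``tol``; raises
    :class:`UndefinedBaselineError` for a zero acclimation mean.
    """
    if not (math.isfinite(nee_acc_mean) and math.isfinite(nee_d)):
        raise InvalidArgumentError("resistance inputs must be finite")
    if nee_acc_mean == 0.0:
        raise UndefinedBaselineError("acclimation-mean NEE of zero leaves resistance undefined")
    denom = nee_d - nee_acc_mean
    if abs(denom) < tol:
        return math.inf
    return nee_acc_mean / denom


def resilience_delta(
    nee_acc_mean: float, nee_d: float, nee_rec: float, tol: float = DEGENERACY_TOL
) -> float:
    """Unsigned resilience: how far NEE returned toward baseline.

    Returns ``math.inf`` (infinite-resilience marker) when the
    end-of-recovery NEE equals the acclimation mean within ``tol``
    (a complete return).
    """
    if not all(math.isfinite(v) for v in (nee_acc_mean, nee_d, nee_rec)):
        raise InvalidArgumentError("resilience inputs must be finite")
    denom = nee_rec - nee_acc_mean
    if abs(denom) < tol:
        return math.inf
    return abs((nee_d - nee_acc_mean) / denom)


def phase_slope(series: NeeSeries, phase: Phase) -> tuple[float, float]:
    """OLS slope of NEE against day within one phase.

    Days are re-zeroed to the phase's first measurement (slope and
    standard error are shift-invariant).  Returns
    ``(slope, stderr)`` in umol m-2 s-1 per day.  Requires at least
    three records in the phase.
    """
    phase = Phase(phase)
    x = series.phase_days(phase).astype(float)
    y = series.phase_values(phase)
    if x.size < 3:
        raise InsufficientDataError(int(x.size), 3, context=f"phase {phase.value}")
    x = x - x.min()
    if np.ptp(y) == 0.0:
        return 0.0, 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.stderr)


@dataclass(frozen=True)
class StabilityResult:
    """All per-mesocosm stability statistics."""

    mesocosm_id: str
    composition: MixtureComposition
    treatment: Treatment
    nee_acc_mean: float
    nee_d: float
    nee_rec: float
    omega: float
    delta: float
    drawdown_slope: float
    drawdown_slope_stderr: float
    recovery_rate: float
    recovery_rate_stderr: float
    degenerate_flags: frozenset[str] = frozenset()
    #: (slope, stderr) for every phase with >= 3 records.
    phase_slopes: Mapping[Phase, tuple[float, float]] = field(default_factory=dict)


def _final_day_mean(series: NeeSeries, phase: Phase) -> float:
    """Mean NEE over the last measurement day of a phase.

    Normally a single reading; the mean makes the statistic robust to
    accidental duplicate closures on the same day.
    """
    days = series.phase_days(phase)
    vals = series.phase_values(phase)
    last = days.max()
    return float(vals[days == last].mean())


def summarize_mesocosm(
    series: NeeSeries, schedule: PhaseSchedule | None = None
) -> StabilityResult:
    """Assemble the full stability summary for one mesocosm.

    Requires >= 2 acclimation records, >= 1 record in the arm's final
    drawdown phase, and >= 1 recovery record; otherwise raises a
    structured error naming the offending phase.  The ``schedule``
    argument is accepted for signature symmetry with the pipeline but
    the phase tags on the series are authoritative.
    """
    acc = series.phase_values(Phase.ACCLIMATION)
    if acc.size == 0:
        raise MissingPhaseError(Phase.ACCLIMATION, series.mesocosm_id)
    if acc.size < 2:
        raise InsufficientDataError(int(acc.size), 2, context="acclimation period")
    drawdown_phase = (
        Phase.DEEP_DRAWDOWN
        if series.treatment is Treatment.DEEP and series.has_phase(Phase.DEEP_DRAWDOWN)
        else Phase.MILD_DRAWDOWN
    )
    if not series.has_phase(drawdown_phase):
        raise MissingPhaseError(drawdown_phase, series.mesocosm_id)
    if not series.has_phase(Phase.RECOVERY):
        raise MissingPhaseError(Phase.RECOVERY, series.mesocosm_id)

    nee_acc_mean = float(acc.mean())
    nee_d = _final_day_mean(series, drawdown_phase)
    nee_rec = _final_day_mean(series, Phase.RECOVERY)

    flags: set[str] = set()
    omega = resistance_omega(nee_acc_mean, nee_d)
    if math.isinf(omega):
        flags.add(OMEGA_INFINITE)
    delta = resilience_delta(nee_acc_mean, nee_d, nee_rec)
    if math.isinf(delta):
        flags.add(DELTA_INFINITE)

    slopes: dict[Phase, tuple[float, float]] = {}
    for p in (Phase.ACCLIMATION, Phase.MILD_DRAWDOWN, Phase.DEEP_DRAWDOWN, Phase.RECOVERY):
        if series.phase_days(p).size >= 3:
            slopes[p] = phase_slope(series, p)

    dd_slope, dd_se = slopes.get(drawdown_phase, (math.nan, math.nan))
    rec_slope, rec_se = slopes.get(Phase.RECOVERY, (math.nan, math.nan))
    return StabilityResult(
        mesocosm_id=series.mesocosm_id,
        composition=series.composition,
        treatment=series.treatment,
        nee_acc_mean=nee_acc_mean,
        nee_d=nee_d,
        nee_rec=nee_rec,
        omega=omega,
        delta=delta,
        drawdown_slope=dd_slope,
        drawdown_slope_stderr=dd_se,
        recovery_rate=rec_slope,
        recovery_rate_stderr=rec_se,
        degenerate_flags=frozenset(flags),
        phase_slopes=slopes,
    )


def summarize_all(
    series: list[NeeSeries], schedule: PhaseSchedule | None = None
) -> list[StabilityResult]:
    """Stability summaries for a list of mesocosm series."""
    return [summarize_mesocosm(s, schedule) for s in series]
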
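"""Core domain types shared by the simulation, flux and analysis layers.

The experiment modelled here is a two-species replacement series of
*Sphagnum* peat-moss mesocosms subjected to a mild (one week) or deep
(three weeks total) water-table drawdown, followed by rewetting.  Net
ecosystem CO2 exchange (NEE, ecological sign convention: positive =
uptake) is measured repeatedly through four phases: acclimation, mild
drawdown, deep drawdown (deep arm only) and recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


class Phase(str, Enum):
    """Experimental phase, in chronological order."""

    ACCLIMATION = "acclimation"
    MILD_DRAWDOWN = "mild_drawdown"
    DEEP_DRAWDOWN = "deep_drawdown"
    RECOVERY = "recovery"


#: Chronological ordering of phases.
PHASE_ORDER: tuple[Phase, ...] = (
    Phase.ACCLIMATION,
    Phase.MILD_DRAWDOWN,
    Phase.DEEP_DRAWDOWN,
    Phase.RECOVERY,
)


class Treatment(str, Enum):
    """Water-table drawdown arm a mesocosm is assigned to."""

    MILD = "mild"
    DEEP = "deep"


#: Canonical replacement-series points (fraction of S. cuspidatum cover),
#: in the design's row order: 100/0, 75/25, 50/50, 25/75, 0/100.
DESIGN_FRACTIONS: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)


@dataclass(frozen=True)
class MixtureComposition:
    """Fractional cover of the two moss species in a mesocosm.

    A point on the replacement series: total cover is constant, so the
    two fractions must sum to one.

    Parameters
    ----------
    cuspidatum_fraction
        Cover fraction of *S. cuspidatum* in [0, 1].
    medium_fraction
        Cover fraction of *S. medium* in [0, 1].
    """

    cuspidatum_fraction: float
    medium_fraction: float

    def __post_init__(self) -> None:
        for name in ("cuspidatum_fraction", "medium_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidArgumentError(f"{name}={v!r} outside [0, 1]")
        if abs(self.cuspidatum_fraction + self.medium_fraction - 1.0) > 1e-9:
            raise InvalidArgumentError(
                "species fractions must sum to 1 "
                f"(got {self.cuspidatum_fraction} + {self.medium_fraction})"
            )

    @classmethod
    def from_cuspidatum(cls, fraction: float) -> "MixtureComposition":
        """Build a composition from the S. cuspidatum fraction alone."""
        return cls(fraction, 1.0 - fraction)

    @property
    def label(self) -> str:
        """Human-readable mixture label, e.g. ``'75/25'``."""
        return f"{round(self.cuspidatum_fraction * 100)}/{round(self.medium_fraction * 100)}"


@dataclass(frozen=True)
class MesocosmRecord:
    """One experimental unit: a moss core with its assigned treatment."""

    mesocosm_id: str
    composition: MixtureComposition
    treatment: Treatment
    replicate: int


@dataclass(frozen=True)
class PhaseSchedule:
    """Calendar of one treatment arm's phases and measurement days.

    ``phase_bounds`` maps each phase present in the arm to a
    ``(start_day, end_day)`` pair; phases must be contiguous (each
    phase starts where the previous one ends) and in chronological
    order.  The mild arm simply has no ``deep_drawdown`` entry.
    ``measurement_days`` lists the integer days on which chamber
    measurements are taken, per phase, each within that phase's bounds.
    """

    phase_bounds: Mapping[Phase, tuple[int, int]]
    measurement_days: Mapping[Phase, tuple[int, ...]]

    def __post_init__(self) -> None:
        phases = self.phases
        if not phases:
            raise InvalidArgumentError("schedule has no phases")
        order = [p for p in PHASE_ORDER if p in self.phase_bounds]
        if list(phases) != order:
            raise InvalidArgumentError("schedule phases out of chronological order")
        prev_end = None
        for p in phases:
            start, end = self.phase_bounds[p]
            if end <= start:
                raise InvalidArgumentError(f"phase {p.value} has non-positive length")
            if prev_end is not None and start != prev_end:
                raise InvalidArgumentError(
                    f"phase {p.value} starts at day {start}, expected day {prev_end}"
                )
            prev_end = end
            days = self.measurement_days.get(p, ())
            if any(not (start <= d <= end) for d in days):
                raise InvalidArgumentError(
                    f"measurement days for {p.value} fall outside [{start}, {end}]"
                )
            if list(days) != sorted(set(days)):
                raise InvalidArgumentError(
                    f"measurement days for {p.value} must be strictly increasing"
                )

    @property
    def phases(self) -> tuple[Phase, ...]:
        return tuple(p for p in PHASE_ORDER if p in self.phase_bounds)

    def start(self, phase: Phase) -> int:
        return self.phase_bounds[phase][0]

    def end(self, phase: Phase) -> int:
        return self.phase_bounds[phase][1]


class NeeSeries:
    """Per-mesocosm NEE time series tagged by phase and day.

    Days are strictly increasing within each phase (recovery days may
    be re-indexed to a phase-local origin by alignment, so global
    monotonicity is not required).
    """

    __slots__ = ("mesocosm_id", "composition", "treatment", "days", "phases", "nee")

    def __init__(
        self,
        mesocosm_id: str,
        composition: MixtureComposition,
        treatment: Treatment,
        days: Sequence[int],
        phases: Sequence[Phase],
        nee: Sequence[float],
    ):
        self.mesocosm_id = mesocosm_id
        self.composition = composition
        self.treatment = treatment
        self.days = np.asarray(days, dtype=int)
        self.phases = np.asarray([Phase(p) for p in phases], dtype=object)
        self.nee = np.asarray(nee, dtype=float)
        if not (len(self.days) == len(self.phases) == len(self.nee)):
            raise InvalidArgumentError("days, phases and nee must have equal length")
        for p in PHASE_ORDER:
            d = self.phase_days(p)
            if d.size > 1 and not np.all(np.diff(d) > 0):
                raise InvalidArgumentError(
                    f"days within phase {p.value} must be strictly increasing"
                )

    def __len__(self) -> int:
        return len(self.days)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"NeeSeries({self.mesocosm_id!r}, {self.composition.label}, "
            f"{self.treatment.value}, n={len(self)})"
        )

    def phase_mask(self, phase: Phase) -> np.ndarray:
        """Boolean mask of records belonging to ``phase``.

        Comparison is by enum identity (numpy would otherwise coerce a
        str-enum scalar to its ``str()`` form).
        """
        phase = Phase(phase)
        return np.fromiter((p is phase for p in self.phases), dtype=bool,
                           count=len(self.phases))

    def has_phase(self, phase: Phase) -> bool:
        return bool(self.phase_mask(phase).any())

    def phase_days(self, phase: Phase) -> np.ndarray:
        return self.days[self.phase_mask(phase)]

    def phase_values(self, phase: Phase) -> np.ndarray:
        return self.nee[self.phase_mask(phase)]

    def records(self) -> Iterator[tuple[int, Phase, float]]:
        yield from zip(self.days.tolist(), self.phases.tolist(), self.nee.tolist())

    def with_days(self, days: Sequence[int]) -> "NeeSeries":
        """Copy of this series with replaced day indices."""
        return NeeSeries(
            self.mesocosm_id, self.composition, self.treatment,
            days, self.phases, self.nee,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: mesocosm_id, day, phase, nee_umol_m2_s."""
        return pd.DataFrame(
            {
                "mesocosm_id": self.mesocosm_id,
                "day": self.days,
                "phase": [p.value for p in self.phases],
                "nee_umol_m2_s": self.nee,
            }
        )
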
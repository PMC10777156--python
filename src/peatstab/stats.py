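"""Group-level inference on per-mesocosm response slopes and stability
metrics: slope summary tables, classical one-way ANOVA, Tukey HSD
pairwise contrasts, recovery-period alignment, and a repeated-measures
mixed-model convenience fit.

The mild drawdown week is shared by both treatment arms, so mild-phase
analyses pool all replicates per mixture (n = 8 in the full design);
deep-phase analyses use the deep arm only (n = 4, one cell n = 3 after
the configured dropout).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DESIGN_FRACTIONS, MesocosmRecord, NeeSeries, Phase, Treatment
from .errors import InvalidArgumentError, MissingPhaseError
from .stability import StabilityResult


def align_recovery(series: Sequence[NeeSeries]) -> list[NeeSeries]:
    """Re-index recovery days to a common origin across arms.

    The two arms start rewetting on different calendar days; for joint
    analysis each series' recovery records are re-zeroed to its own
    first recovery measurement.  All other phases, record counts and
    NEE values are untouched.  Raises :class:`MissingPhaseError` for a
    series without recovery records.
    """
    out: list[NeeSeries] = []
    for s in series:
        rec_days = s.phase_days(Phase.RECOVERY)
        if rec_days.size == 0:
            raise MissingPhaseError(Phase.RECOVERY, s.mesocosm_id)
        days = s.days.copy()
        days[s.phase_mask(Phase.RECOVERY)] = rec_days - rec_days.min()
        out.append(s.with_days(days))
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- standard error of member slopes for one design cell."""

    cuspidatum_fraction: float
    treatment: Treatment | None  # None when arms are pooled
    phase: Phase
    mean_slope: float
    stderr: float  # sample SD / sqrt(n); NaN when n = 1
    n: int


def group_slope_table(
    results: Sequence[StabilityResult],
    design: Sequence[MesocosmRecord],
    phase: Phase,
) -> list[GroupSummary]:
    """Per-mixture slope summaries for one phase.

    Drawdown phases pool every mesocosm that experienced them (the
    mild week: both arms; the deep phase: deep arm only), grouping by
    composition.  Recovery differs between arms, so recovery summaries
    are additionally split by treatment.  Raises ``KeyError`` for a
    result whose mesocosm id is not in the design.
    """
    phase = Phase(phase)
    by_id = {r.mesocosm_id: r for r in design}
    members: dict[tuple[float, Treatment | None], list[float]] = {}
    for res in results:
        if res.mesocosm_id not in by_id:
            raise KeyError(f"mesocosm id {res.mesocosm_id!r} not in design")
        if phase not in res.phase_slopes:
            continue
        rec = by_id[res.mesocosm_id]
        tr = rec.treatment if phase is Phase.RECOVERY else None
        key = (rec.composition.cuspidatum_fraction, tr)
        members.setdefault(key, []).append(res.phase_slopes[phase][0])
    out: list[GroupSummary] = []
    treatments: tuple[Treatment | None, ...] = (
        (Treatment.MILD, Treatment.DEEP) if phase is Phase.RECOVERY else (None,)
    )
    for frac in DESIGN_FRACTIONS:
        for tr in treatments:
            if (frac, tr) not in members:
                continue
            vals = np.asarray(members[(frac, tr)], dtype=float)
            n = vals.size
            stderr = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            out.append(GroupSummary(frac, tr, phase, float(vals.mean()), stderr, n))
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Classical equal-variance one-way ANOVA."""

    factor: str
    df_between: int
    df_within: int
    f_statistic: float  # math.inf marks zero within-group variance
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float


def oneway_anova(
    values: Sequence[float], groups: Sequence, factor: str = "group"
) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares definitions.

    ``F = (SS_between / df_between) / (SS_within / df_within)`` with the
    p-value from the F distribution.  Requires >= 2 groups with >= 2
    members each.  Zero within-group variance yields an infinite-F
    marker with p = 0.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if y.size != g.size:
        raise InvalidArgumentError("values and groups must have equal length")
    labels = list(dict.fromkeys(g.tolist()))  # preserve first-seen order
    if len(labels) < 2:
        raise InvalidArgumentError("ANOVA needs at least two groups")
    chunks = [y[g == lab] for lab in labels]
    if any(c.size < 2 for c in chunks):
        raise InvalidArgumentError("every group needs at least two members")
    grand = y.mean()
    ss_between = float(sum(c.size * (c.mean() - grand) ** 2 for c in chunks))
    ss_within = float(sum(((c - c.mean()) ** 2).sum() for c in chunks))
    ss_total = float(((y - grand) ** 2).sum())
    df_between = len(labels) - 1
    df_within = int(y.size) - len(labels)
    if ss_within == 0.0:
        # all-equal data is a zero effect, not an infinite one
        f_stat, p = (0.0, 1.0) if ss_between == 0.0 else (math.inf, 0.0)
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(factor, df_between, df_within, float(f_stat), p,
                       ss_between, ss_within, ss_total)


@dataclass(frozen=True)
class Contrast:
    """One Tukey HSD pairwise comparison."""

    group_a: str
    group_b: str
    estimate: float  # mean(b) - mean(a)
    p_adjusted: float


def pairwise_contrasts(
    values: Sequence[float], groups: Sequence, method: str = "tukey"
) -> list[Contrast]:
    """All-pairs contrasts with familywise adjustment.

    Only Tukey's HSD (studentized-range adjustment) is offered; the
    heavy lifting is statsmodels' ``pairwise_tukeyhsd``.
    """
    if method != "tukey":
        raise InvalidArgumentError(f"unsupported contrast method {method!r}")
    # validate grouping with the same rules as the ANOVA
    oneway_anova(values, groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float),
                            np.asarray([str(x) for x in groups]))
    pairs = list(itertools.combinations(res.groupsunique.tolist(), 2))
    return [
        Contrast(a, b, float(est), float(p))
        for (a, b), est, p in zip(pairs, res.meandiffs, res.pvalues)
    ]


def series_to_frame(series: Sequence[NeeSeries]) -> pd.DataFrame:
    """Long-format frame of many series with design columns attached."""
    frames = []
    for s in series:
        f = s.to_frame()
        f["cuspidatum_fraction"] = s.composition.cuspidatum_fraction
        f["mixture"] = s.composition.label
        f["treatment"] = s.treatment.value
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def fit_repeated_measures(
    series: Sequence[NeeSeries],
    phase: Phase,
    formula: str = "nee_umol_m2_s ~ day * C(mixture)",
):
    """Repeated-measures mixed model within one phase (convenience).

    Fits ``formula`` with a random intercept per mesocosm via
    statsmodels ``MixedLM`` — a pragmatic stand-in for a full
    repeated-measures specification; the implemented inference surface
    of this package is the per-mesocosm slope + ANOVA path.  Returns
    the fitted results object.
    """
    import statsmodels.formula.api as smf

    frame = series_to_frame(series)
    frame = frame[frame["phase"] == Phase(phase).value].copy()
    frame["day"] = frame["day"] - frame["day"].min()
    model = smf.mixedlm(formula, frame, groups=frame["mesocosm_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=True)
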
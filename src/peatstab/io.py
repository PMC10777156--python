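"""CSV readers/writers for the pipeline's plain-text interchange files.

Schemas
-------
``design.csv``      mesocosm_id, cuspidatum_fraction, treatment, replicate
``nee_series.csv``  mesocosm_id, day, phase, nee_umol_m2_s
``stability.csv``   one row per mesocosm with all stability statistics
``traces/<id>_<day>.csv``  time_s, co2_ppm
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import MesocosmRecord, MixtureComposition, NeeSeries, Phase, Treatment
from .flux import ChamberSpec, ConcentrationTrace
from .stability import DELTA_INFINITE, OMEGA_INFINITE, StabilityResult


def write_design(design: Sequence[MesocosmRecord], path) -> None:
    pd.DataFrame(
        {
            "mesocosm_id": [r.mesocosm_id for r in design],
            "cuspidatum_fraction": [r.composition.cuspidatum_fraction for r in design],
            "treatment": [r.treatment.value for r in design],
            "replicate": [r.replicate for r in design],
        }
    ).to_csv(path, index=False)


def read_design(path) -> list[MesocosmRecord]:
    df = pd.read_csv(path)
    return [
        MesocosmRecord(
            str(row.mesocosm_id),
            MixtureComposition.from_cuspidatum(float(row.cuspidatum_fraction)),
            Treatment(row.treatment),
            int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_nee_series(series: Sequence[NeeSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def read_nee_series(path, design: Sequence[MesocosmRecord]) -> list[NeeSeries]:
    """Join a long-format NEE table back onto design records."""
    df = pd.read_csv(path)
    by_id = {r.mesocosm_id: r for r in design}
    out = []
    for mid, grp in df.groupby("mesocosm_id", sort=False):
        rec = by_id[str(mid)]
        out.append(
            NeeSeries(
                rec.mesocosm_id,
                rec.composition,
                rec.treatment,
                grp["day"].astype(int).tolist(),
                [Phase(p) for p in grp["phase"]],
                grp["nee_umol_m2_s"].astype(float).tolist(),
            )
        )
    return out


def trace_filename(mesocosm_id: str, day: int) -> str:
    return f"{mesocosm_id}_{day}.csv"


def write_trace(trace: ConcentrationTrace, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / trace_filename(trace.mesocosm_id, trace.day)
    pd.DataFrame({"time_s": trace.time_s, "co2_ppm": trace.co2_ppm}).to_csv(path, index=False)
    return path


def read_trace(path, chamber: ChamberSpec | None = None) -> ConcentrationTrace:
    """Read one trace CSV; mesocosm id and day are parsed from the name."""
    path = Path(path)
    stem = path.stem
    mesocosm_id, _, day = stem.rpartition("_")
    df = pd.read_csv(path)
    return ConcentrationTrace(
        df["time_s"].to_numpy(), df["co2_ppm"].to_numpy(),
        chamber=chamber, mesocosm_id=mesocosm_id, day=int(day),
    )


def stability_frame(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """Tabular view of stability results (flags as booleans).

    Infinite omega/delta markers are written as empty cells with their
    flag column set, so the CSV stays numeric.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "mesocosm_id": r.mesocosm_id,
                "cuspidatum_fraction": r.composition.cuspidatum_fraction,
                "treatment": r.treatment.value,
                "nee_acc_mean": r.nee_acc_mean,
                "nee_d": r.nee_d,
                "nee_rec": r.nee_rec,
                "omega": r.omega if math.isfinite(r.omega) else math.nan,
                "delta": r.delta if math.isfinite(r.delta) else math.nan,
                "drawdown_slope": r.drawdown_slope,
                "drawdown_slope_stderr": r.drawdown_slope_stderr,
                "recovery_rate": r.recovery_rate,
                "recovery_rate_stderr": r.recovery_rate_stderr,
                "omega_infinite": OMEGA_INFINITE in r.degenerate_flags,
                "delta_infinite": DELTA_INFINITE in r.degenerate_flags,
            }
        )
    return pd.DataFrame(rows)


def write_stability(results: Sequence[StabilityResult], path) -> None:
    stability_frame(results).to_csv(path, index=False)
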
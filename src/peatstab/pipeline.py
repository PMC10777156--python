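"""End-to-end pipeline: simulate (or ingest) -> flux -> stability -> stats.

``run_pipeline`` executes the whole chain from a single configuration
mapping (or YAML file) and writes the interchange CSVs plus a
machine-readable run log.  Three entry points are supported, mirroring
how real campaigns arrive: a generator configuration (synthetic run),
a directory of raw chamber traces, or a ready-made NEE series CSV.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .core import DESIGN_FRACTIONS, NeeSeries, Phase, Treatment
from .errors import ConfigurationError, PipelineError
from .flux import ChamberSpec, batch_fluxes
from .stability import DELTA_INFINITE, OMEGA_INFINITE, StabilityResult, summarize_all
from .stats import group_slope_table, oneway_anova, pairwise_contrasts
from .synth import (
    GeneratorConfig,
    apply_missingness,
    build_design,
    default_schedules,
    generate_concentration_trace,
    generate_nee_series,
)

#: The design cell the default run drops, emulating the one
#: leaking-container exclusion (a deep-arm 75/25 mesocosm).
DEFAULT_DROP = "DD_75-25_r1"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_replicates": 4,
    "noise_sd": None,  # None -> generator default
    "drop_mesocosm": DEFAULT_DROP,
    "simulate_traces": False,
    "trace_noise_sd_ppm": 0.0,
    "ambient_co2": 420.0,
    "dead_band_s": 30.0,
    "write_traces": False,
    "chamber": {},
    "baseline_nee": None,
    "mild_slopes": None,
    "deep_slopes": None,
    "recovery_slopes": None,
    "rewet_to_baseline": None,
    "nee_csv": None,
    "design_csv": None,
    "traces_dir": None,
}


def load_config(source: Mapping[str, Any] | str | Path | None) -> dict[str, Any]:
    """Merge a mapping or YAML file over the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
    else:
        loaded = dict(source)
    unknown = set(loaded) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def _generator_config(cfg: Mapping[str, Any], seed: int) -> GeneratorConfig:
    gen = GeneratorConfig.default(seed=seed, n_replicates=int(cfg["n_replicates"]))
    if cfg["noise_sd"] is not None:
        gen.noise_sd = float(cfg["noise_sd"])
    if cfg["baseline_nee"] is not None:
        gen.baseline_nee = {float(k): float(v) for k, v in cfg["baseline_nee"].items()}
    for key, phase, arms in (
        ("mild_slopes", Phase.MILD_DRAWDOWN, (Treatment.MILD, Treatment.DEEP)),
        ("deep_slopes", Phase.DEEP_DRAWDOWN, (Treatment.DEEP,)),
    ):
        if cfg[key] is not None:
            for frac, val in cfg[key].items():
                for arm in arms:
                    gen.phase_slope[(float(frac), arm, phase)] = float(val)
    if cfg["recovery_slopes"] is not None:
        for arm_label, val in cfg["recovery_slopes"].items():
            arm = Treatment(arm_label)
            per_frac = val if isinstance(val, Mapping) else {f: val for f in DESIGN_FRACTIONS}
            for frac, v in per_frac.items():
                gen.phase_slope[(float(frac), arm, Phase.RECOVERY)] = float(v)
    if cfg["rewet_to_baseline"] is not None:
        gen.rewet_to_baseline = {
            Treatment(k): bool(v) for k, v in cfg["rewet_to_baseline"].items()
        }
    drop = cfg["drop_mesocosm"]
    gen.drop_mesocosm = None if drop in (None, "", "none") else str(drop)
    return gen


def _roundtrip_through_traces(
    series: Sequence[NeeSeries],
    cfg: Mapping[str, Any],
    out_dir: Path | None,
) -> list[NeeSeries]:
    """Replace each NEE value by its trace -> flux reconstruction."""
    chamber = ChamberSpec(**cfg["chamber"])
    replaced = []
    for i, s in enumerate(series):
        traces = [
            generate_concentration_trace(
                nee,
                chamber=chamber,
                ambient_co2=float(cfg["ambient_co2"]),
                noise_sd_ppm=float(cfg["trace_noise_sd_ppm"]),
                seed=i * 10_000 + j,
                mesocosm_id=s.mesocosm_id,
                day=int(day),
            )
            for j, (day, nee) in enumerate(zip(s.days, s.nee))
        ]
        if out_dir is not None and cfg["write_traces"]:
            for tr in traces:
                io.write_trace(tr, out_dir / "traces")
        results, failures = batch_fluxes(traces, float(cfg["dead_band_s"]))
        if failures:
            raise ConfigurationError(f"trace round-trip failed for {failures[0]}")
        by_day = {r.day: r.nee for r in results}
        replaced.append(
            NeeSeries(s.mesocosm_id, s.composition, s.treatment,
                      s.days, s.phases, [by_day[int(d)] for d in s.days])
        )
    return replaced


def _group_frame(results, design, phases) -> pd.DataFrame:
    rows = []
    for phase in phases:
        for g in group_slope_table(results, design, phase):
            rows.append(
                {
                    "phase": g.phase.value,
                    "cuspidatum_fraction": g.cuspidatum_fraction,
                    "treatment": g.treatment.value if g.treatment else "pooled",
                    "mean_slope": g.mean_slope,
                    "stderr": g.stderr,
                    "n": g.n,
                }
            )
    return pd.DataFrame(rows)


def _anova_frame(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """One-way ANOVAs of slopes and stability metrics across mixtures."""
    rows = []

    def add(name: str, values: list[float], groups: list[str]) -> None:
        vals = np.asarray(values, float)
        labs = np.asarray(groups, object)
        keep = np.isfinite(vals)
        try:
            res = oneway_anova(vals[keep], labs[keep], factor=name)
        except Exception:
            return  # a cell emptied by flags/dropout: no valid test
        rows.append(
            {
                "response": name,
                "factor": "mixture",
                "df_between": res.df_between,
                "df_within": res.df_within,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "n_excluded": int((~keep).sum()),
            }
        )

    mild = [r for r in results if Phase.MILD_DRAWDOWN in r.phase_slopes]
    add("mild_drawdown_slope",
        [r.phase_slopes[Phase.MILD_DRAWDOWN][0] for r in mild],
        [r.composition.label for r in mild])
    deep = [r for r in results if Phase.DEEP_DRAWDOWN in r.phase_slopes]
    add("deep_drawdown_slope",
        [r.phase_slopes[Phase.DEEP_DRAWDOWN][0] for r in deep],
        [r.composition.label for r in deep])
    for arm in Treatment:
        sub = [r for r in results if r.treatment is arm]
        add(f"recovery_rate_{arm.value}",
            [r.recovery_rate for r in sub], [r.composition.label for r in sub])
        add(f"omega_{arm.value}",
            [r.omega if math.isfinite(r.omega) else math.nan for r in sub],
            [r.composition.label for r in sub])
        add(f"delta_{arm.value}",
            [r.delta if math.isfinite(r.delta) else math.nan for r in sub],
            [r.composition.label for r in sub])
    return pd.DataFrame(rows)


def _contrast_frame(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """Tukey HSD on deep-phase slopes across mixtures."""
    deep = [r for r in results if Phase.DEEP_DRAWDOWN in r.phase_slopes]
    if not deep:
        return pd.DataFrame(columns=["group_a", "group_b", "estimate", "p_adjusted"])
    contrasts = pairwise_contrasts(
        [r.phase_slopes[Phase.DEEP_DRAWDOWN][0] for r in deep],
        [r.composition.label for r in deep],
    )
    return pd.DataFrame(
        [
            {"group_a": c.group_a, "group_b": c.group_b,
             "estimate": c.estimate, "p_adjusted": c.p_adjusted}
            for c in contrasts
        ]
    )


def _stability_groups_frame(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """Group means of the stability metrics, flagged values excluded."""
    rows = []
    for frac in DESIGN_FRACTIONS:
        for arm in Treatment:
            sub = [r for r in results
                   if r.composition.cuspidatum_fraction == frac and r.treatment is arm]
            if not sub:
                continue
            omega = np.array([r.omega for r in sub if math.isfinite(r.omega)])
            delta = np.array([r.delta for r in sub if math.isfinite(r.delta)])
            rows.append(
                {
                    "cuspidatum_fraction": frac,
                    "treatment": arm.value,
                    "n": len(sub),
                    "omega_mean": omega.mean() if omega.size else math.nan,
                    "omega_sd": omega.std(ddof=1) if omega.size > 1 else math.nan,
                    "n_omega_infinite": sum(OMEGA_INFINITE in r.degenerate_flags for r in sub),
                    "delta_mean": delta.mean() if delta.size else math.nan,
                    "delta_sd": delta.std(ddof=1) if delta.size > 1 else math.nan,
                    "n_delta_infinite": sum(DELTA_INFINITE in r.degenerate_flags for r in sub),
                    "recovery_rate_mean": float(np.mean([r.recovery_rate for r in sub])),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: Mapping[str, Any] | str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full chain and (optionally) write the report bundle.

    Returns a dict with the design, series, stability results and all
    report frames.  A stage failure raises :class:`PipelineError`
    naming the stage; outputs written by earlier stages are retained.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    gen = stage("configure", _generator_config, cfg, int(cfg["seed"]))

    if cfg["design_csv"]:
        design = stage("design", io.read_design, cfg["design_csv"])
    else:
        design = stage("design", build_design, gen.n_replicates, gen.seed)

    entry = "simulate"
    if cfg["nee_csv"]:
        entry = "nee_csv"
        series = stage("ingest", io.read_nee_series, cfg["nee_csv"], design)
    elif cfg["traces_dir"]:
        entry = "traces"
        series = stage("flux", _ingest_traces, cfg, design)
    else:
        series = stage("simulate", generate_nee_series, design, None, gen)
        if cfg["simulate_traces"]:
            series = stage("flux", _roundtrip_through_traces, series, cfg, out)

    if gen.drop_mesocosm and entry == "simulate":
        series = stage("missingness", apply_missingness, series, gen.drop_mesocosm)

    if out is not None:
        io.write_design(design, out / "design.csv")
        io.write_nee_series(series, out / "nee_series.csv")

    results = stage("stability", summarize_all, series)
    slopes = stage(
        "report", _group_frame, results, design,
        (Phase.MILD_DRAWDOWN, Phase.DEEP_DRAWDOWN, Phase.RECOVERY),
    )
    anova = stage("report", _anova_frame, results)
    contrasts = stage("report", _contrast_frame, results)
    groups = stage("report", _stability_groups_frame, results)

    log = {
        "peatstab_version": __version__,
        "seed": int(cfg["seed"]),
        "entry_point": entry,
        "n_mesocosms": len(series),
        "dropped": gen.drop_mesocosm,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if out is not None:
        io.write_stability(results, out / "stability.csv")
        slopes.to_csv(out / "table1_slopes.csv", index=False)
        anova.to_csv(out / "anova.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        groups.to_csv(out / "stability_groups.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return {
        "config": cfg,
        "design": design,
        "series": series,
        "stability": results,
        "slope_table": slopes,
        "anova": anova,
        "contrasts": contrasts,
        "stability_groups": groups,
        "run_log": log,
    }


def _ingest_traces(cfg: Mapping[str, Any], design) -> list[NeeSeries]:
    """Entry point from a directory of raw trace CSVs."""
    chamber = ChamberSpec(**cfg["chamber"])
    paths = sorted(Path(cfg["traces_dir"]).glob("*.csv"))
    traces = [io.read_trace(p, chamber) for p in paths]
    results, failures = batch_fluxes(traces, float(cfg["dead_band_s"]))
    if failures:
        raise ConfigurationError(
            f"{len(failures)} trace(s) failed flux fitting, first: {failures[0]}"
        )
    schedules = default_schedules()
    by_id = {r.mesocosm_id: r for r in design}
    frames: dict[str, list] = {}
    for r in results:
        frames.setdefault(r.mesocosm_id, []).append((r.day, r.nee))
    out = []
    for mid, rows in frames.items():
        rec = by_id[mid]
        sched = schedules[rec.treatment]
        day_phase = {d: p for p in sched.phases for d in sched.measurement_days[p]}
        rows.sort()
        out.append(
            NeeSeries(mid, rec.composition, rec.treatment,
                      [d for d, _ in rows],
                      [day_phase[d] for d, _ in rows],
                      [v for _, v in rows])
        )
    return out
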
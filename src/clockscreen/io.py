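"""Table ingestion and the full screen pipeline.

Canonical interchange is CSV. Luminescence tables are long-format with
columns ``experiment_id, population_id, plant_id, time_h, intensity`` (plus
optional ``is_control``); a separate layout table may instead map
``plant_id -> (experiment_id, population_id, is_control)``. All hour values
are decimal hours since the first dawn of constant light (0-based).

:func:`run_full_screen` chains the stages — per-plant FFT-NLLS fits,
batch-level QC on control-period spread, control-mean normalization,
histogram subpopulation detection on period differences, and Welch/Bonferroni
hit calling for period (vs wildtype pool) and phase (vs all-decoys pool) —
and emits a JSON-able run manifest with the configuration and the counts at
every filter, so identical inputs and configuration reproduce identical
outputs. No plant is dropped silently: every exclusion is logged and
reconciled in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .rhythm import (
    DegenerateInputError,
    Trace,
    classify_rhythmicity,
    fit_fftnlls,
)
from .screen import EmptyControlError, ScreenBatch, call_hits, normalize, qc_filter
from .subpop import SubpopPartition, detect_subpopulations

logger = logging.getLogger("clockscreen.io")

__all__ = [
    "ParseError",
    "PipelineResult",
    "read_trace_table",
    "read_layout_table",
    "read_fit_table",
    "fit_traces",
    "build_batches",
    "run_full_screen",
    "write_result",
]

TRACE_COLUMNS = ["experiment_id", "population_id", "plant_id", "time_h", "intensity"]
LAYOUT_COLUMNS = ["plant_id", "experiment_id", "population_id", "is_control"]
FIT_COLUMNS = [
    "experiment_id",
    "population_id",
    "plant_id",
    "is_control",
    "period_h",
    "phase_h",
    "amplitude",
    "rae",
    "rhythmic",
    "convergence_flag",
    "status",
]


class ParseError(ValueError):
    """Malformed input table; the message names the offending row."""


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(("true", "1", "yes"))


def read_layout_table(path: str | Path) -> pd.DataFrame:
    """Layout CSV: plant_id -> (experiment_id, population_id, is_control)."""
    df = pd.read_csv(path)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"layout {path}: missing columns {sorted(missing)}")
    if df["plant_id"].duplicated().any():
        dup = df.loc[df["plant_id"].duplicated(), "plant_id"].iloc[0]
        raise ParseError(f"layout {path}: plant {dup} listed more than once")
    df["is_control"] = _as_bool(df["is_control"])
    return df[LAYOUT_COLUMNS]


def read_trace_table(
    path: str | Path, layout: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a long-format luminescence CSV.

    Returns ``(traces, layout)``. Control status comes from an ``is_control``
    column when present, otherwise from the supplied layout table. Duplicate
    ``(plant_id, time_h)`` rows and non-numeric values raise :class:`ParseError`
    naming the plant and hour/row.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"trace table {path}: missing columns {sorted(missing)}")
    for col in ("time_h", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"trace table {path}: non-numeric {col} {df[col].iloc[i]!r} "
                f"in row {i + 2} (plant {df['plant_id'].iloc[i]})"
            )
        if coerced.isna().any():
            i = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(
                f"trace table {path}: missing {col} in row {i + 2} "
                f"(plant {df['plant_id'].iloc[i]})"
            )
        df[col] = coerced
    dup = df.duplicated(subset=["plant_id", "time_h"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ParseError(
            f"trace table {path}: duplicated timepoint {row['time_h']} h "
            f"for plant {row['plant_id']}"
        )
    if layout is None:
        if "is_control" in df.columns:
            df["is_control"] = _as_bool(df["is_control"])
            layout = (
                df[LAYOUT_COLUMNS].drop_duplicates(subset="plant_id").reset_index(drop=True)
            )
        else:
            raise ParseError(
                f"trace table {path}: no is_control column and no layout table given"
            )
    return df[TRACE_COLUMNS].copy(), layout


def read_fit_table(path: str | Path) -> pd.DataFrame:
    """Per-plant rhythm-metric CSV (accepts published source-data layouts)."""
    df = pd.read_csv(path)
    required = {"experiment_id", "population_id", "plant_id", "is_control", "period_h"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"fit table {path}: missing columns {sorted(missing)}")
    df["is_control"] = _as_bool(df["is_control"])
    for optional, default in (("phase_h", np.nan), ("rae", np.nan)):
        if optional not in df.columns:
            df[optional] = default
    return df


def fit_traces(traces: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """FFT-NLLS every plant in a long-format trace table.

    Returns one row per plant with period/phase/amplitude/RAE, a
    rhythmicity call, and a status of ``fit`` or ``failed`` (degenerate or
    non-convergent traces are kept, flagged, and excluded downstream).
    """
    config = config or RunConfig()
    rows = []
    for (exp_id, pop_id, plant_id), grp in traces.groupby(
        ["experiment_id", "population_id", "plant_id"], sort=True
    ):
        grp = grp.sort_values("time_h")
        is_control = bool(grp["is_control"].iloc[0]) if "is_control" in grp.columns else False
        row = {
            "experiment_id": exp_id,
            "population_id": pop_id,
            "plant_id": plant_id,
            "is_control": is_control,
        }
        try:
            trace = Trace(
                plant_id=str(plant_id),
                times=grp["time_h"].to_numpy(dtype=float),
                values=grp["intensity"].to_numpy(dtype=float),
            ).validate()
            fit = fit_fftnlls(
                trace,
                window=config.window,
                alpha_component=config.alpha_component,
                max_components=config.max_components,
            )
        except (DegenerateInputError, ValueError) as exc:
            logger.warning("plant %s: fit failed (%s)", plant_id, exc)
            row.update(
                period_h=np.nan, phase_h=np.nan, amplitude=np.nan, rae=np.nan,
                rhythmic=False, convergence_flag=False, status="failed",
            )
            rows.append(row)
            continue
        rhythmic = classify_rhythmicity(fit, cutoff=config.rae_cutoff) == "rhythmic"
        row.update(
            period_h=fit.period,
            phase_h=fit.phase,
            amplitude=fit.amplitude,
            rae=fit.rae,
            rhythmic=rhythmic,
            convergence_flag=fit.converged,
            status="fit" if fit.converged else "failed",
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def build_batches(fits: pd.DataFrame) -> list[ScreenBatch]:
    """Group a per-plant fit table into one ScreenBatch per experiment."""
    batches = []
    for exp_id, grp in fits.groupby("experiment_id", sort=True):
        batches.append(ScreenBatch(experiment_id=str(exp_id), plants=grp.reset_index(drop=True)))
    return batches


PARTITION_COLUMNS = ["population_id", "subpop_index", "plant_id", "mean_diff", "n"]


def _partitions_table(partitions: dict[str, SubpopPartition]) -> pd.DataFrame:
    rows = []
    for pop, part in sorted(partitions.items()):
        for k, grp in enumerate(part.groups):
            for pid in grp.plant_ids:
                rows.append(
                    {
                        "population_id": pop,
                        "subpop_index": k,
                        "plant_id": pid,
                        "mean_diff": grp.mean_diff,
                        "n": grp.n,
                    }
                )
    return pd.DataFrame(rows, columns=PARTITION_COLUMNS)


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    normalized: pd.DataFrame
    partitions: pd.DataFrame
    hits: pd.DataFrame
    manifest: dict


def run_full_screen(
    config: RunConfig,
    traces: pd.DataFrame | None = None,
    fits: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the complete screen: fit, QC, normalize, subpopulations, hits.

    Provide either a long-format ``traces`` table (fitted here) or a
    precomputed per-plant ``fits`` table (e.g. published source data). The
    manifest reconciles every count: input plants = fit + failed; fit =
    rhythmic + arrhythmic; QC-failing batches contribute no statistics. If
    every batch fails QC the hit table is empty and the manifest carries a
    prominent warning.
    """
    if (traces is None) == (fits is None):
        raise ValueError("provide exactly one of traces or fits")
    if traces is not None:
        fits = fit_traces(traces, config)
    assert fits is not None
    if "status" not in fits.columns:
        fits = fits.copy()
        fits["status"] = np.where(fits["period_h"].notna(), "fit", "failed")
    if "rhythmic" not in fits.columns:
        fits = fits.copy()
        fits["rhythmic"] = ~(fits["rae"] > config.rae_cutoff) & fits["period_h"].notna()

    manifest: dict = {"config": config.to_dict(), "counts": {}, "warnings": []}
    counts = manifest["counts"]
    counts["plants_input"] = int(len(fits))
    counts["plants_fit"] = int((fits["status"] == "fit").sum())
    counts["plants_failed"] = int((fits["status"] == "failed").sum())
    fitted = fits[fits["status"] == "fit"]
    counts["plants_rhythmic"] = int(fitted["rhythmic"].sum())
    counts["plants_arrhythmic"] = int((~fitted["rhythmic"]).sum())

    batches = [qc_filter(b, sd_cutoff=config.sd_cutoff) for b in build_batches(fits)]
    passing = [b for b in batches if b.qc_pass]
    counts["batches_total"] = len(batches)
    counts["batches_qc_pass"] = len(passing)
    counts["plants_excluded_qc"] = int(
        sum(len(b.plants) for b in batches if not b.qc_pass)
    )
    manifest["qc"] = {b.experiment_id: {"pass": bool(b.qc_pass), "reason": b.qc_reason} for b in batches}

    fits = fits.copy()
    qc_fail_exps = {b.experiment_id for b in batches if not b.qc_pass}
    fits.loc[fits["experiment_id"].astype(str).isin(qc_fail_exps), "status"] = "excluded-QC"

    if not passing:
        warning = "every batch failed QC; no statistics computed"
        logger.warning(warning)
        manifest["warnings"].append(warning)
        empty_hits = pd.DataFrame(
            columns=[
                "population_id", "subpop_index", "metric", "n", "mean_diff",
                "p_value", "alpha_corrected", "significant", "effect_class", "reason",
            ]
        )
        return PipelineResult(
            fits=fits,
            normalized=pd.DataFrame(
                columns=["plant_id", "population_id", "experiment_id", "metric", "diff", "is_control"]
            ),
            partitions=pd.DataFrame(columns=PARTITION_COLUMNS),
            hits=empty_hits,
            manifest=manifest,
        )

    normalized_frames = []
    for metric in ("period", "phase"):
        for b in passing:
            try:
                normalized_frames.append(normalize(b, metric, rae_cutoff=config.rae_cutoff))
            except EmptyControlError as exc:
                manifest["warnings"].append(str(exc))
    normalized = pd.concat(normalized_frames, ignore_index=True)

    norm_period = normalized[normalized["metric"] == "period"]
    norm_phase = normalized[normalized["metric"] == "phase"]

    # subpopulation detection on period differences, per decoy population
    partitions: dict[str, SubpopPartition] = {}
    for pop, grp in norm_period[~norm_period["is_control"]].groupby("population_id", sort=True):
        partitions[str(pop)] = detect_subpopulations(
            grp["diff"].to_numpy(dtype=float),
            plant_ids=grp["plant_id"].to_numpy(),
            bin_width=config.bin_width,
            min_n=config.min_n,
            min_prominence=config.min_prominence,
            min_separation_bins=config.min_separation_bins,
        )
    counts["populations_multimodal"] = int(sum(p.is_multimodal for p in partitions.values()))

    hits_period = call_hits(
        norm_period,
        metric="period",
        control_mode="wildtype",
        alpha_family=config.alpha_family,
        partitions=partitions,
        major_cutoff=config.period_major_cutoff,
    )
    hits_phase = call_hits(
        norm_phase,
        metric="phase",
        control_mode="all_decoys",
        alpha_family=config.alpha_family,
        major_cutoff=config.phase_major_cutoff,
    )
    hits = pd.concat([hits_period, hits_phase], ignore_index=True)

    # populations with two or more arrhythmic plants may ablate clock function
    arr_counts = (
        fitted[~fitted["is_control"]].groupby("population_id")["rhythmic"].agg(lambda s: int((~s).sum()))
    )
    candidates = set(arr_counts[arr_counts >= 2].index.astype(str))
    if candidates:
        mask = hits["population_id"].astype(str).isin(candidates) & hits["subpop_index"].isna()
        hits.loc[mask, "effect_class"] = "arrhythmic-candidate"
    counts["populations_arrhythmic_candidate"] = len(candidates)

    counts["populations_tested_period"] = int(
        hits_period["subpop_index"].isna().sum()
    )
    counts["populations_tested_phase"] = int(hits_phase["subpop_index"].isna().sum())
    counts["subpopulations_tested"] = int(hits_period["subpop_index"].notna().sum())

    return PipelineResult(
        fits=fits,
        normalized=normalized,
        partitions=_partitions_table(partitions),
        hits=hits,
        manifest=manifest,
    )


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    """Write stage CSVs and the JSON run manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.normalized.to_csv(outdir / "normalized.csv", index=False)
    result.partitions.to_csv(outdir / "partitions.csv", index=False)
    result.hits.to_csv(outdir / "hits.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
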
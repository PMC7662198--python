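"""End-to-end orchestration: records -> assemblages -> metrics -> reports.

A run is driven by one YAML config and writes a directory of tidy CSV
tables plus a JSON manifest recording the config snapshot, input file
digests, package version, seeds and thresholds.  Result tables are
deterministic under a fixed config and seed; the manifest additionally
carries timestamps and is the only non-deterministic output.

Stages (each emitting a CSV that the next stage could re-read):

1. read/simulate + harmonize + pool  -> annual_matrix.csv, series_summary.csv
2. diversity + turnover              -> diversity.csv, turnover_consecutive.csv,
                                        turnover_all_pairs.csv
3. trends                            -> trends.csv, trend_counts.csv
4. envelopes / decay / outliers      -> envelope.csv, decay.csv, outliers.csv
5. cross-series summary              -> summary.csv, variability.csv, summary.txt
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, EcoturnError, InsufficientDataError
from .io import (
    annual_matrix_frame,
    harmonize_taxa,
    pool_annual,
    read_long_table,
    series_summary_frame,
)
from .metrics import (
    all_pairs_metrics,
    coefficient_of_variation,
    consecutive_metrics,
    diversity_frame,
    turnover_frame,
)
from .simulate import SimulationConfig, simulate_series
from .trends import (
    TREND_METRICS,
    classify_trends,
    decay_frame,
    detect_extraordinary_years,
    distance_decay,
    envelope_frame,
    fit_linear_trend,
    outlier_frame,
    quantile_envelope,
    trends_frame,
)
from .types import CommunityTimeSeries

logger = logging.getLogger("ecoturn")

DEFAULTS = {
    "alpha": 0.05,
    "min_bin_n": 10,
    "span": 0.75,
    "proportions": True,
    "weighting": "pair",  # pair-weighted cross-series means
    "quantile_interpolation": "linear",
}


def load_config(path: str | Path) -> dict:
    """Load and minimally validate a YAML run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict) or "input" not in config:
        raise ConfigurationError(f"{path}: config must be a mapping with an 'input' section")
    return config


def _stage(name: str):
    logger.info("stage: %s", name)


def build_series(config: Mapping) -> list[CommunityTimeSeries]:
    """Stage 1: obtain pooled annual series from files or the simulator."""
    inp = config["input"]
    kind = inp.get("kind", "long_table")
    if kind == "simulate":
        series_list = []
        for sim_spec in inp["simulate"]:
            sim = SimulationConfig(**sim_spec)
            if "seed" in config:
                sim = replace(sim, seed=int(config["seed"]) + sim.seed)
            series, _, _ = simulate_series(sim)
            series_list.append(series)
        return series_list
    if kind != "long_table":
        raise ConfigurationError(f"unknown input kind {kind!r}")

    records = []
    for p in inp["paths"]:
        records.extend(
            read_long_table(
                p,
                column_map=inp.get("column_map"),
                delimiter=inp.get("delimiter", ","),
            )
        )
    logger.info("read %d records from %d file(s)", len(records), len(inp["paths"]))
    synonyms_path = inp.get("synonyms_path")
    if synonyms_path:
        synonyms = yaml.safe_load(Path(synonyms_path).read_text()) or {}
        records = harmonize_taxa(records, synonyms)
    return pool_annual(records, series_meta=inp.get("series_meta"))


def summarize_across_series(
    consecutive: pd.DataFrame,
    series_meta: Mapping[str, tuple[str, str]] | None = None,
    weighting: str = "pair",
) -> pd.DataFrame:
    """Grand mean +/- sd of adjacent-year ser_r and ser_a, plus strata.

    With pair weighting (default) every adjacent-year pair counts once in
    the pooled mean; with series weighting, per-series means are averaged
    so long series do not dominate.  A single pair has no estimable sd
    (reported as NaN).
    """
    if consecutive.empty:
        raise InsufficientDataError("no adjacent-year pairs to summarize")
    if weighting not in ("pair", "series"):
        raise ConfigurationError(f"weighting must be 'pair' or 'series', got {weighting!r}")
    df = consecutive.copy()
    meta = series_meta or {}
    df["region"] = df["series_id"].map(lambda s: meta.get(s, ("", ""))[0])
    df["organism_group"] = df["series_id"].map(lambda s: meta.get(s, ("", ""))[1])

    def _summary(group: pd.DataFrame, scope: str) -> dict:
        if weighting == "series":
            per = group.groupby("series_id")[["ser_r", "ser_a"]].mean()
            base = per
        else:
            base = group[["ser_r", "ser_a"]]
        n = len(base)
        return {
            "scope": scope,
            "n_pairs": len(group),
            "n_series": group["series_id"].nunique(),
            "mean_ser_r": float(base["ser_r"].mean()),
            "sd_ser_r": float(base["ser_r"].std(ddof=1)) if n > 1 else float("nan"),
            "mean_ser_a": float(base["ser_a"].mean()),
            "sd_ser_a": float(base["ser_a"].std(ddof=1)) if n > 1 else float("nan"),
        }

    rows = [_summary(df, "all")]
    for (region, organism), group in df.groupby(["region", "organism_group"], sort=True):
        if region or organism:
            rows.append(_summary(group, f"{region}/{organism}"))
    return pd.DataFrame(
        rows,
        columns=["scope", "n_pairs", "n_series", "mean_ser_r", "sd_ser_r",
                 "mean_ser_a", "sd_ser_a"],
    )


def variability_table(
    diversity: pd.DataFrame, consecutive: pd.DataFrame
) -> pd.DataFrame:
    """Per-series CV% of ENS, ser_r and ser_a (NaN when not estimable)."""
    rows = []
    for sid, group in diversity.groupby("series_id"):
        rows.append(_cv_row(sid, "ens", group["ens"]))
    for sid, group in consecutive.groupby("series_id"):
        rows.append(_cv_row(sid, "ser_r", group["ser_r"]))
        rows.append(_cv_row(sid, "ser_a", group["ser_a"]))
    return pd.DataFrame(
        rows, columns=["series_id", "metric", "mean", "sd", "cv_percent"]
    ).sort_values(["series_id", "metric"], ignore_index=True)


def _cv_row(sid: str, metric: str, values: pd.Series) -> dict:
    try:
        cv = coefficient_of_variation(values)
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    except EcoturnError:
        cv, mean, sd = float("nan"), float(values.mean()), float("nan")
    return {"series_id": sid, "metric": metric, "mean": mean, "sd": sd,
            "cv_percent": cv}


def _trend_inputs(
    series: CommunityTimeSeries,
    diversity: pd.DataFrame,
    consecutive: pd.DataFrame,
) -> dict[str, tuple[list[int], list[float]]]:
    """Assemble the (year, value) points for each trend metric.

    ENS is regressed on the sampling year; the pairwise metrics ΔS,
    ser_r and ser_a on the first year of each adjacent pair.
    """
    d = diversity[diversity.series_id == series.series_id]
    c = consecutive[consecutive.series_id == series.series_id]
    return {
        "ens": (list(d.year), list(d.ens)),
        "delta_s": (list(c.year_from), list(c.delta_s)),
        "ser_r": (list(c.year_from), list(c.ser_r)),
        "ser_a": (list(c.year_from), list(c.ser_a)),
    }


def run_pipeline(
    config: Mapping | str | Path,
    output_dir: str | Path | None = None,
) -> Path:
    """Run the full analysis and write result tables plus a manifest.

    Returns the output directory.  Any stage failure aborts with a
    stage-named error; tables written before the failure remain on disk
    and the manifest is only written on success.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "ecoturn_results"))
    out.mkdir(parents=True, exist_ok=True)
    opts = {**DEFAULTS, **{k: config[k] for k in DEFAULTS if k in config}}
    alpha = float(opts["alpha"])

    stage = "read_and_pool"
    try:
        _stage(stage)
        series_list = build_series(config)
        if not series_list:
            raise InsufficientDataError("no series found in input")
        annual_matrix_frame(series_list).to_csv(out / "annual_matrix.csv", index=False)
        series_summary_frame(series_list).to_csv(out / "series_summary.csv", index=False)

        stage = "diversity_and_turnover"
        _stage(stage)
        diversity = diversity_frame(series_list)
        consecutive_pairs = {
            s.series_id: consecutive_metrics(s, proportions=opts["proportions"])
            for s in series_list
        }
        all_pairs = {
            s.series_id: all_pairs_metrics(s, proportions=opts["proportions"])
            for s in series_list
            if len(s.non_empty()) >= 2
        }
        consecutive = turnover_frame(
            [p for pairs in consecutive_pairs.values() for p in pairs]
        )
        allpairs_df = turnover_frame([p for pairs in all_pairs.values() for p in pairs])
        diversity.to_csv(out / "diversity.csv", index=False)
        consecutive.to_csv(out / "turnover_consecutive.csv", index=False)
        allpairs_df.to_csv(out / "turnover_all_pairs.csv", index=False)

        stage = "trends"
        _stage(stage)
        results = []
        for s in series_list:
            for metric, (yrs, vals) in _trend_inputs(s, diversity, consecutive).items():
                try:
                    results.append(
                        fit_linear_trend(yrs, vals, metric, series_id=s.series_id,
                                         alpha=alpha, region=s.region,
                                         organism_group=s.organism_group)
                    )
                except InsufficientDataError:
                    logger.info("trend skipped: %s/%s (too few points)",
                                s.series_id, metric)
        trends_frame(results).to_csv(out / "trends.csv", index=False)
        if results:
            classify_trends(results, by_stratum=True).to_csv(
                out / "trend_counts.csv", index=False
            )

        stage = "envelopes_decay_outliers"
        _stage(stage)
        all_pair_objs = [p for pairs in all_pairs.values() for p in pairs]
        env_frames = []
        for metric in ("ser_r", "ser_a"):
            if all_pair_objs:
                env = quantile_envelope(
                    all_pair_objs, metric=metric, min_bin_n=int(opts["min_bin_n"]),
                    interpolation=opts["quantile_interpolation"],
                )
                env_frames.append(envelope_frame(env, metric))
        if env_frames:
            pd.concat(env_frames, ignore_index=True).to_csv(
                out / "envelope.csv", index=False
            )

        curves = []
        for metric in ("ser_r", "ser_a"):
            for sid, pairs in sorted(all_pairs.items()):
                try:
                    curves.append(
                        distance_decay(pairs, metric=metric,
                                       span=float(opts["span"]), label=sid)
                    )
                except InsufficientDataError:
                    logger.info("decay skipped: %s/%s (too few lags)", sid, metric)
            if all_pair_objs:
                try:
                    curves.append(
                        distance_decay(all_pair_objs, metric=metric,
                                       span=float(opts["span"]), label="all")
                    )
                except InsufficientDataError:
                    pass
        decay_frame(curves).to_csv(out / "decay.csv", index=False)

        flags = []
        for metric in ("ser_r", "ser_a"):
            for sid, pairs in sorted(consecutive_pairs.items()):
                try:
                    flags.extend(detect_extraordinary_years(pairs, metric=metric))
                except InsufficientDataError:
                    logger.info("outlier detection skipped: %s/%s (n < 5)", sid, metric)
        outlier_frame(flags).to_csv(out / "outliers.csv", index=False)

        stage = "summary"
        _stage(stage)
        meta = {s.series_id: (s.region, s.organism_group) for s in series_list}
        summary = summarize_across_series(consecutive, series_meta=meta,
                                          weighting=opts["weighting"])
        summary.to_csv(out / "summary.csv", index=False)
        variability_table(diversity, consecutive).to_csv(
            out / "variability.csv", index=False
        )
        (out / "summary.txt").write_text(_summary_text(summary, results, alpha))
    except EcoturnError as exc:
        raise EcoturnError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package": "ecoturn",
        "version": __version__,
        "config": _jsonable(dict(config)),
        "options": opts,
        "alpha": alpha,
        "input_digests": _input_digests(config),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _summary_text(summary: pd.DataFrame, results: Sequence, alpha: float) -> str:
    top = summary.iloc[0]
    lines = [
        "Cross-series turnover summary (adjacent-year pairs)",
        f"  identity turnover  ser_r: {top.mean_ser_r:.3f} +/- {top.sd_ser_r:.3f}",
        f"  dominance turnover ser_a: {top.mean_ser_a:.3f} +/- {top.sd_ser_a:.3f}",
        f"  pairs: {int(top.n_pairs)}, series: {int(top.n_series)}",
        "",
        f"Trend classifications (alpha = {alpha}):",
    ]
    by_metric: dict[str, dict[str, int]] = {m: {"positive": 0, "negative": 0, "none": 0}
                                            for m in TREND_METRICS}
    for r in results:
        by_metric[r.metric][r.classification] += 1
    for metric, counts in by_metric.items():
        lines.append(
            f"  {metric}: {counts['positive']} positive, "
            f"{counts['negative']} negative, {counts['none']} none"
        )
    return "\n".join(lines) + "\n"


def _input_digests(config: Mapping) -> dict[str, str]:
    digests = {}
    for p in config.get("input", {}).get("paths", []) or []:
        path = Path(p)
        if path.exists():
            digests[str(p)] = hashlib.sha256(path.read_bytes()).hexdigest()
    return digests


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
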
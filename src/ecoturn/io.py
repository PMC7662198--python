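"""Reading, validating and pooling long-format monitoring records.

Monitoring data arrive as long tables: one row per (series, sampling
time, taxon, abundance).  Because monitoring protocols record presences
only, a taxon unrecorded at a sampling event counts as zero for that
event's contribution to the annual mean — treating absence as missing
would bias annual means upward.  A sampling event is identified by a
unique (series, exact time value) pair, so the annual mean of a taxon is

    sum of its recorded abundances in the year / number of distinct
    sampling events in the year.

Years whose pooled total abundance is zero are kept in the series but
flagged empty and excluded from metric computation downstream.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .types import AnnualAssemblage, CommunityRecord, CommunityTimeSeries, parse_year

REQUIRED_ROLES = ("series", "time", "taxon", "abundance")

DEFAULT_COLUMN_MAP = {
    "series": "series_id",
    "time": "time",
    "taxon": "taxon",
    "abundance": "abundance",
}


def read_long_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[CommunityRecord]:
    """Read a delimited long-format community table into records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping of the roles ``series``, ``time``, ``taxon``,
        ``abundance`` to column names in the file.
    delimiter
        Field separator (``","`` for CSV, ``"\\t"`` for TSV).

    Raises
    ------
    ConfigurationError
        If a mapped column is missing from the file.
    ValidationError
        If an abundance is negative, non-numeric or missing, or a time
        value does not parse to a calendar year.  The error message
        names the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing_roles = [r for r in REQUIRED_ROLES if r not in cmap]
    if missing_roles:
        raise ConfigurationError(f"column_map missing roles: {missing_roles}")

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: mapped columns {missing_cols} not found; file has {list(df.columns)}"
        )

    records: list[CommunityRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {role: getattr(row, col) for role, col in cmap.items()}
        raw_ab = vals["abundance"]
        try:
            abundance = float(raw_ab)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}, data row {i}: abundance {raw_ab!r} is not numeric"
            ) from None
        if abundance != abundance:  # NaN: missing abundance is an input error
            raise ValidationError(f"{path}, data row {i}: abundance is missing")
        if abundance < 0:
            raise ValidationError(
                f"{path}, data row {i}: abundance {abundance} is negative"
            )
        try:
            year = parse_year(vals["time"])
        except ValidationError as exc:
            raise ValidationError(f"{path}, data row {i}: {exc}") from None
        records.append(
            CommunityRecord(
                series_id=str(vals["series"]),
                time=str(vals["time"]),
                year=year,
                taxon=str(vals["taxon"]),
                abundance=abundance,
            )
        )
    return records


def harmonize_taxa(
    records: Sequence[CommunityRecord],
    synonyms: Mapping[str, str],
) -> list[CommunityRecord]:
    """Rename taxa to canonical names using a flattened synonym map.

    Every taxon appearing as a key is renamed to its canonical value.
    Rows are not merged here — records for the same (series, time,
    canonical taxon) stay distinct and are summed during pooling.

    Raises
    ------
    ConfigurationError
        If the map contains a chain (a canonical name is itself a key,
        e.g. ``{"a": "b", "b": "c"}``); supply a flattened map instead.
    """
    chained = [old for old, new in synonyms.items() if new in synonyms]
    if chained:
        raise ConfigurationError(
            f"synonym map contains chains via keys {sorted(chained)}; "
            "flatten the map so every value is a canonical name"
        )
    if not synonyms:
        return list(records)
    return [
        CommunityRecord(
            series_id=r.series_id,
            time=r.time,
            year=r.year,
            taxon=synonyms.get(r.taxon, r.taxon),
            abundance=r.abundance,
        )
        for r in records
    ]


def pool_annual(
    records: Iterable[CommunityRecord],
    series_meta: Mapping[str, Mapping[str, str]] | None = None,
) -> list[CommunityTimeSeries]:
    """Pool records to yearly averages across all samples, per series.

    For each series and year, each taxon's annual value is the sum of
    its abundances over all sampling events of that year divided by the
    number of distinct sampling events (time values) in that year; a
    taxon unrecorded at an event contributes zero to its mean.

    Duplicate (series, time, taxon) rows are summed before averaging,
    with a warning (they commonly arise from subsample rows).

    Parameters
    ----------
    records
        Validated, harmonized observation records.
    series_meta
        Optional ``series_id -> {"region": ..., "organism_group": ...}``
        annotations carried onto the output series.

    Returns
    -------
    One :class:`CommunityTimeSeries` per series_id, years sorted.
    """
    # (series, year, taxon) -> summed abundance; (series, year) -> set of event labels
    totals: dict[tuple[str, int, str], float] = defaultdict(float)
    events: dict[tuple[str, int], set[str]] = defaultdict(set)
    seen_rows: set[tuple[str, str, str]] = set()
    dup_keys: set[tuple[str, str, str]] = set()

    for r in records:
        key = (r.series_id, r.time, r.taxon)
        if key in seen_rows:
            dup_keys.add(key)
        seen_rows.add(key)
        totals[(r.series_id, r.year, r.taxon)] += r.abundance
        events[(r.series_id, r.year)].add(r.time)

    if dup_keys:
        warnings.warn(
            f"{len(dup_keys)} duplicate (series, time, taxon) combinations were "
            "summed before annual averaging",
            stacklevel=2,
        )

    by_series: dict[str, dict[int, dict[str, float]]] = defaultdict(dict)
    n_samples: dict[tuple[str, int], int] = {}
    for (sid, year), evset in events.items():
        n_samples[(sid, year)] = len(evset)
        by_series[sid][year] = {}
    for (sid, year, taxon), total in totals.items():
        mean = total / n_samples[(sid, year)]
        if mean > 0:  # zero annual means are equivalent to absence
            by_series[sid][year][taxon] = mean

    meta = series_meta or {}
    out: list[CommunityTimeSeries] = []
    for sid in sorted(by_series):
        assemblages = [
            AnnualAssemblage(
                series_id=sid,
                year=year,
                abundances=by_series[sid][year],
                n_samples=n_samples[(sid, year)],
            )
            for year in sorted(by_series[sid])
        ]
        m = meta.get(sid, {})
        out.append(
            CommunityTimeSeries(
                series_id=sid,
                assemblages=assemblages,
                taxon_universe=sorted({t for a in assemblages for t in a.abundances}),
                region=str(m.get("region", "")),
                organism_group=str(m.get("organism_group", "")),
            )
        )
    return out


def annual_matrix_frame(series_list: Sequence[CommunityTimeSeries]) -> pd.DataFrame:
    """Tidy annual table: one row per (series, year, taxon, annual mean)."""
    rows = [
        {
            "series_id": s.series_id,
            "year": a.year,
            "taxon": taxon,
            "annual_mean_abundance": value,
        }
        for s in series_list
        for a in s.assemblages
        for taxon, value in sorted(a.abundances.items())
    ]
    return pd.DataFrame(
        rows, columns=["series_id", "year", "taxon", "annual_mean_abundance"]
    )


def series_summary_frame(series_list: Sequence[CommunityTimeSeries]) -> pd.DataFrame:
    """Per-series summary: region, organism, extent TE, station-years SY,
    total taxa S — the columns a monitoring inventory table reports."""
    rows = [
        {
            "series_id": s.series_id,
            "region": s.region,
            "organism_group": s.organism_group,
            "extent_years": s.extent_years,
            "station_years": len(s.assemblages),
            "n_taxa": len(s.taxon_universe),
        }
        for s in series_list
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "series_id", "region", "organism_group",
            "extent_years", "station_years", "n_taxa",
        ],
    )


def write_long_table(series_list: Sequence[CommunityTimeSeries], path: str | Path) -> None:
    """Write series back to the long CSV dialect :func:`read_long_table`
    reads (one pooled sample per year), enabling lossless round trips."""
    rows = [
        {
            "series_id": s.series_id,
            "time": a.year,
            "taxon": taxon,
            "abundance": value,
        }
        for s in series_list
        for a in s.assemblages
        for taxon, value in sorted(a.abundances.items())
    ]
    pd.DataFrame(rows, columns=["series_id", "time", "taxon", "abundance"]).to_csv(
        path, index=False
    )
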
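"""Per-series trend fitting, turnover envelopes, distance decay and
extraordinary-year detection.

Trend fits are ordinary least squares of a metric against calendar year,
one model per (series, metric), classified positive/negative/none by the
sign of the slope at a two-sided significance threshold alpha (default
0.05, no multiple-testing correction by default — a Benjamini-Hochberg
option is available for ensembles of series).

The turnover-vs-richness-change envelope bins all-pairs turnover by
absolute net richness change |ΔS| and reports empirical 5/25/50/75/95%
quantiles per bin; under-filled bins are merged upward so every envelope
row rests on a configurable minimum sample size.

Distance decay smooths turnover against temporal lag with locally
weighted regression (lowess); the saturation lag is the smallest lag at
which the smoothed curve first reaches 95% of its maximum, or None while
the curve is still rising at the largest lag.

Extraordinary years are consecutive-year turnover values outside the
series' own Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) — a robust,
parameter-light operationalization of variance-based outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .types import PairwiseTurnover

TREND_METRICS = ("ens", "delta_s", "ser_r", "ser_a")


@dataclass(frozen=True)
class TrendResult:
    """One OLS fit of metric ~ year for one series."""

    series_id: str
    metric: str
    n_points: int
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    classification: str  # positive | negative | none
    region: str = ""
    organism_group: str = ""


@dataclass(frozen=True)
class QuantileEnvelope:
    """Empirical quantiles of a turnover metric within one |ΔS| bin."""

    delta_s_bin: int
    n: int
    q05: float
    q25: float
    median: float
    q75: float
    q95: float


@dataclass(frozen=True)
class OutlierFlag:
    """A year pair whose turnover lies outside the series' Tukey fences."""

    series_id: str
    metric: str
    year_from: int
    year_to: int
    value: float
    lower_fence: float
    upper_fence: float


@dataclass(frozen=True)
class DecayCurve:
    """Lowess-smoothed turnover as a function of temporal lag."""

    label: str
    metric: str
    lags: tuple[int, ...]
    smoothed: tuple[float, ...]
    saturation_lag: int | None


def _classify(slope: float, p_value: float, alpha: float) -> str:
    if p_value < alpha and slope > 0:
        return "positive"
    if p_value < alpha and slope < 0:
        return "negative"
    return "none"


def fit_linear_trend(
    years: Sequence[int],
    values: Sequence[float],
    metric: str,
    series_id: str = "",
    alpha: float = 0.05,
    region: str = "",
    organism_group: str = "",
) -> TrendResult:
    """OLS fit of value ~ year with a two-sided t-test on the slope.

    Requires at least three points and distinct years.  A zero-variance
    response yields slope 0 and classification "none" (the slope test is
    degenerate there, so p is reported as 1).
    """
    x = np.asarray(list(years), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("years and values must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"trend fit needs >= 3 points, got {x.size}")
    if np.unique(x).size != x.size or np.ptp(x) == 0:
        raise InsufficientDataError("years must be distinct with non-zero variance")
    res = stats.linregress(x, y)
    p_value = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return TrendResult(
        series_id=series_id,
        metric=metric,
        n_points=int(x.size),
        slope=slope,
        intercept=float(res.intercept),
        p_value=p_value,
        r_squared=r2,
        classification=_classify(slope, p_value, alpha),
        region=region,
        organism_group=organism_group,
    )


def classify_trends(
    results: Sequence[TrendResult],
    by_stratum: bool = False,
    fdr_adjust: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tally positive / negative / none classifications per metric.

    With ``by_stratum=True`` the tally is additionally split by
    (region, organism_group), retaining zero rows for every observed
    stratum x metric combination.  ``fdr_adjust=True`` re-derives the
    classifications after Benjamini-Hochberg adjustment of the p-values
    within each metric (off by default: raw per-series significance is
    the convention this tally mirrors).
    """
    if not results:
        raise InsufficientDataError("no trend results to classify")
    rows = [
        {
            "series_id": r.series_id,
            "metric": r.metric,
            "region": r.region,
            "organism_group": r.organism_group,
            "slope": r.slope,
            "p_value": r.p_value,
            "classification": r.classification,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if fdr_adjust:
        for metric, idx in df.groupby("metric").groups.items():
            rej, p_adj, _, _ = multipletests(
                df.loc[idx, "p_value"], alpha=alpha, method="fdr_bh"
            )
            cls = [
                _classify(s, p, alpha)
                for s, p in zip(df.loc[idx, "slope"], np.where(rej, 0.0, 1.0))
            ]
            df.loc[idx, "classification"] = cls

    keys = ["metric"] + (["region", "organism_group"] if by_stratum else [])
    counts = (
        df.groupby(keys)["classification"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["positive", "negative", "none"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts["n_series"] = counts[["positive", "negative", "none"]].sum(axis=1)
    counts["n_significant"] = counts["positive"] + counts["negative"]
    return counts


def quantile_envelope(
    pairs: Sequence[PairwiseTurnover],
    metric: str = "ser_r",
    min_bin_n: int = 10,
    interpolation: str = "linear",
) -> list[QuantileEnvelope]:
    """Quantile envelope of a turnover metric over absolute richness change.

    Pairs are grouped by |ΔS| (integer bins).  Sweeping bins in
    ascending |ΔS| order, a bin with fewer than ``min_bin_n`` members is
    merged upward into the next bin; a trailing under-filled remainder
    is merged into the last emitted envelope.  Quantiles use the stated
    interpolation rule between order statistics (default "linear").
    """
    if not pairs:
        raise InsufficientDataError("no turnover pairs for envelope")
    if metric not in ("ser_r", "ser_a"):
        raise ValueError(f"metric must be ser_r or ser_a, got {metric!r}")
    values_by_bin: dict[int, list[float]] = {}
    for p in pairs:
        values_by_bin.setdefault(abs(p.delta_s), []).append(getattr(p, metric))

    # Ascending sweep; a trailing under-filled remainder folds into the
    # final bucket so every envelope row rests on >= min_bin_n values.
    buckets: list[tuple[int, list[float]]] = []
    carry: list[float] = []
    for ds in sorted(values_by_bin):
        bucket = carry + values_by_bin[ds]
        if len(bucket) < min_bin_n:
            carry = bucket
            continue
        buckets.append((ds, bucket))
        carry = []
    if carry:
        if buckets:
            ds, bucket = buckets[-1]
            buckets[-1] = (ds, bucket + carry)
        else:
            buckets = [(max(values_by_bin), carry)]
    return [_envelope_row(ds, vals, interpolation) for ds, vals in buckets]


def _envelope_row(ds: int, values: list[float], interpolation: str) -> QuantileEnvelope:
    q = np.quantile(np.asarray(values, dtype=float),
                    [0.05, 0.25, 0.5, 0.75, 0.95], method=interpolation)
    return QuantileEnvelope(
        delta_s_bin=int(ds), n=len(values),
        q05=float(q[0]), q25=float(q[1]), median=float(q[2]),
        q75=float(q[3]), q95=float(q[4]),
    )


def distance_decay(
    pairs: Sequence[PairwiseTurnover],
    metric: str = "ser_r",
    span: float = 0.75,
    label: str = "",
    saturation_fraction: float = 0.95,
) -> DecayCurve:
    """Lowess curve of turnover against temporal lag and its saturation lag.

    Needs at least 5 pairs spanning at least 3 distinct lags.  The curve
    is evaluated at each observed lag and clipped to [0, 1].  The
    saturation lag is the smallest lag whose smoothed value reaches
    ``saturation_fraction`` of the curve maximum; it is None when that
    point is the largest lag and the curve is still strictly rising
    there (turnover not yet saturated within the observed window).
    """
    if metric not in ("ser_r", "ser_a"):
        raise ValueError(f"metric must be ser_r or ser_a, got {metric!r}")
    lags = np.array([p.lag for p in pairs], dtype=float)
    vals = np.array([getattr(p, metric) for p in pairs], dtype=float)
    distinct = np.unique(lags)
    if lags.size < 5 or distinct.size < 3:
        raise InsufficientDataError(
            f"distance decay needs >= 5 pairs over >= 3 distinct lags "
            f"(got {lags.size} pairs, {distinct.size} lags)"
        )
    fitted = lowess(vals, lags, frac=span, return_sorted=True)
    # lowess returns one row per input point; average duplicates per lag
    df = pd.DataFrame(fitted, columns=["lag", "smooth"]).groupby("lag").mean()
    grid = df.index.to_numpy()
    smoothed = np.clip(df["smooth"].to_numpy(), 0.0, 1.0)

    peak = smoothed.max()
    threshold = saturation_fraction * peak
    reach = np.nonzero(smoothed >= threshold - 1e-12)[0]
    sat: int | None = None
    if reach.size:
        first = int(reach[0])
        still_rising = (
            first == len(grid) - 1
            and len(grid) >= 2
            and smoothed[-1] > smoothed[-2] + 1e-9
        )
        sat = None if still_rising else int(round(grid[first]))
    return DecayCurve(
        label=label,
        metric=metric,
        lags=tuple(int(round(g)) for g in grid),
        smoothed=tuple(float(v) for v in smoothed),
        saturation_lag=sat,
    )


def detect_extraordinary_years(
    pairs: Sequence[PairwiseTurnover],
    metric: str = "ser_r",
    k: float = 1.5,
) -> list[OutlierFlag]:
    """Flag year pairs with turnover outside the series' Tukey fences.

    Fences are Q1 - k*IQR and Q3 + k*IQR of the series' own
    consecutive-year values (k = 1.5 by default).  Requires at least 5
    pairs so the spread is estimable; values exactly on a fence are
    inside.  A constant series has collapsed fences and yields no flags.
    """
    if metric not in ("ser_r", "ser_a"):
        raise ValueError(f"metric must be ser_r or ser_a, got {metric!r}")
    if len(pairs) < 5:
        raise InsufficientDataError(
            f"outlier detection needs >= 5 pairs, got {len(pairs)}"
        )
    series_ids = {p.series_id for p in pairs}
    if len(series_ids) != 1:
        raise ValueError(f"pairs must come from one series, got {sorted(series_ids)}")
    values = np.array([getattr(p, metric) for p in pairs], dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    return [
        OutlierFlag(
            series_id=p.series_id,
            metric=metric,
            year_from=p.year_from,
            year_to=p.year_to,
            value=float(v),
            lower_fence=float(lower),
            upper_fence=float(upper),
        )
        for p, v in zip(pairs, values)
        if v > upper or v < lower
    ]


def trends_frame(results: Sequence[TrendResult]) -> pd.DataFrame:
    """Tidy table of TrendResult rows."""
    rows = [
        {
            "series_id": r.series_id,
            "region": r.region,
            "organism_group": r.organism_group,
            "metric": r.metric,
            "n_points": r.n_points,
            "slope": r.slope,
            "intercept": r.intercept,
            "p_value": r.p_value,
            "r_squared": r.r_squared,
            "classification": r.classification,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["series_id", "region", "organism_group", "metric", "n_points",
                 "slope", "intercept", "p_value", "r_squared", "classification"],
    )


def envelope_frame(envelopes: Sequence[QuantileEnvelope], metric: str) -> pd.DataFrame:
    rows = [
        {
            "metric": metric,
            "delta_s_bin": e.delta_s_bin,
            "n": e.n,
            "q05": e.q05,
            "q25": e.q25,
            "median": e.median,
            "q75": e.q75,
            "q95": e.q95,
        }
        for e in envelopes
    ]
    return pd.DataFrame(
        rows, columns=["metric", "delta_s_bin", "n", "q05", "q25", "median", "q75", "q95"]
    )


def decay_frame(curves: Sequence[DecayCurve]) -> pd.DataFrame:
    rows = [
        {
            "label": c.label,
            "metric": c.metric,
            "lag": lag,
            "smoothed": val,
            "saturation_lag": c.saturation_lag if c.saturation_lag is not None else "",
        }
        for c in curves
        for lag, val in zip(c.lags, c.smoothed)
    ]
    return pd.DataFrame(rows, columns=["label", "metric", "lag", "smoothed", "saturation_lag"])


def outlier_frame(flags: Sequence[OutlierFlag]) -> pd.DataFrame:
    rows = [
        {
            "series_id": f.series_id,
            "metric": f.metric,
            "year_from": f.year_from,
            "year_to": f.year_to,
            "value": f.value,
            "lower_fence": f.lower_fence,
            "upper_fence": f.upper_fence,
        }
        for f in flags
    ]
    return pd.DataFrame(
        rows,
        columns=["series_id", "metric", "year_from", "year_to", "value",
                 "lower_fence", "upper_fence"],
    )
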
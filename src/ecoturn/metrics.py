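"""Diversity and turnover metrics for annual assemblages.

Standing diversity
    richness S — count of taxa with positive abundance.
    ENS — effective number of species, the inverse Simpson concentration
    1 / sum(p_i^2) (Hill number of order 2): the number of equally
    abundant taxa that would produce the observed dominance structure.

Turnover between two years
    delta_s — net richness change S(to) - S(from) = immigrations - extinctions.
    ser_r — species exchange ratio on identities: Jaccard dissimilarity
    of the presence sets, (immigrations + extinctions) / |union|.
    0 means no exchange of identities, 1 a complete overturn.
    ser_a — abundance-based species exchange ratio: Wishart's
    dissimilarity on relative-abundance vectors x, y over the union
    taxon set,

        ser_a = 1 - sum(x*y) / (sum(x^2) + sum(y^2) - sum(x*y)).

    0 means identity and relative dominance unchanged, 1 a complete
    species exchange.  Abundances are normalized to proportions per year
    by default, so total-abundance (biomass) trends cannot masquerade as
    turnover; ``proportions=False`` applies the formula to raw values.

Zero/boundary handling: taxa with zero abundance in both years are
dropped from the union before any formula, and the 0/1 boundary cases
are decided by exact set logic rather than floating equality.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .types import (
    AnnualAssemblage,
    CommunityTimeSeries,
    DiversityRecord,
    PairwiseTurnover,
    SeriesVariability,
)


def richness(assemblage: AnnualAssemblage) -> int:
    """Number of taxa with abundance strictly greater than zero."""
    if assemblage.is_empty:
        raise UndefinedMetricError(
            f"richness undefined on empty assemblage {assemblage.series_id!r}/{assemblage.year}"
        )
    return len(assemblage.presence_set())


def effective_number_of_species(assemblage: AnnualAssemblage) -> float:
    """Inverse Simpson ENS = 1 / sum(p_i^2), with p_i the relative abundances.

    Equals richness exactly when all present taxa are equally abundant,
    and 1 for a monoculture; 1 <= ENS <= richness always.
    """
    total = assemblage.total_abundance
    if total <= 0:
        raise UndefinedMetricError(
            f"ENS undefined: zero total abundance in {assemblage.series_id!r}/{assemblage.year}"
        )
    p = np.array([v for v in assemblage.abundances.values() if v > 0], dtype=float) / total
    return float(1.0 / np.sum(p * p))


def _check_pair(a: AnnualAssemblage, b: AnnualAssemblage) -> None:
    if a.series_id != b.series_id:
        raise ValidationError(
            f"cross-series pair: {a.series_id!r} vs {b.series_id!r}"
        )
    if a.is_empty or b.is_empty:
        raise UndefinedMetricError("turnover undefined when either year is empty")


def delta_richness(a: AnnualAssemblage, b: AnnualAssemblage) -> int:
    """Net richness change S(b) - S(a) = immigrations - extinctions."""
    _check_pair(a, b)
    return richness(b) - richness(a)


def ser_r(a: AnnualAssemblage, b: AnnualAssemblage) -> float:
    """Richness-based species exchange ratio: Jaccard dissimilarity.

    ser_r = 1 - |A ∩ B| / |A ∪ B| on the presence sets; symmetric,
    0 iff the presence sets are identical, 1 iff they are disjoint.
    """
    _check_pair(a, b)
    sa, sb = a.presence_set(), b.presence_set()
    if sa == sb:
        return 0.0
    inter = len(sa & sb)
    if inter == 0:
        return 1.0
    return 1.0 - inter / len(sa | sb)


def ser_a(
    a: AnnualAssemblage,
    b: AnnualAssemblage,
    proportions: bool = True,
) -> float:
    """Abundance-based species exchange ratio: Wishart's dissimilarity.

    With x, y the (by default relative) abundance vectors over the union
    taxon set:

        ser_a = (sum x^2 + sum y^2 - 2 sum xy) / (sum x^2 + sum y^2 - sum xy)

    0 iff the relative-abundance vectors are identical, 1 iff the
    presence sets are disjoint.  Invariant under rescaling either year's
    total abundance when ``proportions=True``.
    """
    _check_pair(a, b)
    sa, sb = a.presence_set(), b.presence_set()
    if not (sa & sb):
        return 1.0
    union = sorted(sa | sb)
    x = np.array([a.abundances.get(t, 0.0) for t in union], dtype=float)
    y = np.array([b.abundances.get(t, 0.0) for t in union], dtype=float)
    if proportions:
        x = x / x.sum()
        y = y / y.sum()
    if np.array_equal(x, y):
        return 0.0
    xy = float(x @ y)
    xx = float(x @ x)
    yy = float(y @ y)
    value = (xx + yy - 2.0 * xy) / (xx + yy - xy)
    return float(min(max(value, 0.0), 1.0))


def pair_turnover(
    a: AnnualAssemblage,
    b: AnnualAssemblage,
    proportions: bool = True,
) -> PairwiseTurnover:
    """All pairwise turnover quantities for one ordered year pair (b later)."""
    if b.year <= a.year:
        raise ValidationError(f"year_to {b.year} must exceed year_from {a.year}")
    return PairwiseTurnover(
        series_id=a.series_id,
        year_from=a.year,
        year_to=b.year,
        lag=b.year - a.year,
        delta_s=delta_richness(a, b),
        ser_r=ser_r(a, b),
        ser_a=ser_a(a, b, proportions=proportions),
    )


def consecutive_metrics(
    series: CommunityTimeSeries, proportions: bool = True
) -> list[PairwiseTurnover]:
    """Turnover between each year x and the following calendar year x+1.

    Only pairs of adjacent calendar years are formed (lag exactly 1);
    pairs spanning a missing or empty year are omitted, keeping
    annual-turnover summaries comparable across series with different
    gap structures.
    """
    by_year = {a.year: a for a in series.non_empty()}
    pairs = [
        pair_turnover(by_year[y], by_year[y + 1], proportions=proportions)
        for y in sorted(by_year)
        if y + 1 in by_year
    ]
    if not pairs:
        warnings.warn(
            f"series {series.series_id!r}: no valid adjacent-year pairs", stacklevel=2
        )
    return pairs


def all_pairs_metrics(
    series: CommunityTimeSeries, proportions: bool = True
) -> list[PairwiseTurnover]:
    """Turnover for all ordered pairs of sampled non-empty years.

    Unlike :func:`consecutive_metrics` gaps are allowed: every pair
    (x, y) with y > x contributes one record with lag y - x, the input
    to distance-decay (turnover accumulation) analysis.
    """
    assemblages = series.non_empty()
    pairs = [
        pair_turnover(assemblages[i], assemblages[j], proportions=proportions)
        for i in range(len(assemblages))
        for j in range(i + 1, len(assemblages))
    ]
    if not pairs:
        warnings.warn(f"series {series.series_id!r}: fewer than two non-empty years",
                      stacklevel=2)
    return pairs


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean.

    Requires at least two values and a non-zero mean; scale-invariant.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise UndefinedMetricError("CV requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedMetricError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def diversity_records(series: CommunityTimeSeries) -> list[DiversityRecord]:
    """Richness and ENS for every non-empty year of a series."""
    return [
        DiversityRecord(
            series_id=series.series_id,
            year=a.year,
            richness=richness(a),
            ens=effective_number_of_species(a),
        )
        for a in series.non_empty()
    ]


def series_variability(
    series_id: str, metric: str, values: Sequence[float]
) -> SeriesVariability:
    """Mean, sd and CV% of a metric's values within one series."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise UndefinedMetricError(
            f"variability of {metric} in {series_id!r} needs >= 2 values"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0:
        raise UndefinedMetricError(f"CV of {metric} undefined: mean is zero")
    return SeriesVariability(
        series_id=series_id, metric=metric, mean=mean, sd=sd,
        cv_percent=100.0 * sd / mean,
    )


def diversity_frame(series_list: Sequence[CommunityTimeSeries]) -> pd.DataFrame:
    """Tidy table of DiversityRecord rows across series."""
    rows = [
        {"series_id": d.series_id, "year": d.year, "richness": d.richness, "ens": d.ens}
        for s in series_list
        for d in diversity_records(s)
    ]
    return pd.DataFrame(rows, columns=["series_id", "year", "richness", "ens"])


def turnover_frame(pairs: Sequence[PairwiseTurnover]) -> pd.DataFrame:
    """Tidy table of PairwiseTurnover rows."""
    rows = [
        {
            "series_id": p.series_id,
            "year_from": p.year_from,
            "year_to": p.year_to,
            "lag": p.lag,
            "delta_s": p.delta_s,
            "ser_r": p.ser_r,
            "ser_a": p.ser_a,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["series_id", "year_from", "year_to", "lag", "delta_s", "ser_r", "ser_a"],
    )
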
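"""Domain containers for community monitoring time series.

The unit of observation is one abundance record (series, time, taxon,
abundance); the unit of analysis is one pooled annual assemblage.  A
*series* is one monitored site x organism group, e.g. "Wadden Sea
macrozoobenthos".  Absent taxa are represented by absence from the
abundance mapping, never by stored zeros.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

_YEAR_RE = re.compile(r"^\s*(\d{4})(?:[-/]\d{1,2}[-/]\d{1,2})?\s*$")


def parse_year(time_value: object) -> int:
    """Extract an integer calendar year from a time value.

    Accepts bare integer years (``2001``, ``"2001"``) and ISO-8601-style
    dates (``"2001-06-15"``, ``"2001/06/15"``).
    """
    if isinstance(time_value, int):
        return time_value
    if isinstance(time_value, float) and time_value == int(time_value):
        return int(time_value)
    m = _YEAR_RE.match(str(time_value))
    if m is None:
        raise ValidationError(f"cannot parse a calendar year from time value {time_value!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class CommunityRecord:
    """One raw observation: a taxon's abundance at one sampling event.

    ``time`` keeps the exact raw time label because a sampling event is
    identified by the unique (series, time) pair; ``year`` is derived
    from it.  Abundance units (counts, density, biomass) are opaque to
    the pipeline.
    """

    series_id: str
    time: str
    year: int
    taxon: str
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance is None or not self.abundance >= 0:
            raise ValidationError(
                f"abundance must be a non-negative number, got {self.abundance!r} "
                f"(series {self.series_id!r}, time {self.time!r}, taxon {self.taxon!r})"
            )


@dataclass
class AnnualAssemblage:
    """One series-year: taxon -> mean annual abundance over all samples.

    Taxa absent in the year are absent from ``abundances``; taxa whose
    annual mean is exactly zero are likewise dropped so explicit zeros
    never alter downstream metrics.
    """

    series_id: str
    year: int
    abundances: dict[str, float]
    n_samples: int = 1

    @property
    def total_abundance(self) -> float:
        return float(sum(self.abundances.values()))

    @property
    def is_empty(self) -> bool:
        """True when no taxon has positive abundance; such years are
        excluded from metric computation."""
        return not any(v > 0 for v in self.abundances.values())

    def presence_set(self) -> frozenset[str]:
        return frozenset(t for t, v in self.abundances.items() if v > 0)


@dataclass
class CommunityTimeSeries:
    """An ordered sequence of annual assemblages for one series."""

    series_id: str
    assemblages: list[AnnualAssemblage]
    taxon_universe: list[str] = field(default_factory=list)
    region: str = ""
    organism_group: str = ""

    def __post_init__(self) -> None:
        years = [a.year for a in self.assemblages]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError(
                f"series {self.series_id!r}: years must be strictly increasing, got {years}"
            )
        observed = {t for a in self.assemblages for t in a.abundances}
        missing = observed - set(self.taxon_universe)
        if missing:
            self.taxon_universe = sorted(set(self.taxon_universe) | observed)

    @property
    def years(self) -> list[int]:
        return [a.year for a in self.assemblages]

    @property
    def extent_years(self) -> int:
        """Temporal extent TE = max(year) - min(year) + 1."""
        if not self.assemblages:
            return 0
        return self.assemblages[-1].year - self.assemblages[0].year + 1

    def non_empty(self) -> list[AnnualAssemblage]:
        return [a for a in self.assemblages if not a.is_empty]

    def assemblage(self, year: int) -> AnnualAssemblage:
        for a in self.assemblages:
            if a.year == year:
                return a
        raise KeyError(f"series {self.series_id!r} has no year {year}")


@dataclass(frozen=True)
class PairwiseTurnover:
    """Turnover between two years of one series.

    delta_s is richness(year_to) - richness(year_from); ser_r is the
    Jaccard dissimilarity of the presence sets; ser_a the Wishart
    dissimilarity of the relative-abundance vectors.
    """

    series_id: str
    year_from: int
    year_to: int
    lag: int
    delta_s: int
    ser_r: float
    ser_a: float


@dataclass(frozen=True)
class DiversityRecord:
    """Univariate standing diversity of one series-year."""

    series_id: str
    year: int
    richness: int
    ens: float


@dataclass(frozen=True)
class SeriesVariability:
    """Per-series coefficient of variation of one metric (percent of mean)."""

    series_id: str
    metric: str
    mean: float
    sd: float
    cv_percent: float
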
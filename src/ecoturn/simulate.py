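"""Synthetic community time series with known ground truth.

The generator emulates the statistical structure of long-running coastal
monitoring series — tens of sampled years, tens to hundreds of taxa,
strongly right-skewed species-abundance distributions (SADs), year-to-
year identity replacement and dominance reshuffling, within-year
replicate sampling, and occasional missing years — and doubles as a null
model of random compositional drift.

Drift operators are applied each year in a fixed order (the order
changes the joint statistics, so it is part of the model definition):

1. *Replacement*: ``replace_k`` uniformly chosen present taxa are
   swapped for uniformly chosen absent taxa from a finite regional pool;
   newcomers draw fresh SAD abundances.  Richness-conserving, so the
   expected richness-based exchange ratio between adjacent years has the
   closed form 2k / (S + k).
2. *Reshuffle*: with probability ``reshuffle_prob`` the abundances of
   the present taxa are permuted — dominance turnover with zero identity
   turnover (ΔS = 0, ser_r = 0, ser_a > 0).
3. *Immigration / extinction*: Poisson-count additions from the pool and
   removals (never below one taxon) — richness-changing events.
4. *Observation*: ``samples_per_year`` sampling events; with a finite
   ``sampling_depth`` each event is a multinomial draw of that many
   individuals, otherwise the true abundances are recorded noise-free.
5. Each year is independently dropped with ``missing_year_prob``.

Abundances for year 1 (and for newcomers) are log-normal with shape
``sad_sigma``, the standard skewed SAD.  One master random stream per
series is seeded from the config; per-year substreams are spawned
deterministically, so identical configs reproduce identical output
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import pool_annual
from .types import CommunityRecord, CommunityTimeSeries


def expected_ser_r_fixed_replacement(s: int, k: int) -> float:
    """Closed-form Jaccard dissimilarity for richness-conserving replacement.

    Two presence sets of equal size ``s`` sharing ``s - k`` taxa have
    union size s + k and intersection size s - k, hence

        ser_r = 1 - (s - k) / (s + k) = 2k / (s + k).
    """
    if not 0 <= k <= s:
        raise ValueError(f"need 0 <= k <= s, got k={k}, s={s}")
    if s == 0:
        raise ValueError("s must be positive")
    return 2.0 * k / (s + k)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic series."""

    seed: int
    n_years: int = 25
    n_taxa_initial: int = 60
    pool_size: int = 240
    sad_sigma: float = 1.0
    replace_k: int = 4
    reshuffle_prob: float = 0.25
    immigration_rate: float = 0.0
    extinction_rate: float = 0.0
    samples_per_year: int = 4
    sampling_depth: int | None = 500
    missing_year_prob: float = 0.0
    series_id: str = "sim"
    start_year: int = 2000
    region: str = "SIM"
    organism_group: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_taxa_initial < 1:
            raise ConfigurationError("n_years and n_taxa_initial must be positive")
        if self.pool_size < self.n_taxa_initial:
            raise ConfigurationError("pool_size must be >= n_taxa_initial")
        if not 0 <= self.replace_k < self.n_taxa_initial:
            raise ConfigurationError("need 0 <= replace_k < n_taxa_initial")
        if not 0.0 <= self.reshuffle_prob <= 1.0:
            raise ConfigurationError("reshuffle_prob must be in [0, 1]")
        if not 0.0 <= self.missing_year_prob <= 1.0:
            raise ConfigurationError("missing_year_prob must be in [0, 1]")
        if self.immigration_rate < 0 or self.extinction_rate < 0:
            raise ConfigurationError("immigration/extinction rates must be >= 0")
        if self.sad_sigma <= 0:
            raise ConfigurationError("sad_sigma must be positive")
        if self.samples_per_year < 1:
            raise ConfigurationError("samples_per_year must be positive")
        if self.sampling_depth is not None and self.sampling_depth < 1:
            raise ConfigurationError("sampling_depth must be positive or None")


@dataclass
class GroundTruth:
    """Pre-observation truth of a simulated series.

    ``true_abundances`` maps every simulated year (including years later
    dropped from the observed records) to its taxon -> abundance vector;
    ``pairs`` records, per adjacent simulated-year pair, the number of
    replaced taxa, the net richness change, and the closed-form expected
    ser_r under richness-conserving replacement.
    """

    config: SimulationConfig
    true_abundances: dict[int, dict[str, float]] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)
    missing_years: list[int] = field(default_factory=list)


def _taxon_names(pool_size: int) -> list[str]:
    width = len(str(pool_size))
    return [f"taxon_{i:0{width}d}" for i in range(1, pool_size + 1)]


def _sad_draw(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def simulate_series(
    config: SimulationConfig,
) -> tuple[CommunityTimeSeries, GroundTruth, list[CommunityRecord]]:
    """Simulate one community time series.

    Returns the pooled :class:`CommunityTimeSeries` (built by running
    the simulated long-format records through the same annual pooling
    the real pipeline uses), the :class:`GroundTruth`, and the raw
    long-format observation records.
    """
    ss = np.random.SeedSequence(config.seed)
    year_streams: Iterator[np.random.Generator] = iter(
        np.random.default_rng(child) for child in ss.spawn(config.n_years + 1)
    )
    pool = _taxon_names(config.pool_size)
    rng0 = next(year_streams)

    present_idx = list(rng0.choice(config.pool_size, size=config.n_taxa_initial,
                                   replace=False))
    abund = dict(zip(present_idx, _sad_draw(rng0, config.n_taxa_initial,
                                            config.sad_sigma)))

    truth = GroundTruth(config=config)
    records: list[CommunityRecord] = []
    prev_set: frozenset[int] | None = None
    prev_year: int | None = None

    for t in range(config.n_years):
        year = config.start_year + t
        rng = next(year_streams) if t > 0 else rng0
        if t > 0:
            replaced = _apply_replacement(abund, rng, config)
            _apply_reshuffle(abund, rng, config)
            _apply_immigration_extinction(abund, rng, config)
        else:
            replaced = 0

        current_set = frozenset(abund)
        truth.true_abundances[year] = {
            pool[i]: float(v) for i, v in sorted(abund.items())
        }
        if prev_set is not None:
            union = len(prev_set | current_set)
            inter = len(prev_set & current_set)
            truth.pairs.append(
                {
                    "year_from": prev_year,
                    "year_to": year,
                    "replaced_count": replaced,
                    "true_delta_s": len(current_set) - len(prev_set),
                    "true_ser_r": 1.0 - inter / union if union else 0.0,
                    "expected_ser_r_closed_form": expected_ser_r_fixed_replacement(
                        len(prev_set), replaced
                    )
                    if len(prev_set) == len(current_set)
                    else float("nan"),
                }
            )
        prev_set, prev_year = current_set, year

        if config.missing_year_prob > 0 and rng.random() < config.missing_year_prob:
            truth.missing_years.append(year)
            continue
        records.extend(_observe_year(abund, pool, year, rng, config))

    meta = {config.series_id: {"region": config.region,
                               "organism_group": config.organism_group}}
    series_list = pool_annual(records, series_meta=meta)
    if series_list:
        series = series_list[0]
    else:  # every year dropped
        series = CommunityTimeSeries(
            series_id=config.series_id, assemblages=[],
            region=config.region, organism_group=config.organism_group,
        )
    return series, truth, records


def _apply_replacement(
    abund: dict[int, float], rng: np.random.Generator, config: SimulationConfig
) -> int:
    """Swap replace_k present taxa for absent pool taxa (richness-conserving)."""
    k = min(config.replace_k, len(abund) - 1)
    absent = np.setdiff1d(np.arange(config.pool_size), np.fromiter(abund, dtype=int))
    k = min(k, absent.size)
    if k <= 0:
        return 0
    leavers = rng.choice(np.fromiter(abund, dtype=int), size=k, replace=False)
    arrivers = rng.choice(absent, size=k, replace=False)
    for i in leavers:
        del abund[int(i)]
    for i, v in zip(arrivers, _sad_draw(rng, k, config.sad_sigma)):
        abund[int(i)] = float(v)
    return int(k)


def _apply_reshuffle(
    abund: dict[int, float], rng: np.random.Generator, config: SimulationConfig
) -> None:
    """With probability reshuffle_prob, permute abundances among present taxa."""
    if config.reshuffle_prob <= 0 or len(abund) < 2:
        return
    if rng.random() < config.reshuffle_prob:
        keys = sorted(abund)
        values = np.array([abund[k] for k in keys])
        rng.shuffle(values)
        for k, v in zip(keys, values):
            abund[k] = float(v)


def _apply_immigration_extinction(
    abund: dict[int, float], rng: np.random.Generator, config: SimulationConfig
) -> None:
    """Poisson-count richness-changing events; never empties the community."""
    if config.immigration_rate > 0:
        absent = np.setdiff1d(np.arange(config.pool_size),
                              np.fromiter(abund, dtype=int))
        n_imm = min(int(rng.poisson(config.immigration_rate)), absent.size)
        if n_imm > 0:
            newcomers = rng.choice(absent, size=n_imm, replace=False)
            for i, v in zip(newcomers, _sad_draw(rng, n_imm, config.sad_sigma)):
                abund[int(i)] = float(v)
    if config.extinction_rate > 0:
        n_ext = min(int(rng.poisson(config.extinction_rate)), len(abund) - 1)
        if n_ext > 0:
            losers = rng.choice(np.fromiter(abund, dtype=int), size=n_ext,
                                replace=False)
            for i in losers:
                del abund[int(i)]


def _observe_year(
    abund: dict[int, float],
    pool: list[str],
    year: int,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[CommunityRecord]:
    """Emit long-format records for one year's sampling events.

    Sampling-event times are ISO dates within the year so the pooled
    annual mean divides by the number of distinct time values.
    """
    records: list[CommunityRecord] = []
    idx = sorted(abund)
    true_vals = np.array([abund[i] for i in idx], dtype=float)
    for s in range(config.samples_per_year):
        time = f"{year}-06-{s + 1:02d}"
        if config.sampling_depth is None:
            observed = true_vals
        else:
            p = true_vals / true_vals.sum()
            observed = rng.multinomial(config.sampling_depth, p).astype(float)
        for i, v in zip(idx, observed):
            if v > 0:
                records.append(
                    CommunityRecord(
                        series_id=config.series_id,
                        time=time,
                        year=year,
                        taxon=pool[i],
                        abundance=float(v),
                    )
                )
    return records


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Adjacent-pair ground truth as a tidy table."""
    return pd.DataFrame(
        truth.pairs,
        columns=["year_from", "year_to", "replaced_count", "true_delta_s",
                 "true_ser_r", "expected_ser_r_closed_form"],
    )


#: Fixture battery spanning the structural range of real monitoring data:
#: series lengths 8-72 years, 14-292 taxa, with and without gaps,
#: replicate observation noise, dominance reshuffling and richness drift.
FIXTURE_CONFIGS: tuple[SimulationConfig, ...] = (
    SimulationConfig(seed=0, series_id="short_fish", n_years=8, n_taxa_initial=14,
                     pool_size=40, replace_k=2, reshuffle_prob=0.2,
                     samples_per_year=2, sampling_depth=300,
                     region="RSA", organism_group="fish"),
    SimulationConfig(seed=0, series_id="frozen_birds", n_years=15, n_taxa_initial=22,
                     pool_size=60, replace_k=0, reshuffle_prob=0.0,
                     samples_per_year=1, sampling_depth=None,
                     region="GER", organism_group="birds"),
    SimulationConfig(seed=0, series_id="drift_benthos", n_years=44, n_taxa_initial=180,
                     pool_size=600, replace_k=12, reshuffle_prob=0.3,
                     samples_per_year=4, sampling_depth=2000,
                     region="GER", organism_group="invertebrates"),
    SimulationConfig(seed=0, series_id="gappy_plankton", n_years=30, n_taxa_initial=100,
                     pool_size=400, replace_k=8, reshuffle_prob=0.5,
                     samples_per_year=6, sampling_depth=1000,
                     missing_year_prob=0.15,
                     region="RSA", organism_group="plankton"),
    SimulationConfig(seed=0, series_id="long_benthos", n_years=72, n_taxa_initial=292,
                     pool_size=900, replace_k=15, reshuffle_prob=0.25,
                     samples_per_year=2, sampling_depth=5000,
                     immigration_rate=1.0, extinction_rate=1.0,
                     region="GER", organism_group="invertebrates"),
    SimulationConfig(seed=0, series_id="reshuffle_zoo", n_years=20, n_taxa_initial=50,
                     pool_size=50, replace_k=0, reshuffle_prob=1.0,
                     samples_per_year=1, sampling_depth=None,
                     region="RSA", organism_group="plankton"),
)


def make_fixture_suite(output_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the fixture battery as long-format CSVs with ground-truth sidecars.

    Each fixture yields three files: ``<id>.csv`` (long-format records
    readable by :func:`ecoturn.io.read_long_table` with default
    columns), ``<id>.truth.csv`` (adjacent-pair ground truth) and
    ``<id>.config.yaml``.  Fixed seed -> byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for base in FIXTURE_CONFIGS:
        config = replace(base, seed=base.seed + seed)
        _, truth, records = simulate_series(config)
        data_path = out / f"{config.series_id}.csv"
        pd.DataFrame(
            [
                {"series_id": r.series_id, "time": r.time, "taxon": r.taxon,
                 "abundance": r.abundance}
                for r in records
            ],
            columns=["series_id", "time", "taxon", "abundance"],
        ).to_csv(data_path, index=False)
        truth_path = out / f"{config.series_id}.truth.csv"
        ground_truth_frame(truth).to_csv(truth_path, index=False)
        config_path = out / f"{config.series_id}.config.yaml"
        config_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
        written.extend([data_path, truth_path, config_path])
    return written
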
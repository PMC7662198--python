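# Methods

## Unit of analysis and pooling

The raw input is a long-format table of observations (series, sampling
time, taxon, abundance), where a *series* is one monitored site ×
organism group. Because inter-annual change is the target, all samples
of a year are pooled to an annual assemblage. A *sampling event* is
defined as a unique (series, exact time value) pair — the only
reconstruction possible from a long table — and a taxon's annual value
is its summed abundance over the year divided by the number of events
in that year. A taxon unrecorded at an event counts as zero for that
event: monitoring protocols record presences only, and treating absence
as missing would bias annual means upward. Duplicate (series, time,
taxon) rows, which typically arise from subsample rows, are summed
before averaging, with a warning. Pooling conserves mass: annual mean ×
number of events equals the recorded annual total per taxon.

Years whose pooled total abundance is zero are flagged empty and
excluded from all metrics; adjacency of year pairs is *not* bridged
across an empty or missing year. Abundance units (counts, densities,
biomass) are opaque to the pipeline; all abundance-sensitive metrics
operate on relative abundances.

## Metrics

Richness S counts taxa with strictly positive annual abundance. The
effective number of species is fixed as the inverse Simpson
concentration, ENS = 1/Σpᵢ² (Hill order 2), not exp(Shannon): it shares
its basis (Simpson dominance) with the abundance-based exchange ratio,
is maximally robust to uneven sampling effort, and satisfies
1 ≤ ENS ≤ S with equality to S exactly for perfectly even communities.

Turnover between two years is measured twice:

- SERr = Jaccard dissimilarity of the presence sets =
  (immigrations + extinctions)/|union|;
- SERa = Wishart dissimilarity of the abundance vectors over the union
  taxon set, computed on per-year *proportions* by default, so a trend
  in total biomass cannot masquerade as compositional turnover. A
  raw-abundance mode exists behind an explicit option
  (`proportions=False`) for users whose abundances are already
  standardized. Whether proportion normalization precedes the Wishart
  formula is a genuine methodological fork; the proportion default
  follows the "relative dominance" reading and is recorded here
  deliberately.

Boundary cases (0 = identical, 1 = disjoint) are decided by exact set
logic, never by floating comparison of the formula output, and taxa
with zero abundance in both years are dropped from the union first.
Consecutive-year summaries use calendar adjacency only (lag = 1);
all-pairs analyses use every ordered pair of sampled non-empty years.

Useful identities used as oracles throughout the tests: for equal-size
presence sets sharing S − k taxa, SERr = 2k/(S + k) exactly; a
two-taxon dominance swap (1−ε, ε) → (ε, 1−ε) has ΔS = 0, SERr = 0 and
SERa → 1 as ε → 0.

## Trend analysis

Each (series, metric) pair gets an ordinary least-squares fit of the
metric against year — ENS against the sampling year; ΔS, SERr and SERa
against the first year of each adjacent pair (the convention is
recorded because either endpoint is defensible). A series is classified
positive/negative by the slope sign when the two-sided slope test falls
below α, else none. α defaults to 0.05 (disciplinary convention, stated
in the run manifest) and no multiple-testing correction is applied by
default, matching how per-series significance counts are conventionally
reported; a Benjamini–Hochberg option is available. Fits require ≥ 3
points; a zero-variance response is reported as slope 0, p = 1,
classification none (the t-test is degenerate there).

## Envelopes, distance decay, outliers

The turnover-vs-richness-change envelope bins all-pairs turnover by
|ΔS| and reports empirical 5/25/50/75/95% quantiles per bin (linear
interpolation between order statistics, recorded in output metadata).
Bins with fewer than 10 pairs (configurable) are merged upward into the
next bin so every row rests on a stable sample; a trailing under-filled
remainder merges into the last emitted bin.

Distance decay smooths turnover against temporal lag with locally
weighted regression (statsmodels lowess, default span 0.75,
configurable; not bit-identical to any particular loess
implementation), evaluated at each observed lag and clipped to [0, 1].
"Maximum turnover reached after L years" is operationalized as the
*saturation lag*: the smallest lag whose smoothed value reaches 95% of
the curve maximum. The saturation lag is None when that point is the
largest observed lag and the curve is still strictly rising into it; a
constant curve saturates at the smallest lag. On a deterministic
sliding-window drift (40 taxa, 5 replaced per year, true 95% lag = 8)
the estimate lands at 8–9 across spans 0.3–0.75.

Extraordinary years are flagged per series by Tukey fences on the
series' own consecutive-year turnover values: Q1 − 1.5·IQR and
Q3 + 1.5·IQR, values strictly outside flagged, both fences reported. At
least 5 pairs are required (spread not estimable below that); equality
with a fence is inside, so constant series produce no flags. This is a
robust, parameter-light operationalization of variance-based outlier
screening, not a claim about any particular boxplot convention.

## Synthetic communities

The simulator generates ground-truthed series with the statistical
structure of real monitoring data: series lengths 8–72 years, tens to
hundreds of taxa, strongly right-skewed abundance distributions,
within-year replicate samples, identity replacement, dominance
reshuffling, richness drift and missing years. Defaults: 25 years, 60
initial taxa from a 240-taxon regional pool, log-normal abundances with
σ = 1 (a realistic dominance skew — top taxon typically holding tens of
percent of individuals), 4 taxa replaced per year, reshuffle
probability 0.25, 4 samples of 500 individuals per year, no missing
years.

Drift operators apply per year in a fixed order — replacement →
reshuffle → immigration/extinction → observation — because operator
order changes the joint statistics; the order is therefore part of the
model definition. Replacement draws newcomers only from taxa not
currently present, which makes the 2k/(S+k) closed form hold exactly
and gives the parameter-recovery oracle its teeth. Randomness comes
from one master seed per series with per-year substreams spawned
deterministically (numpy SeedSequence), so identical configs are
bit-for-bit reproducible.

What the simulator does *not* emulate: environmental forcing and
covariate-driven change, spatial metacommunity structure and dispersal
limitation, taxonomic misidentification drift, phenology (within-year
composition shifts), and non-multinomial observation error such as
patchiness-driven overdispersion. Passing tests therefore demonstrate
the correctness and calibration of the *computations* on data whose
generating process is known, not that real coastal communities follow
the drift model.

## Pipeline and numerical choices

The pipeline writes one tidy CSV per stage (each re-readable as the
next stage's input), a plain-text cross-series summary, and a JSON run
manifest holding the config snapshot, input digests, package version,
thresholds and a timestamp. Result tables are byte-identical across
re-runs with the same config and seed; the manifest's timestamp is the
sole non-deterministic output. Cross-series turnover means are
pair-weighted by default (every adjacent-year pair counts once);
series-weighted means are available where long series should not
dominate. Coefficients of variation are 100·sd/mean with the sample
(n−1) standard deviation, undefined below two values or at zero mean.

Problem sizes in the test suite and acceptance script (ensembles of
~16 series of 15–44 years, 1,000-replicate null calibrations,
1,000-pair oracle sweeps) were chosen as the smallest sizes at which
the binomial/Monte-Carlo assertions have stable power.

## Known limitations

- The exchange ratios are undefined on empty assemblages; series
  dominated by empty years lose most pairs.
- OLS trend classification inherits the usual caveats on
  autocorrelated series: a random walk in ENS yields "significant"
  linear trends at well above the nominal rate. This is a property of
  the method being replicated, not a defect of the implementation; the
  type-I calibration holds for i.i.d. null series.
- Lowess gives no confidence band; the saturation lag is a point
  estimate whose stability degrades near the largest observed lag.
- No rarefaction or coverage standardization is applied; series whose
  sampling effort changed systematically over time will register that
  change as turnover.
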
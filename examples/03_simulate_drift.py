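"""Simulate community drift with known ground truth and recover the
closed-form turnover.

Richness-conserving replacement of k of S taxa per year gives an exact
adjacent-year identity turnover of 2k/(S+k); with S = 50, k = 5 that is
10/55 = 0.18182.  The pipeline recovers it from the simulated records.
"""

import numpy as np

from ecoturn import (
    SimulationConfig,
    all_pairs_metrics,
    consecutive_metrics,
    expected_ser_r_fixed_replacement,
    simulate_series,
)

cfg = SimulationConfig(
    seed=1, n_years=20, n_taxa_initial=50, pool_size=400, replace_k=5,
    reshuffle_prob=0.0, samples_per_year=1, sampling_depth=None,
)
series, truth, _ = simulate_series(cfg)

pairs = consecutive_metrics(series)
print(f"expected ser_r = 2k/(S+k) = {expected_ser_r_fixed_replacement(50, 5):.5f}")
print(f"observed adjacent-pair ser_r: mean = {np.mean([p.ser_r for p in pairs]):.5f} "
      f"over {len(pairs)} pairs (all delta_S = 0)")

# turnover accumulates with temporal distance: median ser_r per lag rises
lags = {}
for p in all_pairs_metrics(series):
    lags.setdefault(p.lag, []).append(p.ser_r)
print("\nmedian all-pairs ser_r by lag (drift accumulates, never reverses):")
for lag in sorted(lags)[:10]:
    print(f"  lag {lag:2d}: {np.median(lags[lag]):.3f}")
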
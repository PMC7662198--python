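"""Per-series trend classification and extraordinary-year detection.

A linear OLS trend of a diversity or turnover metric against year is
classified positive/negative/none at alpha = 0.05.  Years whose
adjacent-pair turnover falls outside the series' own Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR) are flagged as extraordinary.
"""

import numpy as np

from ecoturn import detect_extraordinary_years, fit_linear_trend
from ecoturn.types import PairwiseTurnover

rng = np.random.default_rng(0)
years = list(range(2000, 2020))

rising = 5.0 + 0.3 * np.arange(20) + rng.normal(0, 0.5, 20)
result = fit_linear_trend(years, rising, metric="ens", series_id="demo")
print(f"ENS trend: slope = {result.slope:.3f}/yr, p = {result.p_value:.2e}, "
      f"classified {result.classification!r}")

noise = rng.normal(0, 1.0, 20)
null = fit_linear_trend(years, noise, metric="ens", series_id="demo")
print(f"null ENS : slope = {null.slope:.3f}/yr, p = {null.p_value:.3f}, "
      f"classified {null.classification!r}")

# a stable turnover regime with one extraordinary year
values = list(rng.uniform(0.18, 0.28, 14)) + [0.85]
pairs = [
    PairwiseTurnover("demo", 2000 + i, 2001 + i, 1, 0, float(v), float(v))
    for i, v in enumerate(values)
]
flags = detect_extraordinary_years(pairs, metric="ser_r")
for f in flags:
    print(f"extraordinary turnover {f.year_from}->{f.year_to}: "
          f"ser_r = {f.value:.2f} outside fences "
          f"[{f.lower_fence:.3f}, {f.upper_fence:.3f}]")
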
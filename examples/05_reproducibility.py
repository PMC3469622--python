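"""Replicate reproducibility of SILAC ratios via log2 ratio-of-ratios.

Simulates per-replicate ratios with log-normal channel noise (sigma = 0.2)
and summarizes pairwise replicate agreement, comparing the measured
in-range fraction with its closed-form normal-CDF prediction.
"""

import numpy as np
from scipy.stats import norm

from phosquant.stats import reproducibility_stats

rng = np.random.default_rng(3)
sigma = 0.2
# ratio per replicate: true ratio 1 times exp of the two channels' noise
ratios = np.exp(rng.normal(0, sigma, (2000, 3)) - rng.normal(0, sigma, (2000, 3)))

table = reproducibility_stats(ratios)
print(table.round(3))
for pair, row in table.iterrows():
    predicted = 2 * norm.cdf(0.6 / row["sd"]) - 1
    print(f"{pair}: measured in [-0.6, 0.6] = {row['frac_in_range']:.1%}, "
          f"normal-CDF prediction = {predicted:.1%}")
# Mean log2 ratio-of-ratios near 0 indicates no systematic replicate bias;
# the in-range fraction tracks the closed form because the log ratios are
# (approximately) normal.
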
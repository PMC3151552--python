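"""Normal-scores transform of skewed anxious-depression sum scores.

Sum scores of symptom checklists pile up at zero and are strongly
right-skewed; the rank-based normal-scores transform (Blom) replaces them
by expected normal order statistics while preserving the observed mean and
standard deviation, which is what the modeling assumes.
"""

import numpy as np
from scipy import stats

from twinfactor.normalize import normal_scores

rng = np.random.default_rng(0)
raw = np.round(rng.gamma(shape=1.2, scale=4.0, size=2000))  # sum-score-like
raw[rng.random(2000) < 0.1] = np.nan                        # missing surveys

transformed = normal_scores(raw)
obs = ~np.isnan(raw)
print(f"raw        : mean={np.nanmean(raw):.2f} sd={np.nanstd(raw):.2f} "
      f"skew={stats.skew(raw[obs]):.2f}")
print(f"transformed: mean={np.nanmean(transformed):.2f} "
      f"sd={np.nanstd(transformed):.2f} "
      f"skew={stats.skew(transformed[obs]):.2f}")
print("-> identical first two moments, skewness removed; missing entries "
      f"preserved ({np.isnan(transformed).sum()} of {len(raw)}).")
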
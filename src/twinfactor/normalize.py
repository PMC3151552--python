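"""Rank-based normal-scores transform for skewed sum scores.

Anxious-depression sum scores are strongly right-skewed; before modeling
they are replaced by expected normal order statistics for their ranks
(Blom's approximation), then linearly rescaled to the original observed
mean and standard deviation.  The transform is applied column-wise on the
pooled total sample before any subsetting to the genotyped subsample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normal_scores", "normal_scores_frame"]


def normal_scores(x) -> np.ndarray:
    """Normal-scores (rank inverse-normal) transform of one score vector.

    Observed values are mapped to Phi^-1((r - 3/8) / (n + 1/4)) where r is
    the (tie-averaged) rank, then rescaled so the observed mean and SD equal
    those of the input.  Missing entries stay missing.  If all observed
    values are identical the input is returned unchanged with a warning.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    obs = ~np.isnan(x)
    vals = x[obs]
    if vals.size < 3:
        raise ValueError("normal_scores requires at least 3 observed values")
    if np.ptp(vals) == 0.0:
        warnings.warn("all observed values identical; returning input unchanged")
        return out
    n = vals.size
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    # rescale to the original first two moments
    z = (z - z.mean()) / z.std(ddof=0)
    out[obs] = vals.mean() + vals.std(ddof=0) * z
    return out


def normal_scores_frame(df: pd.DataFrame, columns, group: pd.Series | None = None
                        ) -> pd.DataFrame:
    """Apply :func:`normal_scores` to selected columns of a wide table.

    ``group`` optionally transforms within levels of a label series (e.g.
    per sex) instead of pooling the total sample.
    """
    out = df.copy()
    for col in columns:
        if group is None:
            out[col] = normal_scores(df[col].to_numpy())
        else:
            g = group.reindex(df.index)
            for level in g.dropna().unique():
                mask = (g == level).to_numpy()
                out.loc[mask, col] = normal_scores(df.loc[mask, col].to_numpy())
    return out
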
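"""Correlation-based feature filtering.

Redundant columns are removed by a greedy scan in canonical column order: a
column is kept unless its absolute Pearson correlation with some already-kept
column exceeds the threshold (strictly).  Constant columns, whose correlation
is undefined, are dropped and logged.  The procedure is deterministic and
independent of row order, and idempotent by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def pearson_filter(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Names of the columns kept by the greedy |r| > threshold filter.

    Output order preserves input column order (first of any redundant pair
    wins).  Requires >= 2 rows; threshold must lie in (0, 1].
    """
    if len(X) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    values = X.to_numpy(dtype=float)
    names = list(X.columns)
    stds = values.std(axis=0)
    kept: list[int] = []
    for j, name in enumerate(names):
        if stds[j] == 0.0:
            logger.info("dropping constant column %r (correlation undefined)", name)
            continue
        redundant = False
        for k in kept:
            r = np.corrcoef(values[:, j], values[:, k])[0, 1]
            if abs(r) > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(j)
    return [names[j] for j in kept]


def apply_filter(X: pd.DataFrame, kept: list[str]) -> pd.DataFrame:
    """Project a feature frame onto a previously selected column set."""
    missing = [c for c in kept if c not in X.columns]
    if missing:
        raise KeyError(f"selected columns absent from frame: {missing[:5]}")
    return X.loc[:, kept]
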
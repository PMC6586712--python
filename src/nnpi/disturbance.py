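"""Composite site-level human-disturbance index.

Eight raw sub-indices (physical disturbance classes, hydrologic alteration,
soil heavy metals) are each min-max standardized across all sampled sites
to a 0-10 scale, summed, and scaled by 10/8 to give an overall site index
on 0-100.  A constant sub-index carries no signal and standardizes to 0
(with a logged warning); a site missing any sub-index reports a missing
overall score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUB_INDEX_COLUMNS = [f"idx{i}" for i in range(1, 9)]


def standardize_index(x, min_x: float, max_x: float):
    """Linear rescale of a raw sub-index to [0, 10] given the dataset
    min/max; a degenerate (constant) index maps to 0 everywhere."""
    x = np.asarray(x, dtype=float)
    if max_x < min_x:
        raise ValueError(f"max_x ({max_x}) < min_x ({min_x})")
    if max_x == min_x:
        log.warning("constant sub-index (min == max == %s); scoring 0", min_x)
        out = np.zeros_like(x)
    else:
        out = (x - min_x) / (max_x - min_x) * 10.0
    return float(out) if out.ndim == 0 else out


def overall_disturbance(scores) -> float:
    """Combine eight standardized 0-10 scores: (sum) * 10/8, range 0-100."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (8,):
        raise ValueError(f"expected exactly 8 sub-index scores, got shape {scores.shape}")
    if np.isnan(scores).any():
        return float("nan")
    if ((scores < 0) | (scores > 10)).any():
        raise ValueError("standardized scores must lie in [0, 10]")
    return float(scores.sum() * 10.0 / 8.0)


def score_disturbance(
    disturbance: pd.DataFrame,
    reference_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Standardize all eight sub-indices and compute the overall index.

    Min/max default to the dataset being processed; fixed
    ``reference_ranges`` (column -> (min, max)) may be supplied for
    cross-dataset comparability.  Returns the input plus ``score_idx1..8``
    and ``overall`` columns; sites with any missing sub-index get a missing
    overall score.
    """
    missing = [c for c in SUB_INDEX_COLUMNS if c not in disturbance.columns]
    if missing:
        raise ValueError(f"disturbance table missing column(s) {missing}")
    out = disturbance.copy()
    for col in SUB_INDEX_COLUMNS:
        raw = out[col].astype(float)
        if reference_ranges and col in reference_ranges:
            lo, hi = reference_ranges[col]
        else:
            lo, hi = float(raw.min()), float(raw.max())
        # clipping only binds when fixed reference ranges narrower than the
        # data are supplied
        out[f"score_{col}"] = np.clip(
            standardize_index(raw.to_numpy(), lo, hi), 0.0, 10.0
        )
    score_cols = [f"score_{c}" for c in SUB_INDEX_COLUMNS]
    scores = out[score_cols].to_numpy()
    overall = scores.sum(axis=1) * 10.0 / 8.0
    overall[np.isnan(scores).any(axis=1)] = np.nan
    out["overall"] = overall
    return out
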
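"""Detection filtering and quantile normalization of probe-level matrices."""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from .types import ExpressionExperiment, FilterSummary, ValidationError, truncate


def detection_calls(p_values: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean detection calls from a detection p-value matrix (p < alpha)."""
    return p_values < alpha


def detection_filter(
    exp: ExpressionExperiment, keep_nonhuman: bool = False
) -> Tuple[ExpressionExperiment, FilterSummary]:
    """Drop non-human probes and probes detected in no sample.

    A probe is retained when it is flagged human (unless ``keep_nonhuman``)
    and carries a detected call in at least one sample. The summary reports
    the retained percentage truncated to 2 decimals.
    """
    if exp.intensities.empty:
        raise ValidationError("cannot filter an empty expression matrix")
    keep = exp.detected.any(axis=1)
    if not keep_nonhuman:
        keep &= exp.probe_meta["human"].reindex(exp.intensities.index).fillna(False).astype(bool)
    total = int(len(keep))
    retained = int(keep.sum())
    summary = FilterSummary(total=total, retained=retained, percentage=truncate(100.0 * retained / total, 2))
    if retained == 0:
        warnings.warn("detection filter removed every probe", stacklevel=2)
    return exp.subset_probes(exp.intensities.index[keep]), summary


def quantile_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common (row-mean-of-sorted) distribution.

    Tied values within a column receive the mean of the candidate quantile
    values, so the operation is idempotent. Indexing is preserved.
    """
    if intensities.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if intensities.isna().any().any():
        raise ValidationError("missing values present; impute or remove them upstream")
    v = intensities.to_numpy(dtype=float)
    n = v.shape[0]
    mean_sorted = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="mergesort")
        sv = col[order]
        starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        counts = np.diff(np.r_[starts, n])
        block_means = np.add.reduceat(mean_sorted, starts) / counts
        out[order, j] = np.repeat(block_means, counts)
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)
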
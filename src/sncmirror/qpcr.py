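"""ddCT relative quantification, platform concordance and group comparison.

Relative expression follows the 2^-ddCT convention: per sample, each assay's
CT is normalized against the arithmetic mean CT of the endogenous-control
assays (equivalent to the geometric mean of their expression); group-level
dCT means are then contrasted against a reference group and exponentiated.
Cross-platform concordance is Pearson's r between array and qPCR log2 fold
changes. Group comparisons gate the test choice on Shapiro-Wilk normality:
t-test when normal, Wilcoxon otherwise (paired variants on paired designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import QpcrPlate, ValidationError

REPLICATE_SD_FLAG = 0.5  # cycles; triplicates wider than this are suspect


def collapse_replicates(plate: QpcrPlate) -> pd.DataFrame:
    """Mean CT per (sample, assay); flags records with replicate SD > 0.5.

    Returns columns sample, assay, ct, is_control, flagged. Single-replicate
    records are unflagged.
    """
    g = plate.records.groupby(["sample", "assay"], as_index=False).agg(
        ct=("ct", "mean"),
        sd=("ct", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        is_control=("is_control", "first"),
    )
    g["flagged"] = g["sd"] > REPLICATE_SD_FLAG
    return g.drop(columns="sd")


def delta_delta_ct(
    plate: QpcrPlate,
    design: Optional[Mapping[str, str]] = None,
    reference_group: str = "reference",
) -> pd.DataFrame:
    """Per-assay per-group fold changes by the 2^-ddCT method.

    dCT(sample, assay) = CT(assay) - mean CT of the sample's endogenous
    controls; ddCT(group, assay) = mean dCT(group) - mean dCT(reference);
    fold = 2^-ddCT (reference fold is exactly 1). Returns a table indexed by
    (assay, group) with columns delta_delta_ct and fold.
    """
    groups = pd.Series(design) if design is not None else plate.groups
    if reference_group not in set(groups):
        raise ValidationError(f"reference group {reference_group!r} absent from design")
    collapsed = collapse_replicates(plate)
    ctrl = collapsed[collapsed["is_control"]].groupby("sample")["ct"].mean()
    missing = set(collapsed["sample"]) - set(ctrl.index)
    if missing:
        raise ValidationError(f"samples lacking endogenous-control assays: {sorted(missing)}")
    targets = collapsed[~collapsed["is_control"]].copy()
    targets["dct"] = targets["ct"] - targets["sample"].map(ctrl)
    targets["group"] = targets["sample"].map(groups)
    if targets["group"].isna().any():
        bad = sorted(targets.loc[targets["group"].isna(), "sample"].unique())
        raise ValidationError(f"samples missing from design: {bad}")
    mean_dct = targets.groupby(["assay", "group"])["dct"].mean()
    rows = []
    for assay in mean_dct.index.get_level_values(0).unique():
        ref = mean_dct[(assay, reference_group)]
        for group in mean_dct[assay].index:
            ddct = mean_dct[(assay, group)] - ref
            rows.append((assay, group, ddct, 2.0**-ddct))
    return pd.DataFrame(rows, columns=["assay", "group", "delta_delta_ct", "fold"]).set_index(
        ["assay", "group"]
    )


def platform_concordance(
    array_log2fc: Mapping[str, float], qpcr_log2fc: Mapping[str, float]
) -> Tuple[float, float]:
    """Pearson r and two-sided p between array and qPCR log2 fold changes."""
    keys = sorted(set(array_log2fc) & set(qpcr_log2fc))
    if len(keys) < 3:
        raise ValidationError("platform concordance needs >= 3 paired values")
    a = np.array([array_log2fc[k] for k in keys], dtype=float)
    b = np.array([qpcr_log2fc[k] for k in keys], dtype=float)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
    shapiro_p: Tuple[Optional[float], ...]
    paired: bool


def _shapiro_normal(x: np.ndarray, alpha: float) -> Tuple[bool, Optional[float]]:
    if np.ptp(x) == 0:  # constant data: Shapiro undefined, treat as normal
        return True, None
    p = float(stats.shapiro(x).pvalue)
    return p >= alpha, p


def group_compare(
    values_a, values_b, paired: bool = False, alpha: float = 0.05
) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison.

    Paired designs test the differences (Shapiro on a-b; paired t or signed-
    rank Wilcoxon); unpaired designs require both groups normal for the
    t-test, otherwise fall back to the rank-sum Wilcoxon. Degenerate inputs
    with no variation report p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs >= 3 values")
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired comparison requires equal-length groups")
        d = a - b
        normal, sp = _shapiro_normal(d, alpha)
        shapiro_ps: Tuple[Optional[float], ...] = (sp,)
        if np.ptp(d) == 0 and d[0] == 0:
            return GroupComparison("t", 0.0, 1.0, shapiro_ps, True)
        if normal:
            res = stats.ttest_rel(a, b)
            return GroupComparison("t", float(res.statistic), float(res.pvalue), shapiro_ps, True)
        res = stats.wilcoxon(a, b)
        return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_ps, True)
    na, pa = _shapiro_normal(a, alpha)
    nb, pb = _shapiro_normal(b, alpha)
    shapiro_ps = (pa, pb)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return GroupComparison("t", 0.0, 1.0, shapiro_ps, False)
    if na and nb:
        res = stats.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), shapiro_ps, False)
    res = stats.ranksums(a, b)
    return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_ps, False)
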
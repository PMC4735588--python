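"""Mirror-pattern analysis: shared two-phase signatures and the sign test.

A probe shows the *mirror pattern* when it is differentially expressed in
both disease phases but in opposite directions, each measured against healthy
controls (overexpressed in relapse while underexpressed in remission, or vice
versa). Given two differential-expression results and control-referenced fold
changes for both phases, :func:`shared_signature` intersects the significant
sets and labels each shared probe opposite or concordant; :func:`sign_test`
attaches the exact one-sided binomial p-value under the symmetric null that
every shared probe is opposite with probability 1/2 independently.
"""

from __future__ import annotations

from math import comb
from typing import Mapping, NamedTuple, Optional, Set

import numpy as np
import pandas as pd

from .types import DifferentialResult, MirrorReport, ValidationError


def sign_test(n: int, k: int) -> float:
    """Exact one-sided sign test: P(X >= k) for X ~ Binomial(n, 1/2)."""
    if n < 1:
        raise ValidationError("sign test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValidationError("k must lie in [0, n]")
    return sum(comb(n, i) for i in range(k, n + 1)) / 2**n


def shared_signature(
    de_a: DifferentialResult,
    de_b: DifferentialResult,
    fc_reference: pd.DataFrame,
) -> MirrorReport:
    """Intersect two significant sets and classify direction concordance.

    ``fc_reference`` must carry two columns — control-referenced log2 fold
    changes of phase A and phase B, in that order — indexed by probe. A
    shared probe is *opposite* when the two signs disagree strictly; a zero
    fold change counts as concordant (conservative toward the mirror claim).
    """
    if fc_reference.shape[1] != 2:
        raise ValidationError("fc_reference needs exactly two columns (phase A FC, phase B FC)")
    shared_probes = sorted(de_a.significant_probes & de_b.significant_probes)
    missing = [p for p in shared_probes if p not in fc_reference.index]
    if missing:
        raise ValidationError(f"control-referenced FC missing for shared probes: {missing}")
    fa = fc_reference.iloc[:, 0].reindex(shared_probes).to_numpy(dtype=float)
    fb = fc_reference.iloc[:, 1].reindex(shared_probes).to_numpy(dtype=float)
    opposite = np.sign(fa) * np.sign(fb) < 0
    shared = pd.DataFrame(
        {"fc_a": fa, "fc_b": fb, "opposite": opposite},
        index=pd.Index(shared_probes, name="probe"),
    )
    n, k = len(shared_probes), int(opposite.sum())
    return MirrorReport(
        shared=shared,
        n_shared=n,
        n_opposite=k,
        pct_opposite=100.0 * k / n if n else None,
        p_sign=sign_test(n, k) if n else None,
    )


class ListComparison(NamedTuple):
    same_direction: Set[str]
    opposite_direction: Set[str]
    a_only: Set[str]
    b_only: Set[str]


def compare_lists(
    list_a: Mapping[str, str], list_b: Mapping[str, str]
) -> ListComparison:
    """Partition two direction-labelled probe lists into four disjoint sets.

    Directions are "up"/"down"; probes present in both lists are split into
    same-direction and opposite-direction sets.
    """
    a, b = set(list_a), set(list_b)
    both = a & b
    same = {p for p in both if list_a[p] == list_b[p]}
    return ListComparison(
        same_direction=same,
        opposite_direction=both - same,
        a_only=a - b,
        b_only=b - a,
    )


def plot_mirror(report: MirrorReport, path: str, labels=("relapse", "remission")) -> None:
    """Two-panel bar plot of the shared signature's control-referenced FCs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, col, label in zip(axes, ("fc_a", "fc_b"), labels):
        vals = report.shared[col]
        ax.bar(range(len(vals)), vals, color=np.where(vals >= 0, "#c0392b", "#2980b9"))
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels(report.shared.index, rotation=90, fontsize=7)
        ax.axhline(0, color="black", lw=0.8)
        ax.set_title(f"{label} vs control")
        ax.set_ylabel("log2 FC vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
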
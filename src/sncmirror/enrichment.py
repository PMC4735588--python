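"""Hypergeometric over-representation analysis with Benjamini-Hochberg control.

For a query gene set drawn from a background (here, the blood-expressed
genes), each term of a GMT collection is tested with the upper hypergeometric
tail P(X >= overlap), population = |background|, successes = |term ∩
background|, draws = |query|. p-values are adjusted across all tested terms
by the BH step-up procedure; a term is significant when its q-value falls
below alpha.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentResult, ValidationError


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: Set[str],
    background: Set[str],
    collection: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Test every term of ``collection`` for over-representation in ``query``."""
    offenders = set(query) - set(background)
    if offenders:
        raise ValidationError(f"query genes outside the background: {sorted(offenders)}")
    bg = set(background)
    q = set(query)
    rows = []
    for term, genes in collection.items():
        t = set(genes) & bg
        overlap = t & q
        k, m_pop, n_succ, n_draw = len(overlap), len(bg), len(t), len(q)
        p = float(hypergeom.sf(k - 1, m_pop, n_succ, n_draw)) if n_succ else 1.0
        rows.append((term, n_succ, k, ",".join(sorted(overlap)), p))
    table = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "overlap_genes", "p_hyper"]
    ).set_index("term")
    table["q_bh"] = bh_adjust(table["p_hyper"]) if len(table) else []
    table["significant"] = table["q_bh"] < alpha
    return EnrichmentResult(table=table, alpha=alpha)
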
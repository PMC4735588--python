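"""Rank-product differential expression with a permutation null.

The rank product of a probe is the geometric mean, across ratio columns, of
its within-column rank (ascending ratios for the "down" direction, descending
for "up"; ties receive average ranks). Small rank products flag consistently
extreme regulation. Significance comes from a permutation null that shuffles
probe labels independently within every column, preserving each column's rank
multiset:

* ``p_perm(g)`` — pooled permutation p-value: (1 + #{permuted RP <= observed
  RP(g)}) / (1 + n_permutations * n_probes).
* ``E[FP](g)`` — expected number of false positives at g's rank:
  #{permuted RP <= observed RP(g)} / n_permutations.
* ``pFP(g)`` — E[FP](g) / rank(g), the expected proportion of false positives
  among probes called at g's rank (the rank-product analogue of FDR), capped
  at 1 and monotonized by a cumulative minimum from worst to best RP.

Paired two-class designs use one ratio column per patient; unpaired designs
use every class-a x class-b cross pair of samples.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import Comparison, DifferentialResult, ExpressionExperiment, ValidationError

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


def _stratum_design(design: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "females":
        return design[design["sex"] == "F"]
    if stratum == "males":
        return design[design["sex"] == "M"]
    return design


def _resolve_classes(exp: ExpressionExperiment, comp: Comparison):
    """Design rows of the two classes after stratum/treatment filtering."""
    design = _stratum_design(exp.design, comp.stratum)
    a = design[design["phase"] == comp.class_a]
    b = design[design["phase"] == comp.class_b]
    if comp.same_treatment_only and "control" not in (comp.class_a, comp.class_b):
        treat_a = a.set_index("patient")["treatment"]
        treat_b = b.set_index("patient")["treatment"]
        same = {p for p in set(treat_a.index) & set(treat_b.index) if treat_a[p] == treat_b[p]}
        a = a[a["patient"].isin(same)]
        b = b[b["patient"].isin(same)]
    return a, b


def build_ratio_matrix(exp: ExpressionExperiment, comp: Comparison) -> pd.DataFrame:
    """Per-comparison log2 ratios (class_b is the reference).

    Paired: one column per patient owning both phases. Unpaired: one column
    per (a, b) cross pair of samples. Raises when fewer than 2 usable columns
    result.
    """
    a, b = _resolve_classes(exp, comp)
    x = exp.intensities
    cols = {}
    if comp.paired:
        a_by_pat = dict(zip(a["patient"], a.index))
        b_by_pat = dict(zip(b["patient"], b.index))
        for pat in sorted(set(a_by_pat) | set(b_by_pat)):
            if pat not in a_by_pat or pat not in b_by_pat:
                logger.warning("patient %s lacks one phase; excluded from paired comparison %s", pat, comp.name)
                continue
            cols[pat] = x[a_by_pat[pat]] - x[b_by_pat[pat]]
    else:
        for sa in a.index:
            for sb in b.index:
                cols[f"{sa}|{sb}"] = x[sa] - x[sb]
    if len(cols) < 2:
        raise ValidationError(
            f"comparison {comp.name!r} yields {len(cols)} usable ratio column(s); need >= 2"
        )
    return pd.DataFrame(cols)


def _rank_matrix(ratios: np.ndarray, direction: str) -> np.ndarray:
    signed = ratios if direction == "down" else -ratios
    return rankdata(signed, axis=0, method="average")


def _null_tables(
    index: pd.Index,
    obs_rp: Dict[str, np.ndarray],
    counts: Dict[str, np.ndarray],
    order: Dict[str, np.ndarray],
    n_permutations: int,
) -> Dict[str, pd.DataFrame]:
    """Assemble p_perm / E[FP] / pFP tables from pooled tail counts.

    ``counts[d]`` holds, in RP-ascending order, the number of permuted RPs
    <= each observed RP. pFP = E[FP]/rank, capped at 1 and monotonized by a
    cumulative minimum from worst to best RP.
    """
    n = len(index)
    out: Dict[str, pd.DataFrame] = {}
    for d in DIRECTIONS:
        c_sorted = counts[d].astype(float)
        p_sorted = (1.0 + c_sorted) / (1.0 + n_permutations * n)
        e_fp_sorted = c_sorted / n_permutations
        sorted_obs = obs_rp[d][order[d]]
        ranks_sorted = rankdata(sorted_obs, method="average")
        pfp_sorted = np.minimum(e_fp_sorted / ranks_sorted, 1.0)
        pfp_sorted = np.minimum.accumulate(pfp_sorted[::-1])[::-1]
        inv = np.empty(n, dtype=int)
        inv[order[d]] = np.arange(n)
        out[d] = pd.DataFrame(
            {
                "rp": obs_rp[d],
                "rank": ranks_sorted[inv],
                "p_perm": p_sorted[inv],
                "e_fp": e_fp_sorted[inv],
                "pfp": pfp_sorted[inv],
            },
            index=index,
        )
    return out


def rank_product(ratios: pd.DataFrame, direction: str) -> pd.Series:
    """Geometric mean of per-column ranks (average ranks on ties)."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if ratios.shape[0] < 2:
        raise ValidationError("rank product needs >= 2 probes")
    r = _rank_matrix(ratios.to_numpy(dtype=float), direction)
    rp = np.exp(np.log(r).mean(axis=1))
    return pd.Series(rp, index=ratios.index, name=f"rp_{direction}")


def permutation_null(
    ratios: pd.DataFrame, n_permutations: int, seed: int
) -> Dict[str, pd.DataFrame]:
    """Permutation p-values and pFP per probe, for both directions.

    Each permutation shuffles probe labels independently within every column
    (one shared shuffle feeds both directions) and recomputes all rank
    products; observed values are compared against the pooled permuted pool.
    Returns {"up": table, "down": table} with columns rp, rank, p_perm, e_fp,
    pfp.
    """
    if n_permutations <= 0:
        raise ValidationError("n_permutations must be >= 1")
    v = ratios.to_numpy(dtype=float)
    n, k = v.shape
    if n < 2:
        raise ValidationError("rank product needs >= 2 probes")
    rng = np.random.default_rng(seed)
    log_ranks = {d: np.log(_rank_matrix(v, d)) for d in DIRECTIONS}
    obs_rp = {d: np.exp(log_ranks[d].mean(axis=1)) for d in DIRECTIONS}
    order = {d: np.argsort(obs_rp[d], kind="mergesort") for d in DIRECTIONS}
    sorted_obs = {d: obs_rp[d][order[d]] for d in DIRECTIONS}
    counts = {d: np.zeros(n, dtype=np.int64) for d in DIRECTIONS}
    col_idx = np.arange(k)
    for _ in range(n_permutations):
        idx = np.argsort(rng.random((n, k)), axis=0)
        for d in DIRECTIONS:
            perm_rp = np.exp(log_ranks[d][idx, col_idx].mean(axis=1))
            perm_rp.sort()
            # counts of permuted RPs <= each observed RP, via merged order
            counts[d] += np.searchsorted(perm_rp, sorted_obs[d], side="right")
    return _null_tables(ratios.index, obs_rp, counts, order, n_permutations)


def permutation_null_crosspairs(
    class_a: pd.DataFrame, class_b: pd.DataFrame, n_permutations: int, seed: int
) -> Dict[str, pd.DataFrame]:
    """Sample-level permutation null for unpaired cross-pair designs.

    Cross-pair ratio columns that share a sample are correlated (a sample's
    noise enters every column it participates in), so shuffling within ratio
    columns understates the null tails. Here every permutation shuffles probe
    labels within each *original sample* and rebuilds all class-a x class-b
    ratio columns, preserving the shared-sample correlation structure.
    """
    if n_permutations <= 0:
        raise ValidationError("n_permutations must be >= 1")
    xa = class_a.to_numpy(dtype=float)
    xb = class_b.to_numpy(dtype=float)
    n = xa.shape[0]
    if n < 2:
        raise ValidationError("rank product needs >= 2 probes")
    na, nb = xa.shape[1], xb.shape[1]
    rng = np.random.default_rng(seed)

    def _rp_pair(ratios: np.ndarray) -> Dict[str, np.ndarray]:
        down = rankdata(ratios, axis=0, method="average")
        return {
            "down": np.exp(np.log(down).mean(axis=1)),
            "up": np.exp(np.log(n + 1 - down).mean(axis=1)),
        }

    obs_ratios = (xa[:, :, None] - xb[:, None, :]).reshape(n, na * nb)
    obs_rp = _rp_pair(obs_ratios)
    order = {d: np.argsort(obs_rp[d], kind="mergesort") for d in DIRECTIONS}
    sorted_obs = {d: obs_rp[d][order[d]] for d in DIRECTIONS}
    counts = {d: np.zeros(n, dtype=np.int64) for d in DIRECTIONS}
    for _ in range(n_permutations):
        pa = np.argsort(rng.random((n, na)), axis=0)
        pb = np.argsort(rng.random((n, nb)), axis=0)
        xa_p = xa[pa, np.arange(na)]
        xb_p = xb[pb, np.arange(nb)]
        perm = _rp_pair((xa_p[:, :, None] - xb_p[:, None, :]).reshape(n, na * nb))
        for d in DIRECTIONS:
            perm[d].sort()
            counts[d] += np.searchsorted(perm[d], sorted_obs[d], side="right")
    return _null_tables(class_a.index, obs_rp, counts, order, n_permutations)


def differential_expression(
    exp: ExpressionExperiment,
    comp: Comparison,
    n_permutations: int = 1000,
    seed: int = 0,
    p_cut: float = 0.001,
    fdr_cut: float = 0.05,
) -> DifferentialResult:
    """Run the full rank-product test for one comparison.

    A probe is significant when, in at least one direction, p_perm <= p_cut
    and pFP < fdr_cut; its direction is the significant one (ties broken by
    the smaller rank product). log2_fc is the mean ratio with class_b as the
    reference, so positive values mean higher expression in class_a.
    """
    ratios = build_ratio_matrix(exp, comp)
    if comp.paired:
        null = permutation_null(ratios, n_permutations, seed)
    else:
        a, b = _resolve_classes(exp, comp)
        null = permutation_null_crosspairs(
            exp.intensities[list(a.index)], exp.intensities[list(b.index)], n_permutations, seed
        )
    up, down = null["up"], null["down"]
    sig_up = (up["p_perm"] <= p_cut) & (up["pfp"] < fdr_cut)
    sig_down = (down["p_perm"] <= p_cut) & (down["pfp"] < fdr_cut)
    prefer_up = np.where(
        sig_up & ~sig_down, True, np.where(sig_down & ~sig_up, False, up["rp"] <= down["rp"])
    )
    chosen = np.where(prefer_up, "up", "down")
    pick = lambda col: np.where(prefer_up, up[col], down[col])  # noqa: E731
    table = pd.DataFrame(
        {
            "direction": chosen,
            "rp": pick("rp"),
            "p_perm": pick("p_perm"),
            "pfp": pick("pfp"),
            "log2_fc": ratios.mean(axis=1),
            "significant": (sig_up | sig_down).to_numpy(),
        },
        index=ratios.index,
    )
    return DifferentialResult(
        table=table,
        comparison=comp,
        n_permutations=n_permutations,
        seed=seed,
        n_columns=ratios.shape[1],
    )


def fold_change_filter(fc: pd.Series, threshold: float = 2.0) -> pd.Index:
    """Probes with linear fold change strictly beyond |threshold|.

    Retains FC > threshold or FC < 1/threshold (i.e. |log2 FC| > log2 t);
    the boundary itself is excluded.
    """
    fc = pd.Series(fc, dtype=float)
    if (fc <= 0).any():
        raise ValidationError("fold changes must be positive linear-scale values")
    if threshold <= 1:
        raise ValidationError("threshold must exceed 1")
    return fc.index[(fc > threshold) | (fc < 1.0 / threshold)]
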
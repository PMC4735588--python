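"""miRNA-target prediction filtering and regulatory-network construction.

Predicted miRNA -> gene interactions pass three filters before entering the
network: a minimum number of predicting source algorithms (>= 3), a minimum
integrated confidence score (>= 40 on the 0-100 standard-score scale), and
membership of the target gene in a tissue-expressed gene list. A fourth,
biological filter keeps only anti-correlated pairs — target fold change of
the opposite sign to the regulator miRNA's — reflecting the repressive mode
of miRNA action. The surviving records form a bipartite directed graph whose
gene nodes are annotated as transcription factors and/or GWAS-associated.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Set

import networkx as nx
import numpy as np
import pandas as pd

from .types import RegulatoryNetwork, ValidationError

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["mirna", "gene", "n_sources", "score"]


def _check(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(PREDICTION_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"prediction table lacks columns: {sorted(missing)}")
    if len(records) and ((records["score"] < 0) | (records["score"] > 100)).any():
        raise ValidationError("scores must lie in [0, 100]")
    if len(records) and (records["n_sources"] < 1).any():
        raise ValidationError("n_sources must be >= 1")
    return records


def filter_predictions(
    records: pd.DataFrame, min_sources: int = 3, min_score: float = 40.0
) -> pd.DataFrame:
    """Keep records with n_sources >= min_sources and score >= min_score."""
    records = _check(records)
    return records[(records["n_sources"] >= min_sources) & (records["score"] >= min_score)]


def expression_filter(records: pd.DataFrame, expressed_genes: Set[str]) -> pd.DataFrame:
    """Keep records whose target gene belongs to the expressed-gene set."""
    records = _check(records)
    if not expressed_genes:
        raise ValidationError("expressed_genes must be non-empty")
    return records[records["gene"].isin(expressed_genes)]


def anticorrelation_filter(
    records: pd.DataFrame,
    mirna_fc: Mapping[str, float],
    gene_fc: Mapping[str, float],
) -> pd.DataFrame:
    """Keep records whose miRNA and gene log2 FCs have strictly opposite signs.

    Records with a missing fold change on either endpoint, or a zero fold
    change (no opposition demonstrable), are dropped; missing endpoints are
    logged.
    """
    records = _check(records)
    if records.empty:
        return records
    mf = records["mirna"].map(lambda m: mirna_fc.get(m, np.nan)).to_numpy(dtype=float)
    gf = records["gene"].map(lambda g: gene_fc.get(g, np.nan)).to_numpy(dtype=float)
    n_missing = int(np.isnan(mf).sum() + np.isnan(gf).sum())
    if n_missing:
        logger.warning("anticorrelation filter dropped records with missing fold changes")
    keep = np.sign(mf) * np.sign(gf) < 0
    keep &= ~np.isnan(mf) & ~np.isnan(gf)
    return records[keep]


def dedupe_predictions(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (miRNA, gene) rows, keeping the maximum score/sources."""
    records = _check(records)
    if records.empty:
        return records
    return (
        records.groupby(["mirna", "gene"], as_index=False)
        .agg(n_sources=("n_sources", "max"), score=("score", "max"))
    )


def build_network(
    records: pd.DataFrame,
    tf_set: Set[str],
    gwas_set: Set[str],
    mirna_fc: Mapping[str, float],
    gene_fc: Mapping[str, float],
) -> RegulatoryNetwork:
    """Assemble the annotated bipartite miRNA -> gene graph.

    Node kinds: "miRNA" for sources, "TF" for targets in ``tf_set``, "gene"
    otherwise; ``gwas_flag`` marks disease-associated genes; ``degree`` is
    the incident edge count. Weakly connected components are counted. A gene
    that also appears as a miRNA source violates bipartiteness and raises.
    """
    records = dedupe_predictions(_check(records))
    g = nx.DiGraph()
    if records.empty:
        return RegulatoryNetwork(graph=g, n_components=0)
    mirnas = set(records["mirna"])
    genes = set(records["gene"])
    clash = mirnas & genes
    if clash:
        raise ValidationError(f"bipartite violation: appear as both miRNA and target: {sorted(clash)}")
    for m in sorted(mirnas):
        g.add_node(m, kind="miRNA", log2_fc=float(mirna_fc.get(m, np.nan)), gwas_flag=False)
    for t in sorted(genes):
        g.add_node(
            t,
            kind="TF" if t in tf_set else "gene",
            log2_fc=float(gene_fc.get(t, np.nan)),
            gwas_flag=t in gwas_set,
        )
    g.add_edges_from(records[["mirna", "gene"]].itertuples(index=False, name=None))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.in_degree(n) + g.out_degree(n)
    return RegulatoryNetwork(graph=g, n_components=nx.number_weakly_connected_components(g))
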
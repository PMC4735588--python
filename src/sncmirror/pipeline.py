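"""End-to-end orchestration: preprocess -> DE per stratum -> mirror ->
network -> enrichment -> qPCR concordance.

A single :class:`RunConfig` drives the run. Inputs come either from a
synthetic-cohort block (the bundled generator, recommended for demos and
tests) or from files on disk; every random draw derives from the single
configured seed, so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .enrichment import hypergeom_enrich
from .mirror import shared_signature
from .network import (
    anticorrelation_filter,
    build_network,
    expression_filter,
    filter_predictions,
)
from .preprocess import detection_filter, quantile_normalize
from .qpcr import delta_delta_ct, group_compare, platform_concordance
from .rankprod import differential_expression
from .simulate import simulate_cohort, simulate_genesets, simulate_predictions, simulate_qpcr
from .types import CohortConfig, Comparison, ConfigError, ValidationError

logger = logging.getLogger(__name__)

STRATA = ("all", "females", "males")


def default_comparisons(stratum: str) -> List[Comparison]:
    return [
        Comparison(f"relapse_vs_control_{stratum}", "relapse", "control", paired=False, stratum=stratum),
        Comparison(f"remission_vs_control_{stratum}", "remission", "control", paired=False, stratum=stratum),
        Comparison(
            f"relapse_vs_remission_{stratum}",
            "relapse",
            "remission",
            paired=True,
            stratum=stratum,
            same_treatment_only=True,
        ),
    ]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Either ``cohort`` (synthetic mode) or ``input_dir`` (a directory written
    by :func:`sncmirror.io.write_experiment`, plus prediction/annotation
    files) must be given. Thresholds default to the analysis' standard
    values: permutation p <= 0.001, pFP < 0.05, >= 3 predicting sources,
    score >= 40, enrichment alpha 0.05.
    """

    outdir: str
    seed: int
    cohort: Optional[CohortConfig] = None
    input_dir: Optional[str] = None
    predictions_path: Optional[str] = None
    gene_fc_path: Optional[str] = None  # two columns: gene, log2_fc (+ optional tf/gwas flags)
    gmt_path: Optional[str] = None
    n_permutations: int = 1000
    p_cut: float = 0.001
    fdr_cut: float = 0.05
    min_sources: int = 3
    min_score: float = 40.0
    alpha: float = 0.05
    n_decoys: int = 100
    n_terms: int = 20
    qpcr_ct_sd: float = 0.25
    strata: tuple = STRATA

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            raise ConfigError("either a synthetic cohort block or input_dir is required")
        if self.seed is None:
            raise ConfigError("seed is required")
        for name, v, lo, hi in (
            ("p_cut", self.p_cut, 0.0, 1.0),
            ("fdr_cut", self.fdr_cut, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("min_score", self.min_score, 0.0, 100.0),
        ):
            if not lo <= v <= hi:
                raise ConfigError(f"{name} out of range [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "n_permutations": config.n_permutations, "stages": {}}

    # ------------------------------------------------------------------ input
    truth = None
    if config.cohort is not None:
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        exp, truth = simulate_cohort(cohort)
        io_mod.write_experiment(exp, out / "input")
    else:
        exp = io_mod.read_experiment(config.input_dir)

    # ------------------------------------------------------------- preprocess
    exp.intensities = quantile_normalize(exp.intensities)
    exp, summary = detection_filter(exp)
    report["stages"]["preprocess"] = {
        "total_probes": summary.total,
        "retained_probes": summary.retained,
        "retained_pct": summary.percentage,
    }

    # ------------------------------------------------------- DE per stratum
    de_results: Dict[str, object] = {}
    de_report: dict = {}
    for stratum in config.strata:
        for comp in default_comparisons(stratum):
            try:
                res = differential_expression(
                    exp,
                    comp,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    p_cut=config.p_cut,
                    fdr_cut=config.fdr_cut,
                )
            except ValidationError as err:
                logger.warning("skipping %s: %s", comp.name, err)
                de_report[comp.name] = {"skipped": str(err)}
                continue
            de_results[comp.name] = res
            res.table.to_csv(out / f"de_{comp.name}.tsv", sep="\t")
            io_mod.write_json(
                {
                    "comparison": comp.name,
                    "n_columns": res.n_columns,
                    "n_permutations": res.n_permutations,
                    "seed": res.seed,
                },
                out / f"de_{comp.name}.meta.json",
            )
            de_report[comp.name] = {
                "n_columns": res.n_columns,
                "n_significant": int(res.table["significant"].sum()),
            }
    report["stages"]["differential_expression"] = de_report

    # ----------------------------------------------------------------- mirror
    mirror_report: dict = {}
    for stratum in config.strata:
        rel = de_results.get(f"relapse_vs_control_{stratum}")
        rem = de_results.get(f"remission_vs_control_{stratum}")
        if rel is None or rem is None:
            mirror_report[stratum] = {"skipped": "missing phase-vs-control result"}
            continue
        fc_ref = pd.DataFrame(
            {"relapse": rel.table["log2_fc"], "remission": rem.table["log2_fc"]}
        )
        rep = shared_signature(rel, rem, fc_ref)
        rep.shared.to_csv(out / f"mirror_{stratum}.tsv", sep="\t")
        io_mod.write_json(rep.to_dict(), out / f"mirror_{stratum}.json")
        mirror_report[stratum] = {
            "n_shared": rep.n_shared,
            "n_opposite": rep.n_opposite,
            "pct_opposite": rep.pct_opposite_rounded,
            "p_sign": rep.p_sign,
        }
    report["stages"]["mirror"] = mirror_report

    # ---------------------------------------------------------------- network
    if config.cohort is not None and truth is not None and truth.regulation_pairs:
        predictions = simulate_predictions(truth, n_decoys=config.n_decoys, seed=config.seed + 1)
        gene_fc = dict(truth.gene_log2_fc)
        mirna_fc = dict(truth.mirna_log2_fc)
        genes = sorted(gene_fc)
        tf_set = set(genes[::5])
        gwas_set = set(genes[::7])
        expressed = set(genes)
    elif config.predictions_path and config.gene_fc_path:
        predictions = io_mod.read_predictions(config.predictions_path)
        ann = pd.read_csv(config.gene_fc_path, sep="\t", index_col=0)
        gene_fc = dict(ann["log2_fc"])
        tf_set = set(ann.index[ann.get("tf", pd.Series(False, index=ann.index)).astype(bool)])
        gwas_set = set(ann.index[ann.get("gwas", pd.Series(False, index=ann.index)).astype(bool)])
        expressed = set(ann.index)
        mirna_fc = {}
        for res in de_results.values():
            mirna_fc.update(dict(res.significant["log2_fc"]))
    else:
        predictions = None

    network = None
    if predictions is not None:
        if not mirna_fc:  # fall back to planted/known miRNA fold changes only
            logger.warning("no miRNA fold changes available; network skipped")
            report["stages"]["network"] = {"skipped": "no miRNA fold changes"}
        else:
            kept = filter_predictions(predictions, config.min_sources, config.min_score)
            kept = expression_filter(kept, expressed)
            kept = anticorrelation_filter(kept, mirna_fc, gene_fc)
            network = build_network(kept, tf_set, gwas_set, mirna_fc, gene_fc)
            io_mod.write_graphml(network, out / "network.graphml")
            io_mod.write_sif(network, out / "network.sif")
            network.node_table.to_csv(out / "network_nodes.tsv", sep="\t")
            nt = network.node_table
            report["stages"]["network"] = {
                "n_records_in": int(len(predictions)),
                "n_records_kept": int(len(kept)),
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "n_components": network.n_components,
                "n_mirna": int((nt["kind"] == "miRNA").sum()) if len(nt) else 0,
                "n_tf": int((nt["kind"] == "TF").sum()) if len(nt) else 0,
                "n_gene": int((nt["kind"] == "gene").sum()) if len(nt) else 0,
            }
    else:
        report["stages"]["network"] = {"skipped": "no prediction table"}

    # ------------------------------------------------------------- enrichment
    if network is not None and network.n_nodes:
        nt = network.node_table
        query = set(nt.index[nt["kind"] != "miRNA"]) & expressed
        if config.gmt_path:
            collection = io_mod.read_gmt(config.gmt_path)
        else:
            planted = sorted(query)[: max(min(len(query), 10), 1)]
            collection = simulate_genesets(
                sorted(expressed), n_terms=config.n_terms, enriched_term_genes=planted,
                seed=config.seed + 2,
            )
        enr = hypergeom_enrich(query, expressed, collection, alpha=config.alpha)
        enr.table.to_csv(out / "enrichment.tsv", sep="\t")
        report["stages"]["enrichment"] = {
            "n_terms": int(len(enr.table)),
            "n_significant": int(enr.table["significant"].sum()),
        }
    else:
        report["stages"]["enrichment"] = {"skipped": "no network genes"}

    # ------------------------------------------------------------------ qPCR
    if config.cohort is not None and truth is not None and len(truth.mirna_log2_fc) >= 3:
        top = sorted(truth.mirna_log2_fc, key=lambda m: -abs(truth.mirna_log2_fc[m]))[:11]
        planted = {m: float(2.0 ** truth.mirna_log2_fc[m]) for m in top}
        plate = simulate_qpcr(planted, ct_sd=config.qpcr_ct_sd, seed=config.seed + 3)
        ddct = delta_delta_ct(plate, reference_group="reference")
        qpcr_fc = {
            assay: float(np.log2(ddct.loc[(assay, "case"), "fold"])) for assay in planted
        }
        array_fc = {m: truth.mirna_log2_fc[m] for m in planted}
        r, p = platform_concordance(array_fc, qpcr_fc)
        ddct.to_csv(out / "qpcr_ddct.tsv", sep="\t")
        io_mod.write_json(
            {"pearson_r": r, "pearson_p": p, "assays": sorted(planted)}, out / "qpcr_report.json"
        )
        report["stages"]["qpcr"] = {"n_assays": len(planted), "pearson_r": r, "pearson_p": p}
    else:
        report["stages"]["qpcr"] = {"skipped": "no planted fold changes / no plate input"}

    io_mod.write_json(report, out / "report.json")
    return report
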
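"""Readers and writers for the pipeline's plain-text formats.

Matrices are tab-separated with a header row of sample ids and a first
column of probe ids; gene sets use the standard GMT layout (term,
description, member genes); networks are exported as GraphML (with node
attributes kind, log2_fc, gwas_flag, degree) and SIF; qPCR plates as
tab-separated replicate tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Union

import networkx as nx
import pandas as pd

from .types import ExpressionExperiment, QpcrPlate, RegulatoryNetwork

PathLike = Union[str, Path]


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t")


def read_design(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: PathLike) -> None:
    design.to_csv(path, sep="\t")


def write_experiment(exp: ExpressionExperiment, outdir: PathLike) -> None:
    """Three tab-separated files: intensities, detection calls, design (+ probe meta)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(exp.intensities, outdir / "intensities.tsv")
    write_matrix(exp.detected.astype(int), outdir / "detected.tsv")
    write_design(exp.design, outdir / "design.tsv")
    write_design(exp.probe_meta, outdir / "probe_meta.tsv")


def read_experiment(indir: PathLike) -> ExpressionExperiment:
    indir = Path(indir)
    meta = read_design(indir / "probe_meta.tsv")
    meta["human"] = meta["human"].astype(bool)
    return ExpressionExperiment(
        intensities=read_matrix(indir / "intensities.tsv"),
        detected=read_matrix(indir / "detected.tsv").astype(bool),
        design=read_design(indir / "design.tsv"),
        probe_meta=meta,
    )


def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    collection: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            collection[fields[0]] = [g for g in fields[2:] if g]
    return collection


def write_gmt(collection: Mapping[str, List[str]], path: PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in collection.items():
            fh.write("\t".join([term, description, *genes]) + "\n")


def write_graphml(net: RegulatoryNetwork, path: PathLike) -> None:
    nx.write_graphml(net.graph, path)


def read_graphml(path: PathLike) -> RegulatoryNetwork:
    g = nx.read_graphml(path)
    n_comp = nx.number_weakly_connected_components(g) if g.number_of_nodes() else 0
    return RegulatoryNetwork(graph=g, n_components=n_comp)


def write_sif(net: RegulatoryNetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in net.graph.edges:
            fh.write(f"{u}\ttargets\t{v}\n")


def read_predictions(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_predictions(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_plate(path: PathLike, groups_path: PathLike) -> QpcrPlate:
    records = pd.read_csv(path, sep="\t")
    records["is_control"] = records["is_control"].astype(bool)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return QpcrPlate(records=records, groups=groups)


def write_plate(plate: QpcrPlate, path: PathLike, groups_path: PathLike) -> None:
    out = plate.records.copy()
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, sep="\t", index=False)
    plate.groups.rename("group").to_csv(groups_path, sep="\t")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
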
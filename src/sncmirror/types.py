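"""Core containers shared across the pipeline stages.

The central object is :class:`ExpressionExperiment`: a probe x sample matrix of
log2 intensities together with same-shape boolean detection calls, a sample
design table (patient, phase, sex, treatment) and per-probe metadata (probe
class and a human/non-human flag). Every upstream stage (detection filtering,
quantile normalization, differential expression) transforms or consumes it.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Optional, Set, Tuple

import networkx as nx
import pandas as pd

PHASES = ("relapse", "remission", "control")
STRATA = ("all", "females", "males")


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


class ValidationError(ValueError):
    """Raised when an input table violates a structural precondition."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3), unlike banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (62.9169 -> 62.91)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_DOWN))


@dataclass
class ExpressionExperiment:
    """Probe-level expression experiment.

    Parameters
    ----------
    intensities
        Probe x sample matrix of log2 intensities.
    detected
        Boolean matrix with identical indexing: detection-above-background calls.
    design
        One row per sample (index = sample id) with columns ``patient``,
        ``phase`` (relapse/remission/control), ``sex`` (F/M), ``treatment``.
    probe_meta
        One row per probe (index = probe id) with columns ``kind``
        (miRNA/snoRNA/other) and ``human`` (bool).
    """

    intensities: pd.DataFrame
    detected: pd.DataFrame
    design: pd.DataFrame
    probe_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.detected.index) or not (
            self.intensities.columns.equals(self.detected.columns)
        ):
            raise ValidationError("intensities and detected must share identical probe/sample indexing")
        if self.design.index.has_duplicates:
            raise ValidationError("every sample id must appear exactly once in design")
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")
        for col in ("patient", "phase", "sex"):
            if col not in self.design.columns:
                raise ValidationError(f"design lacks required column {col!r}")
        bad_phase = set(self.design["phase"]) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"unknown phase labels: {sorted(bad_phase)}")
        # paired-cohort structure: a relapse sample implies a remission sample
        pat = self.design[self.design["phase"] != "control"]
        by_patient = pat.groupby("patient")["phase"].agg(set)
        orphans = [p for p, ph in by_patient.items() if ph == {"relapse"}]
        if orphans:
            raise ValidationError(f"relapse sample without matching remission for patients: {orphans}")
        extra = set(self.intensities.index) - set(self.probe_meta.index)
        if extra:
            raise ValidationError(f"probes missing from probe_meta: {sorted(extra)[:5]}...")

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset_probes(self, probes) -> "ExpressionExperiment":
        return ExpressionExperiment(
            intensities=self.intensities.loc[probes],
            detected=self.detected.loc[probes],
            design=self.design,
            probe_meta=self.probe_meta.loc[probes],
        )

    def subset_samples(self, samples) -> "ExpressionExperiment":
        return ExpressionExperiment(
            intensities=self.intensities[samples],
            detected=self.detected[samples],
            design=self.design.loc[samples],
            probe_meta=self.probe_meta,
        )


@dataclass(frozen=True)
class FilterSummary:
    total: int
    retained: int
    percentage: float  # 100*retained/total, truncated to 2 decimals


@dataclass(frozen=True)
class Comparison:
    """A two-class contrast resolved against the sample design.

    ``class_b`` is the reference: positive log2 ratios mean higher expression
    in ``class_a``. ``stratum`` restricts to females/males before pairing;
    ``same_treatment_only`` keeps only patients treated identically in both
    phases (only meaningful when both classes are patient phases).
    """

    name: str
    class_a: str
    class_b: str
    paired: bool = False
    stratum: str = "all"
    same_treatment_only: bool = False

    def __post_init__(self) -> None:
        if self.class_a not in PHASES or self.class_b not in PHASES:
            raise ConfigError(f"comparison classes must be one of {PHASES}")
        if self.stratum not in STRATA:
            raise ConfigError(f"stratum must be one of {STRATA}")
        if self.paired and "control" in (self.class_a, self.class_b):
            raise ConfigError("paired comparisons require two patient phases")


@dataclass
class DifferentialResult:
    """Per-probe rank-product output for one comparison x stratum.

    ``table`` columns: probe (index), direction (up/down), rp, p_perm, pfp,
    log2_fc, significant.
    """

    table: pd.DataFrame
    comparison: Comparison
    n_permutations: int
    seed: int
    n_columns: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def significant_probes(self) -> Set[str]:
        return set(self.significant.index)

    def directions(self) -> Dict[str, str]:
        """Direction label for every significant probe."""
        return dict(self.significant["direction"])


@dataclass
class MirrorReport:
    """Shared two-phase signature with per-probe direction concordance.

    ``shared`` columns: fc_a, fc_b (control-referenced log2 FC in the two
    phases) and ``opposite`` (True when the signs disagree).
    """

    shared: pd.DataFrame
    n_shared: int
    n_opposite: int
    pct_opposite: Optional[float]
    p_sign: Optional[float]

    @property
    def empty(self) -> bool:
        return self.n_shared == 0

    @property
    def pct_opposite_rounded(self) -> Optional[int]:
        if self.pct_opposite is None:
            return None
        return int(round_half_up(self.pct_opposite, 0))

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_opposite": self.n_opposite,
            "pct_opposite": self.pct_opposite,
            "pct_opposite_rounded": self.pct_opposite_rounded,
            "p_sign": self.p_sign,
            "probes": {
                str(p): {
                    "fc_a": float(r["fc_a"]),
                    "fc_b": float(r["fc_b"]),
                    "opposite": bool(r["opposite"]),
                }
                for p, r in self.shared.iterrows()
            },
        }


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA -> gene graph with annotated nodes.

    Node attributes: kind (miRNA/TF/gene), log2_fc, gwas_flag, degree.
    """

    graph: nx.DiGraph
    n_components: int

    @property
    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "kind": d["kind"],
                "log2_fc": d["log2_fc"],
                "gwas_flag": d["gwas_flag"],
                "degree": d["degree"],
            }
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
            columns=["kind", "log2_fc", "gwas_flag", "degree"]
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class EnrichmentResult:
    """Per-term over-representation results with BH control.

    ``table`` columns: term (index), term_size, overlap, overlap_genes,
    p_hyper, q_bh, significant.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def significant_terms(self) -> Set[str]:
        return set(self.table.index[self.table["significant"]])


@dataclass
class QpcrPlate:
    """qPCR plate: replicate CT values per (sample, assay).

    ``records`` columns: sample, assay, replicate, ct, is_control.
    ``groups`` maps sample id -> group label (the design).
    """

    records: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        req = {"sample", "assay", "replicate", "ct", "is_control"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"plate records lack columns: {sorted(missing)}")
        ct = self.records["ct"]
        if ((ct < 0) | (ct > 45)).any():
            raise ValidationError("CT values must lie in [0, 45]")
        controls = self.records[self.records["is_control"]]
        samples_with_ctrl = set(controls["sample"])
        orphan = set(self.records["sample"]) - samples_with_ctrl
        if orphan:
            raise ValidationError(f"samples without an endogenous-control assay: {sorted(orphan)}")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic relapse/remission cohort.

    Defaults emulate the study design this package models: 24 relapsing-
    remitting patients sampled in both phases plus 24 healthy controls on a
    1769-probe sncRNA array (~48% miRNA probes), female-predominant
    (sex_ratio 0.72 ~ 2.6:1), with planted differential expression of 38
    probes in female relapse, 42 in female remission and 7 in male remission,
    8 of which follow the mirror pattern (opposite directions in the two
    phases relative to controls).
    """

    n_patients: int = 24
    n_controls: int = 24
    n_probes: int = 1769
    frac_mirna: float = 0.48
    sex_ratio: float = 0.72
    n_de_relapse_f: int = 38
    n_de_remission_f: int = 42
    n_de_remission_m: int = 7
    n_mirror: int = 8
    effect_log2: float = 1.5
    patient_sd: float = 0.7
    noise_sd: float = 0.5
    detect_floor: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_patients", "n_controls", "n_probes"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{f} must be >= 1")
        for f in ("frac_mirna", "sex_ratio"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must lie in [0, 1]")
        for f in ("n_de_relapse_f", "n_de_remission_f", "n_de_remission_m", "n_mirror"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        if self.n_mirror > min(self.n_de_relapse_f, self.n_de_remission_f):
            raise ConfigError("n_mirror must not exceed min(n_de_relapse_f, n_de_remission_f)")
        for f in ("patient_sd", "noise_sd"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        if self.effect_log2 < 0:
            raise ConfigError("effect_log2 must be >= 0")
        n_de = self.n_de_relapse_f + self.n_de_remission_f - self.n_mirror + self.n_de_remission_m
        if n_de > self.n_probes:
            raise ConfigError("planted DE probes exceed n_probes")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated cohort.

    de_membership maps (comparison, stratum) -> {probe id: direction}, where
    directions are relative to controls. mirror_set holds the probes planted
    with opposite directions in relapse and remission. regulation_pairs are
    planted (miRNA probe, gene) regulations; mirna_log2_fc / gene_log2_fc are
    the planted control-referenced log2 fold changes used by the network stage.
    """

    de_membership: Dict[Tuple[str, str], Dict[str, str]]
    mirror_set: FrozenSet[str]
    regulation_pairs: FrozenSet[Tuple[str, str]]
    mirna_log2_fc: Dict[str, float] = field(default_factory=dict)
    gene_log2_fc: Dict[str, float] = field(default_factory=dict)

    def planted(self, comparison: str, stratum: str) -> Set[str]:
        return set(self.de_membership.get((comparison, stratum), {}))
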
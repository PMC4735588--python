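"""Synthetic cohort, prediction-table, qPCR-plate and gene-set generators.

The simulator produces data with the statistical structure the downstream
analysis assumes: a paired relapse/remission cohort plus controls, planted
sex-specific differential expression, a planted mirror set (probes shifted in
opposite directions in the two phases relative to controls), anti-correlated
miRNA -> target-gene fold changes, detection calls, triplicate qPCR plates and
GMT gene-set collections with one planted enriched term.

Intensity model (log2 scale)::

    x[p, s] = baseline[p] + patient_effect[patient(s)] + planted_effect[p, s]
              + Normal(0, noise_sd)

with baseline ~ Normal(8, 2) and patient_effect ~ Normal(0, patient_sd) shared
by the two samples of a patient (controls carry their own random effect).
A probe-sample pair is called detected when its intensity exceeds
``detect_floor``.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CohortConfig, ConfigError, ExpressionExperiment, QpcrPlate, SyntheticTruth

TARGETS_PER_MIRNA = 3


def _probe_ids(config: CohortConfig) -> Tuple[pd.Index, pd.DataFrame]:
    n_mirna = int(round(config.frac_mirna * config.n_probes))
    ids = [f"miR-{i:04d}" for i in range(n_mirna)]
    ids += [f"SNORD-{i:04d}" for i in range(config.n_probes - n_mirna)]
    kind = ["miRNA"] * n_mirna + ["snoRNA"] * (config.n_probes - n_mirna)
    meta = pd.DataFrame({"kind": kind, "human": True}, index=pd.Index(ids, name="probe"))
    return meta.index, meta


def _design(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_f = int(round(config.sex_ratio * config.n_patients))
    sexes = ["F"] * n_f + ["M"] * (config.n_patients - n_f)
    for i, sex in enumerate(sexes):
        pat = f"P{i:03d}"
        for phase in ("relapse", "remission"):
            rows.append((f"{pat}_{phase[:3]}", pat, phase, sex, "A"))
    n_cf = int(round(config.sex_ratio * config.n_controls))
    csex = ["F"] * n_cf + ["M"] * (config.n_controls - n_cf)
    for i, sex in enumerate(csex):
        rows.append((f"C{i:03d}", f"C{i:03d}", "control", sex, "none"))
    df = pd.DataFrame(rows, columns=["sample", "patient", "phase", "sex", "treatment"])
    return df.set_index("sample")


def simulate_cohort(config: CohortConfig) -> Tuple[ExpressionExperiment, SyntheticTruth]:
    """Simulate a paired relapse/remission cohort with planted effects.

    Returns the experiment plus a :class:`SyntheticTruth` recording the
    planted DE membership per (comparison, stratum), the mirror set and the
    planted miRNA -> gene regulations with their fold changes. Deterministic
    for a fixed config (the seed lives in the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probes, meta = _probe_ids(config)
    design = _design(config, rng)

    baseline = rng.normal(8.0, 2.0, size=config.n_probes)
    patient_ids = design["patient"].unique()
    pat_eff = dict(zip(patient_ids, rng.normal(0.0, config.patient_sd, size=len(patient_ids))))

    # planted probe sets: mirror probes belong to both female phases
    n_extra_rel = config.n_de_relapse_f - config.n_mirror
    n_extra_rem = config.n_de_remission_f - config.n_mirror
    n_total = config.n_mirror + n_extra_rel + n_extra_rem + config.n_de_remission_m
    chosen = rng.choice(config.n_probes, size=n_total, replace=False)
    mirror_idx = chosen[: config.n_mirror]
    rel_only_idx = chosen[config.n_mirror : config.n_mirror + n_extra_rel]
    rem_only_idx = chosen[config.n_mirror + n_extra_rel : config.n_mirror + n_extra_rel + n_extra_rem]
    rem_m_idx = chosen[config.n_mirror + n_extra_rel + n_extra_rem :]

    e = config.effect_log2
    # per-probe planted shifts vs control: (relapse female, remission female, remission male)
    delta_rel_f = np.zeros(config.n_probes)
    delta_rem_f = np.zeros(config.n_probes)
    delta_rem_m = np.zeros(config.n_probes)
    mirror_signs = rng.choice([-1.0, 1.0], size=config.n_mirror)
    delta_rel_f[mirror_idx] = mirror_signs * e
    delta_rem_f[mirror_idx] = -mirror_signs * e
    delta_rel_f[rel_only_idx] = rng.choice([-1.0, 1.0], size=n_extra_rel) * e
    delta_rem_f[rem_only_idx] = rng.choice([-1.0, 1.0], size=n_extra_rem) * e
    delta_rem_m[rem_m_idx] = rng.choice([-1.0, 1.0], size=config.n_de_remission_m) * e

    x = np.empty((config.n_probes, len(design)))
    for j, (sample, row) in enumerate(design.iterrows()):
        col = baseline + pat_eff[row["patient"]]
        if row["phase"] == "relapse" and row["sex"] == "F":
            col = col + delta_rel_f
        elif row["phase"] == "remission" and row["sex"] == "F":
            col = col + delta_rem_f
        elif row["phase"] == "remission" and row["sex"] == "M":
            col = col + delta_rem_m
        x[:, j] = col + rng.normal(0.0, config.noise_sd, size=config.n_probes)

    intensities = pd.DataFrame(x, index=probes, columns=design.index)
    detected = intensities > config.detect_floor

    def _members(idx: np.ndarray, delta: np.ndarray) -> Dict[str, str]:
        return {probes[i]: ("up" if delta[i] > 0 else "down") for i in idx}

    de_membership = {
        ("relapse_vs_control", "females"): _members(
            np.concatenate([mirror_idx, rel_only_idx]).astype(int), delta_rel_f
        ),
        ("remission_vs_control", "females"): _members(
            np.concatenate([mirror_idx, rem_only_idx]).astype(int), delta_rem_f
        ),
        ("remission_vs_control", "males"): _members(rem_m_idx.astype(int), delta_rem_m),
        ("relapse_vs_control", "males"): {},
    }
    if e == 0:
        de_membership = {k: {} for k in de_membership}
        mirror_set: frozenset = frozenset()
    else:
        mirror_set = frozenset(probes[i] for i in mirror_idx)

    # planted regulations: each DE miRNA (female strata) represses a few genes
    mirna_log2_fc: Dict[str, float] = {}
    for i in np.concatenate([mirror_idx, rel_only_idx]).astype(int):
        if meta.loc[probes[i], "kind"] == "miRNA":
            mirna_log2_fc[probes[i]] = delta_rel_f[i]
    for i in rem_only_idx.astype(int):
        if meta.loc[probes[i], "kind"] == "miRNA":
            mirna_log2_fc[probes[i]] = delta_rem_f[i]
    pairs = set()
    gene_log2_fc: Dict[str, float] = {}
    g = 0
    for mir, fc in sorted(mirna_log2_fc.items()):
        for _ in range(TARGETS_PER_MIRNA):
            gene = f"GENE{g:04d}"
            g += 1
            pairs.add((mir, gene))
            gene_log2_fc[gene] = -np.sign(fc) * rng.uniform(0.5, 2.0) if fc != 0 else 0.0

    truth = SyntheticTruth(
        de_membership=de_membership,
        mirror_set=mirror_set,
        regulation_pairs=frozenset(pairs),
        mirna_log2_fc=mirna_log2_fc,
        gene_log2_fc=gene_log2_fc,
    )
    exp = ExpressionExperiment(intensities=intensities, detected=detected, design=design, probe_meta=meta)
    return exp, truth


def simulate_predictions(truth: SyntheticTruth, n_decoys: int, seed: int) -> pd.DataFrame:
    """Emulate an integrated target-prediction export for the planted truth.

    True pairs get n_sources in {3..12} and score in [40, 100], so all of
    them survive the source/score filters; decoys sample n_sources uniformly
    on {1..12} and score uniformly on [0, 100], so a known fraction fails
    each filter. Decoy genes are fresh symbols (``DECOY``-prefixed).
    """
    if n_decoys < 0:
        raise ConfigError("n_decoys must be >= 0")
    if not truth.regulation_pairs:
        raise ConfigError("truth has no planted regulation pairs")
    rng = np.random.default_rng(seed)
    rows = []
    for mir, gene in sorted(truth.regulation_pairs):
        rows.append((mir, gene, int(rng.integers(3, 13)), float(rng.uniform(40.0, 100.0))))
    mirnas = sorted({m for m, _ in truth.regulation_pairs})
    for d in range(n_decoys):
        mir = mirnas[int(rng.integers(len(mirnas)))]
        rows.append((mir, f"DECOY{d:04d}", int(rng.integers(1, 13)), float(rng.uniform(0.0, 100.0))))
    return pd.DataFrame(rows, columns=["mirna", "gene", "n_sources", "score"])


def simulate_qpcr(
    truth_fold_changes: Mapping[str, float],
    n_replicates: int = 3,
    ct_sd: float = 0.25,
    seed: int = 0,
    n_samples_per_group: int = 6,
) -> QpcrPlate:
    """Simulate triplicate CT plates whose 2^-ddCT recovers the planted FC.

    Two groups ("case" vs "reference") with ``n_samples_per_group`` samples
    each; two endogenous-control assays (RNU48, U6) per sample. Case samples'
    target CTs are lowered by log2(FC); per-sample loading offsets cancel in
    the control subtraction. With ct_sd = 0 recovery is exact.
    """
    fcs = dict(truth_fold_changes)
    if any(fc <= 0 for fc in fcs.values()):
        raise ConfigError("all planted fold changes must be > 0")
    rng = np.random.default_rng(seed)
    samples = [(f"case{i:02d}", "case") for i in range(n_samples_per_group)]
    samples += [(f"ref{i:02d}", "reference") for i in range(n_samples_per_group)]
    base_ct = {assay: 26.0 + (k % 5) for k, assay in enumerate(sorted(fcs))}
    rows = []
    for sample, group in samples:
        offset = rng.normal(0.0, 0.5)
        for assay, base in (("RNU48", 20.0), ("U6", 22.0)):
            for r in range(n_replicates):
                rows.append((sample, assay, r, base + offset + rng.normal(0.0, ct_sd), True))
        for assay, fc in sorted(fcs.items()):
            shift = -np.log2(fc) if group == "case" else 0.0
            for r in range(n_replicates):
                rows.append((sample, assay, r, base_ct[assay] + offset + shift + rng.normal(0.0, ct_sd), False))
    records = pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct", "is_control"])
    groups = pd.Series(dict(samples), name="group")
    return QpcrPlate(records=records, groups=groups)


def simulate_genesets(
    gene_universe: Sequence[str],
    n_terms: int,
    enriched_term_genes: Iterable[str],
    seed: int,
    term_size: int = 15,
) -> Dict[str, list]:
    """GMT-style collection with one term planted to overlap the query.

    The planted term ("TERM_PLANTED") is exactly ``enriched_term_genes``;
    the remaining ``n_terms - 1`` terms are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    planted = sorted(set(enriched_term_genes))
    if not planted:
        raise ConfigError("enriched_term_genes must be non-empty")
    collection: Dict[str, list] = {"TERM_PLANTED": planted}
    for t in range(max(n_terms - 1, 0)):
        size = min(term_size, len(universe))
        idx = rng.choice(len(universe), size=size, replace=False)
        collection[f"TERM_{t:04d}"] = sorted(universe[i] for i in idx)
    return collection
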
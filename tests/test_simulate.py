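"""Synthetic-cohort generator: determinism, planted structure, filter algebra."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sncmirror import (
    CohortConfig,
    ConfigError,
    collapse_replicates,
    delta_delta_ct,
    filter_predictions,
    hypergeom_enrich,
    simulate_cohort,
    simulate_genesets,
    simulate_predictions,
    simulate_qpcr,
)


def small_config(**overrides):
    base = dict(
        n_patients=13,
        n_controls=13,
        n_probes=120,
        sex_ratio=1.0,
        n_de_relapse_f=6,
        n_de_remission_f=6,
        n_de_remission_m=0,
        n_mirror=4,
        effect_log2=2.0,
        noise_sd=0.3,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestSimulateCohort:
    def test_same_seed_identical_output(self):
        exp1, _ = simulate_cohort(small_config())
        exp2, _ = simulate_cohort(small_config())
        pd.testing.assert_frame_equal(exp1.intensities, exp2.intensities)
        pd.testing.assert_frame_equal(exp1.detected, exp2.detected)

    def test_different_seed_differs(self):
        exp1, _ = simulate_cohort(small_config())
        exp2, _ = simulate_cohort(small_config(seed=8))
        assert not exp1.intensities.equals(exp2.intensities)

    def test_mirror_probes_have_opposite_empirical_fc_signs(self):
        """The 4 planted mirror probes flip sign between relapse and remission
        relative to controls in the empirical group means."""
        exp, truth = simulate_cohort(small_config(n_mirror=4))
        d = exp.design
        rel = exp.intensities[d.index[(d.phase == "relapse") & (d.sex == "F")]].mean(axis=1)
        rem = exp.intensities[d.index[(d.phase == "remission") & (d.sex == "F")]].mean(axis=1)
        ctl = exp.intensities[d.index[d.phase == "control"]].mean(axis=1)
        assert len(truth.mirror_set) == 4
        for probe in truth.mirror_set:
            assert np.sign(rel[probe] - ctl[probe]) == -np.sign(rem[probe] - ctl[probe])

    def test_zero_effect_plants_nothing(self):
        _, truth = simulate_cohort(small_config(effect_log2=0.0))
        assert truth.mirror_set == frozenset()
        assert all(not members for members in truth.de_membership.values())

    def test_mirror_set_subset_of_both_phases(self):
        _, truth = simulate_cohort(small_config())
        assert truth.mirror_set <= truth.planted("relapse_vs_control", "females")
        assert truth.mirror_set <= truth.planted("remission_vs_control", "females")

    def test_paired_design_structure(self):
        exp, _ = simulate_cohort(small_config())
        patients = exp.design[exp.design.phase != "control"]
        phases = patients.groupby("patient")["phase"].agg(set)
        assert all(p == {"relapse", "remission"} for p in phases)

    def test_detection_calls_follow_floor(self):
        cfg = small_config(detect_floor=8.0)
        exp, _ = simulate_cohort(cfg)
        assert exp.detected.equals(exp.intensities > 8.0)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_mirna", 1.5),
            ("noise_sd", -1.0),
            ("n_probes", 0),
            ("n_mirror", 10),  # > min of the phase DE counts
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError):
            simulate_cohort(small_config(**{field: value}))


class TestSimulatePredictions:
    def test_all_true_pairs_pass_filters(self):
        _, truth = simulate_cohort(small_config())
        records = simulate_predictions(truth, n_decoys=0, seed=1)
        kept = filter_predictions(records)
        assert len(kept) == len(records) == len(truth.regulation_pairs)

    def test_deterministic_pass_count(self):
        _, truth = simulate_cohort(small_config())
        a = simulate_predictions(truth, n_decoys=100, seed=5)
        b = simulate_predictions(truth, n_decoys=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_decoy_source_filter_pass_fraction(self):
        """Decoy n_sources uniform on {1..12}: the >= 3 filter passes 10/12."""
        _, truth = simulate_cohort(small_config())
        records = simulate_predictions(truth, n_decoys=4000, seed=3)
        decoys = records[records.gene.str.startswith("DECOY")]
        frac = (decoys.n_sources >= 3).mean()
        assert abs(frac - 10 / 12) < 3 * np.sqrt((10 / 12) * (2 / 12) / 4000)

    def test_negative_decoys_rejected(self):
        _, truth = simulate_cohort(small_config())
        with pytest.raises(ConfigError):
            simulate_predictions(truth, n_decoys=-1, seed=0)


class TestSimulateQpcr:
    def test_zero_noise_recovers_planted_fold_exactly(self):
        plate = simulate_qpcr({"miR-a": 2.0, "miR-b": 1.0}, ct_sd=0.0, seed=0)
        ddct = delta_delta_ct(plate, reference_group="reference")
        assert ddct.loc[("miR-a", "case"), "fold"] == pytest.approx(2.0, abs=1e-12)
        assert ddct.loc[("miR-b", "case"), "fold"] == pytest.approx(1.0, abs=1e-12)
        assert ddct.loc[("miR-b", "case"), "delta_delta_ct"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_unbiased(self):
        """Mean recovered log2 FC over many noisy assays is within 0.1 of 1."""
        recovered = []
        for seed in range(60):
            plate = simulate_qpcr({"miR-a": 2.0}, ct_sd=0.2, seed=seed)
            ddct = delta_delta_ct(plate, reference_group="reference")
            recovered.append(-ddct.loc[("miR-a", "case"), "delta_delta_ct"])
        assert abs(np.mean(recovered) - 1.0) < 0.1

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ConfigError):
            simulate_qpcr({"miR-a": -2.0}, seed=0)

    def test_two_endogenous_controls_present(self):
        plate = simulate_qpcr({"miR-a": 2.0}, seed=0)
        controls = set(plate.records.loc[plate.records.is_control, "assay"])
        assert controls == {"RNU48", "U6"}


class TestSimulateGenesets:
    def test_planted_term_is_most_enriched(self):
        universe = [f"G{i}" for i in range(200)]
        query = set(universe[:12])
        coll = simulate_genesets(universe, n_terms=15, enriched_term_genes=query, seed=2)
        res = hypergeom_enrich(query, set(universe), coll)
        assert res.table["p_hyper"].idxmin() == "TERM_PLANTED"
        assert res.table.loc["TERM_PLANTED", "q_bh"] == res.table["q_bh"].min()

    def test_disjoint_term_p_one(self):
        universe = [f"G{i}" for i in range(50)]
        coll = {"DISJOINT": universe[40:]}
        res = hypergeom_enrich(set(universe[:10]), set(universe), coll)
        assert res.table.loc["DISJOINT", "p_hyper"] == pytest.approx(1.0)

    def test_null_terms_give_uniform_pvalues(self):
        """Random terms vs a random query: hypergeometric p-values are
        super-uniform (conservative), so the empirical CDF never exceeds the
        uniform CDF by more than sampling error."""
        universe = [f"G{i}" for i in range(300)]
        rng = np.random.default_rng(99)
        query = set(rng.choice(universe, size=30, replace=False))
        coll = simulate_genesets(universe, n_terms=500, enriched_term_genes=query, seed=5)
        coll.pop("TERM_PLANTED")
        res = hypergeom_enrich(query, set(universe), coll)
        p = np.sort(res.table["p_hyper"].to_numpy())
        ecdf = np.arange(1, len(p) + 1) / len(p)
        assert (ecdf - p <= 0.08).all()  # discrete test: P(P<=x) <= x + slack
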
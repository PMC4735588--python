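"""Rank-product statistics: hand-ranked cases, an exhaustive permutation
oracle, symmetry/conservation properties and the fold-change filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from sncmirror import (
    Comparison,
    ValidationError,
    build_ratio_matrix,
    differential_expression,
    fold_change_filter,
    permutation_null,
    rank_product,
    simulate_cohort,
)
from sncmirror.types import CohortConfig


def ratios_df(rows, probes=None):
    rows = np.asarray(rows, dtype=float)
    probes = probes or [f"p{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=probes)


class TestRankProduct:
    def test_hand_ranked_three_by_two(self):
        """ratios [[-2,-1],[0,0],[2,1]]: down RPs (1,2,3), up RPs (3,2,1)."""
        r = ratios_df([[-2, -1], [0, 0], [2, 1]])
        assert rank_product(r, "down").tolist() == pytest.approx([1.0, 2.0, 3.0])
        assert rank_product(r, "up").tolist() == pytest.approx([3.0, 2.0, 1.0])

    def test_extreme_probe_gets_rp_one(self):
        r = ratios_df([[-5, -9], [0, 1], [1, 0]])
        assert rank_product(r, "down")["p0"] == 1.0

    def test_all_identical_probes_share_mean_rank(self):
        r = ratios_df([[1, 1], [1, 1], [1, 1], [1, 1]])
        assert np.allclose(rank_product(r, "down"), 2.5)
        assert np.allclose(rank_product(r, "up"), 2.5)

    def test_rank_sums_conserved_per_column(self, rng):
        v = rng.normal(size=(15, 4))
        v[3] = v[7]  # ties across probes within columns
        ranks = rankdata(v, axis=0, method="average")
        assert np.allclose(ranks.sum(axis=0), 15 * 16 / 2)


def exhaustive_null(ratios: pd.DataFrame):
    """Brute-force oracle: enumerate every within-column shuffle of probe
    labels, pooling rank products over the full permutation group."""
    v = ratios.to_numpy(dtype=float)
    n, k = v.shape
    down_ranks = rankdata(v, axis=0, method="average")
    pool = {"down": [], "up": []}
    for perms in itertools.product(itertools.permutations(range(n)), repeat=k):
        r = np.column_stack([down_ranks[list(p), j] for j, p in enumerate(perms)])
        pool["down"].extend(np.exp(np.log(r).mean(axis=1)))
        pool["up"].extend(np.exp(np.log(n + 1 - r).mean(axis=1)))
    out = {}
    for d in ("down", "up"):
        obs = np.exp(np.log(down_ranks if d == "down" else n + 1 - down_ranks).mean(axis=1))
        pooled = np.sort(pool[d])
        frac = np.searchsorted(pooled, obs, side="right") / len(pooled)
        out[d] = pd.Series(frac, index=ratios.index)  # P(RP_perm <= obs)
    return out


class TestPermutationNull:
    def test_sampled_matches_exhaustive_enumeration(self, rng):
        """On a 3-probe x 2-column matrix the sampled tail probabilities agree
        with full enumeration of all (3!)^2 shuffles within Monte-Carlo error."""
        r = ratios_df(rng.normal(size=(3, 2)))
        n_perm = 10_000
        oracle = exhaustive_null(r)
        sampled = permutation_null(r, n_permutations=n_perm, seed=1)
        for d in ("down", "up"):
            frac_sampled = sampled[d]["e_fp"] / 3  # counts / (n_perm * n_probes)
            for probe in r.index:
                p_true = oracle[d][probe]
                se = np.sqrt(max(p_true * (1 - p_true), 1e-4) / n_perm)
                assert abs(frac_sampled[probe] - p_true) <= 3 * se

    def test_up_down_swap_under_negation(self, rng):
        r = ratios_df(rng.normal(size=(8, 3)))
        null_pos = permutation_null(r, 200, seed=3)
        null_neg = permutation_null(-r, 200, seed=3)
        pd.testing.assert_frame_equal(null_pos["up"], null_neg["down"])
        pd.testing.assert_frame_equal(null_pos["down"], null_neg["up"])

    def test_pfp_monotone_in_rp(self, rng):
        r = ratios_df(rng.normal(size=(20, 3)))
        null = permutation_null(r, 100, seed=0)
        for d in ("up", "down"):
            t = null[d].sort_values("rp")
            assert (np.diff(t["pfp"]) >= -1e-12).all()
            assert (t["pfp"] >= 0).all() and (t["pfp"] <= 1).all()

    def test_p_floor_and_determinism(self, rng):
        r = ratios_df(rng.normal(size=(10, 3)))
        a = permutation_null(r, 150, seed=9)
        b = permutation_null(r, 150, seed=9)
        for d in ("up", "down"):
            pd.testing.assert_frame_equal(a[d], b[d])
            assert (a[d]["p_perm"] >= 1 / (1 + 150 * 10)).all()

    def test_invalid_permutation_count(self):
        with pytest.raises(ValidationError):
            permutation_null(ratios_df([[1, 2], [3, 4]]), 0, seed=0)


class TestBuildRatioMatrix:
    def test_paired_gives_one_column_per_patient(self):
        cfg = CohortConfig(n_patients=13, n_controls=4, n_probes=20, sex_ratio=1.0,
                           n_de_relapse_f=0, n_de_remission_f=0, n_de_remission_m=0,
                           n_mirror=0, seed=1)
        exp, _ = simulate_cohort(cfg)
        comp = Comparison("rvr", "relapse", "remission", paired=True, stratum="all",
                          same_treatment_only=True)
        ratios = build_ratio_matrix(exp, comp)
        assert ratios.shape[1] == 13

    def test_unpaired_cross_pairs(self):
        cfg = CohortConfig(n_patients=3, n_controls=2, n_probes=10, sex_ratio=1.0,
                           n_de_relapse_f=0, n_de_remission_f=0, n_de_remission_m=0,
                           n_mirror=0, seed=1)
        exp, _ = simulate_cohort(cfg)
        comp = Comparison("rvc", "relapse", "control", stratum="all")
        assert build_ratio_matrix(exp, comp).shape[1] == 3 * 2

    def test_patient_missing_one_phase_excluded(self):
        cfg = CohortConfig(n_patients=4, n_controls=2, n_probes=10, sex_ratio=1.0,
                           n_de_relapse_f=0, n_de_remission_f=0, n_de_remission_m=0,
                           n_mirror=0, seed=1)
        exp, _ = simulate_cohort(cfg)
        exp.design = exp.design.drop("P000_rem")
        exp.intensities = exp.intensities.drop(columns="P000_rem")
        exp.detected = exp.detected.drop(columns="P000_rem")
        comp = Comparison("rvr", "relapse", "remission", paired=True)
        assert build_ratio_matrix(exp, comp).shape[1] == 3

    def test_same_treatment_only_excludes_switchers(self):
        cfg = CohortConfig(n_patients=5, n_controls=2, n_probes=10, sex_ratio=1.0,
                           n_de_relapse_f=0, n_de_remission_f=0, n_de_remission_m=0,
                           n_mirror=0, seed=1)
        exp, _ = simulate_cohort(cfg)
        exp.design.loc["P000_rel", "treatment"] = "B"  # switched between phases
        comp = Comparison("rvr", "relapse", "remission", paired=True,
                          same_treatment_only=True)
        assert build_ratio_matrix(exp, comp).shape[1] == 4

    def test_too_few_columns_error(self):
        cfg = CohortConfig(n_patients=1, n_controls=1, n_probes=10, sex_ratio=1.0,
                           n_de_relapse_f=0, n_de_remission_f=0, n_de_remission_m=0,
                           n_mirror=0, seed=1)
        exp, _ = simulate_cohort(cfg)
        with pytest.raises(ValidationError, match="usable ratio"):
            build_ratio_matrix(exp, Comparison("rvr", "relapse", "remission", paired=True))


class TestDifferentialExpression:
    def test_planted_effects_recovered_paired(self, strong_cohort):
        exp, truth = strong_cohort
        comp = Comparison("rvr_f", "relapse", "remission", paired=True, stratum="females")
        res = differential_expression(exp, comp, n_permutations=300, seed=5)
        planted = truth.planted("relapse_vs_control", "females") | truth.planted(
            "remission_vs_control", "females"
        )
        sig = res.significant_probes
        recall = len(sig & planted) / len(planted)
        assert recall >= 0.9
        assert len(sig - planted) <= max(1, 0.1 * len(sig))

    def test_unplanted_stratum_stays_clean(self):
        cfg = CohortConfig(n_patients=10, n_controls=10, n_probes=150, sex_ratio=0.5,
                           n_de_relapse_f=8, n_de_remission_f=8, n_de_remission_m=0,
                           n_mirror=4, effect_log2=2.0, noise_sd=0.3, seed=3)
        exp, _ = simulate_cohort(cfg)
        comp = Comparison("rvc_m", "relapse", "control", stratum="males")
        res = differential_expression(exp, comp, n_permutations=300, seed=5)
        assert len(res.significant_probes) <= 2  # nothing planted in males

    def test_zero_p_cut_gives_empty_set(self, strong_cohort):
        exp, _ = strong_cohort
        comp = Comparison("rvr_f", "relapse", "remission", paired=True, stratum="females")
        res = differential_expression(exp, comp, n_permutations=50, seed=5, p_cut=0.0)
        assert res.significant_probes == set()

    def test_direction_matches_planted_sign(self, strong_cohort):
        exp, truth = strong_cohort
        comp = Comparison("rvc_f", "relapse", "control", stratum="females")
        res = differential_expression(exp, comp, n_permutations=300, seed=5)
        planted = truth.de_membership[("relapse_vs_control", "females")]
        for probe, direction in planted.items():
            if probe in res.significant_probes:
                assert res.table.loc[probe, "direction"] == direction

    def test_seeded_determinism(self, strong_cohort):
        exp, _ = strong_cohort
        comp = Comparison("rvc_f", "relapse", "control", stratum="females")
        a = differential_expression(exp, comp, n_permutations=100, seed=5)
        b = differential_expression(exp, comp, n_permutations=100, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestFoldChangeFilter:
    @pytest.mark.parametrize(
        "fc,kept",
        [(2.0, False), (2.01, True), (0.4, True), (0.5, False), (1.0, False), (3.0, True)],
    )
    def test_strict_twofold_boundary(self, fc, kept):
        selected = fold_change_filter(pd.Series({"x": fc}))
        assert ("x" in selected) is kept

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValidationError):
            fold_change_filter(pd.Series({"x": -1.0}))
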
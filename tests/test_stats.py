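import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bbbmap import (
    CohortDesign,
    apply_exclusions,
    clinical_lmm,
    cluster_threshold,
    demographic_tests,
    gaussian_smooth,
    generate_cohort,
    permutation_cluster_fwe,
    posthoc_pairwise,
    rm_anova,
    voxelwise_ttest,
)


def study_manifest():
    """Recruited cohort with the study's QC flags: 51 PD + 17 CP + 34 CN,
    2 incomplete scans, 3 injection failures, 2 non-physiological vp."""
    rows = []
    for group, n in (("PD", 51), ("CP", 17), ("CN", 34)):
        for i in range(n):
            rows.append({"subject": f"{group}{i:03d}", "group": group,
                         "incomplete_scan": False, "injection_failure": False,
                         "nonphysiological_vp": False})
    df = pd.DataFrame(rows)
    # excluded: 2 PD, 2 CP, 3 CN (leaving 49 PD, 15 CP, 31 CN)
    df.loc[df[df.group == "PD"].index[:1], "incomplete_scan"] = True
    df.loc[df[df.group == "CN"].index[:1], "incomplete_scan"] = True
    df.loc[df[df.group == "CN"].index[1:3], "injection_failure"] = True
    df.loc[df[df.group == "PD"].index[1:2], "injection_failure"] = True
    df.loc[df[df.group == "CP"].index[:2], "nonphysiological_vp"] = True
    return df


class TestApplyExclusions:
    def test_study_counts(self):
        kept, report = apply_exclusions(study_manifest())
        assert report.n_recruited == 102
        assert report.n_excluded == 7
        assert report.n_analysable == 95
        assert report.by_reason == {
            "incomplete_scan": 2, "injection_failure": 3, "nonphysiological_vp": 2
        }
        assert report.remaining_by_group == {"PD": 49, "CN": 31, "CP": 15}

    def test_no_flags_is_identity(self):
        df = study_manifest()
        for c in ("incomplete_scan", "injection_failure", "nonphysiological_vp"):
            df[c] = False
        kept, report = apply_exclusions(df)
        assert len(kept) == 102 and report.n_excluded == 0

    def test_all_flagged_preserves_totals(self):
        df = study_manifest()
        df["incomplete_scan"] = True
        kept, report = apply_exclusions(df)
        assert kept.empty
        assert report.n_recruited == 102
        assert report.by_reason["incomplete_scan"] == 102

    def test_duplicate_ids_rejected(self):
        df = study_manifest()
        df.loc[1, "subject"] = df.loc[0, "subject"]
        with pytest.raises(ValueError, match="duplicate"):
            apply_exclusions(df)


def fisher_two_sided_by_enumeration(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability does
    not exceed the observed table's."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-12)
    )


class TestDemographics:
    def _cohort(self, seed=0):
        return generate_cohort(CohortDesign(seed=seed))

    def test_identical_groups_give_null_result(self):
        ages = [60.0, 62.0, 64.0, 66.0, 68.0]
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(10)],
                "group": ["CN"] * 5 + ["CP"] * 5,
                "age": ages + ages,
                "region": "SN",
                "metric": "ktrans",
                "value": 1e-3,
            }
        )
        out = demographic_tests(df, continuous=("age",), categorical=())
        row = out[(out.pair == "CN vs CP") & (out.variable == "age")].iloc[0]
        assert row["stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_on_small_tables(self):
        tables = [
            [[1, 9], [9, 1]], [[3, 7], [5, 5]], [[0, 10], [8, 2]],
            [[2, 2], [2, 2]], [[6, 1], [2, 9]], [[4, 0], [0, 4]],
            [[12, 5], [3, 14]], [[1, 0], [0, 1]],
        ]
        for t in tables:
            p_scipy = sps.fisher_exact(t).pvalue
            assert p_scipy == pytest.approx(fisher_two_sided_by_enumeration(t), rel=1e-9)

    def test_fisher_printed_example(self):
        p = sps.fisher_exact([[1, 9], [9, 1]]).pvalue
        assert p == pytest.approx(202 / 184756, rel=1e-9)
        assert p == pytest.approx(0.0010933, abs=1e-7)

    def test_fisher_row_swap_invariance(self):
        t = [[3, 8], [10, 2]]
        assert sps.fisher_exact(t).pvalue == pytest.approx(
            sps.fisher_exact(t[::-1]).pvalue
        )

    def test_all_three_pairs_reported(self):
        out = demographic_tests(self._cohort())
        assert set(out["pair"]) == {"CN vs PD", "CP vs PD", "CN vs CP"}


def rm_anova_group_f_oracle(table: pd.DataFrame, dv: str):
    """Textbook split-plot sums-of-squares for the between-subject group F:
    subject means, SS_group over SS_subjects-within-group."""
    df = table[table.metric == dv]
    subj = df.groupby(["subject", "group"])["value"].mean().reset_index()
    grand = subj["value"].mean()
    groups = subj.groupby("group")["value"]
    n_g = groups.count()
    ss_group = float((n_g * (groups.mean() - grand) ** 2).sum())
    ss_within = float(
        sum(((v - v.mean()) ** 2).sum() for _, v in groups)
    )
    g = len(n_g)
    n = len(subj)
    return (ss_group / (g - 1)) / (ss_within / (n - g))


class TestRmAnova:
    def test_group_f_matches_ss_oracle(self):
        table = generate_cohort(
            CohortDesign(group_sizes={"CN": 10, "CP": 10, "PD": 10}, seed=21)
        )
        out = rm_anova(table, "ktrans")
        f_oracle = rm_anova_group_f_oracle(table, "ktrans")
        f_pkg = out.loc[out.term == "group", "F"].iloc[0]
        assert f_pkg == pytest.approx(f_oracle, rel=1e-6)
        assert out.loc[out.term == "group", "df_num"].iloc[0] == 2
        assert out.loc[out.term == "group", "df_den"].iloc[0] == 27

    def test_strong_group_shift_detected(self):
        design = CohortDesign(seed=3).null().with_group_shift("ktrans", "PD", 3.0)
        table = generate_cohort(design)
        out = rm_anova(table, "ktrans")
        assert out.loc[out.term == "group", "p"].iloc[0] < 0.001

    def test_covariates_reported(self):
        table = generate_cohort(CohortDesign(seed=4))
        out = rm_anova(table, "vp", covariates=("age", "gender", "wml_cuberoot"))
        assert {"group", "age", "gender", "wml_cuberoot", "region", "group:region"} <= set(out.term)
        assert (out["F"].dropna() >= 0).all()
        assert out["p"].dropna().between(0, 1).all()

    def test_type_one_error_calibrated(self):
        """Group-term type-I error over 200 null cohorts stays near the
        nominal 5% level (the full 500-replicate calibration runs in the
        acceptance suite)."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            design = CohortDesign(
                group_sizes={"CN": 15, "CP": 15, "PD": 15}, seed=10_000 + rep
            ).null()
            table = generate_cohort(design)
            p = rm_anova(table, "ktrans").set_index("term").loc["group", "p"]
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_needs_two_groups_and_regions(self):
        table = generate_cohort(CohortDesign(seed=5))
        with pytest.raises(ValueError):
            rm_anova(table[table.group == "PD"], "ktrans")


class TestPosthoc:
    def test_bonferroni_multiplication_and_cap(self):
        table = generate_cohort(CohortDesign(seed=6))
        out = posthoc_pairwise(table, "ktrans")
        overall = out[out.region == "overall"]
        for _, row in overall.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 3 * row["p_raw"]))
            assert row["p_bonferroni"] >= row["p_raw"]

    def test_identical_groups_fully_corrected(self):
        design = CohortDesign(
            group_sizes={"CN": 5, "CP": 5, "PD": 5},
            between_subject_sd={"ktrans": 0.0, "vp": 0.0},
            within_subject_sd={"ktrans": 0.0, "vp": 0.0},
        ).null()
        out = posthoc_pairwise(generate_cohort(design), "ktrans")
        assert (out[out.region == "overall"]["p_bonferroni"] == 1.0).all()

    def test_shifted_pair_detected(self):
        design = CohortDesign(seed=7).null().with_group_shift("ktrans", "PD", 3.0)
        out = posthoc_pairwise(generate_cohort(design), "ktrans")
        row = out[(out.region == "overall") & (out.pair == "CN vs PD")].iloc[0]
        assert row["p_bonferroni"] < 0.05


class TestClinicalLmm:
    def _pd_cohort(self, seed, ledd_slope=0.0):
        design = CohortDesign(
            group_sizes={"CN": 2, "CP": 2, "PD": 49},
            region_names=("SN", "CA", "PU", "P", "NAWM", "FC", "PC"),
            seed=seed,
        ).null()
        table = generate_cohort(design)
        if ledd_slope:
            sel = (table.group == "PD") & (table.metric == "vp")
            table.loc[sel, "value"] += ledd_slope * table.loc[sel, "ledd"]
        return table

    def test_ledd_effect_recovered(self):
        # slope 2e-5 per mg: LEDD SD ~400 mg -> vp effect SD ~8e-3, well
        # above the 3e-3 between-subject SD
        table = self._pd_cohort(seed=8, ledd_slope=2e-5)
        out = clinical_lmm(table, "vp").set_index("term")
        assert out.loc["ledd", "p"] < 0.01

    def test_table_structure(self):
        out = clinical_lmm(self._pd_cohort(seed=9), "vp")
        assert {"region", "moca", "ledd", "updrs",
                "region:moca", "region:ledd", "region:updrs"} == set(out.term)
        assert out.set_index("term").loc["region", "df_num"] == 6

    def test_zero_variance_response_is_error(self):
        table = self._pd_cohort(seed=10)
        table.loc[table.metric == "vp", "value"] = 0.01
        with pytest.raises(ValueError, match="zero variance"):
            clinical_lmm(table, "vp")

    def test_constant_predictor_dropped(self):
        table = self._pd_cohort(seed=11)
        table["updrs"] = table["updrs"].where(table.group != "PD", 30.0)
        out = clinical_lmm(table, "vp")
        assert "updrs" not in set(out.term)

    def test_null_type_one_error_calibrated(self):
        """LEDD term type-I rate under the null over 150 simulated PD cohorts
        stays near the nominal level."""
        hits, n_rep = 0, 150
        for rep in range(n_rep):
            table = self._pd_cohort(seed=40_000 + rep)
            p = clinical_lmm(table, "vp").set_index("term").loc["ledd", "p"]
            hits += p < 0.05
        assert 0.015 <= hits / n_rep <= 0.1


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        img = rng.normal(size=(8, 8, 4))
        assert np.array_equal(gaussian_smooth(img, 0.0, (1.5, 1.5, 4.0)), img)

    def test_constant_field_unchanged(self):
        img = np.full((10, 10, 6), 3.7)
        out = gaussian_smooth(img, 8.0, (1.5, 1.5, 4.0))
        assert np.allclose(out, 3.7)

    def test_centered_delta_mass_preserved(self):
        img = np.zeros((31, 31, 31))
        img[15, 15, 15] = 1.0
        out = gaussian_smooth(img, 3.0, (1.5, 1.5, 1.5))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)


class TestVoxelwiseTtest:
    def test_identical_sets_give_zero_t(self, rng):
        a = rng.normal(size=(5, 4, 4, 2))
        t, df = voxelwise_ttest(a, a.copy())
        assert np.allclose(t[np.isfinite(t)], 0.0)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=(5, 4, 4, 2))
        b = rng.normal(size=(6, 4, 4, 2))
        t_ab, _ = voxelwise_ttest(a, b)
        t_ba, _ = voxelwise_ttest(b, a)
        assert np.allclose(t_ab, -t_ba, equal_nan=True)

    def test_hand_evaluated_welch_formula(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        b = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1)
        t, df = voxelwise_ttest(a, b)
        # means 2 and 5, each variance 1: t = -3 / sqrt(2/3), df = 4
        assert t[0, 0, 0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert df[0, 0, 0] == pytest.approx(4.0)

    def test_zero_variance_everywhere_is_missing(self):
        a = np.ones((3, 2, 2, 1))
        t, df = voxelwise_ttest(a, np.ones((3, 2, 2, 1)))
        assert np.isnan(t).all()


def t_field_with_blobs(blob_slices, t_value=10.0, shape=(12, 12, 8)):
    t = np.zeros(shape)
    for sl in blob_slices:
        t[sl] = t_value
    df = np.full(shape, 20.0)
    return t, df


class TestClusterThreshold:
    def test_extent_rule_keeps_only_large_blob(self):
        # one 60-voxel blob (4x5x3) and one 40-voxel blob (4x5x2), separated
        t, df = t_field_with_blobs(
            [(slice(0, 4), slice(0, 5), slice(0, 3)),
             (slice(7, 11), slice(6, 11), slice(5, 7))]
        )
        res = cluster_threshold(t, df, voxel_p=0.001, min_extent=50)
        assert len(res.clusters) == 1
        assert res.clusters[0].size == 60

    def test_subthreshold_field_gives_empty_result(self):
        t = np.full((6, 6, 4), 1.0)
        res = cluster_threshold(t, np.full_like(t, 20.0))
        assert res.clusters == []
        assert not res.label_map.any()

    def test_corner_touching_blobs_merge_under_26_connectivity(self):
        t, df = t_field_with_blobs(
            [(slice(0, 4), slice(0, 4), slice(0, 4)),
             (slice(4, 8), slice(4, 8), slice(4, 8))]
        )
        res = cluster_threshold(t, df, min_extent=50)
        assert len(res.clusters) == 1
        assert res.clusters[0].size == 128

    def test_peak_location_reported(self):
        t, df = t_field_with_blobs([(slice(0, 4), slice(0, 5), slice(0, 3))])
        t[2, 2, 1] = 15.0
        res = cluster_threshold(t, df)
        assert res.clusters[0].peak_index == (2, 2, 1)
        assert res.clusters[0].peak_t == 15.0


class TestPermutationFwe:
    def test_corrected_p_floor(self, rng):
        a = rng.normal(0, 1, (8, 10, 10, 4))
        b = rng.normal(0, 1, (8, 10, 10, 4))
        a[:, 2:6, 2:6, 1:3] += 4.0  # planted 64-voxel effect
        res = permutation_cluster_fwe(a, b, min_extent=20, n_perm=199, seed=0)
        assert res.clusters, "planted effect not detected"
        for c in res.clusters:
            assert c.corrected_p >= 1.0 / 200.0
        assert res.clusters[0].corrected_p == pytest.approx(1.0 / 200.0)

    def test_exhaustive_enumeration_for_tiny_groups(self, rng):
        a = rng.normal(0, 1, (3, 6, 6, 3)) + 3.0
        b = rng.normal(0, 1, (3, 6, 6, 3))
        res = permutation_cluster_fwe(a, b, min_extent=1, n_perm=100, seed=0)
        assert res.exhaustive
        assert res.n_permutations == comb(6, 3)

    def test_null_fwe_rate_short_run(self, rng):
        """Family-wise error rate of the permutation cluster test on 60 null
        replicates stays at or below ~nominal (full 500-replicate calibration
        runs in the acceptance suite)."""
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            a = rng.normal(size=(10, 12, 12, 6))
            b = rng.normal(size=(10, 12, 12, 6))
            sm = lambda x: np.stack([gaussian_smooth(m, 5.0, (2.0, 2.0, 2.0)) for m in x])
            res = permutation_cluster_fwe(sm(a), sm(b), min_extent=1,
                                          n_perm=199, seed=500 + rep)
            hits += any(c.corrected_p <= 0.05 for c in res.clusters)
        assert hits / n_rep <= 0.15
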
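"""Cluster regressions, demographic tests and FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lewyquant import groupstats as gs
from lewyquant import synthcohort as sc
from lewyquant.grouping import aggregate_loads, assign_groups
from lewyquant.regions import load_registry


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

def _subjects():
    return pd.DataFrame({
        "subject_id": ["s1", "s2"],
        "age_at_death": [70.0, 80.0],
        "sex": ["female", "male"],
        "apoe_allele_1": [3, 3],
        "apoe_allele_2": [4, 3],
        "braak_stage": ["V", "VI"],
        "thal_phase": [5, 5],
        "tdp43": ["negative", "positive"],
    })


def _measurements():
    rows = []
    for subj in ("s1", "s2"):
        for stain in ("alpha_syn", "tau"):
            for region in ("amygdala", "cingulate_gyrus", "olfactory_bulb"):
                rows.append(dict(subject_id=subj, stain=stain, region=region,
                                 annotation_index=1, covered_area_pct=0.5, qc_flag="pass"))
    return pd.DataFrame(rows)


def _assignments():
    return pd.DataFrame({
        "subject_id": ["s1", "s2"],
        "group": ["alpha_syn_positive", "alpha_syn_negative"],
        "subgroup": ["A", "none"],
        "eligible": [True, True],
    })


class TestBuildFrame:
    def test_row_count_and_cluster_join(self):
        frame = gs.build_frame(_measurements(), _subjects(), _assignments())
        # olfactory bulb (unassigned cluster) excluded: 2 regions x 2 stains x 2 subjects
        assert len(frame) == 8
        assert set(frame["cluster"]) == {"amygdala_entorhinal", "cortical"}

    def test_age_band_and_apoe_derivations(self):
        frame = gs.build_frame(_measurements(), _subjects(), _assignments())
        s1 = frame[frame["subject_id"] == "s1"].iloc[0]
        s2 = frame[frame["subject_id"] == "s2"].iloc[0]
        assert s1["age_group"] == "65-75" and s2["age_group"] == ">=75"
        assert bool(s1["apoe4_carrier"]) and not bool(s2["apoe4_carrier"])

    @pytest.mark.parametrize("age,band", [(64.9, "<65"), (65.0, "65-75"),
                                          (74.9, "65-75"), (75.0, ">=75")])
    def test_age_band_boundaries(self, age, band):
        assert gs.age_group(age) == band

    def test_orphan_measurements_rejected(self):
        bad = _measurements()
        bad.loc[0, "subject_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            gs.build_frame(bad, _subjects(), _assignments())

    def test_eligible_negatives_relabeled(self):
        frame = gs.build_frame(_measurements(), _subjects(), _assignments())
        assert set(frame.loc[frame["group"] == "alpha_syn_negative", "subgroup"]) == {"negative"}


# ---------------------------------------------------------------------------
# chi-squared and rank tests
# ---------------------------------------------------------------------------

class TestChisq:
    def test_published_sex_table(self):
        res = gs.chisq_test([[13, 16], [27, 16]])
        assert res.statistic == pytest.approx(1.6, abs=0.05)
        assert res.continuity_correction and res.dof == 1

    def test_homogeneous_table_is_zero(self):
        assert gs.chisq_test([[10, 10], [10, 10]]).statistic == 0.0

    def test_published_braak_table_without_correction(self):
        res = gs.chisq_test([[1, 7, 21], [7, 7, 29]])
        assert res.statistic == pytest.approx(3.2, abs=0.05)
        assert not res.continuity_correction and res.dof == 2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gs.chisq_test([[1, -2], [3, 4]])


class TestRankTests:
    def test_identical_samples_near_one(self):
        res = gs.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p > 0.9
        assert res.statistic == pytest.approx(8.0)  # n*m/2

    def test_complete_separation_u_zero(self):
        assert gs.mann_whitney([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_kruskal_three_groups(self):
        res = gs.kruskal_wallis([1, 2], [1.1, 2.1], [0.9, 1.9])
        assert res.test == "kruskal_wallis_K" and 0 < res.p <= 1

    def test_wilcoxon_zero_differences_convention(self):
        res = gs.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_empty_or_unpaired_rejected(self):
        with pytest.raises(ValueError):
            gs.mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            gs.wilcoxon_signed_rank([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Brute-force Benjamini-Hochberg: p*m/rank with step-up monotonization."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert gs.fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_three_value_example(self):
        assert np.allclose(gs.fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(gs.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.fdr_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_bruteforce_oracle_and_dominates_raw(self, p):
        adj = gs.fdr_adjust(p)
        assert np.allclose(adj, _bh_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestSummarizeClusters:
    def test_median_and_iqr(self):
        frame = pd.DataFrame({
            "group": "g", "cluster": "cortical", "stain": "tau",
            "covered_area_pct": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        out = gs.summarize_clusters(frame)
        row = out.iloc[0]
        assert row["median"] == 3.0 and row["q25"] == 2.0 and row["q75"] == 4.0
        assert row["n"] == 5

    def test_single_value_collapses(self):
        frame = pd.DataFrame({"group": "g", "cluster": "c", "stain": "t",
                              "covered_area_pct": [0.7]})
        row = gs.summarize_clusters(frame).iloc[0]
        assert row["median"] == row["q25"] == row["q75"] == 0.7

    def test_counts_conserved(self, easy_cohort):
        subjects, measurements = easy_cohort
        frame = gs.build_frame(measurements, sc.subjects_to_frame(subjects),
                               assign_groups(measurements))
        out = gs.summarize_clusters(frame)
        assert out["n"].sum() == len(frame)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            gs.summarize_clusters(pd.DataFrame(columns=["group", "cluster", "stain",
                                                        "covered_area_pct"]))


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _two_group_frame(seed, n_subj=20, regions=("r1", "r2", "r3", "r4"),
                     offset=0.0, subj_sd=0.0, noise_sd=0.005, base=0.01):
    """Fraction-scale loads around `base` with an additive `offset` for g1."""
    r = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_subj):
        lab = "g0" if i < n_subj else "g1"
        u = r.normal(0, subj_sd)
        age = float(np.clip(r.normal(72.8, 11.5), 40, 100))
        sex = "female" if r.random() < 0.56 else "male"
        for reg in regions:
            y = base + u + (offset if lab == "g1" else 0.0) + r.normal(0, noise_sd)
            rows.append(dict(subject_id=f"s{i}", stain="alpha_syn", region=reg,
                             cluster="cortical", covered_area_pct=max(y, 0.0) * 100,
                             sex=sex, age_at_death=age, lab=lab))
    return pd.DataFrame(rows)


class TestPairwiseRegression:
    def test_degenerate_single_region_equals_mean_difference(self):
        frame = _two_group_frame(3, regions=("r1",), offset=0.02)
        res = gs.fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                                 ("g0", "g1"), "none", "lab")
        means = frame.groupby("lab")["covered_area_pct"].mean() / 100
        assert res.beta == pytest.approx(means["g1"] - means["g0"], abs=1e-12)

    def test_missing_label_flagged(self):
        frame = _two_group_frame(4)
        res = gs.fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                                 ("g0", "zz"), "age_sex", "lab")
        assert not res.ok and np.isnan(res.beta)

    def test_simulation_frame_marginals(self):
        # the calibration simulations draw demographics like the cohort
        frame = gs._simulation_frame(np.random.default_rng(0), offset=0.0)
        assert set(frame["arm"]) == {"g0", "g1"}
        assert frame["covered_area_pct"].min() >= 0.0
        assert len(frame) == 40 * 4


class TestMixedControl:
    def test_matches_ols_at_zero_between_subject_variance(self):
        frame = _two_group_frame(7, offset=0.02, subj_sd=0.0)
        ols = gs.fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                                 ("g0", "g1"), "age_sex", "lab")
        mixed = gs.fit_mixed_control(frame, "cortical", "alpha_syn", ("g0", "g1"), "lab")
        assert mixed.ok
        assert mixed.beta == pytest.approx(ols.beta, abs=1e-6)

    def test_single_observation_per_subject_reduces_to_ols(self):
        frame = _two_group_frame(8, regions=("r1",), offset=0.02)
        ols = gs.fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                                 ("g0", "g1"), "age_sex", "lab")
        mixed = gs.fit_mixed_control(frame, "cortical", "alpha_syn", ("g0", "g1"), "lab")
        assert mixed.beta == pytest.approx(ols.beta, abs=1e-4)

    def test_mixed_controls_type_one_error_under_subject_effects(self):
        # strong random subject effects inflate OLS false positives; the
        # mixed model must not be worse
        ols_rej = mixed_rej = 0
        for i in range(200):
            frame = _two_group_frame(5000 + i, n_subj=15, offset=0.0,
                                     subj_sd=0.01, noise_sd=0.003)
            o = gs.fit_pairwise_cluster_regression(frame, "cortical", "alpha_syn",
                                                   ("g0", "g1"), "age_sex", "lab")
            m = gs.fit_mixed_control(frame, "cortical", "alpha_syn", ("g0", "g1"), "lab")
            ols_rej += o.p < 0.05
            mixed_rej += m.ok and m.p < 0.05
        assert mixed_rej <= ols_rej

    def test_too_few_subjects_flagged(self):
        frame = _two_group_frame(9, n_subj=1)
        res = gs.fit_mixed_control(frame, "cortical", "alpha_syn", ("g0", "g1"), "lab")
        assert not res.ok


class TestPredictorRegression:
    @staticmethod
    def _frame_with_sex_effect(seed, female_offset):
        subjects, measurements = sc.generate_cohort(
            sc.realistic_cohort_config(
                seed=seed,
                effects={"abeta": sc.CovariateEffects(female=female_offset)},
                missingness=0.0,
            )
        )
        return gs.build_frame(measurements, sc.subjects_to_frame(subjects),
                              assign_groups(measurements))

    def test_configured_female_abeta_offset_recovered(self):
        frame = self._frame_with_sex_effect(21, female_offset=0.6)
        results = gs.predictor_regression(frame, "cortical", "abeta", "sex")
        (res,) = results
        assert res.contrast == ("male", "female")
        assert res.beta > 0 and res.p < 0.05

    def test_permuted_labels_reject_at_nominal_rate(self):
        frame = self._frame_with_sex_effect(22, female_offset=0.0)
        sub = frame[(frame["cluster"] == "cortical") & (frame["stain"] == "abeta")]
        subj_sex = sub.groupby("subject_id")["sex"].first()
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            permuted = pd.Series(rng.permutation(subj_sex.to_numpy()), index=subj_sex.index)
            shuffled = frame.copy()
            shuffled["sex"] = shuffled["subject_id"].map(permuted).fillna(shuffled["sex"])
            (res,) = gs.predictor_regression(shuffled, "cortical", "abeta", "sex")
            rejections += res.p < 0.05
        assert rejections <= 11  # 95% binomial bound at alpha=0.05, 100 draws

    def test_age_groups_pairwise_contrasts(self, easy_cohort):
        subjects, measurements = easy_cohort
        frame = gs.build_frame(measurements, sc.subjects_to_frame(subjects),
                               assign_groups(measurements))
        results = gs.predictor_regression(frame, "cortical", "alpha_syn", "age_group")
        assert len(results) == 3  # three pairwise age-band contrasts

    def test_single_level_predictor_rejected(self):
        frame = _two_group_frame(10).assign(apoe4_carrier=False)
        with pytest.raises(ValueError):
            gs.predictor_regression(frame, "cortical", "alpha_syn", "apoe4")


class TestContrastAnalysis:
    def test_family_wide_fdr_applied_across_clusters(self, easy_cohort):
        subjects, measurements = easy_cohort
        frame = gs.build_frame(measurements, sc.subjects_to_frame(subjects),
                               assign_groups(measurements))
        table = gs.run_contrast_analysis(frame, "alpha_syn",
                                         ("alpha_syn_negative", "alpha_syn_positive"))
        assert len(table) == 5
        ok = table["flag"] == ""
        assert np.all(table.loc[ok, "p_fdr"] >= table.loc[ok, "p"] - 1e-12)
        # easy preset: positives carry far more alpha-syn in every cluster
        assert (table.loc[ok, "beta"] > 0).all()
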
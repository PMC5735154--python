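"""Lesion index, contrasts, transforms and the model-fitting stages."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from intransit.stats import (
    DEFAULT_LOG_OFFSET,
    build_contrasts,
    build_group_task_design,
    compute_ldi,
    fit_group_task_model,
    half_triplet_offset,
    item_involvement_counts,
    item_involvement_test,
    laterality_comparison,
    ldi_behavior_correlation,
    log_transform_scores,
    rt_analyses,
    triplet_level_regressions,
    variance_homogeneity_check,
)
from intransit.transitivity import dataset_involvement, score_dataset, triplet_table


class TestLDI:
    def test_equal_volumes_zero(self):
        assert compute_ldi(3.1, 3.1).ldi == 0.0

    def test_worked_value(self):
        assert compute_ldi(0.62, 0.38).ldi == pytest.approx(0.24)

    def test_side_symmetry_and_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            left, right = rng.uniform(0.05, 10.0, size=2)
            rec = compute_ldi(left, right)
            assert rec.ldi == pytest.approx(compute_ldi(right, left).ldi)
            assert 0.0 <= rec.ldi < 1.0
            assert (rec.ldi == 0.0) == (left == right)

    def test_vanishing_side_approaches_one(self):
        assert compute_ldi(1.0, 1e-9).ldi == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_ldi(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_ldi(1.0, -2.0)


class TestLdiCorrelation:
    @staticmethod
    def _frames(ldi, pct):
        ids = [f"s{i}" for i in range(len(ldi))]
        records = pd.DataFrame(
            {"subject_id": ids, "vol_left": 1.0, "vol_right": 1.0, "ldi": ldi}
        )
        scores = pd.DataFrame({"subject_id": ids, "pct_intransitive": pct})
        return records, scores

    def test_monotone_pairs_give_unity(self):
        records, scores = self._frames([0.1, 0.2, 0.3, 0.4], [1, 2, 5, 9])
        assert ldi_behavior_correlation(records, scores).rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        records, scores = self._frames([0.1, 0.2, 0.3, 0.4], [9, 5, 2, 1])
        assert ldi_behavior_correlation(records, scores).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(12)
        ldi = rng.uniform(0, 0.9, 15)
        pct = rng.uniform(0, 12, 15)
        records, scores = self._frames(ldi, pct)
        result = ldi_behavior_correlation(records, scores)
        brute = scipy.stats.pearsonr(
            scipy.stats.rankdata(ldi), scipy.stats.rankdata(pct)
        )[0]
        assert result.rho == pytest.approx(brute, abs=1e-12)

    def test_orphan_ids_reported(self):
        records, scores = self._frames([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        with pytest.raises(KeyError, match="s3"):
            ldi_behavior_correlation(records, scores.iloc[:-1])

    def test_minimum_sample(self):
        records, scores = self._frames([0.1, 0.2, 0.3], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 4"):
            ldi_behavior_correlation(records, scores)


class TestContrasts:
    def test_weights_sum_to_zero_and_orthogonal(self):
        scheme = build_contrasts()
        c1 = np.array([scheme.codes[g][0] for g in ("CON", "ETL", "MTL")])
        c2 = np.array([scheme.codes[g][1] for g in ("CON", "ETL", "MTL")])
        assert c1.sum() == 0.0
        assert c2.sum() == 0.0
        assert c1 @ c2 == 0.0

    def test_second_contrast_on_group_means(self):
        scheme = build_contrasts()
        means = {"CON": 2.75, "ETL": 3.37, "MTL": 6.07}
        applied = sum(scheme.codes[g][1] * m for g, m in means.items())
        assert applied == pytest.approx(6.07 - (2.75 + 3.37) / 2)
        assert applied == pytest.approx(3.01)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            build_contrasts(("CON", "ETL", "XXX"))


class TestDesignMatrix:
    @staticmethod
    def _scores():
        rows = []
        for g, s in (("CON", "c1"), ("ETL", "e1"), ("MTL", "m1")):
            for task in ("preference", "number"):
                rows.append(
                    {"subject_id": s, "group": g, "task": task,
                     "pct_intransitive": 1.0}
                )
        return pd.DataFrame(rows)

    def test_columns_and_coding(self):
        X = build_group_task_design(self._scores())
        assert list(X.columns) == [
            "intercept", "etl_vs_con", "mtl_vs_controls", "task",
            "etl_vs_con:task", "mtl_vs_controls:task",
        ]
        pref_mtl = X[(self._scores()["group"] == "MTL")
                     & (self._scores()["task"] == "preference")]
        assert pref_mtl["mtl_vs_controls"].iloc[0] == 1.0
        assert pref_mtl["task"].iloc[0] == 0.5
        assert pref_mtl["mtl_vs_controls:task"].iloc[0] == 0.5

    def test_full_rank(self):
        X = build_group_task_design(self._scores())
        assert np.linalg.matrix_rank(X.to_numpy()) == 6

    def test_single_task_subject_rejected(self):
        bad = self._scores().iloc[:-1]
        with pytest.raises(ValueError, match="both tasks"):
            build_group_task_design(bad)

    def test_unknown_labels_rejected(self):
        bad = self._scores().assign(group="WHO")
        with pytest.raises(ValueError, match="unknown group"):
            build_group_task_design(bad)


class TestLogTransform:
    def test_zero_maps_to_log_offset(self):
        vals, off = log_transform_scores(np.array([0.0]))
        assert off == DEFAULT_LOG_OFFSET
        assert vals[0] == pytest.approx(np.log(off))

    def test_monotone_and_ties_preserved(self):
        vals, _ = log_transform_scores(np.array([0.0, 1.0, 1.0, 5.0]))
        assert vals[1] == vals[2]
        assert np.all(np.diff(vals) >= 0)

    def test_half_triplet_policy(self):
        assert half_triplet_offset(20) == pytest.approx(100 / 2280)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform_scores(np.array([-1.0]))


class TestBartlett:
    def test_equal_variances_small_statistic(self):
        k2, df, p = variance_homogeneity_check(
            {"a": [1.0, 2.0, 3.0], "b": [11.0, 12.0, 13.0]}
        )
        assert k2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_against_scipy_on_fixture(self):
        a, b = [1.0, 2.0, 4.0], [1.0, 5.0, 13.0]
        k2, df, p = variance_homogeneity_check({"a": a, "b": b})
        k2_ref, p_ref = scipy.stats.bartlett(a, b)
        assert k2 == pytest.approx(k2_ref)
        assert p == pytest.approx(p_ref)
        assert k2 > 0

    def test_permutation_invariance(self):
        base = variance_homogeneity_check({"a": [1, 5, 2, 8], "b": [2, 2, 3, 9]})
        perm = variance_homogeneity_check({"a": [8, 1, 5, 2], "b": [9, 2, 2, 3]})
        assert base[0] == pytest.approx(perm[0])

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="'b'"):
            variance_homogeneity_check({"a": [1.0, 2.0], "b": [3.0, 3.0]})

    def test_transform_reduces_task_inequality(self, small_cohort):
        scores = score_dataset(small_cohort.dataset)
        raw = {t: g["pct_intransitive"].to_numpy()
               for t, g in scores.groupby("task")}
        logv = {t: log_transform_scores(v)[0] for t, v in raw.items()}
        assert variance_homogeneity_check(logv)[0] < variance_homogeneity_check(raw)[0]


class TestGroupTaskModel:
    def test_terms_present_and_p_in_range(self, small_cohort):
        scores = score_dataset(small_cohort.dataset)
        result = fit_group_task_model(scores)
        assert set(result.terms["term"]) == {
            "intercept", "etl_vs_con", "mtl_vs_controls", "task",
            "etl_vs_con:task", "mtl_vs_controls:task",
        }
        assert ((result.terms["p"] >= 0) & (result.terms["p"] <= 1)).all()

    def test_offset_shift_leaves_interactions(self, small_cohort):
        """The offset rescales the intercept but contrasts of differences
        move far less; interaction terms stay within a small band."""
        scores = score_dataset(small_cohort.dataset)
        r1 = fit_group_task_model(scores, offset=1.0)
        r2 = fit_group_task_model(scores, offset=2.0)
        i1 = r1.estimate("mtl_vs_controls:task")
        i2 = r2.estimate("mtl_vs_controls:task")
        d_int = abs(r1.estimate("intercept") - r2.estimate("intercept"))
        assert abs(i1 - i2) < d_int + 1.0


class TestTripletRegressions:
    def test_all_transitive_raises_separation(self):
        trips = pd.DataFrame(
            {
                "subject_id": ["s"] * 4,
                "group": ["CON"] * 4,
                "is_intransitive": [False] * 4,
                "last_trial_index": [3, 4, 5, 6],
                "trial_index_variance": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="separation"):
            triplet_level_regressions(trips)

    def test_terms_per_feature(self, small_cohort):
        trips = triplet_table(small_cohort.dataset)
        pref = trips[trips["task"] == "preference"]
        out = triplet_level_regressions(pref)
        assert set(out) == {"last_trial_index", "trial_index_variance"}
        terms = out["trial_index_variance"].terms["term"].tolist()
        assert terms == [
            "intercept", "trial_index_variance", "mtl", "trial_index_variance:mtl"
        ]

    def test_shuffling_trial_indices_kills_spacing_effect(self):
        """Permuting trial indices within subject destroys the generative
        link between spacing and inconsistency."""
        from intransit.synthetic import CohortSpec, generate_cohort

        spec = CohortSpec(n_con=10, n_etl=10, n_mtl=10, n_lesion=5)
        coefs, coefs_shuffled = [], []
        for rep in range(6):
            cohort = generate_cohort(spec, seed=777 + rep)
            trips = triplet_table(cohort.dataset)
            pref = trips[trips["task"] == "preference"].copy()
            res = triplet_level_regressions(
                pref, features=("trial_index_variance",)
            )["trial_index_variance"]
            coefs.append(res.estimate("trial_index_variance"))
            rng = np.random.default_rng(rep)
            cols = ["t_ij", "t_jk", "t_ik"]
            shuffled = pref.copy()
            vals = shuffled[cols].to_numpy().astype(float)
            rng.shuffle(vals, axis=0)
            shuffled["trial_index_variance"] = vals.var(axis=1, ddof=1)
            res_s = triplet_level_regressions(
                shuffled, features=("trial_index_variance",)
            )["trial_index_variance"]
            coefs_shuffled.append(res_s.estimate("trial_index_variance"))
        assert np.mean(coefs) > np.mean(coefs_shuffled)
        assert abs(np.mean(coefs_shuffled)) < 0.05


class TestRtAnalyses:
    def test_constant_rt_degenerates_with_warning(self):
        trials = pd.DataFrame(
            {
                "subject_id": ["a"] * 4 + ["b"] * 4,
                "group": ["CON"] * 4 + ["MTL"] * 4,
                "rt": 1.0,
                "involved": [True, False, True, False] * 2,
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            involvement, _ = rt_analyses(trials)
        assert involvement.estimate("rt") == 0.0

    def test_missing_rt_excluded_and_counted(self, small_cohort):
        inv = dataset_involvement(small_cohort.dataset)
        pref = inv[inv["task"] == "preference"].copy()
        pref.loc[pref.index[:10], "rt"] = np.nan
        involvement, _ = rt_analyses(pref)
        assert "10 trial(s) without RT excluded" in involvement.description

    def test_group_rt_terms(self, small_cohort):
        inv = dataset_involvement(small_cohort.dataset)
        _, group_rt = rt_analyses(inv[inv["task"] == "preference"])
        assert group_rt.terms["term"].tolist() == [
            "intercept", "etl_vs_con", "mtl_vs_controls"
        ]
        # the generator's MTL slowdown should appear with a positive sign
        assert group_rt.estimate("mtl_vs_controls") > 0


class TestItemInvolvement:
    def test_identical_counts_no_heterogeneity(self):
        counts = pd.DataFrame(
            {"subject_id": np.repeat(["a", "b", "c"], 4),
             "item": list(range(1, 5)) * 3,
             "count": [2] * 12}
        )
        f, (df1, df2), p = item_involvement_test(counts)
        assert f == 0.0
        assert (df1, df2) == (3, 6)
        assert p == 1.0

    def test_inflated_item_detected(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(12):
            base = rng.poisson(3, size=8)
            base[2] += 12  # one systematically over-involved item
            rows += [
                {"subject_id": f"s{s}", "item": i + 1, "count": int(c)}
                for i, c in enumerate(base)
            ]
        f, _, p = item_involvement_test(pd.DataFrame(rows))
        assert p < 0.001

    def test_single_item_rejected(self):
        counts = pd.DataFrame(
            {"subject_id": ["a", "b"], "item": [1, 1], "count": [1, 2]}
        )
        with pytest.raises(ValueError):
            item_involvement_test(counts)

    def test_counts_table_shape(self, small_cohort):
        trips = triplet_table(small_cohort.dataset)
        pref = trips[trips["task"] == "preference"]
        counts = item_involvement_counts(pref, small_cohort.dataset.n_items)
        n_subjects = pref["subject_id"].nunique()
        assert len(counts) == n_subjects * small_cohort.dataset.n_items


def test_laterality_comparison_runs(small_cohort):
    scores = score_dataset(small_cohort.dataset)
    pref = scores[scores["task"] == "preference"]
    result = laterality_comparison(small_cohort.lesions, pref)
    row = result.terms.iloc[0]
    assert 0 <= row["p"] <= 1
    assert row["df"] == len(small_cohort.lesions) - 2
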
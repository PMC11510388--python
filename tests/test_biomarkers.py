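"""Dual-method biomarker discovery: screen, effect size, models, consensus."""

import numpy as np
import pandas as pd
import pytest

from asdgm.biomarkers import (
    LefseConfig,
    confounder_lm,
    consensus,
    kruskal_screen,
    lda_effect_size,
    pathway_differential,
    run_consensus,
)
from asdgm.features import FeatureTable


def _table_from_groups(rows: dict, n_per_group=6, seed=0, scale=1.0) -> tuple:
    """Two-group table; rows maps feature -> (mean_a, mean_b) of lognormal draws."""
    rng = np.random.default_rng(seed)
    samples = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    labels = pd.Series(["ga"] * n_per_group + ["gb"] * n_per_group, index=samples)
    data = {}
    for fid, (ma, mb) in rows.items():
        a = rng.lognormal(np.log(ma), 0.1, n_per_group)
        b = rng.lognormal(np.log(mb), 0.1, n_per_group)
        data[fid] = np.concatenate([a, b]) * scale
    frame = pd.DataFrame(data, index=samples).T
    return FeatureTable(frame, mode="normalized"), labels


class TestKruskalScreen:
    def test_identical_groups_fail_screen(self):
        table, labels = _table_from_groups({"flat": (10, 10), "diff": (5, 50)})
        out = kruskal_screen(table, labels)
        assert not out.loc["flat", "passed"]
        assert out.loc["diff", "passed"]

    def test_constant_feature_flagged(self):
        samples = [f"s{i}" for i in range(8)]
        frame = pd.DataFrame({s: [1.0, float(i)] for i, s in enumerate(samples)},
                             index=["const", "varies"])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=samples)
        out = kruskal_screen(FeatureTable(frame, mode="normalized"), labels)
        assert out.loc["const", "reason"] == "constant"
        assert not out.loc["const", "passed"]

    def test_separated_supports_minimal_p(self):
        table, labels = _table_from_groups({"sep": (1, 1000)}, n_per_group=8)
        out = kruskal_screen(table, labels)
        assert out.loc["sep", "kw_p"] < 0.001

    def test_three_group_hand_oracle(self):
        samples = [f"s{i}" for i in range(9)]
        frame = pd.DataFrame([np.arange(1.0, 10.0)], index=["f"], columns=samples)
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=samples)
        out = kruskal_screen(FeatureTable(frame, mode="normalized"), labels)
        from scipy.stats import chi2

        expected_p = chi2.sf(7.2, df=2)  # H = 7.2 by hand-rank computation
        assert out.loc["f", "kw_p"] == pytest.approx(expected_p)


class TestLdaEffectSize:
    def test_planted_tenfold_effect_exceeds_threshold(self):
        table, labels = _table_from_groups(
            {"planted": (50, 500), "null": (50, 50)}, n_per_group=10, seed=1
        )
        out = lda_effect_size(table, labels, LefseConfig(seed=0))
        assert out.loc["planted", "lda_score"] > 2.0
        assert out.loc["planted", "enriched_group"] == "gb"
        assert out.loc["null", "lda_score"] < 2.0

    def test_null_feature_rarely_scores(self):
        hits = 0
        for seed in range(20):
            table, labels = _table_from_groups({"null": (50, 50), "filler": (20, 20)},
                                               n_per_group=10, seed=seed)
            out = lda_effect_size(table, labels, LefseConfig(seed=seed))
            if out.loc["null", "lda_score"] > 2.0:
                hits += 1
        assert hits <= 1  # below any positive threshold in >=95% of seeds

    def test_deterministic_per_seed(self):
        table, labels = _table_from_groups({"f": (5, 40), "g": (10, 10)}, seed=2)
        a = lda_effect_size(table, labels, LefseConfig(seed=9))
        b = lda_effect_size(table, labels, LefseConfig(seed=9))
        assert np.allclose(a["lda_score"].values, b["lda_score"].values)

    def test_scale_covariance_and_optional_rescaling(self):
        # on the raw scale, multiplying all abundances by 10 raises scores
        # monotonically; with per-sample rescaling enabled the score becomes
        # invariant to the global factor
        t1, labels = _table_from_groups({"f": (5, 40), "g": (10, 10)}, seed=3, scale=1.0)
        t2, _ = _table_from_groups({"f": (5, 40), "g": (10, 10)}, seed=3, scale=10.0)
        a = lda_effect_size(t1, labels, LefseConfig(seed=4))
        b = lda_effect_size(t2, labels, LefseConfig(seed=4))
        assert (b["lda_score"].values >= a["lda_score"].values).all()
        ar = lda_effect_size(t1, labels, LefseConfig(seed=4, rescale_total=1e6))
        br = lda_effect_size(t2, labels, LefseConfig(seed=4, rescale_total=1e6))
        assert np.allclose(ar["lda_score"].values, br["lda_score"].values)


class TestConfounderLm:
    def _age_design(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        age = rng.uniform(3, 17, n)
        gender = rng.choice(["male", "female"], n)
        cov = pd.DataFrame({"age": age, "gender": gender}, index=samples)
        labels = pd.Series(rng.choice(["x", "y"], n), index=samples)
        return samples, age, cov, labels

    def test_age_driven_feature_not_attributed_to_group(self):
        rejections = 0
        n_sims = 100
        for seed in range(n_sims):
            samples, age, cov, labels = self._age_design(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            abundance = np.exp(0.3 * age + rng.normal(0, 0.3, len(age)))
            frame = pd.DataFrame([abundance], index=["f"], columns=samples)
            out = confounder_lm(FeatureTable(frame, mode="normalized"), labels, cov)
            if out.loc["f", "lm_group_p"] < 0.05:
                rejections += 1
        assert rejections / n_sims < 0.12  # near the nominal 5% level

    def test_planted_group_shift_recovered(self):
        detections = 0
        n_sims = 25
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            n = 60
            samples = [f"s{i}" for i in range(n)]
            labels = pd.Series(["x"] * 30 + ["y"] * 30, index=samples)
            cov = pd.DataFrame(
                {"age": rng.uniform(3, 17, n), "gender": rng.choice(["male", "female"], n)},
                index=samples,
            )
            noise = rng.normal(0, 1.0, n)
            y = np.exp(noise + 2.0 * (labels.values == "y"))  # 2 SD shift
            frame = pd.DataFrame([y], index=["f"], columns=samples)
            out = confounder_lm(FeatureTable(frame, mode="normalized"), labels, cov)
            if out.loc["f", "lm_group_p"] < 0.05:
                detections += 1
        assert detections / n_sims > 0.8

    def test_constant_feature_rejected_with_reason(self):
        samples, _, cov, labels = self._age_design()
        frame = pd.DataFrame([np.ones(len(samples))], index=["c"], columns=samples)
        out = confounder_lm(FeatureTable(frame, mode="normalized"), labels, cov)
        assert out.loc["c", "reason"] == "constant"
        assert np.isnan(out.loc["c", "lm_group_p"])

    def test_collinear_covariates_error_names_pair(self):
        samples, age, cov, labels = self._age_design()
        cov["age2"] = cov["age"]
        frame = pd.DataFrame([np.arange(len(samples), dtype=float)], index=["f"],
                             columns=samples)
        with pytest.raises(ValueError, match="age"):
            confounder_lm(FeatureTable(frame, mode="normalized"), labels, cov)

    def test_three_group_omnibus_uses_nested_f(self):
        rng = np.random.default_rng(0)
        n = 45
        samples = [f"s{i}" for i in range(n)]
        labels = pd.Series(["a"] * 15 + ["b"] * 15 + ["c"] * 15, index=samples)
        cov = pd.DataFrame(
            {"age": rng.uniform(3, 17, n), "gender": rng.choice(["male", "female"], n)},
            index=samples,
        )
        y = np.exp(rng.normal(0, 0.5, n) + 1.5 * (labels.values == "c"))
        frame = pd.DataFrame([y], index=["f"], columns=samples)
        out = confounder_lm(FeatureTable(frame, mode="normalized"), labels, cov)
        assert out.loc["f", "lm_group_p"] < 0.01


class TestConsensus:
    def _arms(self):
        kw = pd.DataFrame({"kw_p": [0.01, 0.01, 0.5], "passed": [True, True, False],
                           "reason": ["", "", ""]},
                          index=pd.Index(["both", "lefse_only", "neither"], name="feature_id"))
        lda = pd.DataFrame({"lda_score": [3.0, 3.0, 0.5], "effect": [1e3, 1e3, 2.0],
                            "enriched_group": ["a", "a", "b"]}, index=kw.index)
        lm = pd.DataFrame({"lm_group_p": [0.01, 0.8, 0.9], "reason": ["", "", ""]},
                          index=kw.index)
        return kw, lda, lm

    def test_intersection_semantics(self):
        kw, lda, lm = self._arms()
        report = consensus(kw, lda, lm)
        assert report.loc["both", "consensus"]
        assert not report.loc["lefse_only", "consensus"]
        assert report.loc["lefse_only", "evidence"] == "single-method"
        assert report.loc["neither", "evidence"] == ""
        # consensus set is contained in each single-method set
        assert (report["consensus"] <= report["lefse_pass"]).all()
        assert (report["consensus"] <= report["lm_pass"]).all()

    def test_enriched_group_present_for_consensus(self):
        kw, lda, lm = self._arms()
        report = consensus(kw, lda, lm)
        assert report.loc[report["consensus"], "enriched_group"].notna().all()

    def test_empty_intersection_is_valid(self):
        kw, lda, lm = self._arms()
        lm["lm_group_p"] = 0.9
        report = consensus(kw, lda, lm)
        assert report["consensus"].sum() == 0


class TestPathwayDifferential:
    def _ko_table(self, n_per=20, fold=2.0, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=samples)
        base = rng.lognormal(5, 1, 30)
        mat = rng.poisson(base, size=(2 * n_per, 30)).astype(float).T
        mat[0, n_per:] *= fold  # planted 2-fold pathway shift in group b
        frame = pd.DataFrame(mat, index=[f"ko{i}" for i in range(30)], columns=samples)
        frame.loc["ko_zero"] = 0.0
        return FeatureTable(frame, mode="counts"), labels

    def test_planted_shift_detected_by_both_arms(self):
        table, labels = self._ko_table()
        report = pathway_differential(table, labels, cfg=LefseConfig(seed=0))
        assert report.loc["ko0", "lefse_pass"]
        assert report.loc["ko0", "lm_pass"]
        assert report.loc["ko0", "consensus"]

    def test_all_zero_row_excluded(self):
        table, labels = self._ko_table()
        report = pathway_differential(table, labels, cfg=LefseConfig(seed=0))
        assert "ko_zero" not in report.index
        assert "ko_zero" in report.attrs["dropped_all_zero"]

    def test_label_permutation_detection_near_alpha(self):
        table, labels = self._ko_table(fold=1.0, seed=3)
        rng = np.random.default_rng(7)
        rates = []
        for _ in range(10):
            perm = pd.Series(rng.permutation(labels.values), index=labels.index)
            report = pathway_differential(table, perm, cfg=LefseConfig(seed=0))
            rates.append(report["consensus"].mean())
        assert np.mean(rates) <= 0.05  # intersection can only shrink error

    def test_voom_weights_variant_runs(self):
        table, labels = self._ko_table()
        report = pathway_differential(table, labels, cfg=LefseConfig(seed=0),
                                      voom_weights=True)
        assert report.attrs["voom_weights"]
        assert report.loc["ko0", "consensus"]


class TestPermutationInvariance:
    def test_sample_and_feature_order_invariance(self, small_cohort):
        from asdgm.features import css_normalize, filter_features

        c = small_cohort
        filtered, _ = filter_features(c.case_table)
        norm = css_normalize(filtered)
        labels = c.truth.labels["CSS"]
        cov = c.clinical.data[["age", "gender"]]
        r1 = run_consensus(norm, labels, cov, LefseConfig(seed=5))
        shuffled = FeatureTable(
            norm.data.sample(frac=1.0, random_state=1).sample(frac=1.0, axis=1, random_state=2),
            mode="normalized",
        )
        r2 = run_consensus(shuffled, labels, cov, LefseConfig(seed=5))
        r2 = r2.reindex(r1.index)
        assert np.allclose(r1["kw_p"].dropna(), r2["kw_p"].dropna())
        assert np.allclose(r1["lm_group_p"].dropna(), r2["lm_group_p"].dropna())
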
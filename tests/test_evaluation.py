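import numpy as np
import pytest
from scipy import stats

from ceusomics.evaluation import (
    baseline_table,
    bootstrap_ci,
    confusion_metrics,
    delong_auc_variance,
    delong_test,
    diagnostics_from_scores,
    icc_2_1,
    net_benefit_curve,
    proportion_ci,
    roc_auc,
    subgroup_indices,
    weighted_kappa,
    wilcoxon_signed_rank,
    youden_threshold,
)
from oracles import brute_auc


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_tie_case(self):
        assert roc_auc([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)

    def test_label_swap_complement(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(40)
        y = rng.integers(0, 2, 40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 40)
        assert roc_auc(s, y).auc == pytest.approx(1 - roc_auc(s, 1 - y).auc)

    def test_trapezoid_equals_mann_whitney_100_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(10, 60)
            s = rng.choice(np.linspace(0, 1, 7), n)  # heavy ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            roc = roc_auc(s, y)
            trapezoid = float(np.trapezoid(roc.sensitivities, 1 - roc.specificities))
            assert abs(roc.auc - trapezoid) < 1e-10
            assert roc.auc == pytest.approx(brute_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestYouden:
    def test_perfect_scores(self):
        roc = roc_auc([1, 2, 8, 9], [0, 0, 1, 1])
        thr, sens, spec = youden_threshold(roc)
        assert sens == 1.0 and spec == 1.0
        assert 2 < thr <= 8

    def test_recovery_on_noisy_labels(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 1000)
        s = y + rng.normal(0, 0.1, 1000)
        thr, sens, spec = youden_threshold(roc_auc(s, y))
        assert sens > 0.95 and spec > 0.95

    def test_null_scores_small_index(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 1000)
        s = rng.standard_normal(1000)
        _, sens, spec = youden_threshold(roc_auc(s, y))
        assert sens + spec - 1 < 0.15


class TestConfusionMetrics:
    def test_printed_specificity_83_36(self):
        row = confusion_metrics(tp=0, fp=36, tn=83, fn=0)
        assert round(row.specificity * 100, 1) == 69.7  # 83/119

    def test_printed_specificity_100_19(self):
        row = confusion_metrics(tp=0, fp=19, tn=100, fn=0)
        assert round(row.specificity * 100, 1) == 84.0

    def test_reader_column_from_printed_counts(self):
        # tp = round(0.944 * 107) = 101, fn = 6
        row = confusion_metrics(tp=101, fp=36, tn=83, fn=6)
        r = row.as_percent_row()
        assert r["ppv_pct"] == 73.7
        assert r["npv_pct"] == 93.3
        assert r["plr"] == 3.1
        assert r["nlr"] == 0.1

    def test_zero_denominator_flagged(self):
        row = confusion_metrics(tp=5, fp=0, tn=10, fn=0)
        assert np.isnan(row.plr)
        assert "plr" in row.flags
        assert row.specificity == 1.0


class TestProportionCI:
    def test_k_equals_n_upper_bound_one(self):
        assert proportion_ci(10, 10)[1] == 1.0

    def test_zero_successes_closed_form(self):
        lo, hi = proportion_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-4)
        assert hi == pytest.approx(0.3085, abs=1e-3)

    def test_coverage_sanity(self):
        lo, hi = proportion_ci(50, 100)
        assert lo < 0.5 < hi


class TestBootstrapCI:
    def test_degenerate_perfect_auc(self):
        ci = bootstrap_ci(lambda s, y: roc_auc(s, y).auc, [1, 2, 9, 10], [0, 0, 1, 1], B=200)
        assert ci == (1.0, 1.0)

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 80)
        s = y + rng.normal(0, 1, 80)
        auc = roc_auc(s, y).auc
        lo, hi = bootstrap_ci(lambda a, b: roc_auc(a, b).auc, s, y, B=500, seed=1)
        assert lo <= auc <= hi


class TestDeLong:
    def test_identical_scores(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        s = np.arange(40.0)
        res = delong_test(s, s, y)
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 60)
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        r1 = delong_test(a, b, y)
        r2 = delong_test(np.exp(a), b, y)
        assert r1["auc_a"] == pytest.approx(r2["auc_a"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(6)
        ok = 0
        for trial in range(5):
            y = np.r_[np.zeros(50, int), np.ones(50, int)]
            s = y * 1.2 + rng.standard_normal(100)
            dl_var = delong_auc_variance(s, y)
            pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
            boot = []
            for _ in range(2000):
                idx = np.r_[rng.choice(pos, 50), rng.choice(neg, 50)]
                boot.append(roc_auc(s[idx], y[idx]).auc)
            if abs(dl_var - np.var(boot, ddof=1)) <= 0.15 * np.var(boot, ddof=1):
                ok += 1
        assert ok >= 4  # within 15% in nearly all replicates

    def test_detects_real_difference(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.zeros(150, int), np.ones(150, int)]
        good = y * 3 + rng.standard_normal(300)
        bad = rng.standard_normal(300)
        assert delong_test(good, bad, y)["p"] < 1e-6


class TestWilcoxon:
    def test_no_difference(self):
        a = np.arange(10.0)
        assert wilcoxon_signed_rank(a, a)["p"] == 1.0

    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res["p"] == pytest.approx(1 / 16)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(12)
        b = a + rng.normal(0.3, 0.5, 12)
        perm = rng.permutation(12)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(a[perm], b[perm])
        assert r1["p"] == pytest.approx(r2["p"])


class TestKappa:
    def test_identical_ratings(self):
        r = [1, 2, 3, 1, 2, 3, 2]
        assert weighted_kappa(r, r) == pytest.approx(1.0)

    def test_2x2_hand_value(self):
        # table [[45, 5], [5, 45]]: observed 0.9, expected 0.5 -> kappa 0.8
        a = [1] * 50 + [2] * 50
        b = [1] * 45 + [2] * 5 + [1] * 5 + [2] * 45
        assert weighted_kappa(a, b) == pytest.approx(0.8)

    def test_matches_sklearn_linear_weights(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(9)
        a = rng.integers(1, 4, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 1, 3)
        ours = weighted_kappa(a, b, weights="linear")
        ref = cohen_kappa_score(a, b, weights="linear")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.integers(1, 4, 500)
        b = rng.integers(1, 4, 500)
        assert abs(weighted_kappa(a, b)) < 0.1

    def test_single_category_flagged(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 1, 1], [1, 1, 1])


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 2))
        assert icc_2_1(x)["icc"] == pytest.approx(1.0)

    def test_bias_penalized_and_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(11)
        subj = rng.normal(0, 10, 40)
        x = np.column_stack([subj, subj + 2.0]) + rng.normal(0, 0.5, (40, 2))
        res = icc_2_1(x)
        assert res["icc"] < 1.0
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile([0, 1], 40),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # two-way random, absolute agreement, single rater
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert res["icc"] == pytest.approx(icc2, abs=1e-9)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((50, 2))
        assert abs(icc_2_1(x)["icc"]) < 0.15


class TestDCA:
    def test_worked_example(self):
        # 10 patients, 5 diseased; flags the 5 diseased plus 1 healthy
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        probs = np.r_[np.full(5, 0.9), 0.9, np.full(4, 0.05)]
        res = net_benefit_curve(probs, labels, thresholds=np.array([0.2]))
        assert res.net_benefit_model[0] == pytest.approx(5 / 10 - (1 / 10) * (0.2 / 0.8))
        assert res.net_benefit_model[0] == pytest.approx(0.475)

    def test_treat_none_zero_and_treat_all_closed_form(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 100)
        probs = rng.random(100)
        res = net_benefit_curve(probs, labels)
        assert np.all(res.net_benefit_none == 0)
        prev = labels.mean()
        expect = prev - (1 - prev) * res.thresholds / (1 - res.thresholds)
        assert np.allclose(res.net_benefit_all, expect)

    def test_treat_all_zero_at_prevalence_threshold(self):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        res = net_benefit_curve(np.full(100, 0.5), labels, thresholds=np.array([0.5]))
        assert res.net_benefit_all[0] == pytest.approx(0.0)

    def test_model_never_beats_perfect_classifier(self):
        rng = np.random.default_rng(14)
        labels = rng.integers(0, 2, 200)
        probs = np.clip(labels * 0.6 + rng.random(200) * 0.4, 0, 1)
        res = net_benefit_curve(probs, labels)
        assert np.all(res.net_benefit_model <= labels.mean() + 1e-12)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError):
            net_benefit_curve([0.5], [1], thresholds=np.array([1.0]))


class TestDiagnosticsFromScores:
    def test_subgroup_ppv_drops_with_prevalence(self):
        # PPV = sens*pi / (sens*pi + (1-spec)(1-pi)): lower prevalence -> lower PPV
        sens, spec = 0.9, 0.8
        for pi_hi, pi_lo in [(0.47, 0.25)]:
            ppv_hi = sens * pi_hi / (sens * pi_hi + (1 - spec) * (1 - pi_hi))
            ppv_lo = sens * pi_lo / (sens * pi_lo + (1 - spec) * (1 - pi_lo))
            assert ppv_lo < ppv_hi

    def test_row_consistency(self):
        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, 120)
        s = y * 2 + rng.standard_normal(120)
        row = diagnostics_from_scores(s, y, B=200)
        assert row.plr == pytest.approx(row.sensitivity / (1 - row.specificity))
        assert row.nlr == pytest.approx((1 - row.sensitivity) / row.specificity)
        lo, hi = row.ci["auc"]
        assert lo <= row.auc <= hi


class TestBaselineTable:
    def test_tumor_number_chi2_printed_p(self):
        # 3x2 contingency 112/4/3 vs 92/8/7: Pearson chi-squared, 2 df
        table = np.array([[112, 4, 3], [92, 8, 7]])
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        assert dof == 2
        assert p == pytest.approx(0.118, abs=5e-4)

    def test_identical_binary_distributions_fisher_p1(self):
        odds, p = stats.fisher_exact([[10, 10], [10, 10]])
        assert p == 1.0

    def test_strong_continuous_difference(self):
        rng = np.random.default_rng(16)
        t, p = stats.ttest_ind(rng.normal(0, 1, 100), rng.normal(3, 1, 100), equal_var=False)
        assert p < 1e-10

    def test_on_synthetic_cohort(self, small_cfg):
        from ceusomics.synthetic_data import simulate_cohort

        cohort = simulate_cohort(small_cfg)
        table = baseline_table(cohort)
        assert "age" in table.index and "afp_band" in table.index
        assert ((table["p"].dropna() >= 0) & (table["p"].dropna() <= 1)).all()


class TestSubgroup:
    def test_predicate_selects_benign_plus_normal_afp_malignant(self, small_cfg):
        from ceusomics.synthetic_data import simulate_cohort

        cohort = simulate_cohort(small_cfg)
        idx = subgroup_indices(cohort)
        labels = cohort.labels()
        for i in idx:
            p = cohort.patients[i]
            assert p.label == 0 or p.covariates["afp_band"] == "<20"
        assert (labels[idx] == 0).sum() == (labels == 0).sum()
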
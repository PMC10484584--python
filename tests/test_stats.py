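"""Agreement and classification statistics against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from somnoscore.stats import (
    ConfusionMatrix4,
    benjamini_yekutieli,
    binary_metrics,
    bland_altman,
    cohen_kappa,
    compare_paired,
    fourclass_metrics,
    icc_absolute,
    lr_ci,
    mcnemar_exact,
    roc_pr_curves,
    severity_class,
    wilson_ci,
)


def wilson_cc_oracle(k: int, n: int, level: float = 0.95):
    """Continuity-corrected Wilson interval via sympy exact arithmetic."""
    import sympy as sp

    z = sp.Float(sps.norm.ppf(0.5 + level / 2.0), 30)
    p = sp.Rational(k, n)
    q = 1 - p
    denom = 2 * (n + z ** 2)
    lo = (2 * n * p + z ** 2 - 1
          - z * sp.sqrt(z ** 2 - 2 - sp.Rational(1, n) + 4 * p * (n * q + 1))) / denom
    hi = (2 * n * p + z ** 2 + 1
          + z * sp.sqrt(z ** 2 + 2 - sp.Rational(1, n) + 4 * p * (n * q - 1))) / denom
    lo = 0.0 if k == 0 else float(sp.Float(lo, 30))
    hi = 1.0 if k == n else float(sp.Float(hi, 30))
    return max(lo, 0.0), min(hi, 1.0)


def icc_a1_oracle(x, y):
    """ICC(A,1) from the exact two-way ANOVA decomposition in Fractions."""
    pairs = [(Fraction(a).limit_denominator(10 ** 12),
              Fraction(b).limit_denominator(10 ** 12)) for a, b in zip(x, y)]
    n = len(pairs)
    k = 2
    grand = sum(a + b for a, b in pairs) / Fraction(n * k)
    row_means = [(a + b) / 2 for a, b in pairs]
    col_means = [sum(p[j] for p in pairs) / Fraction(n) for j in range(2)]
    msr = k * sum((rm - grand) ** 2 for rm in row_means) / Fraction(n - 1)
    msc = n * sum((cm - grand) ** 2 for cm in col_means) / Fraction(k - 1)
    sse = sum((pairs[i][j] - row_means[i] - col_means[j] + grand) ** 2
              for i in range(n) for j in range(2))
    mse = sse / Fraction((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + Fraction(k, n) * (msc - mse)))


class TestWilson:
    def test_boundaries_clip(self):
        assert wilson_ci(10, 10)[1] == 1.0
        assert wilson_ci(0, 10)[0] == 0.0

    @pytest.mark.parametrize("k, n", [(231, 245), (80, 106), (133, 139),
                                      (1, 17), (7, 8)])
    def test_exact_arithmetic_oracle(self, k, n):
        lo, hi = wilson_ci(k, n)
        olo, ohi = wilson_cc_oracle(k, n)
        assert abs(lo - olo) < 1e-12 and abs(hi - ohi) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 5.0, 9.0, 13.0])
        assert icc_absolute(x, x).icc == pytest.approx(1.0, abs=1e-12)

    def test_offset_penalized(self):
        x = np.array([1.0, 5.0, 9.0, 13.0])
        assert icc_absolute(x, x + 3.0).icc < 1.0

    def test_anova_oracle_to_1e12(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 50, size=10).round(3)
        y = (x + rng.normal(0, 5, size=10)).round(3)
        assert icc_absolute(x, y).icc == pytest.approx(icc_a1_oracle(x, y), abs=1e-12)

    def test_cross_check_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        x = rng.uniform(0, 60, size=30)
        y = x + rng.normal(1.0, 6.0, size=30)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["a", "b"], 30),
            "score": np.column_stack([x, y]).reshape(-1),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        ours = icc_absolute(x, y)
        assert ours.icc == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = res.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 decimals
        assert ours.icc_ci[0] == pytest.approx(lo, abs=0.011)
        assert ours.icc_ci[1] == pytest.approx(hi, abs=0.011)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            icc_absolute([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 5.0])
        rep = bland_altman(x, x)
        assert rep.bias == 0.0 and rep.loa_lower == 0.0 and rep.loa_upper == 0.0

    def test_hand_computed_fixture(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([12.0, 19.0, 33.0, 41.0, 52.0])
        d = y - x
        rep = bland_altman(x, y)
        assert rep.bias == pytest.approx(d.mean(), abs=1e-12)
        sd = d.std(ddof=1)
        assert rep.loa_upper == pytest.approx(d.mean() + 1.959963984540054 * sd, abs=1e-9)

    def test_normal_sample_recovers_loa(self):
        rng = np.random.default_rng(1234)
        d = rng.standard_normal(10000)
        rep = bland_altman(np.zeros(10000), d)
        assert abs(rep.loa_lower - (-1.96)) < 0.05
        assert abs(rep.loa_upper - 1.96) < 0.05


class TestCurves:
    def test_perfect_separation(self):
        roc, pr = roc_pr_curves(np.array([0.1, 0.2, 0.8, 0.9]),
                                np.array([0, 0, 1, 1]))
        assert roc.auc == pytest.approx(1.0)
        assert pr.auc >= 0.99

    def test_pairwise_oracle(self):
        scores = np.array([3.0, 1.0, 2.0, 6.0, 5.0, 4.0])
        labels = np.array([0, 0, 1, 1, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        mw = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                      for p in pos for q in neg])
        roc, _ = roc_pr_curves(scores, labels)
        assert roc.auc == pytest.approx(mw, abs=1e-12)

    def test_cross_check_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.4, 200)) > 0.6
        roc, _ = roc_pr_curves(scores, labels)
        assert roc.auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        roc, _ = roc_pr_curves(rng.random(4000), rng.random(4000) > 0.5)
        assert abs(roc.auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves(np.array([0.1, 0.9]), np.array([1, 1]))


class TestKappa:
    def test_diagonal_matrix(self):
        assert cohen_kappa(np.diag([5, 3, 2]))["kappa"] == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        row = np.array([10.0, 20.0, 30.0])
        col = np.array([5.0, 15.0, 40.0])
        m = np.outer(row, col) / col.sum()
        assert abs(cohen_kappa(m)["kappa"]) < 1e-12

    def test_fraction_oracle(self):
        counts = np.array([[16, 0, 0, 0], [10, 38, 20, 0],
                           [4, 7, 38, 26], [0, 0, 6, 80]])
        n = Fraction(int(counts.sum()))
        po = Fraction(int(np.trace(counts))) / n
        pe = sum(Fraction(int(counts[i].sum())) * Fraction(int(counts[:, i].sum()))
                 for i in range(4)) / n ** 2
        kappa_exact = (po - pe) / (1 - pe)
        se_exact = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
        res = cohen_kappa(counts)
        assert res["kappa"] == pytest.approx(float(kappa_exact), abs=1e-12)
        assert res["se"] == pytest.approx(se_exact, abs=1e-12)


class TestLikelihoodRatios:
    def test_uninformative_test(self):
        res = lr_ci(0.5, 0.5, 200, 200)
        assert res["lr_pos"] == pytest.approx(1.0)
        assert res["lr_pos_ci"][0] < 1.0 < res["lr_pos_ci"][1]

    def test_degenerate_sensitivity_one(self):
        res = lr_ci(1.0, 0.533, 215, 30)
        assert res["lr_neg"] == 0.0
        assert res["lr_neg_ci"][0] == 0.0 and math.isnan(res["lr_neg_ci"][1])

    def test_bootstrap_oracle(self):
        # seeded 2x2 sample; the log-method CI should approximate a
        # nonparametric bootstrap of the same likelihood ratio
        rng = np.random.default_rng(7)
        n_pos, n_neg, sens, spec = 120, 150, 0.8, 0.9
        res = lr_ci(sens, spec, n_pos, n_neg)
        boots = []
        for _ in range(1000):
            s = rng.binomial(n_pos, sens) / n_pos
            f = rng.binomial(n_neg, 1 - spec) / n_neg
            if f > 0:
                boots.append(s / f)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert res["lr_pos_ci"][0] == pytest.approx(lo, rel=0.2)
        assert res["lr_pos_ci"][1] == pytest.approx(hi, rel=0.2)


class TestSeverity:
    @pytest.mark.parametrize("value, cls", [
        (0.0, "None"), (4.99, "None"), (5.0, "Mild"), (14.999, "Mild"),
        (15.0, "Moderate"), (29.9, "Moderate"), (30.0, "Severe"), (88.0, "Severe"),
    ])
    def test_bins(self, value, cls):
        assert severity_class(value) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            severity_class(-0.1)


class TestFourClass:
    def test_diagonal_matrix(self):
        fc = fourclass_metrics(ConfusionMatrix4(np.diag([5, 6, 7, 8])))
        assert fc.accuracy == 1.0 and fc.underestimated == 0.0
        assert fc.overestimated == 0.0 and fc.off_by_more_than_one == 0

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(4)
        cm = ConfusionMatrix4(rng.integers(0, 20, size=(4, 4)))
        fc = fourclass_metrics(cm)
        assert fc.accuracy + fc.underestimated + fc.overestimated == pytest.approx(1.0)


class TestBenjaminiYekutieli:
    def test_all_ones_rejects_nothing(self):
        rep = benjamini_yekutieli([1.0] * 10)
        assert not any(rep.significant)

    def test_single_test_reduces_to_alpha(self):
        assert benjamini_yekutieli([0.04]).significant == [True]
        assert benjamini_yekutieli([0.06]).significant == [False]

    def test_threshold_monotone_in_alpha(self):
        ps = [0.001, 0.002, 0.01, 0.2, 0.6]
        t1 = benjamini_yekutieli(ps, alpha=0.01).threshold
        t2 = benjamini_yekutieli(ps, alpha=0.05).threshold
        t3 = benjamini_yekutieli(ps, alpha=0.10).threshold
        assert t1 <= t2 <= t3

    def test_flags_monotone_in_p(self):
        ps = [0.0001, 0.0002, 0.004, 0.2, 0.9]
        rep = benjamini_yekutieli(ps)
        flagged = [p for p, s in zip(rep.pvalues, rep.significant) if s]
        not_flagged = [p for p, s in zip(rep.pvalues, rep.significant) if not s]
        if flagged and not_flagged:
            assert max(flagged) <= min(not_flagged)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([])
        with pytest.raises(ValueError):
            benjamini_yekutieli([1.2])


class TestPairedComparison:
    def test_identical_classifications(self):
        a = np.ones(20, dtype=bool)
        assert compare_paired(a, a) == 1.0

    def test_mcnemar_matches_binomial_tail(self):
        expected = min(1.0, 2.0 * sps.binom.cdf(2, 14, 0.5))
        assert mcnemar_exact(12, 2) == pytest.approx(expected, abs=1e-15)

    def test_bootstrap_stability_across_seeds(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(0, 2, 120).astype(bool)
        a = truth ^ (rng.random(120) < 0.12)
        b = truth ^ (rng.random(120) < 0.25)

        def acc(pred, t):
            return float(np.mean(pred == t))

        p1 = compare_paired(None, kind="stat", stat=acc, a_pred=a, b_pred=b,
                            truth=truth, seed=1, n_boot=10000)
        p2 = compare_paired(None, kind="stat", stat=acc, a_pred=a, b_pred=b,
                            truth=truth, seed=2, n_boot=10000)
        assert abs(p1 - p2) <= 0.01
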
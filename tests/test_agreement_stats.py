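import numpy as np
import pytest
from scipy import stats as sstats

from pvi_scarpipe.agreement_stats import (ConfusionTable, bland_altman,
                                          chi_squared, cohens_kappa,
                                          confusion, diagnostic_summary,
                                          icc_absolute, pearson_r,
                                          t_test_two_sample)
from pvi_scarpipe.segment_model import SEGMENT_KEYS, InjuryCallSet


def _call_set(subject, values, modality="t2w", timepoint="24h"):
    return InjuryCallSet(subject, modality, timepoint,
                         dict(zip(SEGMENT_KEYS, values)))


def random_table(rng, n_max=50):
    while True:
        tp, fp, fn, tn = rng.integers(0, n_max, 4)
        if tp + fp + fn + tn > 0:
            return ConfusionTable(int(tp), int(fp), int(fn), int(tn))


class TestConfusion:
    def test_perfect_agreement(self):
        vals = [True] * 10 + [False] * 6
        a = [_call_set("s1", vals)]
        b = [_call_set("s1", vals)]
        c = confusion(a, b)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 6, 0, 0)

    def test_all_positive_vs_half(self):
        a = [_call_set("s1", [True] * 16)]
        b = [_call_set("s1", [True] * 8 + [False] * 8)]
        c = confusion(a, b)
        assert (c.tp, c.fp) == (8, 8)

    def test_none_calls_dropped_and_counted(self):
        vals = [True] * 8 + [False] * 8
        test_vals = list(vals)
        test_vals[0] = None
        c = confusion([_call_set("s1", test_vals)], [_call_set("s1", vals)])
        assert c.dropped == 1
        assert c.n == 15

    def test_unmatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            confusion([_call_set("s1", [True] * 16)],
                      [_call_set("s2", [True] * 16)])

    def test_pools_across_subjects(self):
        a = [_call_set("s1", [True] * 16), _call_set("s2", [False] * 16)]
        b = [_call_set("s1", [True] * 16), _call_set("s2", [False] * 16)]
        c = confusion(a, b)
        assert (c.tp, c.tn) == (16, 16)


class TestDiagnosticSummary:
    def test_chance_table(self):
        s = diagnostic_summary(ConfusionTable(5, 5, 5, 5))
        assert s.sensitivity == s.specificity == s.accuracy == 0.5

    def test_perfect_table_clipped_ci(self):
        s = diagnostic_summary(ConfusionTable(12, 0, 0, 8))
        assert s.sensitivity == s.specificity == s.accuracy == 1.0
        assert s.ci["sensitivity"][1] == 1.0

    def test_wald_matches_statsmodels(self, rng):
        from statsmodels.stats.proportion import proportion_confint
        for _ in range(100):
            c = random_table(rng)
            if c.n_pos == 0 or c.n_neg == 0:
                continue
            s = diagnostic_summary(c)
            lo, hi = proportion_confint(c.tp, c.n_pos, alpha=0.05,
                                        method="normal")
            assert s.ci["sensitivity"][0] == pytest.approx(max(lo, 0.0),
                                                           abs=1e-12)
            assert s.ci["sensitivity"][1] == pytest.approx(min(hi, 1.0),
                                                           abs=1e-12)
            lo, hi = proportion_confint(c.tp, c.n_pos, alpha=0.05,
                                        method="wilson")
            assert s.ci_wilson["sensitivity"] == pytest.approx((lo, hi),
                                                               abs=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_summary(ConfusionTable(0, 5, 0, 5))


class TestChiSquared:
    def test_independent_margins_zero(self):
        stat, p = chi_squared(ConfusionTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_perfect_association_equals_n(self):
        stat, _ = chi_squared(ConfusionTable(20, 0, 0, 20))
        assert stat == pytest.approx(40.0)

    def test_matches_scipy_contingency(self, rng):
        for _ in range(100):
            c = random_table(rng)
            obs = np.array([[c.tp, c.fn], [c.fp, c.tn]])
            if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
                continue
            stat, p = chi_squared(c)
            ref = sstats.chi2_contingency(obs, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12, abs=1e-12)

    def test_cross_product_identity(self, rng):
        for _ in range(100):
            c = random_table(rng)
            obs = np.array([[c.tp, c.fn], [c.fp, c.tn]], float)
            if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
                continue
            stat, _ = chi_squared(c)
            num = (c.tp * c.tn - c.fp * c.fn) ** 2 * c.n
            den = ((c.tp + c.fp) * (c.fn + c.tn) * (c.tp + c.fn)
                   * (c.fp + c.tn))
            assert stat == pytest.approx(num / den, rel=1e-10)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionTable(10, 0, 0, 5)) == 1.0

    def test_chance_agreement(self):
        assert cohens_kappa(ConfusionTable(9, 3, 3, 1)) == pytest.approx(0.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(100):
            c = random_table(rng)
            a = [1] * c.tp + [1] * c.fp + [0] * c.fn + [0] * c.tn
            b = [1] * c.tp + [0] * c.fp + [1] * c.fn + [0] * c.tn
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert cohens_kappa(c) == pytest.approx(
                cohen_kappa_score(a, b), rel=1e-10, abs=1e-12)

    def test_kappa_never_exceeds_accuracy(self, rng):
        for _ in range(100):
            c = random_table(rng)
            acc = (c.tp + c.tn) / c.n
            assert cohens_kappa(c) <= acc + 1e-12

    def test_invariant_under_label_swap(self, rng):
        for _ in range(50):
            c = random_table(rng)
            swapped = ConfusionTable(c.tn, c.fn, c.fp, c.tp)
            assert cohens_kappa(c) == pytest.approx(cohens_kappa(swapped),
                                                    abs=1e-12)


class TestIcc:
    def test_identical_measurements(self):
        pairs = [(1, 1), (2, 2), (3, 3), (4.5, 4.5)]
        assert icc_absolute(pairs) == pytest.approx(1.0)

    def test_anti_agreement_nonpositive(self):
        pairs = [(-2, 2), (0, 0), (2, -2), (1, -1)]
        assert icc_absolute(pairs) <= 0.0

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        for _ in range(50):
            n = int(rng.integers(4, 12))
            x = rng.normal(10, 3, n)
            y = x + rng.normal(0, 1.5, n) + rng.normal(0, 0.5)
            df = pd.DataFrame({
                "subject": list(range(n)) * 2,
                "rater": ["a"] * n + ["b"] * n,
                "score": np.concatenate([x, y])})
            ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                     ratings="score")
            sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            icc2 = ref.loc[sel, "ICC"].iloc[0]
            assert icc_absolute(np.column_stack([x, y])) == pytest.approx(
                icc2, rel=1e-8, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute([(1, 1), (2, 2)])


class TestBlandAltman:
    def test_identical(self):
        bias, (lo, hi) = bland_altman([(1, 1), (2, 2), (3, 3)])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_forced_differences(self):
        bias, (lo, hi) = bland_altman([(0, -1), (0, 0), (0, 1)])
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-2.0)
        assert hi == pytest.approx(2.0)


class TestPearson:
    def test_collinear(self):
        r, p = pearson_r([(1, 2), (2, 4), (3, 6), (4, 8)])
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            r, p = pearson_r(np.column_stack([x, y]))
            ref = sstats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_seeded_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(2024)
        rho, n = 0.5, 1000
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r, _ = pearson_r(xy)
        se = (1 - rho ** 2) / np.sqrt(n - 3)
        assert abs(r - rho) < 3 * se


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_pooled(self, rng):
        for _ in range(100):
            nx, ny = rng.integers(3, 20, 2)
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.4, 1.3, ny)
            t, p = t_test_two_sample(x, y)
            ref = sstats.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)


class TestInvariants:
    def test_accuracy_decomposition(self, rng):
        for _ in range(50):
            c = random_table(rng)
            if c.n_pos == 0 or c.n_neg == 0:
                continue
            s = diagnostic_summary(c)
            lhs = s.accuracy
            rhs = (s.sensitivity * c.n_pos + s.specificity * c.n_neg) / c.n
            assert lhs == pytest.approx(rhs, rel=1e-12)
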
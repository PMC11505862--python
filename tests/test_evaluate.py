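"""Evaluation statistics: frozen clinical-arithmetic values and
independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as st

from emgpac import evaluate as ev


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = ev.confusion_metrics(ev.ConfusionTable(14, 14, 0, 0), percent=True)
        assert m == {"Acc": 100.0, "Se": 100.0, "Sp": 100.0}

    def test_one_missed_case(self):
        m = ev.confusion_metrics(ev.ConfusionTable(13, 14, 0, 1), percent=True)
        assert m["Se"] == pytest.approx(92.86, abs=0.01)
        assert m["Sp"] == pytest.approx(100.0)
        assert m["Acc"] == pytest.approx(96.43, abs=0.01)

    def test_coin_flip(self):
        m = ev.confusion_metrics(ev.ConfusionTable(5, 5, 5, 5))
        assert m == {"Acc": 0.5, "Se": 0.5, "Sp": 0.5}

    def test_zero_denominator_flagged_not_nan(self):
        m = ev.confusion_metrics(ev.ConfusionTable(0, 5, 0, 0))
        assert m["Se"] is None
        assert m["Sp"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionTable(-1, 0, 0, 0)


class TestBinomialIntervals:
    def test_wald_13_of_14(self):
        lo, hi = ev.wald_ci(13, 14)
        assert lo == pytest.approx(79.37, abs=0.01)
        assert hi == 100.0  # clipped

    def test_wald_6_of_14(self):
        lo, hi = ev.wald_ci(6, 14)
        assert lo == pytest.approx(16.93, abs=0.01)
        assert hi == pytest.approx(68.78, abs=0.01)

    def test_wald_contains_estimate_and_shrinks(self):
        for n in (10, 100, 10000):
            lo, hi = ev.wald_ci(n // 2, n)
            assert lo <= 50.0 <= hi
        w1 = np.diff(ev.wald_ci(50, 100))
        w2 = np.diff(ev.wald_ci(5000, 10000))
        assert w2 < w1

    def test_clopper_pearson_covers_wald_edge_cases(self):
        lo, hi = ev.clopper_pearson_ci(14, 14)
        assert hi == 100.0 and 0 < lo < 100

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.wald_ci(5, 0)


class TestDiagnosticIndices:
    def test_dor_printed_values(self):
        assert ev.dor(0.7857, 0.8571)["value"] == pytest.approx(21.99, abs=0.01)
        assert ev.dor(0.3571, 0.2857)["value"] == pytest.approx(0.22, abs=0.005)

    def test_dor_chance_level_is_one(self):
        assert ev.dor(0.5, 0.5)["value"] == pytest.approx(1.0)

    def test_dor_perfect_rate_is_infinite_flagged(self):
        out = ev.dor(1.0, 0.8)
        assert out["infinite"] and np.isinf(out["value"])

    def test_dor_symmetry_and_threshold(self, rng):
        for _ in range(20):
            se, sp = rng.uniform(0.05, 0.95, 2)
            assert ev.dor(se, sp)["value"] == pytest.approx(
                ev.dor(sp, se)["value"], rel=1e-12)
            assert (ev.dor(se, sp)["value"] > 1) == (se + sp > 1)

    @pytest.mark.parametrize("se,sp,prev,expect", [
        (0.7857, 0.8571, 0.03, 14.53),
        (0.3571, 0.2857, 0.03, 1.52),
        (0.7857, 0.8571, 0.01, 5.26),
        (0.3571, 0.2857, 0.01, 0.50),
    ])
    def test_unbiased_ppv_printed_values(self, se, sp, prev, expect):
        ppv = ev.unbiased_ppv(se, sp, ev.PrevalenceSpec(prev))
        assert 100 * ppv == pytest.approx(expect, abs=0.005)

    def test_ppv_perfect_specificity(self):
        assert ev.unbiased_ppv(0.6, 1.0, ev.PrevalenceSpec(0.03)) == 1.0

    def test_ppv_undefined_without_positives(self):
        with pytest.raises(ValueError):
            ev.unbiased_ppv(0.0, 1.0, ev.PrevalenceSpec(0.03))

    def test_ppv_monotone_in_prevalence_and_specificity(self):
        ppvs = [ev.unbiased_ppv(0.8, 0.8, ev.PrevalenceSpec(p))
                for p in (0.01, 0.03, 0.1, 0.5)]
        assert all(b > a for a, b in zip(ppvs, ppvs[1:]))
        ppvs = [ev.unbiased_ppv(0.8, sp, ev.PrevalenceSpec(0.03))
                for sp in (0.5, 0.8, 0.95, 0.99)]
        assert all(b > a for a, b in zip(ppvs, ppvs[1:]))

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            ev.PrevalenceSpec(0.0)


class TestMcNemar:
    def test_balanced_discordance_is_null(self):
        a = [True] * 3 + [False] * 3
        b = [False] * 3 + [True] * 3
        assert ev.mcnemar(a, b)["p"] == pytest.approx(1.0)

    def test_one_sided_discordance(self):
        a = [True, True, True, True, True]
        b = [False, False, False, False, True]
        out = ev.mcnemar(a, b)
        assert out["b"] == 4 and out["c"] == 0
        assert out["p"] == pytest.approx(0.125)  # 2 * 0.5^4
        assert out["cohens_g"] == pytest.approx(0.5)

    def test_cohens_g(self):
        a = [True, True, True, False, True]
        b = [False, False, False, True, True]
        out = ev.mcnemar(a, b)
        assert out["b"] == 3 and out["c"] == 1
        assert out["cohens_g"] == pytest.approx(0.25)

    def test_no_discordance_flagged(self):
        out = ev.mcnemar([True, False], [True, False])
        assert out["p"] == 1.0 and out["cohens_g"] is None


class TestFriedman:
    def test_identical_columns_null(self):
        m = np.tile([[1.0], [2.0], [3.0]], (1, 3))
        out = ev.friedman(m)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert out["constant_rows"] == 3

    def test_matches_rank_based_oracle(self, rng):
        """Friedman chi-square vs explicit rank arithmetic (no ties)."""
        for _ in range(10):
            m = rng.normal(size=(6, 3))
            n, k = m.shape
            ranks = np.argsort(np.argsort(m, axis=1), axis=1) + 1.0
            col_sums = ranks.sum(axis=0)
            chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3 * n * (k + 1)
            out = ev.friedman(m)
            assert out["statistic"] == pytest.approx(chi2, rel=1e-9)

    def test_rejects_degenerate_shapes(self):
        with pytest.raises(ValueError):
            ev.friedman(np.zeros((1, 3)))


def exact_one_sided_wilcoxon(d):
    """Enumeration oracle: P(W+ >= observed) over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    ranks = st.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    n = len(d)
    count = sum(1 for signs in itertools.product([0, 1], repeat=n)
                if ranks[np.array(signs, dtype=bool)].sum() >= observed)
    return count / 2**n


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        a = np.array([5.0, 6, 7, 8, 9, 10])
        b = np.zeros(6)
        out = ev.wilcoxon_one_sided(a, b)
        assert out["p"] == pytest.approx(1 / 64)
        assert out["rank_biserial"] == pytest.approx(1.0)

    def test_antisymmetric_differences_zero_effect(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        out = ev.wilcoxon_one_sided(a, np.zeros(6))
        assert out["rank_biserial"] == pytest.approx(0.0)

    def test_exact_p_matches_sign_enumeration(self, rng):
        for n in (5, 8, 10):
            for _ in range(5):
                d = rng.normal(size=n)
                out = ev.wilcoxon_one_sided(d, np.zeros(n))
                assert out["p"] == pytest.approx(exact_one_sided_wilcoxon(d),
                                                 rel=1e-9)

    def test_all_zero_differences_flagged(self):
        out = ev.wilcoxon_one_sided(np.ones(6), np.ones(6))
        assert out["p"] is None and out["rank_biserial"] is None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ev.wilcoxon_one_sided([1.0, 2.0], [0.0, 1.0])


class TestIntervalEstimates:
    def test_identical_probs_zero_width(self):
        lo, hi = ev.mean_prob_ci([0.7] * 10)
        assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)

    def test_half_width_closed_form(self, rng):
        probs = np.clip(rng.normal(0.8, 0.1, 4800), 0, 1)
        lo, hi = ev.mean_prob_ci(probs, level=0.999)
        z = st.norm.ppf(0.9995)
        assert z == pytest.approx(3.2905, abs=1e-4)
        expected_half = z * probs.std(ddof=1) / np.sqrt(4800)
        assert (hi - lo) / 2 == pytest.approx(expected_half, rel=1e-9)
        assert expected_half == pytest.approx(0.00475, abs=0.0005)

    def test_bounds_clipped_to_unit_interval(self):
        lo, hi = ev.mean_prob_ci([0.01, 0.02, 0.985, 0.99, 0.995], level=0.999)
        assert 0.0 <= lo <= hi <= 1.0

    def test_single_probability_rejected(self):
        with pytest.raises(ValueError):
            ev.mean_prob_ci([0.5])

    def test_beta_interval_closed_form_all_successes(self):
        lo, hi = ev.beta_credible_interval(10, 10, level=0.999)
        # posterior Beta(11, 1): CDF(x) = x^11
        assert lo == pytest.approx(0.0005 ** (1 / 11), rel=1e-9)
        assert hi == pytest.approx(0.9995 ** (1 / 11), rel=1e-9)

    def test_beta_interval_mirror_symmetry(self):
        lo0, hi0 = ev.beta_credible_interval(0, 10)
        lo1, hi1 = ev.beta_credible_interval(10, 10)
        assert lo0 == pytest.approx(1 - hi1, rel=1e-9)
        assert hi0 == pytest.approx(1 - lo1, rel=1e-9)

    def test_beta_interval_concentrates_with_n(self):
        widths = [np.diff(ev.beta_credible_interval(k, n))[0]
                  for k, n in ((8, 10), (80, 100), (800, 1000))]
        assert all(b < a for a, b in zip(widths, widths[1:]))


class TestAUCSampleSize:
    def test_study_design_value(self):
        n = ev.auc_sample_size(0.7, 0.95, alpha=0.05, power=0.95,
                               one_sided=True)
        assert n == 13

    def test_weaker_power_needs_no_more_subjects(self):
        assert ev.auc_sample_size(0.7, 0.95, power=0.80) <= 13

    def test_vanishing_effect_diverges(self):
        with pytest.raises(ValueError):
            ev.auc_sample_size(0.7, 0.7005, n_max=500)

    def test_invalid_auc_ordering_rejected(self):
        with pytest.raises(ValueError):
            ev.auc_sample_size(0.95, 0.7)
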
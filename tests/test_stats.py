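"""Wilson interval, exact tests and carrier-burden accounting."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlhpanel.cohort_stats import (
    carrier_burden,
    compare_burden,
    fisher_2x2,
    sensitivity_eval,
    wilcoxon_rank_sum,
    wilson_ci,
)
from hlhpanel.variant_filter import hwe_exact_p


class TestWilson:
    def test_validation_interval(self):
        lo, hi = wilson_ci(72, 74)
        assert round(lo, 3) == 0.907
        assert round(hi, 4) == 0.9926

    def test_closed_form_limits(self):
        assert wilson_ci(0, 10)[0] == pytest.approx(0.0)
        assert wilson_ci(10, 10)[1] == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)

    @pytest.mark.parametrize("k,n", [(1, 10), (7, 74), (50, 100), (99, 100)])
    def test_matches_statsmodels(self, k, n):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        want = sm.proportion_confint(k, n, method="wilson")
        got = wilson_ci(k, n)
        assert got == pytest.approx(want, abs=1e-12)

    @given(st.integers(min_value=0, max_value=50), st.integers(min_value=1, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_interval_contains_point_estimate(self, k, n):
        if k > n:
            return
        lo, hi = wilson_ci(k, n)
        assert lo - 1e-12 <= k / n <= hi + 1e-12

    def test_width_decreases_with_n(self):
        widths = [np.diff(wilson_ci(n // 2, n))[0] for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestSensitivity:
    def test_two_misses_of_74(self):
        truth = {("chr1", i, "G", "A", "s") for i in range(74)}
        called = {t for t in truth if t[1] not in (0, 1)}
        rep = sensitivity_eval(truth, called)
        assert round(rep.sensitivity, 3) == 0.973
        assert round(100 * rep.ci_low, 1) == 90.7

    def test_perfect_recall(self):
        truth = {("chr1", 1, "G", "A", "s")}
        rep = sensitivity_eval(truth, truth)
        assert rep.sensitivity == 1.0 and rep.ci_high == pytest.approx(1.0)

    def test_extra_calls_ignored(self):
        truth = {("chr1", i, "G", "A", "s") for i in range(10)}
        rep = sensitivity_eval(truth, truth | {("chr2", 99, "C", "T", "s")})
        assert rep.sensitivity == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_eval(set(), set())


def fisher_oracle(a, b, c, d):
    """Hypergeometric enumeration with exact rational arithmetic."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        return 1.0
    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = prob(a)
    return float(sum(prob(x) for x in xs if prob(x) <= p_obs))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [([[22, 14], [4, 18]], 0.002), ([[2, 0], [0, 2]], 1 / 3),
         ([[3, 5], [3, 5]], 1.0), ([[0, 0], [0, 0]], 1.0)],
    )
    def test_known_values(self, table, expected):
        assert round(fisher_2x2(table), 3) == round(expected, 3)

    def test_matches_oracle_on_grid(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        got = fisher_2x2([[a, b], [c, d]])
                        want = fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-9), (a, b, c, d)

    @given(st.tuples(*[st.integers(min_value=0, max_value=30)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_transposition_and_swap_invariance(self, t):
        a, b, c, d = t
        p = fisher_2x2([[a, b], [c, d]])
        assert fisher_2x2([[a, c], [b, d]]) == pytest.approx(p)
        assert fisher_2x2([[d, c], [b, a]]) == pytest.approx(p)

    def test_invalid_table(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -1], [0, 0]])


class TestWilcoxon:
    def test_small_exact_enumeration(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(100):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.3, 1, 10)
            exact = wilcoxon_rank_sum(x, y)
            approx = wilcoxon_rank_sum(x, y, exact_max_each=0)
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_matches_scipy_asymptotic_with_ties(self):
        from scipy.stats import mannwhitneyu

        x = [1, 2, 2, 3, 5, 5, 6, 8, 9, 9, 11, 12]
        y = [2, 3, 3, 4, 5, 7, 7, 8, 10, 10, 12, 13]
        got = wilcoxon_rank_sum(x, y, exact_max_each=0)
        want = mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
        assert got == pytest.approx(want, abs=1e-9)


class TestCarrierBurden:
    def _geno(self, data, individuals):
        return pd.DataFrame(data, index=individuals)

    def test_nobody_carries(self):
        geno = self._geno({"v1": [0, 0, 0]}, ["a", "b", "c"])
        rep = carrier_burden(geno, {"v1": "PRF1"})
        assert (rep.n_carriers, rep.carrier_fraction) == (0, 0.0)

    def test_homozygote_counted_in_both_tallies(self):
        geno = self._geno({"v1": [2, 1, 0]}, ["a", "b", "c"])
        rep = carrier_burden(geno, {"v1": "PRF1"})
        assert rep.n_carriers == 2
        assert rep.n_homozygous_carriers == 1

    def test_gene_subset_restriction(self):
        geno = self._geno({"v1": [1, 0], "v2": [0, 1]}, ["a", "b"])
        qual = {"v1": "PRF1", "v2": "LYST"}
        full = carrier_burden(geno, qual)
        fhl = carrier_burden(geno, qual, gene_subset={"PRF1", "UNC13D", "STX11", "STXBP2"})
        assert full.n_carriers == 2
        assert fhl.n_carriers == 1
        assert fhl.per_gene_variants == {"PRF1": 1}

    def test_planted_fraction_recovered(self, genes):
        from hlhpanel.synthetic_data import PopulationSite, SimulationConfig, simulate_population

        # one rare damaging site with q chosen so carrier fraction ~ 0.25
        q = 1 - np.sqrt(1 - 0.25)
        cfg = SimulationConfig(seed=3, pop_n=2000,
                               pop_sites=(PopulationSite("UNC13D", q),))
        counts, geno, variants = simulate_population(genes, cfg)
        rep = carrier_burden(geno, {counts.loc[0, "site"]: "UNC13D"})
        se = np.sqrt(0.25 * 0.75 / 2000)
        assert abs(rep.carrier_fraction - 0.25) < 3 * se


class TestCompareBurden:
    def test_identical_proportions(self):
        df = compare_burden({"PRF1": (5, 50)}, {"PRF1": (50, 500)})
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_oracle(self):
        df = compare_burden({"PRF1": (3, 36)}, {"PRF1": (50, 2504)})
        want = fisher_oracle(3, 33, 50, 2454)
        assert df.loc[0, "p"] == pytest.approx(want, abs=1e-9)

    def test_group_swap_symmetry(self):
        a = compare_burden({"g": (4, 20)}, {"g": (10, 100)}).loc[0, "p"]
        b = compare_burden({"g": (10, 100)}, {"g": (4, 20)}).loc[0, "p"]
        assert a == pytest.approx(b)

    def test_bonferroni_column(self):
        df = compare_burden(
            {"a": (5, 10), "b": (1, 10)}, {"a": (5, 100), "b": (10, 100)}
        )
        assert (df["p_bonferroni"] >= df["p"]).all()
        assert (df["p_bonferroni"] <= 1.0).all()


class TestNullCalibration:
    def test_hwe_and_fisher_type_i_error_conservative(self):
        # exact tests are conservative: rejection rate at alpha = 0.05
        # stays within [0.01, 0.06] under the null
        rng = np.random.default_rng(42)
        n_rep = 2000
        q = 0.3
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
        rej_hwe = 0
        for counts in rng.multinomial(80, probs, size=n_rep):
            if hwe_exact_p(*counts) < 0.05:
                rej_hwe += 1
        assert 0.01 <= rej_hwe / n_rep <= 0.06
        rej_f = 0
        for _ in range(n_rep):
            g1 = rng.binomial(30, 0.2)
            g2 = rng.binomial(30, 0.2)
            if fisher_2x2([[g1, 30 - g1], [g2, 30 - g2]]) < 0.05:
                rej_f += 1
        assert 0.0 <= rej_f / n_rep <= 0.06
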
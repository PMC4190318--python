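"""QC and association tests, each checked against an independent oracle:
exact-enumeration HWE, the textbook chi-square formula, and brute-force
label permutation."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from chfmap import (
    GenotypeMatrix,
    PermConfig,
    QcThresholds,
    allelic_scan,
    allelic_test,
    bonferroni,
    genomic_inflation,
    hwe_exact_p,
    maxT_permutation,
    qc_filter,
)
from chfmap.io_formats import MISSING
from chfmap.qc_gwas import CHI2_DF1_MEDIAN

from conftest import make_marker_map


# ---------------------------------------------------------------- oracles


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration over all het counts with fixed allele
    counts (independent of the package's float recurrence)."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_ref + n_het  # ref-allele count
    weights = {}
    for h in range(0, min(na, 2 * n - na) + 1):
        if (na - h) % 2:
            continue
        hom_r = (na - h) // 2
        hom_a = n - h - hom_r
        if hom_r < 0 or hom_a < 0:
            continue
        weights[h] = Fraction(
            comb(n, hom_r) * comb(n - hom_r, h) * 2**h
        )
    total = sum(weights.values())
    p_obs = Fraction(weights[n_het], total)
    return float(sum(w for w in weights.values() if Fraction(w, total) <= p_obs) / total)


def chi2_formula_oracle(a, b, c, d):
    """Sum (O-E)^2/E over the 2x2 table, computed from expected counts."""
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    obs = [[a, b], [c, d]]
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            chi2 += (obs[i][j] - e) ** 2 / e
    return chi2


def brute_force_maxT(calls, n_cases):
    """Exhaustive max-T over all case subsets, plain Python loops."""
    n, m = calls.shape

    def chi2_one(case_idx, j):
        a = b = c = d = 0
        for i in range(n):
            g = int(calls[i, j])
            if g == MISSING:
                continue
            if i in case_idx:
                a += g
                b += 2 - g
            else:
                c += g
                d += 2 - g
        tot = a + b + c + d
        den = (a + b) * (c + d) * (a + c) * (b + d)
        return 0.0 if den == 0 else tot * (a * d - b * c) ** 2 / den

    combos = [set(cb) for cb in itertools.combinations(range(n), n_cases)]
    obs = [chi2_one(set(range(n_cases)), j) for j in range(m)]
    maxima = [max(chi2_one(cb, j) for j in range(m)) for cb in combos]
    eps = 1e-9
    return [sum(mx >= o - eps for mx in maxima) / len(combos) for o in obs]


# ------------------------------------------------------------------- HWE


class TestHwe:
    @pytest.mark.parametrize(
        "counts",
        [(10, 0, 10), (3, 6, 3), (6, 0, 6), (5, 5, 5), (2, 7, 1), (0, 1, 0), (8, 0, 9)],
    )
    def test_matches_exact_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(17, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 4) == 1.0

    def test_probability_ordering(self):
        # balanced het counts are less extreme than a total het deficit
        assert hwe_exact_p(3, 6, 3) >= hwe_exact_p(6, 0, 6)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @given(
        st_.integers(0, 25), st_.integers(0, 25), st_.integers(0, 25)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_in_unit_interval_and_oracle(self, r, h, a):
        if r + h + a == 0:
            return
        p = hwe_exact_p(r, h, a)
        assert 0 < p <= 1
        assert p == pytest.approx(hwe_enumeration_oracle(r, h, a), rel=1e-9)


# ------------------------------------------------------------- allelic test


class TestAllelicTest:
    def test_complete_separation_five_cases_twelve_controls(self):
        chi2, p = allelic_test(10, 0, 0, 24)
        assert chi2 == pytest.approx(34.0)
        assert f"{p:.1e}" == "5.5e-09"

    def test_identical_frequencies(self):
        assert allelic_test(5, 5, 12, 12) == (0.0, 1.0)

    def test_matches_formula_oracle(self):
        chi2, p = allelic_test(7, 3, 6, 18)
        assert chi2 == pytest.approx(chi2_formula_oracle(7, 3, 6, 18), rel=1e-12)
        # cross-check against the independent library implementation
        res = stats.chi2_contingency([[7, 3], [6, 18]], correction=False)
        assert chi2 == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            allelic_test(-1, 3, 6, 18)

    def test_degenerate_margin(self):
        assert allelic_test(0, 0, 5, 5) == (0.0, 1.0)

    @given(st_.tuples(*[st_.integers(0, 40)] * 4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_orientation_invariance(self, t):
        a, b, c, d = t
        chi2_1, p_1 = allelic_test(a, b, c, d)
        chi2_2, p_2 = allelic_test(b, a, d, c)  # swap ref/alt labels
        assert chi2_1 == pytest.approx(chi2_2)
        assert p_1 == pytest.approx(p_2)

    @given(st_.tuples(*[st_.integers(0, 40)] * 4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_chi2_bounded_by_allele_count(self, t):
        a, b, c, d = t
        chi2, _ = allelic_test(a, b, c, d)
        assert chi2 <= a + b + c + d + 1e-9

    def test_equality_iff_complete_separation(self):
        assert allelic_test(10, 0, 0, 24)[0] == pytest.approx(34)
        assert allelic_test(9, 1, 0, 24)[0] < 34


# ---------------------------------------------------- inflation, bonferroni


class TestInflationBonferroni:
    def test_lambda_definition(self):
        assert genomic_inflation([CHI2_DF1_MEDIAN] * 7) == pytest.approx(1.0)
        assert genomic_inflation([0.4549] * 5) == pytest.approx(1.0, rel=1e-3)

    def test_lambda_133(self):
        assert genomic_inflation([CHI2_DF1_MEDIAN * 1.33] * 9) == pytest.approx(1.33)

    def test_lambda_null_sampling(self):
        rng = np.random.default_rng(0)
        draws = rng.chisquare(1, size=10_000)
        assert 0.95 <= genomic_inflation(draws) <= 1.05

    def test_lambda_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_inflation([])

    def test_bonferroni(self):
        assert bonferroni(1.0, 10) == 1.0
        assert bonferroni(0.001, 50) == pytest.approx(0.05)
        _, p = allelic_test(10, 0, 0, 24)
        assert f"{bonferroni(p, 38_394):.2g}" == "0.00021"


# ------------------------------------------------------------------- QC


class TestQcFilter:
    def build_fixture(self):
        """100 markers, 17 samples: 10 planted call-rate failures, 7 MAF
        failures, 3 HWE failures (het deficit), 80 clean."""
        n, m = 17, 100
        base = np.array([0] * 8 + [1] * 6 + [2] * 3, dtype=np.int8)  # maf 0.35
        calls = np.tile(base[:, None], (1, m))
        for j in range(10):  # call rate 14/17 = 0.82
            calls[:3, j] = MISSING
        for j in range(10, 17):  # (16,1,0): maf 1/34 = 0.029
            calls[:, j] = 0
            calls[16, j] = 1
        hwe_col = np.array([0] * 8 + [2] * 9, dtype=np.int8)  # p = 1.1e-5
        for j in range(17, 20):
            calls[:, j] = hwe_col
        mm = make_marker_map(1000 * (np.arange(m) + 1), chrom="chr1")
        return GenotypeMatrix([f"S{i}" for i in range(n)], calls), mm

    def test_planted_failure_counts(self):
        gm, mm = self.build_fixture()
        th = QcThresholds(min_hwe_p=1e-3)  # 17 samples cannot reach p<1e-5
        gm_f, mm_f, rep = qc_filter(gm, mm, th)
        assert (rep.removed_call_rate, rep.removed_maf, rep.removed_hwe) == (10, 7, 3)
        assert rep.m == 80
        assert gm_f.n_markers == mm_f.n_markers == 80

    def test_marker_at_thresholds_retained(self):
        # 16/17 calls (94%) and maf 0.22: passes both rules
        col = np.array([MISSING] + [0] * 11 + [1] * 3 + [2] * 2, dtype=np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(17)], col[:, None])
        mm = make_marker_map([1000], chrom="chr1")
        _, _, rep = qc_filter(gm, mm)
        assert rep.m == 1

    def test_low_call_rate_removed_first(self):
        # 14/17 calls (82%) and also low MAF: attributed to call rate
        col = np.array([MISSING] * 3 + [0] * 13 + [1], dtype=np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(17)], col[:, None])
        mm = make_marker_map([1000], chrom="chr1")
        _, _, rep = qc_filter(gm, mm)
        assert rep.removed_call_rate == 1
        assert rep.removed_maf == 0
        assert rep.reasons.iloc[0]["reason"] == "call_rate"

    def test_all_markers_removed_is_empty_not_error(self):
        col = np.full(17, 0, dtype=np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(17)], col[:, None])
        mm = make_marker_map([1000], chrom="chr1")
        gm_f, _, rep = qc_filter(gm, mm)
        assert rep.m == 0 and gm_f.n_markers == 0


# ------------------------------------------------------------------ max-T


class TestMaxT:
    def test_exhaustive_matches_brute_force(self):
        calls = np.array(
            [[2, 1, 0], [2, 0, 1], [0, 1, MISSING], [0, 2, 1], [1, 0, 0], [0, 1, 2]],
            dtype=np.int8,
        )
        gm = GenotypeMatrix(list("abcdef"), calls)
        mask = np.array([True, True, False, False, False, False])
        got = maxT_permutation(gm, mask, exhaustive=True)
        want = brute_force_maxT(calls, 2)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_single_marker_four_samples_enumeration(self):
        calls = np.array([[2], [2], [0], [0]], dtype=np.int8)
        gm = GenotypeMatrix(list("abcd"), calls)
        mask = np.array([True, True, False, False])
        got = maxT_permutation(gm, mask, exhaustive=True)
        # only 2 of C(4,2)=6 labelings reach the maximal statistic
        assert got[0] == pytest.approx(2 / 6)

    def test_monomorphic_marker_p_one(self):
        calls = np.array([[0, 2], [0, 2], [0, 0], [0, 0]], dtype=np.int8)
        gm = GenotypeMatrix(list("abcd"), calls)
        mask = np.array([True, True, False, False])
        got = maxT_permutation(gm, mask, exhaustive=True)
        assert got[0] == 1.0

    def test_sampled_close_to_exhaustive(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(7, 4)).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(7)], calls)
        mask = np.zeros(7, dtype=bool)
        mask[:3] = True
        exact = maxT_permutation(gm, mask, exhaustive=True)
        R = 20_000
        sampled = maxT_permutation(gm, mask, PermConfig(n_perm=R, seed=3))
        sd = np.sqrt(exact * (1 - exact) / R) + 1e-12
        assert np.all(np.abs(sampled - exact) <= 3 * sd + 1 / (R + 1))

    def test_p_emp_range_and_monotonicity(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(10)], calls)
        mask = np.zeros(10, dtype=bool)
        mask[:4] = True
        p = maxT_permutation(gm, mask, PermConfig(n_perm=500, seed=0))
        assert np.all(p >= 1 / 501) and np.all(p <= 1.0)
        obs = allelic_scan(gm, make_marker_map(100 * (np.arange(30) + 1), "chr1"), mask)
        order = np.argsort(obs["chi2"].to_numpy())
        assert np.all(np.diff(p[order]) <= 1e-12)  # non-increasing in chi2

    def test_bad_config(self):
        with pytest.raises(ValueError):
            PermConfig(n_perm=0)
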
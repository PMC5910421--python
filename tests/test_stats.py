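"""Exact-test machinery against independent enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cistrans.errors import ConfigurationError
from cistrans.stats import (
    bh_fdr,
    binomial_exact_test,
    binomial_exact_test_vec,
    fisher_ratio_test,
    fisher_ratio_test_vec,
)


def binom_pvalue_oracle(k: int, n: int) -> Fraction:
    """Minimum-likelihood two-sided p at p0=1/2 by exact enumeration."""
    weights = [math.comb(n, i) for i in range(n + 1)]
    wk = weights[k]
    return Fraction(sum(w for w in weights if w <= wk), 2**n)


def fisher_pvalue_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating every table with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    tables = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        tables.append((x, w))
    total = sum(w for _, w in tables)
    w_obs = dict(tables)[a]
    return Fraction(sum(w for _, w in tables if w <= w_obs), total)


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (5, 10, 1.0),  # the mode of a symmetric null
            (2, 10, 0.109375),  # 2*(1+10+45)/1024
            (0, 20, 2 * 0.5**20),
        ],
    )
    def test_reference_values(self, k, n, expected):
        assert binomial_exact_test(k, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small_n(self):
        for n in range(1, 16):
            for k in range(n + 1):
                assert binomial_exact_test(k, n) == pytest.approx(
                    float(binom_pvalue_oracle(k, n)), abs=1e-12
                )

    def test_asymmetric_null_matches_scipy(self):
        p = binomial_exact_test(3, 20, p0=0.3)
        assert p == pytest.approx(sps.binomtest(3, 20, 0.3).pvalue, abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ConfigurationError):
            binomial_exact_test(0, 0)
        with pytest.raises(ConfigurationError):
            binomial_exact_test(5, 3)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 5000), st.data())
    def test_symmetry_and_range(self, n, data):
        k = data.draw(st.integers(0, n))
        p = binomial_exact_test(k, n)
        assert 0.0 <= p <= 1.0
        # allele-label swap cannot change the two-sided p-value
        assert p == pytest.approx(binomial_exact_test(n - k, n), abs=1e-12)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        n = rng.integers(1, 3000, size=200)
        k = rng.integers(0, n + 1)
        pv = binomial_exact_test_vec(k, n)
        for ki, ni, pi in zip(k, n, pv):
            assert pi == pytest.approx(binomial_exact_test(int(ki), int(ni)))

    def test_zero_total_is_nan_in_vector_path(self):
        p = binomial_exact_test_vec(np.array([0, 1]), np.array([0, 2]))
        assert np.isnan(p[0]) and p[1] == pytest.approx(1.0)


class TestFisher:
    def test_homogeneous_table_is_null(self):
        assert fisher_ratio_test((10, 10), (10, 10)) == 1.0

    def test_crossed_table_matches_enumeration(self):
        p = fisher_ratio_test((12, 2), (2, 12))
        assert p == pytest.approx(float(fisher_pvalue_oracle(12, 2, 2, 12)), abs=1e-12)

    def test_zero_margin_is_flagged_convention(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_ratio_test((0, 0), (5, 5)) == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_enumeration_small_tables(self, t):
        a, b, c, d = t
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert fisher_ratio_test((a, b), (c, d)) == pytest.approx(
            float(fisher_pvalue_oracle(a, b, c, d)), abs=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(*[st.integers(1, 2000)] * 4))
    def test_large_table_path_matches_scipy(self, t):
        a, b, c, d = t
        p = fisher_ratio_test_vec(*[np.array([x]) for x in t])[0]
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(ref, abs=1e-8)

    def test_label_swap_symmetry(self):
        # swapping alleles A<->B in both generations leaves p unchanged
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            assert fisher_ratio_test((a, b), (c, d)) == pytest.approx(
                fisher_ratio_test((b, a), (d, c)), abs=1e-10
            )

    def test_exact_and_float_paths_agree_at_seam(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(50, 110, size=4)  # totals straddle ~400
            exact = fisher_ratio_test(tuple(t[:2]), tuple(t[2:]))
            vec = fisher_ratio_test_vec(*[np.array([x]) for x in t])[0]
            assert vec == pytest.approx(exact, abs=1e-9)


class TestBhFdr:
    def test_stepup_reference(self):
        q = bh_fdr(np.array([0.001, 0.02, 0.03, 0.5]))
        assert q == pytest.approx([0.004, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        assert bh_fdr(np.array([1.0, 1.0])).tolist() == [1.0, 1.0]
        assert bh_fdr(np.array([0.07])).tolist() == [0.07]

    def test_nan_propagates_without_affecting_ranks(self):
        q = bh_fdr(np.array([0.001, np.nan, 0.02, 0.03, 0.5]))
        assert np.isnan(q[1])
        assert q[[0, 2, 3, 4]] == pytest.approx([0.004, 0.04, 0.04, 0.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_q_dominates_p_and_matches_statsmodels(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(ref, abs=1e-12)
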
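"""Exact SS/GSS tests: tails, inner maxima, outer minima, DSS proxy."""
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import epiroc as ep
from epiroc.contingency import SINGLE_CELLS
from epiroc.exact import _batch_log_lower, _batch_log_upper


def grid_max_log10(x0, x1, t0, t1, n=10001):
    """Dense-grid oracle for the SS inner maximum (log10 scale).

    Pure two-stage grid search: global step 1e-4, then a fine sweep around
    the coarse argmax so the oracle's own discretisation error is
    negligible relative to the comparison tolerance.
    """
    pis = np.linspace(0.0, 1.0, n)
    vals = _batch_log_lower(x0, t0, pis) + _batch_log_upper(x1, t1, pis)
    j = int(np.argmax(vals))
    fine = np.linspace(pis[max(j - 1, 0)], pis[min(j + 1, n - 1)], 4001)
    fvals = _batch_log_lower(x0, t0, fine) + _batch_log_upper(x1, t1, fine)
    return max(float(vals[j]), float(fvals.max())) / math.log(10.0)


class TestBinomialTails:
    def test_full_support_is_one(self):
        assert ep.log_binom_lower(5, 5, 0.3) == 0.0
        assert ep.log_binom_upper(0, 7, 0.9) == 0.0

    def test_direct_summation_values(self):
        assert ep.log_binom_lower(0, 4, 0.5) == pytest.approx(math.log(1 / 16))
        assert ep.log_binom_upper(4, 4, 0.5) == pytest.approx(math.log(1 / 16))

    def test_monotone_in_pi(self):
        pis = np.linspace(0.01, 0.99, 50)
        lower = [ep.log_binom_lower(3, 10, p) for p in pis]
        upper = [ep.log_binom_upper(3, 10, p) for p in pis]
        assert all(a >= b - 1e-12 for a, b in zip(lower, lower[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(upper, upper[1:]))

    def test_complement_identity(self, rng):
        for _ in range(50):
            t = int(rng.integers(1, 200))
            x = int(rng.integers(0, t))
            pi = float(rng.random())
            total = math.exp(ep.log_binom_lower(x, t, pi)) + \
                math.exp(ep.log_binom_upper(x + 1, t, pi))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_no_underflow_at_large_totals(self):
        # far tail at t = 1e5 stays finite and negative in log space
        val = ep.log_binom_lower(100, 100_000, 0.5)
        assert -1e6 < val < -1e4

    def test_domain_errors(self):
        with pytest.raises(Exception):
            ep.log_binom_lower(5, 4, 0.5)
        with pytest.raises(Exception):
            ep.log_binom_upper(1, 4, 1.5)


class TestSsPointPvalue:
    def test_trivial_full_tails(self):
        assert ep.ss_point_pvalue(4, 0, 4, 9).p_value == 1.0

    def test_single_bernoulli(self):
        res = ep.ss_point_pvalue(0, 1, 1, 1)
        assert res.p_value == pytest.approx(0.25, abs=1e-9)
        assert res.arg_pi[0] == pytest.approx(0.5, abs=1e-6)

    def test_two_of_two(self):
        assert ep.ss_point_pvalue(0, 2, 2, 2).p_value == pytest.approx(1 / 16, abs=1e-9)

    def test_matches_dense_grid_oracle(self, rng):
        worst = 0.0
        for _ in range(300):
            t0 = int(rng.integers(1, 61))
            t1 = int(rng.integers(1, 61))
            x0 = int(rng.integers(0, t0 + 1))
            x1 = int(rng.integers(0, t1 + 1))
            mine = -ep.ss_point_pvalue(x0, x1, t0, t1).log10_p
            worst = max(worst, abs(mine - grid_max_log10(x0, x1, t0, t1)))
        assert worst < 1e-6

    def test_monotonicity_in_counts(self):
        t0 = t1 = 30
        base = ep.ss_point_pvalue(10, 20, t0, t1).p_value
        assert ep.ss_point_pvalue(10, 21, t0, t1).p_value <= base + 1e-12
        assert ep.ss_point_pvalue(11, 20, t0, t1).p_value >= base - 1e-12

    def test_score_consistent_with_pvalue(self, rng):
        for _ in range(30):
            t0, t1 = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            res = ep.ss_point_pvalue(int(rng.integers(0, t0)), int(rng.integers(1, t1)),
                                     t0, t1)
            assert res.p_value == pytest.approx(10 ** (-res.log10_p), rel=1e-9)

    def test_close_to_one_sided_fisher(self, rng):
        """SS vertex p-values track one-sided Fisher exact p-values."""
        ss, fisher = [], []
        for _ in range(1000):
            t0, t1 = int(rng.integers(2, 61)), int(rng.integers(2, 61))
            x0, x1 = int(rng.integers(0, t0 + 1)), int(rng.integers(0, t1 + 1))
            ss.append(ep.ss_point_pvalue(x0, x1, t0, t1).p_value)
            fisher.append(ep.fisher_exact_1sided(x0, x1, t0, t1))
        rho = spearmanr(ss, fisher).statistic
        assert rho > 0.99


class TestGssPointPvalue:
    def test_full_unit_square_gives_one(self):
        region = ep.NullRegion(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        assert ep.gss_point_pvalue(3, 7, 10, 10, region).p_value == 1.0

    def test_diagonal_reduction_identity(self, rng):
        region = ep.diagonal_region()
        for _ in range(200):
            t0, t1 = int(rng.integers(1, 61)), int(rng.integers(1, 61))
            x0, x1 = int(rng.integers(0, t0 + 1)), int(rng.integers(0, t1 + 1))
            gss = ep.gss_point_pvalue(x0, x1, t0, t1, region).log10_p
            ss = ep.ss_point_pvalue(x0, x1, t0, t1).log10_p
            assert gss == pytest.approx(ss, abs=1e-8)

    def test_triangle_region_bernoulli(self):
        res = ep.gss_point_pvalue(0, 1, 1, 1, ep.diagonal_region())
        assert res.p_value == pytest.approx(0.25, abs=1e-9)

    def test_matches_chain_grid_oracle(self, rng):
        """Dense sampling along random region chains reproduces the maximum."""
        for _ in range(50):
            t0, t1 = int(rng.integers(4, 41)), int(rng.integers(4, 41))
            status = np.array([0] * t0 + [1] * t1, dtype=np.int8)
            phen = ep.PhenotypeVector(status)
            g1 = rng.integers(0, 3, t0 + t1).astype(np.int8)
            g2 = rng.integers(0, 3, t0 + t1).astype(np.int8)
            r1 = ep.build_roc(ep.build_single_table(g1, phen))
            r2 = ep.build_roc(ep.build_single_table(g2, phen))
            region = ep.build_null_region(r1, r2)
            x0 = int(rng.integers(0, t0 + 1))
            x1 = int(rng.integers(1, t1 + 1))
            oracle = -np.inf
            for a, b in zip(region.upper_boundary, region.upper_boundary[1:]):
                s = np.linspace(0, 1, 10001)
                p0 = a[0] + (b[0] - a[0]) * s
                p1 = a[1] + (b[1] - a[1]) * s
                vals = _batch_log_lower(x0, t0, p0) + _batch_log_upper(x1, t1, p1)
                j = int(np.argmax(vals))
                fine = np.linspace(s[max(j - 1, 0)], s[min(j + 1, 10000)], 4001)
                fvals = _batch_log_lower(x0, t0, a[0] + (b[0] - a[0]) * fine) \
                    + _batch_log_upper(x1, t1, a[1] + (b[1] - a[1]) * fine)
                oracle = max(oracle, float(vals[j]), float(fvals.max()))
            mine = -ep.gss_point_pvalue(x0, x1, t0, t1, region).log10_p
            assert mine == pytest.approx(oracle / math.log(10.0), abs=1e-6)

    def test_region_maximum_on_chain(self, rng):
        """2-D grid over the region never beats the chain maximum."""
        chain = np.array([[0.0, 0.0], [0.3, 0.6], [1.0, 1.0]])
        region = ep.NullRegion(chain)
        x0, x1, t0, t1 = 5, 25, 30, 30
        best = ep.gss_point_pvalue(x0, x1, t0, t1, region).p_value
        p0g = np.linspace(0, 1, 201)
        p1g = np.linspace(0, 1, 201)
        inside_best = -np.inf
        for p0 in p0g:
            top = region.boundary_value(p0)
            ok = p1g[p1g <= top]
            if len(ok) == 0:
                continue
            vals = _batch_log_lower(x0, t0, np.full(len(ok), p0)) \
                + _batch_log_upper(x1, t1, ok)
            inside_best = max(inside_best, float(vals.max()))
        assert math.exp(inside_best) <= best * (1 + 1e-9)


class TestPSs:
    def test_endpoints_only_excluded(self):
        # diagonal curve: both vertices fail the minimal sens/spec rule
        roc = ep.RocCurve(np.array([[0, 0], [10, 10]]), 10, 10)
        res = ep.p_ss(roc)
        assert res.p_value == 1.0 and res.log10_p == 0.0
        assert res.best_vertex is None

    def test_perfect_separation_4v4(self):
        table = ep.ContingencyTable(np.array([[0, 0, 4], [4, 0, 0]]), SINGLE_CELLS)
        res = ep.p_ss(ep.build_roc(table))
        assert res.p_value == pytest.approx(1 / 256, rel=1e-9)
        assert res.log10_p == pytest.approx(math.log10(256), abs=1e-9)
        assert res.best_vertex == (0, 4)

    def test_min_over_superset_never_larger(self, rng):
        for _ in range(20):
            t0 = t1 = 20
            v_mid = [int(rng.integers(1, 20)), int(rng.integers(1, 20))]
            verts = np.array([[0, 0], v_mid, [20, 20]])
            verts = verts[np.lexsort((verts[:, 1], verts[:, 0]))]
            roc_small = ep.RocCurve(verts, t0, t1)
            extra = np.array([[0, 0], [min(v_mid[0], 10), min(v_mid[1], 15)],
                              v_mid, [20, 20]])
            extra = extra[np.lexsort((extra[:, 1], extra[:, 0]))]
            roc_big = ep.RocCurve(np.unique(extra, axis=0), t0, t1)
            assert ep.p_ss(roc_big).log10_p >= ep.p_ss(roc_small).log10_p - 1e-12


class TestPGssAndDss:
    def xor_setup(self):
        g1 = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=np.int8)
        g2 = np.array([0, 0, 1, 1, 1, 1, 0, 0], dtype=np.int8)
        phen = ep.PhenotypeVector(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        pair = ep.build_roc(ep.build_pair_table(g1, g2, phen))
        r1 = ep.build_roc(ep.build_single_table(g1, phen))
        r2 = ep.build_roc(ep.build_single_table(g2, phen))
        return pair, r1, r2

    def test_pair_equal_to_single_gives_no_gain(self):
        # pair of a SNP with itself: pair curve == single curve, so every
        # vertex lies on the region boundary and the gain is void
        g = np.array([0, 1, 2, 0, 2, 1, 0, 2], dtype=np.int8)
        phen = ep.PhenotypeVector(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        single = ep.build_roc(ep.build_single_table(g, phen))
        pair = ep.build_roc(ep.build_pair_table(g, g, phen))
        region = ep.build_null_region(single, single)
        res = ep.p_gss(pair, region)
        assert 0.25 <= res.p_value <= 1.0

    def test_xor_reduces_to_diagonal(self):
        pair, r1, r2 = self.xor_setup()
        region = ep.build_null_region(r1, r2)
        assert region.kind == "diagonal"
        gss = ep.p_gss(pair, region)
        ss = ep.p_ss(pair)
        assert gss.log10_p == pytest.approx(ss.log10_p, abs=1e-8)
        assert gss.log10_p == pytest.approx(math.log10(256), abs=1e-6)

    def test_xor_dss_score(self):
        pair, r1, r2 = self.xor_setup()
        # marginals are diagonal -> their flt_SS is 0 by the exclusion rule
        assert ep.p_ss(r1).log10_p == 0.0
        assert ep.p_ss(r2).log10_p == 0.0
        assert ep.flt_dss(pair, r1, r2) == pytest.approx(math.log10(256), abs=1e-9)

    def test_self_pair_dss_zero(self):
        g = np.array([0, 1, 2, 0, 2, 1, 0, 2], dtype=np.int8)
        phen = ep.PhenotypeVector(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        single = ep.build_roc(ep.build_single_table(g, phen))
        pair = ep.build_roc(ep.build_pair_table(g, g, phen))
        assert ep.flt_dss(pair, single, single) == pytest.approx(0.0, abs=1e-9)

    def test_constant_partner_dss_zero(self, balanced_phenotype):
        g1 = np.array([0, 1, 2, 0, 2, 1, 0, 2], dtype=np.int8)
        g2 = np.zeros(8, dtype=np.int8)
        pair = ep.build_roc(ep.build_pair_table(g1, g2, balanced_phenotype))
        r1 = ep.build_roc(ep.build_single_table(g1, balanced_phenotype))
        r2 = ep.build_roc(ep.build_single_table(g2, balanced_phenotype))
        assert ep.flt_dss(pair, r1, r2) == pytest.approx(0.0, abs=1e-9)

    def test_gss_never_exceeds_ss(self, rng):
        """The GSS region contains the diagonal, so its p cannot be smaller."""
        for _ in range(50):
            n = 40
            status = np.array([0] * 20 + [1] * 20, dtype=np.int8)
            phen = ep.PhenotypeVector(status)
            g1 = rng.integers(0, 3, n).astype(np.int8)
            g2 = rng.integers(0, 3, n).astype(np.int8)
            pair = ep.build_roc(ep.build_pair_table(g1, g2, phen))
            r1 = ep.build_roc(ep.build_single_table(g1, phen))
            r2 = ep.build_roc(ep.build_single_table(g2, phen))
            region = ep.build_null_region(r1, r2)
            gss = ep.p_gss(pair, region).log10_p
            ss = ep.p_ss(pair).log10_p
            assert gss <= ss + 1e-6


class TestMemoizedKernel:
    def test_single_computation_per_key(self):
        kernel = ep.SsKernel(17, 19)
        kernel(3, 11)
        kernel(3, 11)
        kernel(3, 11)
        assert kernel.computations == 1 and kernel.lookups == 3

    def test_cache_matches_direct(self, rng):
        kernel = ep.SsKernel(23, 29)
        for _ in range(100):
            x0, x1 = int(rng.integers(0, 24)), int(rng.integers(0, 30))
            cached = kernel(x0, x1)
            direct = ep.SsKernel(23, 29)(x0, x1)
            assert cached == direct

    def test_distinct_caches_per_totals(self):
        a = ep.memoized_ss_kernel(100, 100)
        b = ep.memoized_ss_kernel(99, 100)
        assert a is not b
        assert a is ep.memoized_ss_kernel(100, 100)
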
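"""Exact sensitivity-specificity tests for case-control genotype data.

The SS test asks: could the observed sensitivity ``x1/t1`` and specificity
``1 - x0/t0`` of a cumulated genotype-call subset arise by biased sampling
from a population with no segregation power (pi0 = pi1)?  Its p-value is

    P_SS = min over ROC vertices (x0, x1), max over pi in [0, 1] of
           P(Bin(t0, pi) <= x0) * P(Bin(t1, pi) >= x1),

an exact product of binomial tails maximised over the nuisance proportion.
The GSS (gain) test replaces the diagonal null with the convex region H0
spanned by the pair's two single-SNP ROC curves, maximising the same
product over (pi0, pi1) on the region; because the objective increases in
pi1 and decreases in pi0 the maximum is attained on the region's upper
boundary chain, reducing the inner problem to a chain of 1-D maximisations.
DSS, the fast proxy used for primary scanning, is the difference of -log10
SS p-values, pair minus best constituent SNP.

All tail probabilities are evaluated in log space from log-gamma binomial
coefficients, so no underflow occurs for totals into the tens of thousands.
The inner maximisations exploit the objective's unimodality: a coarse grid
bracket followed by bounded scalar minimisation.  Per-totals kernels
memoise the SS inner maximum as a function of the counts (x0, x1), which
makes exhaustive pair scanning tractable.
"""
from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betainc, gammaln, logsumexp

from .defs import ANY, CONTRIBUTING, PROTECTIVE, EpirocError
from .roc import NullRegion, RocCurve, demarcate

_LN10 = math.log(10.0)
_N_GRID = 257
_XATOL = 1e-12


@lru_cache(maxsize=256)
def _log_choose(t: int) -> np.ndarray:
    k = np.arange(t + 1)
    return gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)


_UNDERFLOW = 1e-290


def _logsumexp_lower(x: int, t: int, pis: np.ndarray) -> np.ndarray:
    """Direct log-space summation of the lower tail (slow, never underflows)."""
    k = np.arange(x + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(pis)[:, None]
        lq = np.log1p(-pis)[:, None]
        terms = _log_choose(t)[: x + 1][None, :] + k[None, :] * lp + (t - k)[None, :] * lq
        out = logsumexp(terms, axis=1)
    out = np.where(pis <= 0.0, 0.0, out)           # X = 0 <= x surely
    out = np.where(pis >= 1.0, -np.inf, out)       # X = t > x surely
    return out


def _batch_log_lower(x: int, t: int, pis: np.ndarray) -> np.ndarray:
    """log P(Bin(t, pi) <= x) for an array of pi values (exact, log space).

    Evaluated through the regularized incomplete beta
    (P(X <= x) = I_{1-pi}(t - x, x + 1)); values below the double-precision
    floor are recomputed by direct log-space summation of the tail.
    """
    pis = np.asarray(pis, dtype=float)
    if x >= t:
        return np.zeros(pis.shape)
    v = betainc(t - x, x + 1, 1.0 - np.clip(pis, 0.0, 1.0))
    with np.errstate(divide="ignore"):
        out = np.log(v)
    small = v < _UNDERFLOW
    if small.any():
        out[small] = _logsumexp_lower(x, t, pis[small])
    return np.minimum(out, 0.0)


def _batch_log_upper(x: int, t: int, pis: np.ndarray) -> np.ndarray:
    """log P(Bin(t, pi) >= x); by symmetry the lower tail of t - X."""
    return _batch_log_lower(t - x, t, 1.0 - np.asarray(pis, dtype=float))


def log_binom_lower(x: int, t: int, pi: float) -> float:
    """Natural log of the lower binomial tail sum_{i<=x} C(t,i) pi^i (1-pi)^(t-i)."""
    if not (0 <= x <= t):
        raise EpirocError(f"count {x} outside [0, {t}]")
    if not (0.0 <= pi <= 1.0):
        raise EpirocError(f"probability {pi} outside [0, 1]")
    return float(_batch_log_lower(x, t, np.array([pi]))[0])


def log_binom_upper(x: int, t: int, pi: float) -> float:
    """Natural log of the upper binomial tail sum_{j>=x} C(t,j) pi^j (1-pi)^(t-j)."""
    if not (0 <= x <= t):
        raise EpirocError(f"count {x} outside [0, {t}]")
    if not (0.0 <= pi <= 1.0):
        raise EpirocError(f"probability {pi} outside [0, 1]")
    return float(_batch_log_upper(x, t, np.array([pi]))[0])


def _fused_objective(x0: int, t0: int, x1: int, t1: int):
    """Negated log tail-product as a fast scalar function of one pi.

    Used by the inner maximisers, where it is evaluated a few dozen times
    per count pair.
    """
    neg0 = _fused_half_objective(x0, t0, lower=True)
    neg1 = _fused_half_objective(x1, t1, lower=False)

    def neg(p: float) -> float:
        return neg0(p) + neg1(p)

    return neg


_INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_min(f, lo: float, hi: float, xtol: float = 1e-9) -> float:
    """Golden-section minimiser for a unimodal scalar function."""
    c = hi - _INV_PHI * (hi - lo)
    d = lo + _INV_PHI * (hi - lo)
    fc, fd = f(c), f(d)
    while hi - lo > xtol:
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - _INV_PHI * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + _INV_PHI * (hi - lo)
            fd = f(d)
    return (lo + hi) / 2.0


def _fused_half_objective(x: int, t: int, lower: bool):
    """Negated single log tail as a fast scalar function of pi.

    Scalar incomplete-beta evaluation with a log-space summation fallback
    below the double-precision floor.
    """
    if lower:
        if x >= t:
            return lambda p: 0.0
        c = _log_choose(t)[: x + 1]
        k = np.arange(x + 1)
    else:
        if x <= 0:
            return lambda p: 0.0
        c = _log_choose(t)[x:]
        k = np.arange(x, t + 1)
    r = t - k

    def neg(p: float) -> float:
        if lower:
            v = float(betainc(t - x, x + 1, 1.0 - p))
        else:
            v = float(betainc(x, t - x + 1, p))
        if v >= _UNDERFLOW:
            return -min(math.log(v), 0.0)
        a = c + k * math.log(p) + r * math.log1p(-p)
        am = a.max()
        return -min(am + math.log(np.exp(a - am).sum()), 0.0)

    return neg


@dataclass(frozen=True)
class TestResult:
    """Outcome of an SS/GSS evaluation.

    ``log10_p`` is the filter score (-log10 of the p-value, >= 0);
    ``best_vertex`` the (x0, x1) achieving the outer minimum; ``arg_pi`` the
    nuisance proportions achieving the inner maximum.
    """

    log10_p: float
    p_value: float
    best_vertex: tuple[int, int] | None
    arg_pi: tuple[float, float] | None
    direction: str = ANY


def _result(log_p_nat: float, vertex, arg_pi, direction=ANY) -> TestResult:
    log_p_nat = min(log_p_nat, 0.0)
    return TestResult(
        log10_p=-log_p_nat / _LN10,
        p_value=float(np.exp(log_p_nat)),
        best_vertex=vertex,
        arg_pi=arg_pi,
        direction=direction,
    )


class SsKernel:
    """Memoised inner maximum of the SS test for fixed totals (t0, t1).

    Calling the kernel with cumulated counts ``(x0, x1)`` returns
    ``(log_p_nat, pi_star)``; repeated queries of the same key hit the cache
    (``computations`` counts actual optimisations, ``lookups`` all calls).
    """

    def __init__(self, t0: int, t1: int, n_grid: int = _N_GRID):
        self.t0 = int(t0)
        self.t1 = int(t1)
        self._pi = np.linspace(0.0, 1.0, n_grid)
        self._cdf0 = self._build_table(self.t0, lower=True)
        self._sf1 = self._build_table(self.t1, lower=False)
        self._memo: dict[tuple[int, int], tuple[float, float]] = {}
        self.computations = 0
        self.lookups = 0

    def _build_table(self, t: int, lower: bool) -> np.ndarray:
        k = np.arange(t + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logpmf = (
                _log_choose(t)[None, :]
                + k[None, :] * np.log(self._pi)[:, None]
                + (t - k)[None, :] * np.log1p(-self._pi)[:, None]
            )
        logpmf[0] = -np.inf
        logpmf[0, 0] = 0.0
        logpmf[-1] = -np.inf
        logpmf[-1, t] = 0.0
        if lower:
            table = np.logaddexp.accumulate(logpmf, axis=1)
        else:
            table = np.logaddexp.accumulate(logpmf[:, ::-1], axis=1)[:, ::-1]
        return np.minimum(table, 0.0)

    def __call__(self, x0: int, x1: int) -> tuple[float, float]:
        self.lookups += 1
        key = (int(x0), int(x1))
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        result = self._compute(*key)
        self._memo[key] = result
        self.computations += 1
        return result

    def _compute(self, x0: int, x1: int) -> tuple[float, float]:
        if not (0 <= x0 <= self.t0 and 0 <= x1 <= self.t1):
            raise EpirocError(f"counts ({x0}, {x1}) outside totals ({self.t0}, {self.t1})")
        if x1 == 0:
            return 0.0, 0.0  # P(X1 >= 0) = 1 and pi -> 0 makes the other tail 1
        if x0 == self.t0:
            return 0.0, 1.0
        grid = self._cdf0[:, x0] + self._sf1[:, x1]
        j = int(np.argmax(grid))
        lo = max(self._pi[max(j - 2, 0)], 1e-15)
        hi = min(self._pi[min(j + 2, len(self._pi) - 1)], 1.0 - 1e-15)
        neg = _fused_objective(x0, self.t0, x1, self.t1)
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": _XATOL})
        if -res.fun >= grid[j]:
            best, pi_star = -float(res.fun), float(res.x)
        else:
            best, pi_star = float(grid[j]), float(self._pi[j])
        return min(best, 0.0), pi_star


_KERNEL_CACHE: OrderedDict[tuple[int, int], SsKernel] = OrderedDict()
_KERNEL_CACHE_SIZE = 64


def memoized_ss_kernel(t0: int, t1: int) -> SsKernel:
    """Shared per-totals SS kernel (one cache per distinct ``(t0, t1)``)."""
    key = (int(t0), int(t1))
    kernel = _KERNEL_CACHE.get(key)
    if kernel is None:
        kernel = SsKernel(*key)
        _KERNEL_CACHE[key] = kernel
        while len(_KERNEL_CACHE) > _KERNEL_CACHE_SIZE:
            _KERNEL_CACHE.popitem(last=False)
    else:
        _KERNEL_CACHE.move_to_end(key)
    return kernel


def ss_point_pvalue(x0: int, x1: int, t0: int, t1: int) -> TestResult:
    """Inner SS maximum at a single count pair (no outer minimisation)."""
    log_p, pi = memoized_ss_kernel(t0, t1)(x0, x1)
    return _result(log_p, (int(x0), int(x1)), (pi, pi))


def gss_point_pvalue(x0: int, x1: int, t0: int, t1: int,
                     region: NullRegion, n_coarse: int = 33) -> TestResult:
    """Inner GSS maximum over the null region's upper boundary chain.

    The objective log P(Bin(t0, pi0) <= x0) + log P(Bin(t1, pi1) >= x1)
    increases in pi1 and decreases in pi0, so the region maximum lies on the
    chain; each segment is sampled coarsely and the best segments refined by
    bounded scalar maximisation.
    """
    if not (0 <= x0 <= t0 and 0 <= x1 <= t1):
        raise EpirocError(f"counts ({x0}, {x1}) outside totals ({t0}, {t1})")
    if x1 == 0 or x0 == t0:
        return _result(0.0, (int(x0), int(x1)), (0.0, 0.0) if x1 == 0 else (1.0, 1.0))
    chain = region.upper_boundary
    n_seg = len(chain) - 1
    s_grid = np.linspace(0.0, 1.0, n_coarse)
    # coarse stage: all segments sampled in two batched tail evaluations
    a = chain[:-1]
    b = chain[1:]
    pi0 = (a[:, 0, None] + (b[:, 0] - a[:, 0])[:, None] * s_grid).ravel()
    pi1 = (a[:, 1, None] + (b[:, 1] - a[:, 1])[:, None] * s_grid).ravel()
    vals = (_batch_log_lower(x0, t0, pi0) + _batch_log_upper(x1, t1, pi1)) \
        .reshape(n_seg, n_coarse)
    seg_best = sorted(
        ((float(vals[i, j]), i, float(s_grid[j]))
         for i, j in enumerate(np.argmax(vals, axis=1))),
        reverse=True,
    )

    best_val, best_pi = -np.inf, (0.0, 0.0)
    step = s_grid[1] - s_grid[0]
    neg0 = _fused_half_objective(x0, t0, lower=True)
    neg1 = _fused_half_objective(x1, t1, lower=False)
    # refine the best segment; the runner-up too when it is close enough
    # that grid coarseness could hide the true maximum
    refine = seg_best[:1]
    if len(seg_best) > 1 and seg_best[1][0] > seg_best[0][0] - 1.0:
        refine = seg_best[:2]
    for val, i, s_hat in refine:
        ai, bi = chain[i], chain[i + 1]

        def neg(s: float, ai=ai, bi=bi) -> float:
            p0 = min(max(ai[0] + (bi[0] - ai[0]) * s, 1e-15), 1.0 - 1e-15)
            p1 = min(max(ai[1] + (bi[1] - ai[1]) * s, 1e-15), 1.0 - 1e-15)
            return neg0(p0) + neg1(p1)

        lo, hi = max(s_hat - 2 * step, 0.0), min(s_hat + 2 * step, 1.0)
        cand_s = _golden_min(neg, lo, hi)
        cand_val = -neg(cand_s)
        if cand_val < val:
            cand_val, cand_s = val, s_hat
        if cand_val > best_val:
            best_val = cand_val
            best_pi = (
                float(ai[0] + (bi[0] - ai[0]) * cand_s),
                float(ai[1] + (bi[1] - ai[1]) * cand_s),
            )
    return _result(best_val, (int(x0), int(x1)), best_pi)


def _eligible(vertex, t0: int, t1: int, min_ss: float) -> bool:
    x0, x1 = vertex
    return min(1.0 - x0 / t0, x1 / t1) >= min_ss


def p_ss(roc: RocCurve, min_ss: float = 0.02, kernel: SsKernel | None = None) -> TestResult:
    """SS test of a ROC curve: outer minimum over its vertices.

    Vertices whose sensitivity or specificity falls below ``min_ss`` are
    disregarded (limited-sample-size rule); if none qualifies the result is
    p = 1 with a zero filter score.  Ties in the outer minimum go to the
    first vertex in curve order.
    """
    if kernel is None:
        kernel = memoized_ss_kernel(roc.t0, roc.t1)
    best: tuple[float, tuple[int, int], float] | None = None
    for x0, x1 in roc.vertices:
        if not _eligible((x0, x1), roc.t0, roc.t1, min_ss):
            continue
        log_p, pi = kernel(int(x0), int(x1))
        if best is None or log_p < best[0]:
            best = (log_p, (int(x0), int(x1)), pi)
    if best is None:
        return _result(0.0, None, None)
    return _result(best[0], best[1], (best[2], best[2]))


def p_gss(pair_roc: RocCurve, region: NullRegion, direction: str = ANY,
          min_ss: float = 0.02) -> TestResult:
    """GSS test: outer minimum over (optionally demarcated) pair-ROC vertices.

    ``direction`` restricts the minimum to the contributing or protective
    vertex subset as demarcated by segment slopes; ``ANY`` uses all interior
    vertices passing the ``min_ss`` rule.  An empty candidate set yields
    p = 1.
    """
    t0, t1 = pair_roc.t0, pair_roc.t1
    if direction == ANY:
        indices = range(len(pair_roc.vertices))
    elif direction in (CONTRIBUTING, PROTECTIVE):
        cntr, prtv = demarcate(pair_roc)
        indices = cntr if direction == CONTRIBUTING else prtv
    else:
        raise EpirocError(f"unknown direction {direction!r}")
    best: TestResult | None = None
    for i in indices:
        x0, x1 = pair_roc.vertices[i]
        if not _eligible((x0, x1), t0, t1, min_ss):
            continue
        res = gss_point_pvalue(int(x0), int(x1), t0, t1, region)
        if best is None or res.log10_p > best.log10_p:
            best = res
    if best is None:
        return _result(0.0, None, None, direction)
    return TestResult(best.log10_p, best.p_value, best.best_vertex,
                      best.arg_pi, direction)


def flt_dss(pair_roc: RocCurve, roc1: RocCurve, roc2: RocCurve,
            min_ss: float = 0.02, kernel: SsKernel | None = None) -> float:
    """DSS proxy score: flt_SS(pair) - max(flt_SS(g1), flt_SS(g2)).

    All three curves must come from the same sample subset (same totals);
    the score can be slightly negative in edge cases and is reported as-is.
    """
    for roc in (roc1, roc2):
        if (roc.t0, roc.t1) != (pair_roc.t0, pair_roc.t1):
            raise EpirocError("DSS requires curves from the same sample subset")
    if kernel is None:
        kernel = memoized_ss_kernel(pair_roc.t0, pair_roc.t1)
    pair = p_ss(pair_roc, min_ss, kernel).log10_p
    single = max(p_ss(roc1, min_ss, kernel).log10_p,
                 p_ss(roc2, min_ss, kernel).log10_p)
    return pair - single
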
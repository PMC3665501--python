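"""Conventional association filters used as comparators.

Pearson's X^2 on the 2 x V phenotype-by-genotype table, with p-values from
the chi-square distribution (8 df for pair tables, 2 df for single SNPs),
and the one-sided Fisher exact test on a cumulated 2 x 2 table.  The
chi-square p-value relies on the usual large-sample approximation, which is
questionable for sparse 9-cell tables; the degrees of freedom are kept
fixed at V - 1 regardless of empty columns (which contribute 0 to the
statistic), and the effective df is logged as a diagnostic.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from .defs import EpirocError
from .contingency import ContingencyTable

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)

PAIR_DF = 8
SINGLE_DF = 2


def chi2_statistic(table: ContingencyTable) -> float:
    """Pearson X^2 = sum (n_iv - E_iv)^2 / E_iv with E_iv = t_i * n_:v / n.

    Columns with zero total contribute nothing (their expected counts are
    zero as well); the number of non-empty columns is logged when it falls
    short of V, since the nominal df then overstates the table's support.
    """
    counts = table.counts.astype(float)
    col = counts.sum(axis=0)
    n = col.sum()
    live = col > 0
    if live.sum() < table.n_cells:
        logger.debug(
            "chi2 table has %d empty of %d columns (effective df %d)",
            table.n_cells - int(live.sum()), table.n_cells, int(live.sum()) - 1,
        )
    row = counts.sum(axis=1, keepdims=True)
    expected = row * col[None, :] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (counts - expected) ** 2 / expected
    return float(contrib[:, live].sum())


def chi2_pvalue(x2: float, df: int) -> float:
    """Upper-tail chi-square probability as -log10 p (log-space, no underflow).

    For even df the survival function has the closed form
    ``exp(-x/2) * sum_{i<df/2} (x/2)^i / i!``, evaluated here entirely in
    log space so scores remain finite far into the tail (X^2 well beyond
    10^4).  Odd df falls back to scipy's logsf.
    """
    if x2 < 0:
        raise EpirocError(f"chi-square statistic must be >= 0, got {x2}")
    if df < 1:
        raise EpirocError(f"degrees of freedom must be >= 1, got {df}")
    if df % 2 == 0:
        return float(chi2_neglog10_sf(np.array([x2]), df)[0])
    return float(-chi2_dist.logsf(x2, df) / _LN10)


def chi2_neglog10_sf(x2: np.ndarray, df: int) -> np.ndarray:
    """Vectorised -log10 chi-square survival for even df (used by scans)."""
    if df % 2 != 0 or df < 2:
        raise EpirocError("closed-form survival needs even df >= 2")
    u = np.asarray(x2, dtype=float) / 2.0
    k = np.arange(df // 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = k[None, :] * np.log(u)[:, None] - gammaln(k + 1)[None, :]
    terms[u == 0, :] = np.where(k == 0, 0.0, -np.inf)
    log_sf = -u + logsumexp(terms, axis=1)
    return -log_sf / _LN10


def fisher_exact_1sided(x0: int, x1: int, t0: int, t1: int) -> float:
    """One-sided Fisher exact p for the 2 x 2 table [[x0, t0-x0], [x1, t1-x1]].

    The tested direction is enrichment of the covered subset in cases:
    p = P(X >= x1) for X hypergeometric with population t0 + t1, x0 + x1
    marked, t1 drawn.
    """
    if not (0 <= x0 <= t0 and 0 <= x1 <= t1):
        raise EpirocError(f"counts out of range: ({x0}/{t0}, {x1}/{t1})")
    return float(np.exp(hypergeom.logsf(x1 - 1, t0 + t1, x0 + x1, t1)))
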
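"""Exhaustive univariate and pairwise scans with simultaneous filters.

The scan iterates every unordered SNP pair exactly once, builds the 2 x 9
joint contingency table once per pair, and feeds it to each enabled filter
(chi-square, SS, DSS).  Each filter maintains its own result set — either a
fixed-capacity top-k structure or a Bonferroni threshold — so enabling an
extra filter never changes another filter's output.  A slow second stage
(:func:`gss_stage`) re-evaluates surviving candidates with the exact gain
test, which is too expensive to run on all pairs.

The scan is deterministic: records are ordered by descending score with
ties broken by ascending SNP index pair, and two runs on identical input
produce identical output.
"""
from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import PAIR_DF, SINGLE_DF, chi2_pvalue, chi2_statistic
from .contingency import (ContingencyTable, SINGLE_CELLS, build_pair_table,
                          build_single_table, effect_summary)
from .defs import CASE, CONTRIBUTING, CONTROL, MISSING, PROTECTIVE, \
    DegenerateTableError, EpirocError
from .exact import flt_dss, memoized_ss_kernel, p_gss, p_ss
from .io import GenotypeMatrix, PhenotypeVector
from .roc import build_null_region, build_roc

logger = logging.getLogger(__name__)

TOP_K = "top_k"
BONFERRONI = "bonferroni"

FILTER_CHI2 = "chi2"
FILTER_SS = "ss"
FILTER_DSS = "dss"


@dataclass
class PairRecord:
    """Per-pair scan result (unordered pair, snp1_idx < snp2_idx)."""

    snp1_id: str
    snp1_chr: str
    snp1_pos: int
    snp2_id: str
    snp2_chr: str
    snp2_pos: int
    snp1_idx: int
    snp2_idx: int
    flt_ss: float | None = None
    flt_dss: float | None = None
    flt_gss_cntr: float | None = None
    flt_gss_prtv: float | None = None
    chi2_logp: float | None = None
    odds_ratio: float | None = None
    critical_sens_spec: float | None = None
    direction: str | None = None
    best_calls: str | None = None
    primary: float = 0.0


@dataclass
class UnivariateRecord:
    snp_id: str
    snp_idx: int
    flt_ss: float
    chi2_logp: float


@dataclass
class ScanConfig:
    """Configuration of a pairwise scan.

    ``alpha`` defaults to 1, i.e. the Bonferroni threshold is simply one
    over the number of tested pairs.  ``threshold_log10`` overrides the
    Bonferroni level with an explicit -log10 p threshold (used by the
    power harness to apply an external benchmark's level).
    """

    filters: tuple[str, ...] = (FILTER_CHI2, FILTER_SS, FILTER_DSS)
    top_k: int = 500_000
    threshold_mode: str = TOP_K
    alpha: float = 1.0
    min_ss: float = 0.02
    min_distance: int = 0
    threshold_log10: float | None = None

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise EpirocError("top_k must be >= 1")
        if not (0 < self.alpha <= 1):
            raise EpirocError("alpha must be in (0, 1]")
        unknown = set(self.filters) - {FILTER_CHI2, FILTER_SS, FILTER_DSS}
        if unknown:
            raise EpirocError(f"unknown filters: {sorted(unknown)}")


@dataclass
class ScanResult:
    records: dict[str, list[PairRecord]]
    n_pairs_evaluated: int
    n_snps: int


def bonferroni_threshold(m: int, alpha: float = 1.0) -> tuple[float, float]:
    """Family-wise threshold over all C(m, 2) pairs.

    Returns ``(p_threshold, log10_threshold)`` with
    ``p_threshold = alpha / C(m, 2)``.
    """
    if m < 2:
        raise EpirocError("need at least two SNPs")
    n_pairs = m * (m - 1) // 2
    return alpha / n_pairs, math.log10(n_pairs / alpha)


class _TopK:
    """Fixed-capacity result set: best by (score desc, index pair asc)."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._heap: list[tuple[float, int, int, PairRecord]] = []

    def offer(self, score: float, record: PairRecord) -> None:
        item = (score, -record.snp1_idx, -record.snp2_idx, record)
        if len(self._heap) < self.capacity:
            heapq.heappush(self._heap, item)
        elif item > self._heap[0]:
            heapq.heapreplace(self._heap, item)

    def sorted_records(self) -> list[PairRecord]:
        return [
            rec for *_ , rec in sorted(
                self._heap, key=lambda it: (-it[0], -it[1], -it[2])
            )
        ]


def scan_univariate(
    data: GenotypeMatrix, pheno: PhenotypeVector, config: ScanConfig | None = None
) -> list[UnivariateRecord]:
    """Per-SNP SS and chi-square (2 df) scores, in SNP order."""
    config = config or ScanConfig()
    records: list[UnivariateRecord] = []
    for j in range(data.n_snps):
        snp_id = data.snp_meta["snp_id"].iat[j]
        try:
            table = build_single_table(data.genotypes[j], pheno)
        except DegenerateTableError as exc:
            logger.warning("SNP %s skipped: %s", snp_id, exc)
            continue
        roc = build_roc(table)
        flt = p_ss(roc, config.min_ss).log10_p
        x2 = chi2_statistic(table)
        records.append(
            UnivariateRecord(snp_id, j, flt, chi2_pvalue(x2, SINGLE_DF))
        )
    return records


def _marginal_tables(
    g1: np.ndarray, g2: np.ndarray, status: np.ndarray
) -> tuple[ContingencyTable, ContingencyTable]:
    """Single-SNP tables restricted to the pair's complete-case subset."""
    valid = (g1 != MISSING) & (g2 != MISSING)
    tables = []
    for g in (g1, g2):
        counts = np.zeros((2, 3), dtype=np.int64)
        for row, label in ((0, CONTROL), (1, CASE)):
            sel = valid & (status == label)
            counts[row] = np.bincount(g[sel], minlength=3)[:3]
        tables.append(ContingencyTable(counts, SINGLE_CELLS))
    return tables[0], tables[1]


def _flt_ss_from_counts(n0: list[int], n1: list[int], t0: int, t1: int,
                        kernel, min_ss: float) -> float:
    """SS filter score from 9-cell counts without intermediate objects.

    Mirrors build_roc + p_ss exactly: prevalence sort (float equality is
    exact here because cell totals are small integers), tie merge, cumsum,
    eligibility rule, memoised kernel minimum.
    """
    cells = [(n1[v] / (n0[v] + n1[v]), n0[v], n1[v])
             for v in range(len(n0)) if n0[v] + n1[v] > 0]
    cells.sort(key=lambda c: -c[0])
    best = 0.0  # log p (natural), start at log 1
    x0 = x1 = 0
    i = 0
    n_cells = len(cells)
    while i < n_cells:
        prev = cells[i][0]
        while i < n_cells and cells[i][0] == prev:
            x0 += cells[i][1]
            x1 += cells[i][2]
            i += 1
        if min(1.0 - x0 / t0, x1 / t1) >= min_ss:
            log_p = kernel(x0, x1)[0]
            if log_p < best:
                best = log_p
    return -best / math.log(10.0)


def _scan_pairs_dense(data, pheno, config, sinks, emit):
    """Vectorised pair scan for datasets without missing genotypes."""
    from .baselines import chi2_neglog10_sf

    geno = data.genotypes
    status = pheno.status
    m = data.n_snps
    cases = status == CASE
    controls = ~cases
    t0 = int(controls.sum())
    t1 = int(cases.sum())
    onehot_case = np.stack([(geno[:, cases] == c) for c in range(3)], axis=1)
    onehot_ctrl = np.stack([(geno[:, controls] == c) for c in range(3)], axis=1)
    onehot_case = onehot_case.astype(np.float32)
    onehot_ctrl = onehot_ctrl.astype(np.float32)

    want_chi2 = FILTER_CHI2 in config.filters
    want_ss = FILTER_SS in config.filters or FILTER_DSS in config.filters
    want_dss = FILTER_DSS in config.filters
    kernel = memoized_ss_kernel(t0, t1) if want_ss else None

    single_flt = np.zeros(m)
    if want_dss:
        n0s = onehot_ctrl.sum(axis=2)  # (m, 3)
        n1s = onehot_case.sum(axis=2)
        for j in range(m):
            single_flt[j] = _flt_ss_from_counts(
                [int(v) for v in n0s[j]], [int(v) for v in n1s[j]],
                t0, t1, kernel, config.min_ss,
            )

    meta = data.snp_meta
    chroms = meta["chrom"].to_numpy()
    positions = meta["pos"].to_numpy().astype(np.int64)
    ids = meta["snp_id"].to_numpy()
    n_evaluated = 0
    for i in range(m - 1):
        J = np.arange(i + 1, m)
        if config.min_distance > 0:
            close = (chroms[J] == chroms[i]) & (
                np.abs(positions[J] - positions[i]) < config.min_distance
            )
            J = J[~close]
            if len(J) == 0:
                continue
        # counts[j, c_i, c_j] over cases/controls via one BLAS product each
        cnt1 = (onehot_case[J].reshape(-1, t1) @ onehot_case[i].T)
        cnt0 = (onehot_ctrl[J].reshape(-1, t0) @ onehot_ctrl[i].T)
        cnt1 = cnt1.reshape(len(J), 3, 3).transpose(0, 2, 1).reshape(len(J), 9)
        cnt0 = cnt0.reshape(len(J), 3, 3).transpose(0, 2, 1).reshape(len(J), 9)
        cnt1 = np.round(cnt1).astype(np.int64)
        cnt0 = np.round(cnt0).astype(np.int64)
        n_evaluated += len(J)

        chi2_logp = None
        if want_chi2:
            col = (cnt0 + cnt1).astype(float)
            n = t0 + t1
            e0 = t0 * col / n
            e1 = t1 * col / n
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(col > 0, (cnt0 - e0) ** 2 / e0, 0.0) \
                    + np.where(col > 0, (cnt1 - e1) ** 2 / e1, 0.0)
            x2 = contrib.sum(axis=1)
            chi2_logp = chi2_neglog10_sf(x2, PAIR_DF)

        for jj, j in enumerate(J):
            record = PairRecord(
                snp1_id=ids[i], snp1_chr=str(chroms[i]), snp1_pos=int(positions[i]),
                snp2_id=ids[j], snp2_chr=str(chroms[j]), snp2_pos=int(positions[j]),
                snp1_idx=i, snp2_idx=int(j),
            )
            if want_chi2:
                record.chi2_logp = float(chi2_logp[jj])
            if want_ss:
                record.flt_ss = _flt_ss_from_counts(
                    cnt0[jj].tolist(), cnt1[jj].tolist(), t0, t1,
                    kernel, config.min_ss,
                )
                if want_dss:
                    record.flt_dss = record.flt_ss - max(
                        single_flt[i], single_flt[j]
                    )
            if want_chi2:
                emit(FILTER_CHI2, record.chi2_logp, record)
            if FILTER_SS in config.filters:
                emit(FILTER_SS, record.flt_ss, record)
            if want_dss:
                emit(FILTER_DSS, record.flt_dss, record)
    return n_evaluated


def scan_pairs(
    data: GenotypeMatrix, pheno: PhenotypeVector, config: ScanConfig | None = None,
    progress_every: int = 1_000_000,
) -> ScanResult:
    """Exhaustive scan over all unordered SNP pairs.

    Every pair is evaluated exactly once (optionally skipping pairs closer
    than ``min_distance`` base pairs on the same chromosome); the joint
    table is built once and shared by all enabled filters.  Datasets with
    no missing genotypes take a vectorised path with identical results.
    """
    config = config or ScanConfig()
    m = data.n_snps
    if m < 2:
        raise EpirocError("need at least two SNPs to scan pairs")
    meta = data.snp_meta
    geno = data.genotypes
    status = pheno.status
    snp_missing = (geno == MISSING).any(axis=1)

    if config.threshold_mode == BONFERRONI:
        if config.threshold_log10 is not None:
            log10_thresh = config.threshold_log10
        else:
            _, log10_thresh = bonferroni_threshold(m, config.alpha)
    else:
        log10_thresh = None

    # flt_SS of each SNP on the full sample (reused when the pair has no
    # missing calls, which is the common case).
    full_single_flt: dict[int, float] = {}
    if FILTER_DSS in config.filters:
        for j in range(m):
            try:
                table = build_single_table(geno[j], pheno)
                full_single_flt[j] = p_ss(build_roc(table), config.min_ss).log10_p
            except DegenerateTableError:
                full_single_flt[j] = 0.0

    sinks: dict[str, _TopK | list[PairRecord]] = {}
    for name in config.filters:
        sinks[name] = [] if log10_thresh is not None else _TopK(config.top_k)

    def emit(name: str, score: float, record: PairRecord) -> None:
        record = replace(record, primary=score)
        sink = sinks[name]
        if isinstance(sink, list):
            if score >= log10_thresh:
                sink.append(record)
        else:
            sink.offer(score, record)

    if not snp_missing.any():
        n_evaluated = _scan_pairs_dense(data, pheno, config, sinks, emit)
        records = {}
        for name, sink in sinks.items():
            if isinstance(sink, list):
                records[name] = sorted(
                    sink, key=lambda r: (-r.primary, r.snp1_idx, r.snp2_idx)
                )
            else:
                records[name] = sink.sorted_records()
        return ScanResult(records, n_evaluated, m)

    n_evaluated = 0
    chroms = meta["chrom"].to_numpy()
    positions = meta["pos"].to_numpy()
    ids = meta["snp_id"].to_numpy()
    for i in range(m - 1):
        g1 = geno[i]
        for j in range(i + 1, m):
            if (
                config.min_distance > 0
                and chroms[i] == chroms[j]
                and abs(int(positions[i]) - int(positions[j])) < config.min_distance
            ):
                continue
            g2 = geno[j]
            try:
                table = build_pair_table(g1, g2, pheno)
            except DegenerateTableError as exc:
                logger.warning("pair (%s, %s) skipped: %s", ids[i], ids[j], exc)
                continue
            n_evaluated += 1
            if n_evaluated % progress_every == 0:
                logger.info("evaluated %d pairs", n_evaluated)
            record = PairRecord(
                snp1_id=ids[i], snp1_chr=str(chroms[i]), snp1_pos=int(positions[i]),
                snp2_id=ids[j], snp2_chr=str(chroms[j]), snp2_pos=int(positions[j]),
                snp1_idx=i, snp2_idx=j,
            )
            if FILTER_CHI2 in config.filters:
                record.chi2_logp = chi2_pvalue(chi2_statistic(table), PAIR_DF)
            if FILTER_SS in config.filters or FILTER_DSS in config.filters:
                pair_roc = build_roc(table)
                kernel = memoized_ss_kernel(table.t0, table.t1)
                record.flt_ss = p_ss(pair_roc, config.min_ss, kernel).log10_p
                if FILTER_DSS in config.filters:
                    if snp_missing[i] or snp_missing[j]:
                        tab1, tab2 = _marginal_tables(g1, g2, status)
                        single = max(
                            p_ss(build_roc(tab1), config.min_ss, kernel).log10_p,
                            p_ss(build_roc(tab2), config.min_ss, kernel).log10_p,
                        )
                    else:
                        single = max(full_single_flt[i], full_single_flt[j])
                    record.flt_dss = record.flt_ss - single
            if FILTER_CHI2 in config.filters:
                emit(FILTER_CHI2, record.chi2_logp, record)
            if FILTER_SS in config.filters:
                emit(FILTER_SS, record.flt_ss, record)
            if FILTER_DSS in config.filters:
                emit(FILTER_DSS, record.flt_dss, record)

    records = {}
    for name, sink in sinks.items():
        if isinstance(sink, list):
            records[name] = sorted(
                sink, key=lambda r: (-r.primary, r.snp1_idx, r.snp2_idx)
            )
        else:
            records[name] = sink.sorted_records()
    return ScanResult(records, n_evaluated, m)


def gss_stage(
    candidates: list[PairRecord], data: GenotypeMatrix, pheno: PhenotypeVector,
    config: ScanConfig | None = None,
) -> list[PairRecord]:
    """Exact gain test on surviving candidates (the slow second stage).

    Computes contributing and protective gain scores for each candidate and
    retains those whose larger score reaches the Bonferroni level
    ``log10(C(m, 2) / alpha)``; the achieving genotype-call subset and its
    effect summary are attached to each surviving record.
    """
    config = config or ScanConfig()
    if config.threshold_log10 is not None:
        log10_thresh = config.threshold_log10
    else:
        _, log10_thresh = bonferroni_threshold(data.n_snps, config.alpha)
    geno = data.genotypes
    out: list[PairRecord] = []
    for rec in candidates:
        g1, g2 = geno[rec.snp1_idx], geno[rec.snp2_idx]
        try:
            pair_table = build_pair_table(g1, g2, pheno)
        except DegenerateTableError:
            continue
        tab1, tab2 = _marginal_tables(g1, g2, pheno.status)
        pair_roc = build_roc(pair_table)
        region = build_null_region(build_roc(tab1), build_roc(tab2))
        res_c = p_gss(pair_roc, region, CONTRIBUTING, config.min_ss)
        res_p = p_gss(pair_roc, region, PROTECTIVE, config.min_ss)
        gain = max(res_c.log10_p, res_p.log10_p)
        if gain < log10_thresh:
            continue
        best = res_c if res_c.log10_p >= res_p.log10_p else res_p
        rec = replace(rec, flt_gss_cntr=res_c.log10_p, flt_gss_prtv=res_p.log10_p,
                      primary=gain)
        if best.best_vertex is not None:
            x0, x1 = best.best_vertex
            idx = int(np.where(
                (pair_roc.vertices[:, 0] == x0) & (pair_roc.vertices[:, 1] == x1)
            )[0][0])
            if best.direction == CONTRIBUTING:
                cells = [c for grp in pair_roc.cell_order[:idx] for c in grp]
                eff = effect_summary(x0, x1, pair_roc.t0, pair_roc.t1)
            else:
                cells = [c for grp in pair_roc.cell_order[idx:] for c in grp]
                eff = effect_summary(pair_roc.t0 - x0, pair_roc.t1 - x1,
                                     pair_roc.t0, pair_roc.t1)
            rec.odds_ratio = eff.or_value
            rec.critical_sens_spec = eff.critical
            rec.direction = best.direction
            rec.best_calls = ";".join(str(c) for c in cells)
        out.append(rec)
    out.sort(key=lambda r: (-r.primary, r.snp1_idx, r.snp2_idx))
    return out


def snp_frequency_report(records: list[PairRecord]) -> pd.Series:
    """Number of reported pairs each SNP appears in (sums to 2 x |records|)."""
    counts: dict[str, int] = {}
    for rec in records:
        for snp in (rec.snp1_id, rec.snp2_id):
            counts[snp] = counts.get(snp, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def or_sensspec_report(
    records: list[PairRecord], min_critical: float = 0.02, min_log2_or: float = 1.0
) -> pd.DataFrame:
    """Per-record log2 odds ratio vs critical sens/spec.

    Flags records falling below the minimum coverage (critical sens/spec <
    ``min_critical``) or inside the weak-effect band |log2 OR| <
    ``min_log2_or``.
    """
    rows = []
    for rec in records:
        if rec.odds_ratio is None or rec.critical_sens_spec is None:
            continue
        log2_or = (
            math.log2(rec.odds_ratio) if rec.odds_ratio > 0 else -math.inf
        )
        rows.append({
            "snp1_id": rec.snp1_id,
            "snp2_id": rec.snp2_id,
            "log2_or": log2_or,
            "critical_sens_spec": rec.critical_sens_spec,
            "direction": rec.direction,
            "below_min_critical": rec.critical_sens_spec < min_critical,
            "weak_or": abs(log2_or) < min_log2_or,
        })
    return pd.DataFrame(
        rows, columns=["snp1_id", "snp2_id", "log2_or", "critical_sens_spec",
                       "direction", "below_min_critical", "weak_or"]
    )
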
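"""Phenotype-by-genotype contingency tables and effect summaries.

A 2 x V table counts controls (row 0) and cases (row 1) over the V genotype
cells of one SNP (V = 3) or a SNP pair (V = 9, cells ordered (g1, g2) in
{0,1,2} x {0,1,2} row-major).  Samples with a missing genotype at any
involved SNP are excluded from that table (per-pair complete cases), so the
totals t0, t1 can vary between tables built from the same dataset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .defs import CASE, CONTRIBUTING, CONTROL, MISSING, PROTECTIVE, DegenerateTableError, EpirocError

PAIR_CELLS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(3) for b in range(3)
)
SINGLE_CELLS: tuple[int, ...] = (0, 1, 2)


@dataclass(frozen=True)
class ContingencyTable:
    """2 x V counts ``n_iv`` with row 0 = controls, row 1 = cases.

    Zero-count columns are retained; downstream consumers decide how to
    treat them.
    """

    counts: np.ndarray
    cell_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 2:
            raise EpirocError("contingency counts must have shape (2, V)")
        if counts.shape[1] != len(self.cell_labels):
            raise EpirocError("cell_labels length must match V")
        if (counts < 0).any():
            raise EpirocError("negative counts")
        if self.t0 < 1 or self.t1 < 1:
            raise DegenerateTableError(
                f"table needs at least one control and one case "
                f"(t0={self.t0}, t1={self.t1})"
            )

    @property
    def t0(self) -> int:
        return int(self.counts[0].sum())

    @property
    def t1(self) -> int:
        return int(self.counts[1].sum())

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def build_single_table(genotypes, phenotype) -> ContingencyTable:
    """Tally one SNP's codes against case-control status (V = 3)."""
    g = np.asarray(genotypes)
    status = phenotype.status
    if len(g) != len(status):
        raise EpirocError("genotype and phenotype lengths differ")
    valid = g != MISSING
    if not valid.any():
        raise DegenerateTableError("all genotypes missing")
    counts = np.zeros((2, 3), dtype=np.int64)
    for row, label in ((0, CONTROL), (1, CASE)):
        sel = valid & (status == label)
        counts[row] = np.bincount(g[sel], minlength=3)[:3]
    return ContingencyTable(counts, SINGLE_CELLS)


def build_pair_table(g1, g2, phenotype) -> ContingencyTable:
    """Tally a SNP pair's joint calls against status (V = 9).

    A sample missing at either SNP is excluded.  Marginalising the 9 cells
    over one SNP reproduces the other SNP's single table on the shared
    sample subset.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    status = phenotype.status
    if len(g1) != len(status) or len(g2) != len(status):
        raise EpirocError("genotype and phenotype lengths differ")
    valid = (g1 != MISSING) & (g2 != MISSING)
    if not valid.any():
        raise DegenerateTableError("all joint genotypes missing")
    joint = 3 * g1 + g2
    counts = np.zeros((2, 9), dtype=np.int64)
    for row, label in ((0, CONTROL), (1, CASE)):
        sel = valid & (status == label)
        counts[row] = np.bincount(joint[sel], minlength=9)[:9]
    return ContingencyTable(counts, PAIR_CELLS)


@dataclass(frozen=True)
class EffectSummary:
    """Odds ratio and coverage of a cumulated genotype-call subset.

    ``xi0`` / ``xi1`` are the covered fractions of controls / cases.  The
    *critical sens/spec* is the sensitivity ``xi1`` for a contributing
    subset (OR > 1) and the control-side coverage ``xi0`` for a protective
    one.  Zero-denominator odds ratios are reported as 0 / +inf with the
    ``degenerate`` flag set (no pseudo-counts are added).
    """

    or_value: float
    xi0: float
    xi1: float
    direction: str
    critical: float
    degenerate: bool = False

    @property
    def log2_or(self) -> float:
        if self.or_value == 0.0:
            return -math.inf
        return math.log2(self.or_value)


def effect_summary(x0: int, x1: int, t0: int, t1: int) -> EffectSummary:
    """Summarise the subset covering ``x0`` of ``t0`` controls and ``x1`` of
    ``t1`` cases."""
    if not (0 <= x0 <= t0 and 0 <= x1 <= t1):
        raise EpirocError(f"counts out of range: ({x0}/{t0}, {x1}/{t1})")
    xi0 = x0 / t0
    xi1 = x1 / t1
    degenerate = False
    # odds of being covered among cases / among controls
    if x1 == t1 and x0 == t0:
        or_value, degenerate = math.nan, True
    elif x1 == 0 and x0 == 0:
        or_value, degenerate = math.nan, True
    elif x0 == 0 or x1 == t1:
        or_value, degenerate = math.inf, True
    elif x1 == 0 or x0 == t0:
        or_value, degenerate = 0.0, True
    else:
        or_value = (x1 / (t1 - x1)) / (x0 / (t0 - x0))
    direction = CONTRIBUTING if or_value > 1 else PROTECTIVE
    critical = xi1 if direction == CONTRIBUTING else xi0
    return EffectSummary(or_value, xi0, xi1, direction, critical, degenerate)
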
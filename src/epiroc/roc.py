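"""Prevalence-mapping ROC curves and the pair-specific null region.

Each genotype cell of a contingency table is assigned its sample
prevalence, the fraction of cases among the samples carrying that call.
Cumulating cells in decreasing prevalence order traces a concave piecewise
linear ROC curve in (x0/t0, x1/t1) coordinates (false positive rate vs true
positive rate when "positive" means "case").  A fully populated pair table
with distinct cell prevalences yields a 9-piece curve that dominates the
3-piece curves of the constituent SNPs.

The null region H0 for the gain test is the smallest convex region of the
unit square containing both single-SNP curves; only its concave upper
boundary chain matters because the test objective increases towards the
upper-left corner.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .contingency import ContingencyTable
from .defs import EpirocError

PAIR_SPECIFIC = "pair_specific"
DIAGONAL = "diagonal"


@dataclass(frozen=True)
class RocCurve:
    """Ordered cumulative-count vertices from (0, 0) to (t0, t1).

    ``vertices[i] = (x0, x1)`` are cumulated control/case counts after the
    i-th prevalence-ordered cell group; ``cell_order`` records the groups
    (cells with tied prevalence are merged into one segment, zero-total
    cells are skipped).
    """

    vertices: np.ndarray
    t0: int
    t1: int
    cell_order: tuple = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=np.int64))

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    def fractions(self) -> np.ndarray:
        """Vertices in (x0/t0, x1/t1) coordinates."""
        return self.vertices / np.array([self.t0, self.t1], dtype=float)


def build_roc(table: ContingencyTable) -> RocCurve:
    """Build the prevalence-mapping ROC curve of a contingency table.

    Cells are sorted by decreasing prevalence ``n1v / (n0v + n1v)`` with
    exact rational comparison; equal-prevalence cells merge into a single
    segment and empty cells are skipped, so the resulting polyline is
    concave by construction.
    """
    n0 = table.counts[0]
    n1 = table.counts[1]
    tot = n0 + n1
    live = np.where(tot > 0)[0]
    prev = {v: Fraction(int(n1[v]), int(tot[v])) for v in live}
    order = sorted(live, key=lambda v: (-prev[v], v))

    groups: list[tuple] = []
    verts = [(0, 0)]
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and prev[order[j + 1]] == prev[order[i]]:
            j += 1
        group = tuple(table.cell_labels[v] for v in order[i : j + 1])
        x0, x1 = verts[-1]
        dx0 = int(n0[order[i : j + 1]].sum())
        dx1 = int(n1[order[i : j + 1]].sum())
        verts.append((x0 + dx0, x1 + dx1))
        groups.append(group)
        i = j + 1
    return RocCurve(np.array(verts), table.t0, table.t1, tuple(groups))


def _upper_envelope(curve: RocCurve, xs: np.ndarray) -> np.ndarray:
    """Evaluate the curve's upper envelope at abscissas (fraction scale)."""
    fx = curve.vertices[:, 0] / curve.t0
    fy = curve.vertices[:, 1] / curve.t1
    # vertical segments: keep the highest point at each abscissa
    keep_x, keep_y = [], []
    for x, y in zip(fx, fy):
        if keep_x and x == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], y)
        else:
            keep_x.append(x)
            keep_y.append(y)
    return np.interp(xs, keep_x, keep_y)


def dominates(a: RocCurve, b: RocCurve, tol: float = 1e-12) -> bool:
    """True iff curve ``a`` lies on or above curve ``b`` everywhere.

    Both curves are piecewise linear, so it suffices to compare them at the
    union of their breakpoint abscissas.
    """
    if (a.t0, a.t1) != (b.t0, b.t1):
        raise EpirocError("curves must share totals t0, t1")
    xs = np.union1d(a.vertices[:, 0] / a.t0, b.vertices[:, 0] / b.t0)
    return bool(np.all(_upper_envelope(a, xs) >= _upper_envelope(b, xs) - tol))


def demarcate(roc: RocCurve) -> tuple[list[int], list[int]]:
    """Split interior vertices into contributing / protective subsets.

    An interior vertex belongs to the contributing set when its incoming
    segment has slope >= 1 in fraction coordinates (vertical counts as
    +inf) and to the protective set when its outgoing segment has slope
    <= 1 (horizontal counts as 0).  By concavity every interior vertex lands
    in at least one of the two sets; slope-1 vertices land in both.
    """
    v = roc.vertices
    t0, t1 = roc.t0, roc.t1
    cntr: list[int] = []
    prtv: list[int] = []
    for i in range(1, len(v) - 1):
        din = (v[i] - v[i - 1]).astype(np.int64)
        dout = (v[i + 1] - v[i]).astype(np.int64)
        # slope = (dx1/t1) / (dx0/t0) >= 1  <=>  dx1*t0 >= dx0*t1 (exact)
        if din[1] * t0 >= din[0] * t1:
            cntr.append(i)
        if dout[1] * t0 <= dout[0] * t1:
            prtv.append(i)
    return cntr, prtv


@dataclass(frozen=True)
class NullRegion:
    """Convex null region in (pi0, pi1) population-proportion space.

    ``upper_boundary`` is the concave chain from (0, 0) to (1, 1) bounding
    the region from above; the region is everything in the unit square on or
    below the chain.  ``DIAGONAL`` marks the two-point chain pi0 = pi1 used
    by the plain sensitivity-specificity test.
    """

    upper_boundary: np.ndarray
    kind: str = PAIR_SPECIFIC

    def __post_init__(self) -> None:
        chain = np.asarray(self.upper_boundary, dtype=float)
        object.__setattr__(self, "upper_boundary", chain)

    def boundary_value(self, pi0) -> np.ndarray:
        """Chain height at abscissa(s) ``pi0``."""
        xs = self.upper_boundary[:, 0]
        ys = self.upper_boundary[:, 1]
        keep_x, keep_y = [], []
        for x, y in zip(xs, ys):
            if keep_x and x == keep_x[-1]:
                keep_y[-1] = max(keep_y[-1], y)
            else:
                keep_x.append(x)
                keep_y.append(y)
        return np.interp(pi0, keep_x, keep_y)

    def contains(self, pi0: float, pi1: float, tol: float = 1e-12) -> bool:
        if not (-tol <= pi0 <= 1 + tol and -tol <= pi1 <= 1 + tol):
            return False
        return pi1 <= float(self.boundary_value(pi0)) + tol


def _upper_hull(points: list[tuple[Fraction, Fraction]]) -> list[tuple[Fraction, Fraction]]:
    """Concave upper chain of the convex hull (exact rational arithmetic)."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts
    hull: list[tuple[Fraction, Fraction]] = []
    for p in pts:
        while len(hull) >= 2:
            (ox, oy), (ax, ay) = hull[-2], hull[-1]
            # drop a if o->a->p is not a strict right turn (keeps chain concave)
            if (ax - ox) * (p[1] - oy) - (ay - oy) * (p[0] - ox) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def build_null_region(roc1: RocCurve, roc2: RocCurve) -> NullRegion:
    """Smallest convex region of the unit square containing both curves.

    The returned chain is the concave upper hull of the union of both
    curves' vertices (in fraction coordinates) together with the corners
    (0, 0) and (1, 1); hull arithmetic is exact over rationals.
    """
    if (roc1.t0, roc1.t1) != (roc2.t0, roc2.t1):
        raise EpirocError("curves must share totals t0, t1")
    pts: list[tuple[Fraction, Fraction]] = [
        (Fraction(0), Fraction(0)), (Fraction(1), Fraction(1))
    ]
    for roc in (roc1, roc2):
        for x0, x1 in roc.vertices:
            pts.append((Fraction(int(x0), roc.t0), Fraction(int(x1), roc.t1)))
    hull = _upper_hull(pts)
    if hull[0] != (Fraction(0), Fraction(0)):
        hull.insert(0, (Fraction(0), Fraction(0)))
    if hull[-1] != (Fraction(1), Fraction(1)):
        hull.append((Fraction(1), Fraction(1)))
    chain = np.array([[float(x), float(y)] for x, y in hull])
    kind = DIAGONAL if len(hull) == 2 else PAIR_SPECIFIC
    return NullRegion(chain, kind)


def diagonal_region() -> NullRegion:
    """The sub-diagonal null region pi1 <= pi0 (plain SS test)."""
    return NullRegion(np.array([[0.0, 0.0], [1.0, 1.0]]), DIAGONAL)
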
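"""Synthetic case-control genotype data with known structure.

Generates (a) null SNPs under Hardy-Weinberg equilibrium, independent of
phenotype; (b) embedded two-locus pure-epistasis pairs whose penetrance
tables have exactly constant HWE-weighted marginal penetrances, so neither
SNP shows any univariate association in the population; and (c) single
SNPs with strong genotype relative risks, which reproduce the confounding
phenomenon where a univariately strong SNP hubs the top chi-square pair
list.  A power / false-positive-rate harness scans replicated datasets
with the DSS and chi-square filters at a Bonferroni-style threshold.

Sampling is retrospective (case-control): genotypes are drawn from the
exact conditional cell distributions given disease status implied by the
penetrance table and HWE frequencies, until the case and control quotas
n1, n0 are met.  Disease prevalence is implicit in the penetrance table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defs import EpirocError
from .io import GenotypeMatrix, PhenotypeVector

#: zero-HWE-mean interaction patterns per model family (before centring)
_FAMILY_PATTERNS: dict[str, np.ndarray] = {
    "xor": np.array([1.0, -1.0, 1.0]),
    "threshold": np.array([-1.0, -1.0, 1.0]),
    "dominant": np.array([-1.0, 1.0, 1.0]),
}


def hwe_frequencies(maf: float) -> np.ndarray:
    """Genotype frequencies ((1-q)^2, 2q(1-q), q^2) at minor allele frequency q."""
    if not (0.0 < maf <= 0.5):
        raise EpirocError(f"minor allele frequency {maf} outside (0, 0.5]")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


@dataclass(frozen=True)
class PenetranceModel:
    """3 x 3 disease probabilities P(case | g1, g2) for a two-locus model."""

    table: np.ndarray
    maf1: float
    maf2: float
    label: str

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.shape != (3, 3):
            raise EpirocError("penetrance table must be 3 x 3")
        if (table < 0).any() or (table > 1).any():
            raise EpirocError("penetrances must lie in [0, 1]")

    def marginal_penetrances(self) -> tuple[np.ndarray, np.ndarray]:
        """HWE-weighted penetrance by genotype at each locus."""
        w1 = hwe_frequencies(self.maf1)
        w2 = hwe_frequencies(self.maf2)
        return self.table @ w2, self.table.T @ w1

    def prevalence(self) -> float:
        w1 = hwe_frequencies(self.maf1)
        w2 = hwe_frequencies(self.maf2)
        return float(w1 @ self.table @ w2)


def make_pure_epistasis_model(
    family: str = "xor", maf: float = 0.25, effect_scale: float = 0.1,
    base_penetrance: float = 0.25,
) -> PenetranceModel:
    """Two-locus penetrance model with exactly zero marginal effects.

    The family's 1-D pattern is centred to zero HWE mean and normalised to
    unit maximum; its outer product is added to a constant base penetrance,
    scaled by ``effect_scale`` (the maximum penetrance deviation).  Both
    HWE-weighted marginal penetrances are then constant by construction, so
    the pair carries association only jointly.  ``effect_scale = 0`` gives
    a fully null (constant) table.
    """
    if family not in _FAMILY_PATTERNS:
        raise EpirocError(
            f"unknown family {family!r}; choose from {sorted(_FAMILY_PATTERNS)}"
        )
    if effect_scale < 0:
        raise EpirocError("effect_scale must be >= 0")
    w = hwe_frequencies(maf)
    s = _FAMILY_PATTERNS[family] - float(w @ _FAMILY_PATTERNS[family])
    peak = np.abs(s).max()
    if peak == 0:
        raise EpirocError(f"family {family!r} degenerates at maf {maf}")
    s = s / peak
    table = base_penetrance + effect_scale * np.outer(s, s)
    if (table < 0).any() or (table > 1).any():
        limit = min(base_penetrance, 1 - base_penetrance) / (np.abs(s).max() ** 2)
        raise EpirocError(
            f"effect_scale {effect_scale} infeasible at base penetrance "
            f"{base_penetrance}; feasible range is [0, {limit:.4g}]"
        )
    return PenetranceModel(table, maf, maf, f"{family}(maf={maf}, scale={effect_scale})")


def _snp_meta(m: int, prefix: str = "snp") -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": [f"{prefix}{j:05d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A",
        "a2": "B",
    })


def _resolve_maf_sampler(maf_sampler):
    """Accept a scalar MAF, a (low, high) uniform range, or a callable(rng)."""
    if callable(maf_sampler):
        return maf_sampler
    if np.isscalar(maf_sampler):
        value = float(maf_sampler)
        hwe_frequencies(value)  # validates range
        return lambda rng: value
    low, high = map(float, maf_sampler)
    hwe_frequencies(low)
    hwe_frequencies(high)
    return lambda rng: rng.uniform(low, high)


def _null_genotypes(m: int, n: int, maf_sampler, rng) -> np.ndarray:
    geno = np.empty((m, n), dtype=np.int8)
    for j in range(m):
        maf = maf_sampler(rng)
        probs = hwe_frequencies(maf)
        geno[j] = rng.choice(3, size=n, p=probs)
    return geno


def simulate_null(
    m: int, n0: int, n1: int, maf_sampler=(0.05, 0.5), seed: int = 0
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """``m`` HWE SNPs independent of a balanced-coded phenotype.

    Samples are ordered controls first, then cases.  ``maf_sampler`` may be
    a fixed MAF, a uniform range, or a callable drawing from ``rng``.
    """
    if m < 1 or n0 < 1 or n1 < 1:
        raise EpirocError("need m >= 1 SNPs and at least one case and control")
    rng = np.random.default_rng(seed)
    sampler = _resolve_maf_sampler(maf_sampler)
    geno = _null_genotypes(m, n0 + n1, sampler, rng)
    status = np.concatenate([np.zeros(n0, np.int8), np.ones(n1, np.int8)])
    gm = GenotypeMatrix(geno, _snp_meta(m), [f"s{i}" for i in range(n0 + n1)])
    return gm, PhenotypeVector(status)


def _retrospective_cells(model: PenetranceModel, n0: int, n1: int, rng):
    """Draw joint genotype cells for n0 controls and n1 cases.

    Cell probabilities are the exact conditional distributions
    P(g1, g2 | status) implied by the penetrance table under HWE, which is
    what rejection sampling from the prospective model converges to.
    """
    w = np.outer(hwe_frequencies(model.maf1), hwe_frequencies(model.maf2))
    case_w = (w * model.table).ravel()
    ctrl_w = (w * (1 - model.table)).ravel()
    if case_w.sum() == 0 and n1 > 0:
        raise EpirocError("penetrance is identically zero: no cases can arise")
    if ctrl_w.sum() == 0 and n0 > 0:
        raise EpirocError("penetrance is identically one: no controls can arise")
    ctrl_cells = rng.choice(9, size=n0, p=ctrl_w / ctrl_w.sum())
    case_cells = rng.choice(9, size=n1, p=case_w / case_w.sum())
    cells = np.concatenate([ctrl_cells, case_cells])
    return (cells // 3).astype(np.int8), (cells % 3).astype(np.int8)


def simulate_epistatic(
    model: PenetranceModel, n0: int, n1: int, m_background: int,
    seed: int = 0, maf_sampler=(0.05, 0.5),
) -> tuple[GenotypeMatrix, PhenotypeVector, tuple[int, int]]:
    """Dataset with one embedded epistatic pair among null background SNPs.

    Returns the genotype matrix (``m_background + 2`` SNPs), phenotype
    (controls first) and the indices of the planted pair.  The planted
    positions are drawn from the seeded generator, so different seeds give
    different data but the same seed always gives the same planted indices.
    """
    rng = np.random.default_rng(seed)
    n = n0 + n1
    g1, g2 = _retrospective_cells(model, n0, n1, rng)
    sampler = _resolve_maf_sampler(maf_sampler)
    background = _null_genotypes(m_background, n, sampler, rng)
    m = m_background + 2
    planted = tuple(sorted(rng.choice(m, size=2, replace=False)))
    geno = np.empty((m, n), dtype=np.int8)
    rest = [j for j in range(m) if j not in planted]
    geno[planted[0]] = g1
    geno[planted[1]] = g2
    geno[rest] = background
    status = np.concatenate([np.zeros(n0, np.int8), np.ones(n1, np.int8)])
    gm = GenotypeMatrix(geno, _snp_meta(m), [f"s{i}" for i in range(n)])
    return gm, PhenotypeVector(status), (int(planted[0]), int(planted[1]))


def simulate_main_effect(
    maf: float, genotype_relative_risks, n0: int, n1: int,
    seed: int = 0, base_penetrance: float = 0.1,
) -> np.ndarray:
    """One SNP with specified genotype relative risks, sampled retrospectively.

    Penetrance per genotype is ``base_penetrance * risk_g``; returned codes
    are ordered controls first then cases, matching :func:`simulate_null`.
    """
    risks = np.asarray(genotype_relative_risks, dtype=float)
    if risks.shape != (3,) or (risks < 0).any():
        raise EpirocError("genotype_relative_risks must be three values >= 0")
    pen = base_penetrance * risks
    if (pen > 1).any():
        raise EpirocError("base_penetrance * risks exceeds 1")
    rng = np.random.default_rng(seed)
    w = hwe_frequencies(maf)
    case_w = w * pen
    ctrl_w = w * (1 - pen)
    if case_w.sum() == 0 and n1 > 0:
        raise EpirocError("penetrance identically zero: no cases can arise")
    ctrl = rng.choice(3, size=n0, p=ctrl_w / ctrl_w.sum())
    case = rng.choice(3, size=n1, p=case_w / case_w.sum())
    return np.concatenate([ctrl, case]).astype(np.int8)


@dataclass(frozen=True)
class PowerConfig:
    """One cell of the power experiment grid."""

    family: str
    maf: float
    n0: int
    n1: int
    effect_scale: float
    base_penetrance: float = 0.25


def power_fpr_experiment(
    configs: list[PowerConfig], replicates: int, m: int = 1000,
    filters: tuple[str, ...] = ("dss", "chi2"), seed: int = 0,
    threshold_log10: float | None = None, maf_sampler=(0.05, 0.5),
) -> pd.DataFrame:
    """Power and false-positive rate of the pair filters on planted data.

    For each configuration and replicate a dataset with one planted
    pure-epistasis pair among ``m - 2`` null SNPs is scanned with each
    filter; the planted pair counts as detected when its score passes the
    Bonferroni threshold ``log10(C(m, 2))`` (or an explicit
    ``threshold_log10``), and every other passing pair counts towards the
    false-positive rate.  Per-replicate seeds are ``seed + replicate index``
    so the whole report is reproducible from ``(configs, seed)``.
    """
    from .scan import (BONFERRONI, FILTER_CHI2, FILTER_DSS, ScanConfig,
                       bonferroni_threshold, scan_pairs)

    if replicates < 1:
        raise EpirocError("need at least one replicate")
    name_map = {"dss": FILTER_DSS, "chi2": FILTER_CHI2}
    filt = tuple(name_map[f] for f in filters)
    if threshold_log10 is None:
        _, threshold_log10 = bonferroni_threshold(m)
    rows = []
    for cfg_idx, cfg in enumerate(configs):
        model = make_pure_epistasis_model(
            cfg.family, cfg.maf, cfg.effect_scale, cfg.base_penetrance
        )
        detected = {f: 0 for f in filt}
        false_pos = {f: 0.0 for f in filt}
        for rep in range(replicates):
            rep_seed = (seed + 100_000 * cfg_idx + rep) % (2 ** 31)
            gm, phen, planted = simulate_epistatic(
                model, cfg.n0, cfg.n1, m - 2, rep_seed, maf_sampler
            )
            scan_cfg = ScanConfig(
                filters=filt, threshold_mode=BONFERRONI,
                threshold_log10=threshold_log10,
            )
            result = scan_pairs(gm, phen, scan_cfg)
            n_pairs = result.n_pairs_evaluated
            for f in filt:
                hits = {(r.snp1_idx, r.snp2_idx) for r in result.records[f]}
                if planted in hits:
                    detected[f] += 1
                false_pos[f] += (len(hits) - (planted in hits)) / max(n_pairs - 1, 1)
        for f in filt:
            rows.append({
                "family": cfg.family, "maf": cfg.maf, "n0": cfg.n0,
                "n1": cfg.n1, "effect_scale": cfg.effect_scale,
                "filter": {v: k for k, v in name_map.items()}[f],
                "power": detected[f] / replicates,
                "fpr": false_pos[f] / replicates,
                "replicates": replicates,
                "threshold_log10": threshold_log10,
                "seed": seed,
            })
    return pd.DataFrame(rows)
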
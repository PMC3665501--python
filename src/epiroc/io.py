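"""Case-control genotype I/O.

Reads PLINK 1 text (``.ped``/``.map``) and binary (``.bed``/``.bim``/``.fam``,
SNP-major) file sets into a :class:`GenotypeMatrix` plus
:class:`PhenotypeVector`, and writes scan results as TSV.

Genotype codes count copies of the minor allele (0/1/2), where the minor
allele is determined from the allele frequencies of the loaded data; ties go
to the file's A1 allele.  All downstream statistics are invariant to
relabelling genotype cells, so orientation only affects reporting.

Samples whose phenotype is not case/control (PLINK codes other than 1/2) are
dropped on load with a warning; missing genotypes are kept as
:data:`~epiroc.defs.MISSING` and handled per-pair downstream.
"""
from __future__ import annotations

import logging
import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defs import CASE, CONTROL, MISSING, ParseError, StructuralError

logger = logging.getLogger(__name__)

_LEGAL_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """SNP-by-sample matrix of genotype codes with per-SNP metadata.

    Parameters
    ----------
    genotypes
        ``(n_snps, n_samples)`` integer array with values in
        ``{0, 1, 2, MISSING}`` (minor-allele counts).
    snp_meta
        Data frame with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp),
        ``a1``, ``a2``; one row per SNP, identifiers unique.
    sample_ids
        One identifier per sample column.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        if self.genotypes.ndim != 2:
            raise StructuralError("genotype matrix must be 2-D (SNPs x samples)")
        bad = ~np.isin(self.genotypes, list(_LEGAL_CODES))
        if bad.any():
            raise StructuralError(
                f"illegal genotype codes present: {np.unique(self.genotypes[bad])}"
            )
        if len(self.snp_meta) != self.n_snps:
            raise StructuralError("snp_meta length does not match SNP dimension")
        if len(self.sample_ids) != self.n_samples:
            raise StructuralError("sample_ids length does not match sample dimension")
        if self.snp_meta["snp_id"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise StructuralError(f"duplicate SNP identifiers: {sorted(set(dups))}")


@dataclass
class PhenotypeVector:
    """Binary case-control status per sample (0 = control, 1 = case)."""

    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1:
            raise StructuralError("phenotype must be 1-D")
        if not np.isin(self.status, [CONTROL, CASE]).all():
            raise StructuralError("phenotype values must be 0 (control) or 1 (case)")
        if (self.status == CONTROL).sum() == 0 or (self.status == CASE).sum() == 0:
            raise StructuralError("need at least one case and one control")

    @property
    def n_controls(self) -> int:
        return int((self.status == CONTROL).sum())

    @property
    def n_cases(self) -> int:
        return int((self.status == CASE).sum())

    def __len__(self) -> int:
        return len(self.status)


def _decode_phenotype(raw: str, sample: str, line_no: int) -> int | None:
    # PLINK coding: 1 = unaffected (control), 2 = affected (case),
    # 0 / -9 = missing.
    if raw == "1":
        return CONTROL
    if raw == "2":
        return CASE
    if raw in ("0", "-9", "NA"):
        logger.warning(
            "sample %s (line %d): missing phenotype %r, sample dropped",
            sample, line_no, raw,
        )
        return None
    raise ParseError(f"line {line_no}: unrecognised phenotype code {raw!r}")


def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK ``.map`` file (chrom, id, [cM,] 1-based bp position)."""
    rows = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, snp_id, _cm, pos = fields
            elif len(fields) == 3:
                chrom, snp_id, pos = fields
            else:
                raise ParseError(
                    f"{map_path} line {line_no}: expected 3 or 4 columns, "
                    f"got {len(fields)}"
                )
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(
                    f"{map_path} line {line_no}: bad position {pos!r}"
                ) from exc
            rows.append((chrom, snp_id, pos_i))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])


def _orient_to_minor(
    a1_counts: np.ndarray, meta: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip per-SNP codes so that they count the minor allele.

    ``a1_counts`` counts copies of A1 per call (MISSING preserved).  For each
    SNP the allele frequency of A1 is computed over non-missing calls; when A1
    is the major allele the codes are flipped (2 - code) and the allele labels
    swapped.  Exact ties keep A1.
    """
    codes = a1_counts.copy()
    meta = meta.copy()
    valid = codes != MISSING
    n_called = valid.sum(axis=1)
    a1_copies = np.where(valid, codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a1 = a1_copies / np.maximum(2 * n_called, 1)
    flip = (freq_a1 > 0.5) & (n_called > 0)
    if flip.any():
        rows = np.where(flip)[0]
        sub = codes[rows]
        codes[rows] = np.where(sub == MISSING, MISSING, 2 - sub)
        a1 = meta.loc[rows, "a1"].to_numpy()
        meta.loc[rows, "a1"] = meta.loc[rows, "a2"].to_numpy()
        meta.loc[rows, "a2"] = a1
    return codes, meta


def read_plink_text(ped_path, map_path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a PLINK text file set (``.ped`` + ``.map``)."""
    snp_meta = read_map(map_path)
    m = len(snp_meta)

    sample_ids: list[str] = []
    statuses: list[int] = []
    allele_rows: list[list[str]] = []  # per sample: 2*m allele strings
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2 != 0:
                raise ParseError(
                    f"{ped_path} line {line_no}: malformed row with "
                    f"{len(fields)} fields"
                )
            if (len(fields) - 6) // 2 != m:
                raise StructuralError(
                    f"{ped_path} line {line_no}: {(len(fields) - 6) // 2} SNPs "
                    f"but .map lists {m}"
                )
            sample = f"{fields[0]}:{fields[1]}"
            status = _decode_phenotype(fields[5], sample, line_no)
            if status is None:
                continue
            sample_ids.append(sample)
            statuses.append(status)
            allele_rows.append(fields[6:])

    n = len(sample_ids)
    codes = np.full((m, n), MISSING, dtype=np.int8)
    a1_alleles = [""] * m
    a2_alleles = [""] * m
    for j in range(m):
        # A1 = first non-missing allele encountered in file order.
        seen: list[str] = []
        for row in allele_rows:
            for al in (row[2 * j], row[2 * j + 1]):
                if al != "0" and al not in seen:
                    seen.append(al)
        if len(seen) > 2:
            raise ParseError(
                f"SNP {snp_meta['snp_id'][j]}: more than two alleles {seen}"
            )
        a1 = seen[0] if seen else "0"
        a2 = seen[1] if len(seen) > 1 else "0"
        a1_alleles[j], a2_alleles[j] = a1, a2
        for i, row in enumerate(allele_rows):
            pair = (row[2 * j], row[2 * j + 1])
            if "0" in pair:
                continue  # half-calls also treated as missing
            codes[j, i] = (pair[0] == a1) + (pair[1] == a1)
    meta = snp_meta.assign(a1=a1_alleles, a2=a2_alleles)
    codes, meta = _orient_to_minor(codes, meta)
    return GenotypeMatrix(codes, meta, sample_ids), PhenotypeVector(np.array(statuses))


_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK .bed codes -> copies of A1 (01 = missing).
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink_binary(bed_path, bim_path, fam_path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read a PLINK 1 binary file set (``.bed`` + ``.bim`` + ``.fam``)."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    m = len(bim)
    n_all = len(fam)

    keep: list[int] = []
    statuses: list[int] = []
    sample_ids: list[str] = []
    for i, row in fam.iterrows():
        sample = f"{row.fid}:{row.iid}"
        status = _decode_phenotype(str(row.pheno), sample, i + 1)
        if status is None:
            continue
        keep.append(i)
        statuses.append(status)
        sample_ids.append(sample)

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise StructuralError(f"{bed_path}: missing PLINK .bed magic bytes")
        if header[2:3] != _BED_SNP_MAJOR:
            raise StructuralError(
                f"{bed_path}: only SNP-major mode (0x01) is supported"
            )
        body = fh.read()
    bytes_per_snp = (n_all + 3) // 4
    if len(body) != m * bytes_per_snp:
        raise StructuralError(
            f"{bed_path}: expected {m * bytes_per_snp} data bytes for "
            f"{m} SNPs x {n_all} samples, found {len(body)}"
        )
    raw = np.frombuffer(body, dtype=np.uint8).reshape(m, bytes_per_snp)
    # Unpack 2-bit fields, least-significant pair first.
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(m, -1)[:, :n_all]]
    codes = codes[:, keep]
    meta = bim[["chrom", "snp_id", "pos", "a1", "a2"]].reset_index(drop=True)
    codes, meta = _orient_to_minor(np.ascontiguousarray(codes), meta)
    return GenotypeMatrix(codes, meta, sample_ids), PhenotypeVector(np.array(statuses))


def write_plink_binary(gm: GenotypeMatrix, phen: PhenotypeVector, prefix: str) -> None:
    """Write a PLINK 1 binary file set (used for round trips and exports).

    Codes are written as copies of ``a1``: 2 -> hom A1 (00), 1 -> het (10),
    0 -> hom A2 (11), MISSING -> 01.
    """
    m, n = gm.genotypes.shape
    encode = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        bytes_per_snp = (n + 3) // 4
        for j in range(m):
            row = bytearray(bytes_per_snp)
            for i, code in enumerate(gm.genotypes[j]):
                row[i // 4] |= encode[int(code)] << (2 * (i % 4))
            fh.write(struct.pack(f"{bytes_per_snp}B", *row))
    with open(f"{prefix}.bim", "w") as fh:
        for _, r in gm.snp_meta.iterrows():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")
    with open(f"{prefix}.fam", "w") as fh:
        for sid, status in zip(gm.sample_ids, phen.status):
            fid, _, iid = sid.partition(":")
            fh.write(f"{fid}\t{iid or fid}\t0\t0\t0\t{1 + int(status)}\n")


PAIR_RECORD_COLUMNS = [
    "snp1_id", "snp1_chr", "snp1_pos", "snp2_id", "snp2_chr", "snp2_pos",
    "flt_ss", "flt_dss", "flt_gss_cntr", "flt_gss_prtv", "chi2_logp",
    "odds_ratio", "critical_sens_spec", "direction", "best_calls",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_pair_records(records, path) -> None:
    """Write pair-scan records as TSV.

    Rows are sorted by descending primary score (each record's ``primary``
    attribute), ties broken by ascending (SNP1 index, SNP2 index); floats are
    printed with 6 significant digits.
    """
    ordered = sorted(records, key=lambda r: (-r.primary, r.snp1_idx, r.snp2_idx))
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_RECORD_COLUMNS) + "\n")
        for r in ordered:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in PAIR_RECORD_COLUMNS) + "\n")
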
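"""Readers and writers for the external file formats the pipeline touches.

Four inputs drive a scan: a Refined-IBD style segment table, a genotype VCF
(biallelic SNPs, ALT-dosage semantics), a phased-haplotype VCF (pipe-phased
GT), and a two-column phenotype TSV mapping subject IDs to case/control
status.  Results go out as plain TSV.

Coordinates are 1-based with both endpoints inclusive (VCF / Refined-IBD
convention).  Chromosome labels are compared as strings after stripping a
leading ``chr``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IBDSegment",
    "Phenotype",
    "SNPPanel",
    "PhasedHaplotypes",
    "IBDFileError",
    "normalize_chrom",
    "read_ibd",
    "read_phenotype",
    "read_genotype_vcf",
    "read_phased_vcf",
    "write_scan_tsv",
    "read_scan_tsv",
]

MISSING = -1  # sentinel for missing dosage / allele


class IBDFileError(ValueError):
    """Malformed content in one of the pipeline's input files."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` so '3', 'chr3' and 'Chr3' compare equal."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass(frozen=True)
class IBDSegment:
    """One inferred IBD segment between two samples' haplotypes.

    ``hap1``/``hap2`` are 1-based haplotype slot indices into the phased
    data (1 = first phased allele, 2 = second).  ``lod`` and ``cm_length``
    are carried through from Refined-IBD output but play no role in the
    tests.
    """

    sample1: str
    hap1: int
    sample2: str
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    lod: float | None = None
    cm_length: float | None = None

    def __post_init__(self) -> None:
        if self.hap1 not in (1, 2) or self.hap2 not in (1, 2):
            raise IBDFileError(
                f"haplotype index must be 1 or 2, got ({self.hap1}, {self.hap2})"
            )
        if self.start_bp > self.end_bp:
            raise IBDFileError(
                f"segment start {self.start_bp} > end {self.end_bp}"
            )
        if self.sample1 == self.sample2:
            raise IBDFileError(f"segment pairs sample {self.sample1!r} with itself")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered subject pair as a sorted tuple."""
        return tuple(sorted((self.sample1, self.sample2)))  # type: ignore[return-value]

    def hap_of(self, sample: str) -> int:
        if sample == self.sample1:
            return self.hap1
        if sample == self.sample2:
            return self.hap2
        raise KeyError(f"{sample!r} not a member of this segment")

    def covers(self, pos_bp: int) -> bool:
        return self.start_bp <= pos_bp <= self.end_bp


@dataclass(frozen=True)
class Phenotype:
    """Subject ID -> 'case' / 'control' map."""

    status: Mapping[str, str]

    @property
    def cases(self) -> list[str]:
        return [s for s, v in self.status.items() if v == "case"]

    @property
    def controls(self) -> list[str]:
        return [s for s, v in self.status.items() if v == "control"]

    @property
    def n_case(self) -> int:
        return sum(1 for v in self.status.values() if v == "case")

    @property
    def n_control(self) -> int:
        return sum(1 for v in self.status.values() if v == "control")

    def __contains__(self, subject: str) -> bool:
        return subject in self.status

    def is_case(self, subject: str) -> bool:
        return self.status[subject] == "case"


@dataclass
class SNPPanel:
    """Marker map plus per-subject ALT-allele dosages for one chromosome.

    ``dosages`` is subjects x SNPs with entries in {0, 1, 2} or ``MISSING``
    (-1) for a missing genotype.
    """

    chrom: str
    snp_ids: list[str]
    positions_bp: np.ndarray  # int64, strictly increasing
    subjects: list[str]
    dosages: np.ndarray  # int8, subjects x SNPs

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        m = len(self.positions_bp)
        if len(self.snp_ids) != m or self.dosages.shape != (len(self.subjects), m):
            raise ValueError("inconsistent panel dimensions")
        if m > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise IBDFileError("panel positions are not strictly increasing")

    @property
    def n_snps(self) -> int:
        return len(self.positions_bp)


@dataclass
class PhasedHaplotypes:
    """Phased allele array: subjects x SNPs x 2, entries in {0, 1} or -1."""

    chrom: str
    positions_bp: np.ndarray
    subjects: list[str]
    alleles: np.ndarray  # int8, subjects x SNPs x 2

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.subjects), len(self.positions_bp), 2):
            raise ValueError("inconsistent phased-haplotype dimensions")
        self._subject_index = {s: i for i, s in enumerate(self.subjects)}

    def subject_index(self, subject: str) -> int:
        return self._subject_index[subject]


# ---------------------------------------------------------------------------
# readers


def read_ibd(path: str | os.PathLike) -> list[IBDSegment]:
    """Parse a Refined-IBD style whitespace-delimited segment table.

    Expected column order: sample1, hap1, sample2, hap2, chromosome,
    start bp, end bp, then optionally LOD and cM length.  Exact duplicate
    rows are dropped (with a logged count): concatenations of per-chromosome
    files can repeat segments.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"IBD segment file not found: {path}")
    segments: list[IBDSegment] = []
    seen: set[tuple] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 7:
                raise IBDFileError(
                    f"{path}, line {lineno}: expected >=7 columns, got {len(fields)}"
                )
            try:
                seg = IBDSegment(
                    sample1=fields[0],
                    hap1=int(fields[1]),
                    sample2=fields[2],
                    hap2=int(fields[3]),
                    chrom=normalize_chrom(fields[4]),
                    start_bp=int(fields[5]),
                    end_bp=int(fields[6]),
                    lod=float(fields[7]) if len(fields) > 7 else None,
                    cm_length=float(fields[8]) if len(fields) > 8 else None,
                )
            except (ValueError, IBDFileError) as exc:
                raise IBDFileError(f"{path}, line {lineno}: {exc}") from exc
            key = (seg.sample1, seg.hap1, seg.sample2, seg.hap2, seg.chrom,
                   seg.start_bp, seg.end_bp)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            segments.append(seg)
    if n_dup:
        logger.info("read_ibd: dropped %d exact duplicate segment rows", n_dup)
    return segments


_STATUS_TOKENS = {"case": "case", "1": "case", "control": "control", "0": "control"}


def read_phenotype(path: str | os.PathLike) -> Phenotype:
    """Read the two-column phenotype TSV (header ``id<TAB>status``).

    Status tokens accepted: case/control or 1/0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise IBDFileError(f"{path}: expected columns id, status")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise IBDFileError(f"{path}: duplicate subject IDs: {dups}")
    status: dict[str, str] = {}
    for sid, tok in zip(ids, df.iloc[:, 1].astype(str).str.strip().str.lower()):
        if tok not in _STATUS_TOKENS:
            raise IBDFileError(f"{path}: unknown status token {tok!r} for {sid!r}")
        status[sid] = _STATUS_TOKENS[tok]
    pheno = Phenotype(status)
    logger.info(
        "read_phenotype: %d cases, %d controls", pheno.n_case, pheno.n_control
    )
    return pheno


def _iter_biallelic_snps(vcf):
    """Yield (variant, chrom) for biallelic SNP records, counting skips."""
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        yield var
    if n_skipped:
        logger.info("VCF: skipped %d non-biallelic-SNP records", n_skipped)


def _check_chrom(chroms: set[str], path) -> str:
    if len(chroms) != 1:
        raise IBDFileError(
            f"{path}: expected a single chromosome per VCF, found {sorted(chroms)}"
        )
    return next(iter(chroms))


def read_genotype_vcf(path: str | os.PathLike) -> SNPPanel:
    """Load ALT-allele dosages from a single-chromosome genotype VCF.

    Dosage is the ALT allele count (0/1/2); any missing allele makes the
    genotype missing.  Non-biallelic or non-SNP records are skipped with a
    logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[int] = []
    chroms: set[str] = set()
    rows: list[np.ndarray] = []
    for var in _iter_biallelic_snps(vcf):
        chroms.add(normalize_chrom(var.CHROM))
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        gts = np.array([g[:2] for g in var.genotypes], dtype=np.int16)
        dose = gts.sum(axis=1).astype(np.int8)
        dose[(gts < 0).any(axis=1)] = MISSING
        rows.append(dose)
    if not rows:
        raise IBDFileError(f"{path}: no biallelic SNP records")
    chrom = _check_chrom(chroms, path)
    pos = np.array(positions, dtype=np.int64)
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise IBDFileError(f"{path}: positions are not strictly increasing")
    dosages = np.stack(rows, axis=1)  # subjects x SNPs
    return SNPPanel(chrom, snp_ids, pos, subjects, dosages)


def read_phased_vcf(path: str | os.PathLike) -> PhasedHaplotypes:
    """Load phased alleles from a pipe-phased VCF into subjects x SNPs x 2.

    Any ``/``-separated genotype is rejected: the haplotype tests require
    fully phased input (e.g. Beagle output).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    positions: list[int] = []
    chroms: set[str] = set()
    cols: list[np.ndarray] = []
    for var in _iter_biallelic_snps(vcf):
        chroms.add(normalize_chrom(var.CHROM))
        positions.append(var.POS)
        gts = var.genotypes  # [allele1, allele2, phased_flag]
        col = np.empty((len(subjects), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[1], g[-1]
            if a >= 0 and b >= 0 and not phased:
                raise IBDFileError(
                    f"{path}: unphased genotype at {var.CHROM}:{var.POS} "
                    f"for sample {subjects[i]!r}"
                )
            col[i, 0] = a if a >= 0 else MISSING
            col[i, 1] = b if b >= 0 else MISSING
        cols.append(col)
    if not cols:
        raise IBDFileError(f"{path}: no biallelic SNP records")
    chrom = _check_chrom(chroms, path)
    pos = np.array(positions, dtype=np.int64)
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise IBDFileError(f"{path}: positions are not strictly increasing")
    alleles = np.stack(cols, axis=1)  # subjects x SNPs x 2
    return PhasedHaplotypes(chrom, pos, subjects, alleles)


# ---------------------------------------------------------------------------
# writers


def write_scan_tsv(result, path: str | os.PathLike) -> None:
    """Write a ScanResult (or anything with ``to_frame()``) as TSV."""
    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    frame.to_csv(path, sep="\t", index=False)


def read_scan_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a scan TSV written by :func:`write_scan_tsv`."""
    return pd.read_csv(path, sep="\t")
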
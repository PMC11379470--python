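"""Pair roster and the sparse binary pair x SNP IBD indicator matrix.

Rows are unordered subject pairs, columns are the panel's SNPs; an entry is
1 iff some IBD segment for that pair spans the SNP position (endpoints
inclusive).  Case-case pairs form the "case group", control-control pairs
the "control group"; discordant (case-control) pairs are kept in the roster
but excluded from both test groups.  Pairs that never appear in a segment
are implicit all-zero rows: group totals are C(n, 2) over phenotyped
subjects, not the stored row count, because IBD frequency is relative to
all possible pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse

from .io_formats import IBDSegment, Phenotype, SNPPanel, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "CASE_PAIR",
    "CONTROL_PAIR",
    "DISCORDANT",
    "PairSet",
    "IBDMatrix",
    "CountProfile",
    "build_pairs",
    "build_ibd_matrix",
    "count_profile",
    "segment_tracks",
]

CASE_PAIR = 1
CONTROL_PAIR = 2
DISCORDANT = 0


def _pair_group(phenotype: Phenotype, a: str, b: str) -> int:
    ca, cb = phenotype.is_case(a), phenotype.is_case(b)
    if ca and cb:
        return CASE_PAIR
    if not ca and not cb:
        return CONTROL_PAIR
    return DISCORDANT


@dataclass
class PairSet:
    """Ordered roster of unordered subject pairs with group labels."""

    pairs: list[tuple[str, str]]
    groups: np.ndarray  # int8 per pair: CASE_PAIR / CONTROL_PAIR / DISCORDANT
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=np.int8)
        self._index = {p: i for i, p in enumerate(self.pairs)}
        if len(self._index) != len(self.pairs):
            raise ValueError("duplicate unordered pair in PairSet")

    @property
    def t_case(self) -> int:
        """Total possible case-case pairs, C(n_case, 2)."""
        return comb(self.n_case, 2)

    @property
    def t_cont(self) -> int:
        """Total possible control-control pairs, C(n_control, 2)."""
        return comb(self.n_control, 2)

    def index_of(self, pair: tuple[str, str]) -> int:
        return self._index[pair]


def build_pairs(phenotype: Phenotype, segments: list[IBDSegment]) -> PairSet:
    """Collect the unordered subject pairs observed in segments.

    Segments naming an unphenotyped subject are dropped with a warning.
    Requires at least 2 cases and 2 controls so both groups are testable.
    """
    if phenotype.n_case < 2 or phenotype.n_control < 2:
        raise ValueError(
            f"need >=2 cases and >=2 controls, got {phenotype.n_case} cases "
            f"and {phenotype.n_control} controls"
        )
    pairs: list[tuple[str, str]] = []
    groups: list[int] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    for seg in segments:
        if seg.sample1 not in phenotype or seg.sample2 not in phenotype:
            n_dropped += 1
            continue
        p = seg.pair
        if p in seen:
            continue
        seen.add(p)
        pairs.append(p)
        groups.append(_pair_group(phenotype, *p))
    if n_dropped:
        logger.warning(
            "build_pairs: dropped %d segments naming unphenotyped subjects",
            n_dropped,
        )
    return PairSet(pairs, np.array(groups, dtype=np.int8),
                   phenotype.n_case, phenotype.n_control)


@dataclass
class IBDMatrix:
    """Sparse binary pair x SNP indicator matrix with segment provenance.

    Only pairs with at least one segment on the panel's chromosome get a
    stored row; ``provenance[i]`` lists the segments behind row i so the
    haplotype stage can recover which physical haplotype was shared.
    """

    data: sparse.csr_matrix  # rows x SNPs, uint8
    row_pairs: list[tuple[str, str]]
    row_groups: np.ndarray  # int8
    provenance: list[list[IBDSegment]]
    panel: SNPPanel
    pairs: PairSet

    def __post_init__(self) -> None:
        self.row_groups = np.asarray(self.row_groups, dtype=np.int8)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]


def build_ibd_matrix(
    segments: list[IBDSegment], panel: SNPPanel, pairs: PairSet
) -> IBDMatrix:
    """OR-combine each pair's segments into one binary row over panel SNPs.

    Segments on other chromosomes, or for pairs absent from the roster
    (e.g. unphenotyped members), are skipped with a logged count.
    """
    chrom = normalize_chrom(panel.chrom)
    pos = panel.positions_bp
    m = panel.n_snps
    row_of: dict[tuple[str, str], int] = {}
    row_pairs: list[tuple[str, str]] = []
    provenance: list[list[IBDSegment]] = []
    rows_idx: list[int] = []
    cols_idx: list[int] = []
    n_skipped = 0
    for seg in segments:
        if normalize_chrom(seg.chrom) != chrom or seg.pair not in pairs._index:
            n_skipped += 1
            continue
        p = seg.pair
        if p not in row_of:
            row_of[p] = len(row_pairs)
            row_pairs.append(p)
            provenance.append([])
        r = row_of[p]
        provenance[r].append(seg)
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        if hi > lo:
            rows_idx.extend([r] * (hi - lo))
            cols_idx.extend(range(lo, hi))
    if n_skipped:
        logger.info(
            "build_ibd_matrix: skipped %d segments (other chromosome or "
            "unrostered pair)", n_skipped,
        )
    n_rows = len(row_pairs)
    data = sparse.csr_matrix(
        (np.ones(len(rows_idx), dtype=np.uint8), (rows_idx, cols_idx)),
        shape=(n_rows, m),
    )
    data.data[:] = 1  # duplicate (row, col) entries summed by COO->CSR: clamp
    row_groups = np.array([pairs.groups[pairs.index_of(p)] for p in row_pairs],
                          dtype=np.int8)
    return IBDMatrix(data, row_pairs, row_groups, provenance, panel, pairs)


@dataclass
class CountProfile:
    """Per-SNP counts of IBD pairs within each concordant group."""

    i_case: np.ndarray  # int64 per SNP
    i_cont: np.ndarray
    t_case: int
    t_cont: int


def _group_counts(data: sparse.spmatrix, row_groups: np.ndarray):
    case_rows = np.flatnonzero(row_groups == CASE_PAIR)
    cont_rows = np.flatnonzero(row_groups == CONTROL_PAIR)
    m = data.shape[1]
    i_case = (np.asarray(data[case_rows].sum(axis=0)).ravel().astype(np.int64)
              if len(case_rows) else np.zeros(m, dtype=np.int64))
    i_cont = (np.asarray(data[cont_rows].sum(axis=0)).ravel().astype(np.int64)
              if len(cont_rows) else np.zeros(m, dtype=np.int64))
    return i_case, i_cont


def count_profile(matrix: IBDMatrix, pairs: PairSet | None = None) -> CountProfile:
    """Column sums of the indicator matrix within the two concordant groups."""
    pairs = pairs if pairs is not None else matrix.pairs
    i_case, i_cont = _group_counts(matrix.data, matrix.row_groups)
    return CountProfile(i_case, i_cont, pairs.t_case, pairs.t_cont)


def segment_tracks(
    segments: list[IBDSegment],
    chrom: str,
    start_bp: int,
    end_bp: int,
    pairs: PairSet,
) -> pd.DataFrame:
    """Clip segments to a region for profile plots; nested/overlapping
    segments are returned unmerged, one row each, tagged by pair group."""
    chrom = normalize_chrom(chrom)
    rows = []
    if end_bp >= start_bp:
        for seg in segments:
            if normalize_chrom(seg.chrom) != chrom or seg.pair not in pairs._index:
                continue
            if seg.end_bp < start_bp or seg.start_bp > end_bp:
                continue
            group = pairs.groups[pairs.index_of(seg.pair)]
            rows.append(
                {
                    "sample1": seg.sample1,
                    "hap1": seg.hap1,
                    "sample2": seg.sample2,
                    "hap2": seg.hap2,
                    "group": {CASE_PAIR: "case", CONTROL_PAIR: "control",
                              DISCORDANT: "discordant"}[int(group)],
                    "start_bp": max(seg.start_bp, start_bp),
                    "end_bp": min(seg.end_bp, end_bp),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample1", "hap1", "sample2", "hap2", "group",
                 "start_bp", "end_bp"],
    )
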
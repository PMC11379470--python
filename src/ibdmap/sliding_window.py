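"""Rolling-window AND-reduction of the IBD matrix and its permutation test.

A pair is "window-IBD" at anchor j iff its indicator row is 1 at every SNP
j..j+w-1; a matrix with m SNPs yields m-w+1 window columns.  Windows are
SNP-count based, anchored (and reported) at the position of their first
SNP, so w=1 is exactly the per-SNP matrix.  The reduction runs on the
sparse row structure: a run of L consecutive ones contributes L-w+1 window
hits, which equals the dense all-of-w definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .association import ScanResult, fisher_2x2, permuted_d, _odds_ratio
from .io_formats import Phenotype
from .pair_matrix import IBDMatrix, PairSet, _group_counts

__all__ = ["WindowMatrix", "window_matrix", "window_scan"]


@dataclass
class WindowMatrix:
    """AND-reduced indicator matrix over sliding windows of w SNPs."""

    data: sparse.csr_matrix  # rows x (m - w + 1), uint8
    w: int
    source: IBDMatrix

    @property
    def n_windows(self) -> int:
        return self.data.shape[1]

    @property
    def row_pairs(self):
        return self.source.row_pairs

    @property
    def row_groups(self):
        return self.source.row_groups

    def window_snps(self, j: int) -> slice:
        """Panel SNP index range covered by window anchor j."""
        return slice(j, j + self.w)


def _reduce_row(cols: np.ndarray, w: int) -> np.ndarray:
    """Window anchors fully covered by runs of consecutive column indices."""
    if len(cols) == 0:
        return cols
    breaks = np.flatnonzero(np.diff(cols) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(cols) - 1]))
    out = []
    for s, e in zip(starts, ends):
        run_len = e - s + 1
        if run_len >= w:
            a = cols[s]
            out.append(np.arange(a, a + run_len - w + 1))
    return np.concatenate(out) if out else np.empty(0, dtype=cols.dtype)


def window_matrix(matrix: IBDMatrix, w: int) -> WindowMatrix:
    """AND over w consecutive SNPs for every pair row."""
    m = matrix.n_snps
    if not 1 <= w <= m:
        raise ValueError(f"window size must be in [1, {m}], got {w}")
    csr = matrix.data.tocsr()
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    for r in range(csr.shape[0]):
        cols = csr.indices[csr.indptr[r]:csr.indptr[r + 1]]
        anchors = _reduce_row(np.sort(cols), w)
        if len(anchors):
            rows_idx.append(np.full(len(anchors), r, dtype=np.int64))
            cols_idx.append(anchors)
    n_win = m - w + 1
    if rows_idx:
        ri = np.concatenate(rows_idx)
        ci = np.concatenate(cols_idx)
    else:
        ri = ci = np.empty(0, dtype=np.int64)
    data = sparse.csr_matrix(
        (np.ones(len(ri), dtype=np.uint8), (ri, ci)),
        shape=(csr.shape[0], n_win),
    )
    return WindowMatrix(data, w, matrix)


def window_scan(
    wm: WindowMatrix,
    phenotype: Phenotype,
    n_p: int = 0,
    seed: int | np.random.Generator = 0,
    alternative: str = "two_sided",
    smooth: bool = False,
) -> ScanResult:
    """Group counts, Fisher p, and (optionally) permutation p per window.

    ``n_p = 0`` skips the permutation test.  Window j is reported at the
    position of SNP j with ``end_position`` the position of SNP j+w-1.
    """
    pairs: PairSet = wm.source.pairs
    panel = wm.source.panel
    i_case, i_cont = _group_counts(wm.data, wm.row_groups)
    tc, tk = pairs.t_case, pairs.t_cont
    n_win = wm.n_windows
    pvals = np.empty(n_win)
    ors = np.empty(n_win)
    for j in range(n_win):
        a, c = int(i_case[j]), int(i_cont[j])
        pvals[j] = fisher_2x2(a, tc - a, c, tk - c, alternative=alternative)
        ors[j] = _odds_ratio(a, tc - a, c, tk - c)
    perm_p = None
    if n_p > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        d_obs, d_perm = permuted_d(wm.data, wm.row_pairs, phenotype, n_p, rng)
        hits = (d_perm >= d_obs[None, :]).sum(axis=0)
        perm_p = (1 + hits) / (1 + n_p) if smooth else hits / n_p
    return ScanResult(
        chrom=panel.chrom,
        positions=panel.positions_bp[:n_win].copy(),
        end_positions=panel.positions_bp[wm.w - 1:].copy(),
        snp_ids=list(panel.snp_ids[:n_win]),
        i_case=i_case,
        i_cont=i_cont,
        t_case=tc,
        t_cont=tk,
        odds_ratio=ors,
        fisher_p=pvals,
        d=(i_case - i_cont).astype(np.int64),
        perm_p=perm_p,
    )
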
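"""Haplotype extraction within IBD windows and the G-test on their counts.

For every pair that is window-IBD at anchor j, each member's allele string
over the window is read from the phased data — by default from the
haplotype slot named in the IBD segment record, so the shared physical
haplotype is counted rather than the homolog.  Both members contribute one
string to their group's multiset (case-case pairs to the case multiset,
control-control to the control multiset; discordant pairs are excluded).
Group frequency differences over the distinct strings are tested with the
log-likelihood-ratio G-test

    G = 2 sum_ij O_ij ln(O_ij / E_ij),   E_ij = row_i . col_j / total,

with the 0*ln(0) = 0 convention, and optionally with a subject-label
permutation test on G.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .io_formats import MISSING, PhasedHaplotypes, Phenotype
from .pair_matrix import CASE_PAIR, CONTROL_PAIR, DISCORDANT
from .sliding_window import WindowMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeCounts",
    "GTestResult",
    "DegenerateTestError",
    "haplotype_structure",
    "gtest",
    "gtest_permutation",
]


class DegenerateTestError(ValueError):
    """Fewer than two distinct haplotype strings: no frequency test exists."""


@dataclass
class HaplotypeCounts:
    """Multiset of window haplotype strings split by pair group."""

    anchor: int
    w: int
    case_counts: Counter
    control_counts: Counter

    @property
    def strings(self) -> list[str]:
        return sorted(set(self.case_counts) | set(self.control_counts))

    def table(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Observed counts as groups x strings, with row/column labels."""
        strings = self.strings
        rows, labels = [], []
        for name, cnt in (("case", self.case_counts),
                          ("control", self.control_counts)):
            if sum(cnt.values()) > 0:
                rows.append([cnt.get(s, 0) for s in strings])
                labels.append(name)
        obs = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(strings)))
        return obs, labels, strings


@dataclass
class GTestResult:
    g: float
    df: int
    p: float
    perm_p: float | None = None


def _member_string(
    phased: PhasedHaplotypes,
    subject: str,
    segments,
    snp_lo: int,
    snp_hi: int,
    positions: np.ndarray,
    mode: str,
) -> list[str] | None:
    """Window allele string(s) for one member of a window-IBD pair.

    ``shared_slot`` reads, per SNP, the slot named by whichever of the
    pair's segments covers that SNP (segments may chain across the window
    at pair level).  ``both_slots`` returns both physical haplotypes'
    strings.  Returns None if any needed allele is missing.
    """
    si = phased.subject_index(subject)
    if mode == "both_slots":
        out = []
        for slot in (0, 1):
            alleles = phased.alleles[si, snp_lo:snp_hi, slot]
            if np.any(alleles == MISSING):
                return None
            out.append("".join(map(str, alleles)))
        return out
    chars = []
    for k in range(snp_lo, snp_hi):
        pos = int(positions[k])
        seg = next((s for s in segments if s.covers(pos)), None)
        if seg is None:
            raise RuntimeError(
                f"window SNP at {pos} not covered by any provenance segment "
                f"for {subject!r} (internal inconsistency)"
            )
        allele = phased.alleles[si, k, seg.hap_of(subject) - 1]
        if allele == MISSING:
            return None
        chars.append(str(allele))
    return ["".join(chars)]


def _window_strings(
    wm: WindowMatrix,
    phased: PhasedHaplotypes,
    j: int,
    mode: str = "shared_slot",
) -> list[tuple[str, str, list[str], list[str]]]:
    """Per window-IBD pair: (member1, member2, strings1, strings2).

    Subjects with a missing phased allele inside the window are dropped
    with a logged count.
    """
    if mode not in ("shared_slot", "both_slots"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    w = wm.w
    positions = wm.source.panel.positions_bp
    snp_lo, snp_hi = j, j + w
    if snp_hi > len(phased.positions_bp) or not np.array_equal(
        phased.positions_bp[snp_lo:snp_hi], positions[snp_lo:snp_hi]
    ):
        raise ValueError(
            f"phased data does not cover window SNPs {snp_lo}..{snp_hi - 1} "
            "with the panel's marker map"
        )
    col = wm.data.getcol(j).toarray().ravel()
    out = []
    n_dropped = 0
    for r in np.flatnonzero(col):
        a, b = wm.row_pairs[r]
        segs = wm.source.provenance[r]
        if not segs:
            raise RuntimeError(f"no provenance for window-IBD row {r}")
        sa = _member_string(phased, a, segs, snp_lo, snp_hi, positions, mode)
        sb = _member_string(phased, b, segs, snp_lo, snp_hi, positions, mode)
        if sa is None or sb is None:
            n_dropped += 1
            continue
        out.append((a, b, sa, sb))
    if n_dropped:
        logger.info(
            "haplotype extraction: dropped %d pairs with missing phased "
            "alleles in window %d", n_dropped, j,
        )
    return out


def _counts_from_strings(pair_strings, group_of, anchor, w) -> HaplotypeCounts:
    case_counts: Counter = Counter()
    control_counts: Counter = Counter()
    for a, b, sa, sb in pair_strings:
        g = group_of(a, b)
        if g == DISCORDANT:
            continue
        target = case_counts if g == CASE_PAIR else control_counts
        for s in sa:
            target[s] += 1
        for s in sb:
            target[s] += 1
    return HaplotypeCounts(anchor, w, case_counts, control_counts)


def haplotype_structure(
    wm: WindowMatrix,
    phased: PhasedHaplotypes,
    j: int,
    mode: str = "shared_slot",
) -> HaplotypeCounts:
    """Extract and tally shared haplotype strings at window anchor j."""
    pair_strings = _window_strings(wm, phased, j, mode=mode)
    groups = wm.row_groups
    row_of = {p: i for i, p in enumerate(wm.row_pairs)}

    def group_of(a, b):
        return groups[row_of[(a, b)]]

    return _counts_from_strings(pair_strings, group_of, j, wm.w)


def _g_from_table(obs: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def gtest(
    counts: "HaplotypeCounts | np.ndarray",
    df_mode: str = "as_printed",
) -> GTestResult:
    """Log-likelihood-ratio G-test on the group x haplotype count table.

    ``as_printed`` uses df = k - 1 (k distinct haplotype strings);
    ``contingency`` uses the standard (k - 1)(g - 1).  A group with zero
    total is dropped before testing.  With fewer than two distinct strings
    the test is undefined and :class:`DegenerateTestError` is raised.
    """
    if isinstance(counts, HaplotypeCounts):
        obs, _, strings = counts.table()
        obs = obs[:, np.asarray(obs).sum(axis=0) > 0] if obs.size else obs
    else:
        obs = np.atleast_2d(np.asarray(counts, dtype=np.int64))
        obs = obs[obs.sum(axis=1) > 0]
        obs = obs[:, obs.sum(axis=0) > 0] if obs.size else obs
    if obs.size == 0 or obs.sum() == 0:
        raise DegenerateTestError("empty haplotype count table")
    k = obs.shape[1]
    g_rows = obs.shape[0]
    if k < 2:
        raise DegenerateTestError(
            f"need >=2 distinct haplotype strings, got {k}"
        )
    if df_mode == "as_printed":
        df = k - 1
    elif df_mode == "contingency":
        df = (k - 1) * max(g_rows - 1, 0)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    g = _g_from_table(obs)
    p = 1.0 if df == 0 else float(chi2.sf(g, df))
    return GTestResult(g=g, df=df, p=p)


def gtest_permutation(
    wm: WindowMatrix,
    phased: PhasedHaplotypes,
    phenotype: Phenotype,
    j: int,
    n_p: int,
    seed: int | np.random.Generator = 0,
    mode: str = "shared_slot",
    df_mode: str = "as_printed",
) -> GTestResult:
    """G-test at window j with a subject-label permutation p-value.

    Strings are extracted once per pair; each replicate permutes the
    case/control labels over subjects and re-derives pair groups, so
    pairs discordant under one labeling may be concordant under another.
    p = #{G^(p) >= G_obs} / n_p.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pair_strings = _window_strings(wm, phased, j, mode=mode)
    subjects = list(phenotype.status)
    is_case = np.array([phenotype.is_case(s) for s in subjects], dtype=bool)
    sub_idx = {s: i for i, s in enumerate(subjects)}

    def make_group_of(case_vec):
        def group_of(a, b):
            ca, cb = case_vec[sub_idx[a]], case_vec[sub_idx[b]]
            if ca and cb:
                return CASE_PAIR
            if not ca and not cb:
                return CONTROL_PAIR
            return DISCORDANT
        return group_of

    def g_of(case_vec) -> float:
        counts = _counts_from_strings(pair_strings, make_group_of(case_vec), j, wm.w)
        try:
            return gtest(counts, df_mode=df_mode).g
        except DegenerateTestError:
            return 0.0

    obs = gtest(
        _counts_from_strings(pair_strings, make_group_of(is_case), j, wm.w),
        df_mode=df_mode,
    )
    hits = 0
    for _ in range(n_p):
        perm = rng.permutation(is_case)
        if g_of(perm) >= obs.g:
            hits += 1
    return GTestResult(g=obs.g, df=obs.df, p=obs.p, perm_p=hits / n_p)
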
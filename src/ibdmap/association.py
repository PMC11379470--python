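"""Per-locus association tests on IBD sharing counts.

The core contrast at each SNP is the 2x2 table

    [[I_case, T_case - I_case],
     [I_cont, T_cont - I_cont]]

where I_g counts the group-g pairs IBD at the SNP and T_g = C(n_g, 2) is
the number of possible pairs.  Fisher's exact test treats pairs as
independent, which IBD pairs are not (one subject sits in many pairs), so a
permutation test over *subject* case/control labels is provided alongside:
pair groups are re-derived from the permuted subject labels each replicate,
preserving the dependence structure, and the permutation p-value for locus
j is

    p_j = #{ D_j^(p) >= D_j } / n_p,   D_j = I_case,j - I_cont,j.

A conventional allelic GWAS Fisher scan on genotype dosages is included for
comparison with the IBD scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln

from .io_formats import Phenotype, SNPPanel, MISSING
from .pair_matrix import (
    CASE_PAIR,
    CONTROL_PAIR,
    CountProfile,
    IBDMatrix,
    PairSet,
    count_profile,
)

__all__ = [
    "ScanResult",
    "fisher_2x2",
    "fisher_scan",
    "permutation_scan",
    "gwas_fisher",
]

# relative tolerance when collecting "as or more extreme" tables two-sided
_TIE_RTOL = 1e-7


@dataclass
class ScanResult:
    """Per-locus (or per-window) counts and test results."""

    chrom: str
    positions: np.ndarray      # anchor bp per locus/window
    end_positions: np.ndarray  # last bp covered (== positions for per-SNP)
    snp_ids: list[str]
    i_case: np.ndarray
    i_cont: np.ndarray
    t_case: int
    t_cont: int
    odds_ratio: np.ndarray
    fisher_p: np.ndarray
    d: np.ndarray
    perm_p: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "chrom": self.chrom,
            "position": self.positions,
            "end_position": self.end_positions,
            "snp_id": self.snp_ids,
            "i_case": self.i_case,
            "i_cont": self.i_cont,
            "t_case": self.t_case,
            "t_cont": self.t_cont,
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "d": self.d,
        }
        if self.perm_p is not None:
            cols["perm_p"] = self.perm_p
        return pd.DataFrame(cols)


def _hypergeom_pmf(r1: int, r2: int, c1: int):
    """Support and pmf of the table's (1,1) cell under fixed margins."""
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return x, np.exp(logp)


def fisher_2x2(a: int, b: int, c: int, d: int,
               alternative: str = "two_sided") -> float:
    """Fisher exact p-value for the table [[a, b], [c, d]].

    Two-sided: sum of point probabilities no larger than the observed
    table's (within a small relative tolerance for float ties).  "greater"
    is the upper tail on cell a.  Any zero margin gives p = 1 (the table
    carries no information about association).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entries must be nonnegative integers, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    x, pmf = _hypergeom_pmf(r1, r2, c1)
    obs = pmf[a - x[0]]
    if alternative == "two_sided":
        mask = pmf <= obs * (1.0 + _TIE_RTOL)
        if mask.all():
            return 1.0
        p = pmf[mask].sum()
    elif alternative == "greater":
        p = pmf[x >= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def _odds_ratio(a, b, c, d) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.float64(a) * d / (np.float64(b) * c))


def fisher_scan(
    profile: CountProfile,
    pairs: PairSet,
    panel: SNPPanel,
    alternative: str = "two_sided",
) -> ScanResult:
    """Fisher exact test of case-group vs control-group IBD counts per SNP."""
    tc, tk = pairs.t_case, pairs.t_cont
    m = len(profile.i_case)
    pvals = np.empty(m)
    ors = np.empty(m)
    for j in range(m):
        a, c = int(profile.i_case[j]), int(profile.i_cont[j])
        pvals[j] = fisher_2x2(a, tc - a, c, tk - c, alternative=alternative)
        ors[j] = _odds_ratio(a, tc - a, c, tk - c)
    return ScanResult(
        chrom=panel.chrom,
        positions=panel.positions_bp.copy(),
        end_positions=panel.positions_bp.copy(),
        snp_ids=list(panel.snp_ids),
        i_case=profile.i_case.astype(np.int64),
        i_cont=profile.i_cont.astype(np.int64),
        t_case=tc,
        t_cont=tk,
        odds_ratio=ors,
        fisher_p=pvals,
        d=(profile.i_case - profile.i_cont).astype(np.int64),
    )


def _row_member_indices(row_pairs, subjects: list[str]):
    idx = {s: i for i, s in enumerate(subjects)}
    s1 = np.array([idx[p[0]] for p in row_pairs], dtype=np.int64)
    s2 = np.array([idx[p[1]] for p in row_pairs], dtype=np.int64)
    return s1, s2


def permuted_d(
    data: sparse.spmatrix,
    row_pairs: list[tuple[str, str]],
    phenotype: Phenotype,
    n_p: int,
    rng: np.random.Generator,
):
    """Observed D per column and the n_p x m matrix of permuted D values.

    Subject labels are shuffled (the case/control multiset is preserved),
    pair groups re-derived, and D = I_case - I_cont recomputed per
    replicate.  Unstored (all-zero) rows contribute 0 to every D, so only
    stored rows matter.
    """
    subjects = list(phenotype.status)
    is_case = np.array([phenotype.is_case(s) for s in subjects], dtype=bool)
    s1, s2 = _row_member_indices(row_pairs, subjects)

    def weights(case_vec: np.ndarray) -> np.ndarray:
        cc = case_vec[..., s1] & case_vec[..., s2]
        kk = ~case_vec[..., s1] & ~case_vec[..., s2]
        return cc.astype(np.int64) - kk.astype(np.int64)

    # sparse dot keeps memory flat for wide matrices
    w_obs = weights(is_case)
    d_obs = np.asarray((data.T @ w_obs)).ravel().astype(np.int64)
    perm_cases = np.tile(is_case, (n_p, 1))
    perm_cases = rng.permuted(perm_cases, axis=1)
    w_perm = weights(perm_cases)  # n_p x rows
    d_perm = np.asarray((data.T @ w_perm.T)).T.astype(np.int64)  # n_p x m
    return d_obs, d_perm


def permutation_scan(
    matrix: IBDMatrix,
    phenotype: Phenotype,
    n_p: int,
    seed: int | np.random.Generator = 0,
    loci: np.ndarray | list[int] | None = None,
    smooth: bool = False,
) -> np.ndarray:
    """Subject-label permutation p-value per SNP (optionally a locus subset).

    With ``smooth`` the (1 + #) / (1 + n_p) estimator is used; the default
    reports the plain fraction, which can be exactly 0.
    """
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    data = matrix.data if loci is None else matrix.data[:, np.asarray(loci)]
    d_obs, d_perm = permuted_d(data, matrix.row_pairs, phenotype, n_p, rng)
    hits = (d_perm >= d_obs[None, :]).sum(axis=0)
    if smooth:
        return (1 + hits) / (1 + n_p)
    return hits / n_p


def gwas_fisher(
    panel: SNPPanel,
    phenotype: Phenotype,
    alternative: str = "two_sided",
) -> ScanResult:
    """Conventional allelic Fisher scan on genotype dosages.

    Per SNP the 2x2 table is ALT vs REF allele counts in cases vs controls
    (two alleles per non-missing subject); missing genotypes drop that
    subject's two alleles at that SNP only.  Monomorphic SNPs give p = 1
    through the zero-margin rule.
    """
    is_case = np.array(
        [phenotype.is_case(s) if s in phenotype else False for s in panel.subjects]
    )
    in_pheno = np.array([s in phenotype for s in panel.subjects])
    dos = panel.dosages
    m = panel.n_snps
    pvals = np.empty(m)
    ors = np.empty(m)
    alt_case = np.empty(m, dtype=np.int64)
    alt_cont = np.empty(m, dtype=np.int64)
    for j in range(m):
        col = dos[:, j]
        ok = (col != MISSING) & in_pheno
        case_ok = ok & is_case
        cont_ok = ok & ~is_case
        a = int(col[case_ok].sum())          # case ALT alleles
        b = int(2 * case_ok.sum() - a)       # case REF alleles
        c = int(col[cont_ok].sum())
        d = int(2 * cont_ok.sum() - c)
        alt_case[j], alt_cont[j] = a, c
        pvals[j] = fisher_2x2(a, b, c, d, alternative=alternative)
        ors[j] = _odds_ratio(a, b, c, d)
    n_case_sub = int((is_case & in_pheno).sum())
    n_cont_sub = int((~is_case & in_pheno).sum())
    return ScanResult(
        chrom=panel.chrom,
        positions=panel.positions_bp.copy(),
        end_positions=panel.positions_bp.copy(),
        snp_ids=list(panel.snp_ids),
        i_case=alt_case,
        i_cont=alt_cont,
        t_case=2 * n_case_sub,
        t_cont=2 * n_cont_sub,
        odds_ratio=ors,
        fisher_p=pvals,
        d=alt_case - alt_cont,
    )
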
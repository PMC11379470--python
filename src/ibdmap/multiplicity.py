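"""Genome-wide significance via an effective number of independent tests.

Neighbouring loci are strongly dependent (LD, shared segments), so the raw
test count badly overstates the multiplicity burden.  The dependence
between the binary columns actually tested is measured with plug-in mutual
information, mapped to a correlation scale with Joe's transform

    r = sqrt(1 - exp(-2 * MI)),

and the eigenvalues of the resulting matrix feed the Li-Ji rule

    M_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ],

which interpolates between m (independent columns) and 1 (rank one).
M_eff then replaces the raw count in a Benjamini-Hochberg FDR threshold.
For genome-scale scans the matrix is processed in consecutive blocks
(banded approximation) and per-block M_eff values are summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectiveTests",
    "mutual_information",
    "mi_correlation",
    "effective_tests",
    "effective_tests_banded",
    "bh_threshold",
]


@dataclass
class EffectiveTests:
    m_eff: float
    eigenvalues: np.ndarray
    block_bounds: list[tuple[int, int]] | None = None


def mutual_information(x, y) -> float:
    """Plug-in mutual information (nats) of two equal-length binary vectors."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    n11 = np.count_nonzero(x & y)
    n10 = np.count_nonzero(x & ~y)
    n01 = np.count_nonzero(~x & y)
    n00 = n - n11 - n10 - n01
    joint = np.array([[n00, n01], [n10, n11]], dtype=float) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            p = joint[a, b]
            if p > 0:
                mi += p * np.log(p / (px[a] * py[b]))
    return float(max(mi, 0.0))


def mi_correlation(columns: np.ndarray, bandwidth: int | None = None) -> np.ndarray:
    """Pairwise MI of binary columns mapped to a correlation scale.

    ``columns`` is observations x m.  r_ij = sqrt(1 - exp(-2 MI_ij)), with
    unit diagonal; entries farther than ``bandwidth`` off the diagonal are
    set to 0.  Constant columns have MI 0 with everything (r = 0 off the
    diagonal); that is a valid value, not an error.
    """
    cols = np.asarray(columns)
    if cols.ndim != 2 or cols.shape[1] < 1:
        raise ValueError("columns must be a 2-D array with >=1 column")
    x = (cols != 0).astype(np.float64)
    n, m = x.shape
    # all-pairs 2x2 joint counts via dot products
    n11 = x.T @ x
    c1 = x.sum(axis=0)
    n10 = c1[:, None] - n11
    n01 = c1[None, :] - n11
    n00 = n - n11 - n10 - n01
    p1 = c1 / n
    p0 = 1.0 - p1

    def term(nab, pa, pb):
        pab = nab / n
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = pa * pb
            log_ratio = np.where((pab > 0) & (denom > 0),
                                 np.log(np.where(pab > 0, pab, 1.0))
                                 - np.log(np.where(denom > 0, denom, 1.0)),
                                 0.0)
        return pab * log_ratio

    mi = (
        term(n00, p0[:, None], p0[None, :])
        + term(n01, p0[:, None], p1[None, :])
        + term(n10, p1[:, None], p0[None, :])
        + term(n11, p1[:, None], p1[None, :])
    )
    mi = np.maximum(mi, 0.0)
    r = np.sqrt(1.0 - np.exp(-2.0 * mi))
    np.fill_diagonal(r, 1.0)
    if bandwidth is not None:
        i = np.arange(m)
        r[np.abs(i[:, None] - i[None, :]) > bandwidth] = 0.0
    return r


def _li_ji(eigenvalues: np.ndarray) -> float:
    # round before floor: the rule is discontinuous at integers and
    # eigensolvers return e.g. 5 - 1e-15 for an exact eigenvalue of 5
    lam = np.round(np.maximum(np.asarray(eigenvalues, dtype=float), 0.0), 9)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def effective_tests(corr: np.ndarray) -> EffectiveTests:
    """Li-Ji effective number of independent tests from a correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(corr)
    return EffectiveTests(m_eff=_li_ji(lam), eigenvalues=lam)


def effective_tests_banded(
    columns: np.ndarray, block_size: int = 500
) -> EffectiveTests:
    """Per-block M_eff summed over consecutive column blocks.

    Keeps genome scans tractable: dependence between loci farther apart
    than ``block_size`` SNPs is ignored (set to zero), which can only push
    M_eff up, i.e. the threshold is conservative.
    """
    cols = np.asarray(columns)
    m = cols.shape[1]
    total = 0.0
    eigs = []
    bounds = []
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        r = mi_correlation(cols[:, lo:hi])
        res = effective_tests(r)
        total += res.m_eff
        eigs.append(res.eigenvalues)
        bounds.append((lo, hi))
    return EffectiveTests(
        m_eff=total, eigenvalues=np.concatenate(eigs), block_bounds=bounds
    )


def gwas_carrier_columns(panel) -> np.ndarray:
    """Binary carrier-status columns (dosage > 0) for M_eff on GWAS scans.

    The dependence matrix should be built from the columns actually
    tested: IBD indicator columns for IBD scans, carrier indicators for
    allelic scans.  Missing dosages count as non-carrier.
    """
    return (np.asarray(panel.dosages) > 0).astype(np.uint8)


def bh_threshold(pvalues, q: float, m_eff: float):
    """Benjamini-Hochberg threshold with M_eff in place of the test count.

    Sort ascending; the threshold is p_(i*) for the largest i with
    p_(i) <= i * q / m_eff.  Returns (threshold or None, boolean rejection
    mask over the input order); all p <= threshold are rejected.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"FDR level q must be in (0, 1), got {q}")
    if m_eff < 1:
        raise ValueError(f"m_eff must be >= 1, got {m_eff}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return None, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    i = np.arange(1, len(p) + 1)
    ok = sorted_p <= i * q / m_eff
    if not ok.any():
        return None, np.zeros_like(p, dtype=bool)
    threshold = float(sorted_p[np.flatnonzero(ok)[-1]])
    return threshold, p <= threshold
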
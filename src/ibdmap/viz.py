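"""Static plots: group IBD-count profiles and Manhattan-style p-value scans."""

from __future__ import annotations

import logging
import os

import numpy as np

from .association import ScanResult
from .pair_matrix import CountProfile

logger = logging.getLogger(__name__)

__all__ = ["plot_tracks"]

# -log10 cap for permutation p-values that are exactly 0 under the
# as-printed estimator
_NEGLOG_CAP = 16.0


def _neglog10(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        v = -np.log10(p)
    return np.minimum(v, _NEGLOG_CAP)


def plot_tracks(
    scan: ScanResult,
    counts: CountProfile | None,
    path_prefix: str | os.PathLike,
    threshold: float | None = None,
) -> list[str]:
    """Write a count-profile PNG and a Manhattan PNG.

    ``threshold`` draws the BH significance line on the Manhattan plot.
    Empty input is a warning no-op.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(scan.positions) == 0:
        logger.warning("plot_tracks: empty scan result, nothing to plot")
        return []
    written = []
    pos_mb = scan.positions / 1e6

    if counts is not None:
        fig, ax = plt.subplots(figsize=(9, 3.2))
        ax.step(pos_mb, counts.i_case, where="mid", label="case pairs",
                color="#c0392b", lw=1.0)
        ax.step(pos_mb, counts.i_cont, where="mid", label="control pairs",
                color="#2c3e50", lw=1.0)
        ax.set_xlabel(f"chr{scan.chrom} position (Mb)")
        ax.set_ylabel("IBD pair count")
        ax.legend(frameon=False)
        fig.tight_layout()
        profile_path = f"{path_prefix}.profile.png"
        fig.savefig(profile_path, dpi=120)
        plt.close(fig)
        written.append(profile_path)

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.scatter(pos_mb, _neglog10(scan.fisher_p), s=6, color="#2980b9",
               label="Fisher")
    if scan.perm_p is not None:
        ax.scatter(pos_mb, _neglog10(scan.perm_p), s=6, color="#e67e22",
                   label="permutation")
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls="--", color="#7f8c8d",
                   label=f"BH threshold ({threshold:.2e})")
    ax.set_xlabel(f"chr{scan.chrom} position (Mb)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    manhattan_path = f"{path_prefix}.manhattan.png"
    fig.savefig(manhattan_path, dpi=120)
    plt.close(fig)
    written.append(manhattan_path)
    return written
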
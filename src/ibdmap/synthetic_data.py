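"""Simulator for internally consistent IBD-mapping fixtures.

Generates, from one seed, the four files a scan needs: genotype VCF,
phased VCF, Refined-IBD style segment table, and phenotype TSV — with a
plantable causal region of elevated case-case IBD sharing.

The model is deliberately segment-level rather than coalescent: case or
control status is assigned first; every unordered pair then draws a
background segment (uniform placement, uniform length) with probability
``base_rate``; case-case pairs additionally draw a segment spanning the
causal region with probability ``base_rate * (enrichment - 1)``, so the
causal-region rate for case pairs is ``base_rate * enrichment`` and
``enrichment = 1`` is exactly the null.  Within every segment the two
named haplotype slots are constrained to carry identical alleles over the
covered SNPs (enforced jointly over all segments via union-find on
(subject, slot, SNP) cells), so window extraction recovers a genuinely
shared string.  Background sites are independent (no LD model).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import IBDSegment, PhasedHaplotypes, Phenotype, SNPPanel

__all__ = ["SimConfig", "Cohort", "simulate_cohort", "downsample_controls",
           "write_fixture"]


@dataclass
class SimConfig:
    """Generative parameters for one simulated chromosome.

    ``causal_region`` is a (start_bp, end_bp) interval or None;
    ``enrichment`` multiplies the case-case segment rate inside it.
    """

    n_case: int = 40
    n_control: int = 40
    m: int = 500
    chrom: str = "1"
    maf_range: tuple[float, float] = (0.05, 0.5)
    base_rate: float = 0.02
    segment_length_bp: tuple[int, int] = (100_000, 1_000_000)
    start_bp: int = 1_000_000
    spacing_bp: int = 10_000
    causal_region: tuple[int, int] | None = None
    enrichment: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must each be >= 2")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not (0.0 <= self.base_rate <= 1.0):
            raise ValueError("base_rate must be a probability in [0, 1]")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        a, b = self.segment_length_bp
        if not (0 < a <= b):
            raise ValueError("segment_length_bp must be 0 < min <= max")
        if self.spacing_bp < 1 or self.start_bp < 1:
            raise ValueError("spacing_bp and start_bp must be >= 1")
        if self.causal_region is not None:
            s, e = self.causal_region
            if s > e:
                raise ValueError("causal_region must have start <= end")
            if self.enrichment > 1.0:
                last = self.start_bp + (self.m - 1) * self.spacing_bp
                if e < self.start_bp or s > last:
                    raise ValueError("causal_region lies outside the SNP map")


@dataclass
class Cohort:
    panel: SNPPanel
    phased: PhasedHaplotypes
    segments: list[IBDSegment]
    phenotype: Phenotype
    config: SimConfig


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:  # path compression
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort: phenotypes, segments, phased alleles, dosages."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases = [f"case{i:04d}" for i in range(config.n_case)]
    controls = [f"ctrl{i:04d}" for i in range(config.n_control)]
    subjects = cases + controls
    phenotype = Phenotype(
        {**{s: "case" for s in cases}, **{s: "control" for s in controls}}
    )
    m = config.m
    positions = config.start_bp + config.spacing_bp * np.arange(m, dtype=np.int64)
    snp_ids = [f"snp{j:05d}" for j in range(m)]
    maf = rng.uniform(*config.maf_range, size=m)

    # --- segments -----------------------------------------------------
    chrom_lo, chrom_hi = int(positions[0]), int(positions[-1])
    seg_lo, seg_hi = config.segment_length_bp
    segments: list[IBDSegment] = []

    def add_segment(a: str, b: str, start: int, end: int) -> None:
        segments.append(
            IBDSegment(
                sample1=a,
                hap1=int(rng.integers(1, 3)),
                sample2=b,
                hap2=int(rng.integers(1, 3)),
                chrom=config.chrom,
                start_bp=start,
                end_bp=end,
                lod=round(float(rng.uniform(3.0, 12.0)), 2),
                cm_length=round((end - start) / 1e6, 3),
            )
        )

    all_pairs = [
        (subjects[i], subjects[j])
        for i in range(len(subjects))
        for j in range(i + 1, len(subjects))
    ]
    for a, b in all_pairs:
        if rng.random() < config.base_rate:
            length = int(rng.integers(seg_lo, seg_hi + 1))
            start = int(rng.integers(chrom_lo, max(chrom_lo, chrom_hi - length) + 1))
            add_segment(a, b, start, min(start + length, chrom_hi))
    extra = config.base_rate * (config.enrichment - 1.0)
    if config.causal_region is not None and extra > 0:
        region_start, region_end = config.causal_region
        case_pairs = [(a, b) for a, b in all_pairs
                      if phenotype.is_case(a) and phenotype.is_case(b)]
        for a, b in case_pairs:
            if rng.random() < extra:
                add_segment(a, b, int(region_start), int(region_end))

    # --- alleles under segment-identity constraints -------------------
    n = len(subjects)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    # cell layout: subject * 2m + slot * m + snp
    uf = _UnionFind(n * 2 * m)

    def cell(subject: str, slot: int, snp: int) -> int:
        return sub_idx[subject] * 2 * m + slot * m + snp

    for seg in segments:
        lo = int(np.searchsorted(positions, seg.start_bp, side="left"))
        hi = int(np.searchsorted(positions, seg.end_bp, side="right"))
        for k in range(lo, hi):
            uf.union(cell(seg.sample1, seg.hap1 - 1, k),
                     cell(seg.sample2, seg.hap2 - 1, k))
    flat = (rng.random((n, 2, m)) < maf[None, None, :]).astype(np.int8).ravel()
    roots = np.array([uf.find(i) for i in range(n * 2 * m)])
    flat = flat[roots]  # every cell takes its class root's draw
    alleles = flat.reshape(n, 2, m).transpose(0, 2, 1)  # subjects x SNPs x 2
    dosages = alleles.sum(axis=2).astype(np.int8)

    panel = SNPPanel(config.chrom, snp_ids, positions, list(subjects), dosages)
    phased = PhasedHaplotypes(config.chrom, positions, list(subjects), alleles)
    return Cohort(panel, phased, segments, phenotype, config)


def downsample_controls(
    phenotype: Phenotype, n: int, seed: int | np.random.Generator = 0
) -> Phenotype:
    """Keep all cases and a uniform random subset of n controls."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    controls = phenotype.controls
    if n > len(controls):
        raise ValueError(
            f"cannot keep {n} controls, only {len(controls)} available"
        )
    keep = set(rng.choice(len(controls), size=n, replace=False).tolist())
    kept_controls = {c for i, c in enumerate(controls) if i in keep}
    status = {
        s: v
        for s, v in phenotype.status.items()
        if v == "case" or s in kept_controls
    }
    return Phenotype(status)


def _vcf_lines(chrom, positions, snp_ids, subjects, gt_of):
    yield "##fileformat=VCFv4.2"
    yield f"##contig=<ID={chrom}>"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects)
    for j, (pos, sid) in enumerate(zip(positions, snp_ids)):
        gts = "\t".join(gt_of(i, j) for i in range(len(subjects)))
        yield f"{chrom}\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}"


def write_fixture(directory: str | os.PathLike, cohort: Cohort) -> dict[str, str]:
    """Write genotype.vcf, phased.vcf, segments.ibd, phenotype.tsv.

    Files round-trip through :mod:`ibdmap.io_formats` without warnings.
    Returns the path of each file keyed by role.
    """
    os.makedirs(directory, exist_ok=True)
    panel, phased = cohort.panel, cohort.phased
    paths = {
        "genotype": os.path.join(directory, "genotype.vcf"),
        "phased": os.path.join(directory, "phased.vcf"),
        "ibd": os.path.join(directory, "segments.ibd"),
        "phenotype": os.path.join(directory, "phenotype.tsv"),
    }

    def genotype_gt(i, j):
        d = int(panel.dosages[i, j])
        return {0: "0/0", 1: "0/1", 2: "1/1"}.get(d, "./.")

    with open(paths["genotype"], "w") as fh:
        for line in _vcf_lines(panel.chrom, panel.positions_bp, panel.snp_ids,
                               panel.subjects, genotype_gt):
            fh.write(line + "\n")

    def phased_gt(i, j):
        a, b = phased.alleles[i, j]
        if a < 0 or b < 0:
            return ".|."
        return f"{a}|{b}"

    with open(paths["phased"], "w") as fh:
        for line in _vcf_lines(phased.chrom, phased.positions_bp, panel.snp_ids,
                               phased.subjects, phased_gt):
            fh.write(line + "\n")

    with open(paths["ibd"], "w") as fh:
        for s in cohort.segments:
            fh.write(
                f"{s.sample1}\t{s.hap1}\t{s.sample2}\t{s.hap2}\t{s.chrom}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.lod}\t{s.cm_length}\n"
            )

    with open(paths["phenotype"], "w") as fh:
        fh.write("id\tstatus\n")
        for s, v in cohort.phenotype.status.items():
            fh.write(f"{s}\t{v}\n")
    return paths
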
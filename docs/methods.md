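# Methods

## Data model and coordinates

All coordinates are 1-based with both interval endpoints inclusive (VCF /
Refined-IBD convention); chromosome labels are compared after stripping a
leading `chr`. An IBD segment names two subjects and, for each, which of
the two phased haplotype slots (1 or 2) carries the shared material. LOD
and cM columns are parsed and carried through but take no part in any
test. Exact duplicate segment rows (as can arise from concatenated
per-chromosome files) are dropped with a logged count. The genotype
container is VCF throughout; dosage is the ALT-allele count, and
non-biallelic or non-SNP records are skipped (counted), not split.

## Pair matrix

Rows are unordered subject pairs, columns the panel SNPs; an entry is 1
iff any of the pair's segments spans the SNP. Segments for the same pair
combine by OR regardless of haplotype-slot combination — the tests count
pairs, not haplotype pairs — but every segment is retained as row
provenance so the haplotype stage can recover which physical haplotype
was shared. Case-case pairs form the case group, control-control the
control group; discordant pairs are stored but excluded from both groups.
Pairs never observed in a segment are implicit all-zero rows: the Fisher
denominators are `T_g = C(n_g, 2)` over phenotyped subjects, because "IBD
frequency" is relative to all possible pairs, not the stored ones.

## Tests

**Fisher exact.** Implemented by direct hypergeometric enumeration over
the table's support with log-gamma point probabilities. Two-sided p sums
point probabilities no larger than the observed one, with a 1e-7 relative
tie tolerance; if the selection covers the whole support the p-value is
exactly 1. Any zero margin gives p = 1. Agreement with exact integer
enumeration is at the 1e-13 level for all tables with total <= 40, and
with `scipy.stats.fisher_exact` on random tables (scipy is the
independent cross-check in the tests, not the implementation).

**Permutation.** Pairs sharing a subject are dependent, so the exchange
unit is the subject label, never the matrix row: each replicate shuffles
the case/control multiset over subjects, re-derives every stored row's
group, and recomputes `D_j = I_case,j - I_cont,j`. The reported p is the
plain one-sided fraction `#{D^(p) >= D_obs}/n_p` (ties count, zero is
possible); a `smooth` flag switches to `(1+#)/(1+n_p)` for display.
Labelings are drawn uniformly with replacement; the identity labeling is
not forced into the draw.

Because D is integer-valued, the permutation p is discrete and the test
conservative wherever sharing is sparse (at a locus no pair covers,
p = 1 by construction). Calibration checks are therefore run under
conditions where the D distribution is rich — 30+30 subjects at a 0.3
per-pair segment rate, ~435 pairs per group — where the empirical type-I
error at alpha = 0.05 sits inside the 99% binomial band over 200 null
cohorts. At sparser designs the test errs conservative, never
anti-conservative.

**Sliding window.** Window column j is the AND of SNP columns j..j+w-1;
reported at the position of SNP j (left anchor), so w = 1 is bit-for-bit
the per-SNP matrix. The implementation walks each sparse row's runs of
consecutive ones — a run of length L contributes L-w+1 window hits — and
is verified against the dense double-loop definition in the tests.
Windows are SNP-count based, not bp-based. Pair-level OR means two
different-phase segments may stitch one pair's window.

**Haplotype G-test.** For each window-IBD pair, each member's allele
string over the window is read from the phased slot named by whichever
provenance segment covers each SNP (`shared_slot`, the default — this
avoids counting the non-shared homolog); a `both_slots` mode emulates the
literal both-haplotypes reading. Both members contribute one string to
their group's multiset; a missing phased allele disqualifies that
subject's string (logged). The statistic is `G = 2 sum O ln(O/E)` with
`0 ln 0 = 0` and `E` from the margins. The default degrees of freedom are
k-1 for k distinct strings (`as_printed`); the standard contingency
(k-1)(g-1) is available behind `df_mode="contingency"` — the two differ
and the difference is surfaced rather than silently fixed. With fewer
than two distinct strings the test is undefined and raises. The
permutation variant permutes subject labels and re-derives groups, as in
the scan tests.

**GWAS comparison.** Allelic 2x2 per SNP (ALT vs REF counts in cases vs
controls, two alleles per non-missing subject); the genotypic 2x3 test is
out of scope.

## Multiplicity

The dependence between tested columns is measured by plug-in mutual
information on the binary indicator columns, mapped to a correlation
scale by Joe's transform `r = sqrt(1 - exp(-2 MI))`, and reduced to an
effective test count by the Li-Ji rule
`M_eff = sum_i [I(lam_i >= 1) + (lam_i - floor(lam_i))]`. Eigenvalues are
rounded at 1e-9 before the floor because the rule is discontinuous at
integers and eigensolvers return values like 5 - 1e-15. For genome-scale
scans the matrix is processed in consecutive blocks (default 500 columns)
and block M_eff values are summed; ignoring cross-block dependence can
only raise M_eff, i.e. the resulting Benjamini-Hochberg threshold
(`p_(i) <= i q / M_eff`) errs conservative. Each piece (MI estimator,
transform, eigenvalue rule) is isolated behind one function and
swappable. For GWAS columns, dosages are binarized at carrier status
before the MI computation.

## Simulator

The generator is segment-level, not coalescent: the method consumes
segments, so simulating at the segment level exercises exactly the
implemented mathematics with a controllable effect size. Phenotype is
assigned first; each unordered pair then draws a background segment
(uniform start, uniform length) with probability `base_rate`, and
case-case pairs draw an additional segment spanning the causal region
with probability `base_rate * (enrichment - 1)`, so the causal-region
rate for case pairs is `base_rate * enrichment` and `enrichment = 1` is
exactly the null. Defaults: 40+40 subjects, 500 SNPs at 10 kb spacing
from 1 Mb, MAF uniform on (0.05, 0.5), background segments 100 kb - 1 Mb.

Consistency is enforced globally: a union-find over (subject, slot, SNP)
cells merges every cell pair a segment declares identical, and each
equivalence class draws one allele from the SNP's MAF — so every
segment's two named slots agree at every covered SNP even when segments
overlap or chain, and dosages are slot sums by construction.

What the generator does **not** emulate: background LD (sites are
independent; LD enters only through planted shared haplotypes),
recombination maps, genotyping error, IBD-caller false calls and
boundary noise, and population structure. Passing tests therefore show
correctness of the statistics on clean segment input, not robustness to
caller error.

## Problem sizes in the shipped checks

The test suite and acceptance script use desk-scale replicates chosen to
make each property measurable with comfortable margins: the exhaustive
Fisher sweep covers all ~136k tables with total <= 40; localization power
uses 50 seeds of the 40+40 / 500-SNP / 15x-enrichment cohort (the
genome-wide minimum Fisher p falls in the planted 50-SNP region, and the
top w=10 window overlaps it, in >= 90% of seeds — in practice all);
null calibration uses 200 cohorts at n_p = 500; the 4-subject permutation
example is checked against its exhaustive value 1/6 at n_p = 10,000.

## Known limitations

- Exact-duplicate detection ignores LOD/cM, so re-called segments with
  different scores are kept as duplicates of the same interval (harmless:
  rows OR together).
- The banded M_eff ignores long-range dependence; for <= 2,000 columns
  a single block gives the exact eigendecomposition.
- Permutation p-values of 0 are reported as printed; use smoothing for
  -log10 plots (the plot caps at 16).
- The G-test needs two distinct strings; windows where all carriers share
  one founder haplotype are reported as degenerate rather than assigned a
  p-value.
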
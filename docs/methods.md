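# Methods

This note documents the models implemented in `methnome`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinate and data conventions

All coordinates are 0-based, half-open (BED semantics). Methylation data
live in "site tables": one row per (chrom, pos, strand, sample) with
`meth`/`total` counts and a trinucleotide context — `HCG` (endogenous CpG
readout), `GCH` (NOMe-seq accessibility readout), `GCG` (ambiguous between
endogenous CpG and enzymatic GpC methylation; carried in tables, flagged,
and excluded by every downstream consumer), `HCH` (bisulfite-conversion
control), with H = A/C/T. Context is classified against the reference
genome, not the read, the standard NOMe-seq practice. CpG strand collapsing
is exposed as an explicit choice rather than silently applied; the
generator emits plus-strand CpG rows.

Methylation calling from pileup-style records rejects bases from reads with
mapping quality below 30 and ignores bases with base quality below 17; both
thresholds are strict "lower than" rejections, so 30 and 17 themselves
pass.

## DMR calling

The caller follows the BSmooth recipe on count tables:

1. **Smoothing.** Per sample, the methylated fraction is smoothed with a
   tricube-distance, coverage-weighted local fit over a window of at least
   `window_bp` containing at least `min_sites` CpGs. Two fits are offered:
   the plain weighted mean (`degree=0`) and a weighted local line evaluated
   at the site (`degree=1`, the `DmrCaller` default). Local-constant
   kernels are biased at sharp boundaries — they average across a
   methylation step and systematically attenuate the outermost CpGs of a
   differentially methylated block, which shrinks called regions; the
   local-linear fit removes this first-order boundary bias (local
   polynomials are also what BSmooth itself fits). Degree-1 values are
   clipped to [0, 1].
2. **Per-CpG statistic.** t = (m̄₁ − m̄₂) / (σ̃·√(1/n₁+1/n₂)), where σ̃ is
   the pooled cross-sample SD, floored at the 75th percentile of all site
   SDs and then smoothed with a 101-site running mean. Both steps matter
   with two samples per group: the SD estimate has ~2 degrees of freedom,
   so raw values are chi-noisy in *both* directions — flooring removes
   spurious precision, smoothing removes spurious imprecision that would
   otherwise randomly kill strongly differential sites. Two-sided p-values
   use a standard-normal reference; q-values are Benjamini–Hochberg
   genome-wide (the q-value procedure is swappable; BH is the default).
   With one sample per group the statistic degrades to a z-score against
   the genome-wide SD of the smoothed difference and the result is flagged.
3. **Region formation.** Candidate DMRs are maximal runs of same-sign CpGs
   with q ≤ 10⁻⁴ whose consecutive members lie within 300 bp; intervening
   non-significant CpGs do not break a run (the bsseq `regionFinder`
   convention). Candidates are kept with ≥ 4 significant CpGs and an
   absolute group mean smoothed difference ≥ 0.3; the region spans the
   first to last CpG of the run. No region-level p-value is attached —
   the procedure deliberately reports only the per-CpG q-gate and the
   effect-size filter.

**Bandwidth choice.** The defaults `window_bp=2000, min_sites=70` are
BSmooth's published values, tuned to mammalian CpG spacing (~100 bp) and to
methylation that varies smoothly over kilobases. The toy genomes generated
here are i.i.d. sequence — CpG spacing ~20–25 bp and *no* spatial
correlation outside planted blocks — so the appropriate bandwidth is the
planted-block scale, not the mammalian scale: a 70-site kernel spans many
multiples of a 6–12-CpG block and dilutes its smoothed difference several-
fold below the 0.3 filter, for any caller. All toy-genome analyses
therefore use `window_bp=100, min_sites=5, degree=1`. The principle —
match the kernel to the signal's correlation length — is the documented
guidance for real data too.

## NOMe-seq NDR calling

GCH methylation marks accessible chromatin (the GpC methyltransferase can
only reach nucleosome-free DNA), so nucleosome-depleted regions (NDRs) are
segments of elevated GCH methylation.

- **Model.** A two-state hidden Markov model with binomial emissions:
  site i in state s contributes Binomial(totalᵢ, p_s) with p_open > p_closed.
  Baum–Welch fitting (initialised at p = 0.3/0.02, self-transition 0.99,
  uniform start; deterministic, no random restarts) with per-site emission
  renormalisation for numerical range; the EM log-likelihood is checked to
  be non-decreasing and iteration stops at ΔLL < 10⁻⁶ or 100 iterations.
  States are canonicalised after fitting so state 0 is always "open".
  Decoding is Viterbi by default (posterior decoding is available).
  The recursions are numba-compiled; forward/backward/Viterbi on ~10⁵
  sites take milliseconds.
- **Candidate filter.** Maximal runs of open-state sites become putative
  NDRs. Runs with fewer than 4 GCH sites are discarded before testing: a
  single extreme site can flip the Viterbi path, but a sub-nucleosome-width
  "segment" (the nucleosome footprint is ~147 bp) is not a credible NDR,
  and such one-site artifacts are exactly what segmentation of *shuffled*
  data produces.
- **Fisher flank contrast.** Each candidate is tested one-sided (inside
  more GCH-methylated than its flanks) with the exact hypergeometric tail;
  flanks span min(NDR length, 1000 bp) of background territory per side,
  clipped at neighbouring candidates and contig ends. Candidates with no
  GCH observations inside or in both flanks are dropped with a logged
  reason. One-sided is the only sensible direction: accessibility is
  definitionally *elevated* GCH methylation; a two-sided test would admit
  anti-peaks.
- **Empirical FDR.** The (meth, total) pairs are permuted across GCH
  positions per chromosome (preserving the coverage and value multiset
  exactly, destroying spatial structure), the segmentation + Fisher stage
  is re-run per shuffle (5 by default) with the already-fitted HMM, and
  eFDR(p) = [(#null ≤ p)/n_shuffles] / max(1, #observed ≤ p), clipped to
  [0, 1] and made monotone non-decreasing in p. Calls with eFDR < 0.01 are
  kept. Duplicating the shuffle set leaves eFDR unchanged (scale-free).
- NDR calling is per sample; tables containing several samples are
  rejected rather than silently pooled.

## Matched-region permutation enrichment

For query regions (e.g. DMRs) versus an annotation (e.g. TFBS): each
simulation draws one random region per query region with *exactly* the
query's length — the length multiset is matched per template, not pooled —
placed uniformly (chromosome ∝ length, start uniform) and rejection-sampled
until it contains ≥ 4 reference-genome CpGs (up to 10,000 attempts,
then an error naming the template). The empirical p-value is k/n with ties
counting as exceedances — so 21 exceedances in 10⁶ simulations is exactly
0.000021; the k/n (not (k+1)/(n+1)) convention is deliberate and pinned by
a test. CpG content is counted on the reference, not on coverage-dependent
observed sites. No mappability masking is applied (toy genomes); an
exclusion track can be composed upstream by filtering the annotation.

The overlap classifier assigns each query region exactly one of
none / gained / lost / shared_same / shared_different_borders across two
merged peak sets; `shared_same` requires both ends of some overlapping peak
pair to match within `border_tol_bp` (default 0 — exact borders; the
tolerance is configurable since no natural default exists).

## BS/oxBS 5hmC inference

Bisulfite sequencing reads 5mC and 5hmC both as cytosine; oxidative
bisulfite reads only 5mC. Per site: 5mC = oxbs_meth/oxbs_total,
5hmC = max(0, bs fraction − 5mC), flagged when clipped, with delta-method
SEs (difference of independent binomial proportions). The estimator is the
straight ML difference — unbiased before clipping; clipping inflates the
mean at truth 0 (about half the sites clip there, by symmetry), which is
why the clip flag is carried so users can quantify it. The joint constraint
5mC + 5hmC ≤ 1 is enforced by clipping 5hmC only (the oxBS channel is taken
at face value). No conversion-efficiency correction is applied; poorly
converted libraries should be filtered upstream (the HCH conversion-control
summary reports the rate).

## Histone-signature clustering

Regions are represented as log₂((chip/chip_total + pc)/(input/input_total +
pc)) per 25 bp bin (pseudocount pc = 10⁻⁹ on the normalised scale), with
the region body linearly interpolated to 40 bins (a 1 kb equivalent) and
unscaled 1 kb flanks of 40 bins each side; bins beyond a contig end are
missing and imputed as row means before clustering. Total-count
normalisation makes the matrix invariant to library depth. k-means with
k = 3, 10 restarts, fixed seed, labels canonicalised by descending cluster
size. Per (cluster, mark), a paired Student's t-test compares per-region
mean signal between cell types (replicate columns are kept separate for
clustering but averaged into the per-region mean for testing), Bonferroni-
corrected over all performed tests, significant at adjusted p < 0.001;
clusters smaller than two regions are skipped and flagged. Whether the
paired test should use per-region means or per-bin values is genuinely
open; per-region means are used because per-bin pairs within a region are
strongly dependent and would overstate the effective sample size.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the methods assume, with
defaults mirroring the emulated experimental design: two cell types × two donors;
a highly methylated CpG baseline (0.8); planted DMRs with differences drawn
from 0.1–0.6, 96% losing / 4% gaining methylation during differentiation
(gain regions start from the hypomethylated baseline 1 − 0.8 — a saturated
CpG cannot gain); planted blocks of 6–12 consecutive CpGs spanning at least
85 bp (matching the lower end of realistic DMR sizes); NOMe GCH emission
0.5 in open vs 0.05 in closed chromatin at 20× coverage, with more planted
NDRs in macrophage than monocyte (mirroring the direction of the real
contrast); paired BS/oxBS counts at planted (5mC, 5hmC); a TFBS track
hitting 90% of planted DMRs by default over a configurable background
density; and three histone-signature classes (class 1: gain
H3K27ac/H3K4me1/H3K4me3, lose H3K27me3; class 2: the same gains with
constitutive H3K36me3; class 3: constitutively active, H3K4me1 reduced)
with Gaussian bin noise (σ = 0.3 by default).

Counts are Binomial(Poisson(coverage), f·(1−ε) + (1−f)·ε) with a symmetric
bisulfite conversion error ε = 0.005; an optional per-donor baseline shift
(default 0.02, switched off in oracle analyses) mimics donor-level
variance. Every generator is a pure function of (params, seed).

Deliberately **not** emulated: CpG depletion and CpG islands (sequence is
i.i.d. at the chosen GC content, so CpGs are ~4× denser than in mammalian
genomes — the reason the analysis bandwidth is scaled down, above);
read-length autocorrelation in coverage; SNPs, copy-number and mapping
artifacts; genuine spatial correlation of background methylation. Passing
recovery tests therefore demonstrates the *procedures* are correct and
calibrated on data satisfying their assumptions, not that the defaults are
optimal for any particular real genome.

## Problem sizes and numerical tolerances

The test-suite and acceptance analyses use a 300 kb genome / 20 planted
DMRs for methylation (≈13k CpGs, 2 vs 2 samples at 30×), a 1 Mb genome /
10–20 planted NDRs for NOMe (≈94k GCH sites at 20×), 100-replicate oxBS
simulations at 10⁴ reads, 90-region signature matrices, and 10³–2·10⁴
permutation sets — sizes at which every stage completes in seconds while
binomial sampling error is far smaller than the planted effects. Exact
recursions are verified against brute-force enumeration (all 2ⁿ HMM paths
for n ≤ 10; all 2×2 tables with row sums ≤ 30 for Fisher, agreement to
10⁻¹²); EM monotonicity is asserted to 10⁻⁶; forward/backward posteriors
sum to 1 within 10⁻⁹. k-means ties and degenerate inputs (identical rows,
empty regions, zero-coverage sites, contig edges) are exercised explicitly.

## Known limitations

- The per-CpG normal reference for the t-like statistic is approximate at
  n = 2 + 2; the variance floor + smoothing makes it conservative in
  practice (the null-genome false-call rate is ~0 in the calibration
  tests), but it is not an exact test.
- The eFDR has resolution 1/(pooled null size); with few shuffles and few
  candidates the smallest achievable non-zero eFDR is coarse. The minimum
  candidate width (4 GCH sites) is what keeps the shuffled-data floor away
  from 0; without it, exchangeability puts the best observed p below all
  null p with probability ≈ 1/(n_shuffles + 1).
- Permutation enrichment treats query regions as independent; overlapping
  or clustered queries inflate significance.
- The 5hmC estimator is per-site ML with clipping, not hierarchical; at
  low depth and small true 5hmC the clipped mean is biased upward.
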
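# Methods

## Elements and phenotypes

Transcribed regulatory elements are called from the aggregate
(summed-across-individuals) stranded 5′-count track. Bases with count ≥
`min_count` are peak candidates; same-strand candidates chained within
`merge_window` (default 60 bp) collapse to the maximum-count base (leftmost
on ties), carrying the cluster's summed count. Minus-strand peaks are
paired with the nearest plus-strand peak strictly downstream within 300 bp,
greedily by ascending gap, each peak used at most once; unpaired peaks are
discarded. This concrete algorithm is this package's own design: it is
deterministic, respects the 300-bp divergent-pairing constraint, and on the
synthetic generator recovers planted midpoints exactly at default depth.
One peak never belongs to two elements.

Two phenotypes are computed from fixed midpoint-relative windows (plus
[1, 250], minus [−250, 0], class-independent):

- **Level.** Plus + minus window counts per individual, divided by that
  individual's per-million total over all tTRE windows (RPM), then quantile
  normalized. The quantile-normalization reference is the rank-wise mean of
  the median-of-ratios-scaled matrix; size factors use the *arithmetic*
  per-row mean (not a geometric mean) — ratios of each element's count to
  its cross-sample mean, per-sample median. Ties in quantile normalization
  receive the mean of the tied reference values, which makes the transform
  deterministic and idempotent.
- **Directionality.** DI = log₂((plus + pc)/(minus + pc)) on *raw* window
  counts (the ratio cancels sequencing depth), pseudocount pc = 1 by
  default so zero-count windows stay finite; quantile normalization
  downstream absorbs the scale. DI is exactly antisymmetric under strand
  swap.

Promoter/enhancer classification offers two routes: distance to annotated
gene TSSs (promoter ≤ 500 bp from either nTSS, enhancer > 2 kb, the band
between stays unclassified), and a stable-RNA (CAGE-like) route in which
per-nTSS depth-normalized stability counts are compared with an empirical
background built from nTSSs ≥ 1 kb from annotation, with empirical
p = (#{background ≥ observed} + 1)/(B + 1) and BH control at FDR 0.1.

## Association model

Associations are ordinary least squares of phenotype on alt-allele dosage
with k phenotype principal components as covariates. By Frisch–Waugh this
is computed as a simple regression after residualizing both sides on the
centered covariates; the dosage *t* is referred to *t*(n − k − 2). Missing
dosages are mean-imputed per variant (fraction logged). Cis windows are
2 kb from the element midpoint for level/directionality and 200 kb for
expression; BH is applied across all pairs tested in a run (the
conservative multiplicity universe), with FDR 0.1 (ti/di) and 0.05 (e).
The PC count can be scanned (k = 0..k_max, maximizing discoveries), but a
fixed k from configuration is the reproducible default.

The local-minimum filter tiles each contig with 5-kb windows staggered by
1 kb (every SNP lies in five windows). A SNP's best p across elements
competes; a SNP survives iff it is the *strict* minimum in at least one of
its windows, and exact ties at a window minimum eliminate all tied SNPs
from that window. Reading "survives if minimum in ≥ 1 window" (union over
windows) is an interpretive choice; the exhaustive-enumeration oracle test
pins the behavior.

## Variable expression

For each element, absolute deviations from the mean within replicate pairs
are compared with absolute deviations across distinct samples by a
one-sided Wilcoxon rank-sum test ("samples spread more than replicates").
Two corrections keep the null exchangeable: a pair's two deviations are
identical in magnitude, so each pair contributes one value (|a − b|/2), and
deviations from a g-member mean carry factor √(1 − 1/g), which is divided
out of both kinds. Without these, equal replicate and sample noise does not
give calibrated p-values. Deviations are computed on quantile-normalized
values. Absolute (not squared) deviation is used.

π₀ — the non-variable fraction — has two estimators. The default is the
tail density: the mean over λ ∈ {0.5, …, 0.9} of #{p > λ}/((1 − λ)m),
clipped to [0, 1]; it is robust to the discreteness of rank-sum p-values
but is an upper bound on π₀ whenever the alternative leaks mass into the
tail. The second (`method="bum"`) is a Beta-uniform mixture fit,
f(p) = π₀ + (1 − π₀)·a·p^(a−1), profiled over the shape a with the mixture
weight fitted by 1-D concave MLE; among shapes within 2 log-likelihood
units of the optimum the largest π₀ is reported, which resolves the
identifiability ridge of near-uniform alternatives toward the null. The
mixture fit recovers the true mixing weight of continuous mixtures — for a
Beta(0.1, 1) alternative the tail density converges to
π₀ + (1 − π₀)·0.1 rather than π₀, an irreducible bias of any tail-density
estimator — but it assumes continuous p-values and can misfit strongly
discrete ones, hence it is not the default.

## Architecture analyses

QTL positions are binned (default 10 bp; per-base available) by offset to
the nearest element midpoint within ±2 kb. The background band draws the
same number of positions from all SNPs in the same windows, n_resample
times (default 10,000); the per-bin 0.5% and 99.5% quantiles form a 99%
band. Promoter profiles can be oriented dominant-strand-downstream, where
the dominant strand is the one with the higher window count summed over
individuals.

The ±2-kb window partitions into center (midpoint ± 25 bp), core (each
nTSS ± 25 bp), NCNC (inside the element, neither center nor core), out
(within the outermost nTSS ± 200 bp margin), and far-out (beyond, to
±2 kb), with precedence center > core > NCNC > out > far-out so narrow
elements resolve cleanly. Region frequencies (QTLs/SNPs) are each compared
with far-out by two-sided Fisher's exact test. Overlap enrichment between
element sets is a rate ratio with a Fisher p; expression-association
enrichment of SNP classes is a −log₁₀ QQ comparison with a two-sided
two-sample Kolmogorov–Smirnov test; tTRE–gene co-expression is the Pearson
correlation across matched individuals for all pairs within 1 Mb, with
distances signed by the gene's strand.

## Sequence scoring

PWMs are built from position frequency matrices with pseudocount 0.8
distributed by the background and scored as log-odds. TF motifs use log₂
(bits) with a uniform background; the "strong match" threshold of 13 is
interpreted in bits (the base of the original threshold is not
recoverable; both base and threshold are configurable). Allele deltas fix
the stronger allele's best placement (both strands, leftmost-forward
tie-break) and score both alleles there; the delta is high-phenotype minus
low-phenotype allele and is exactly antisymmetric in the labels.

Initiator likelihood uses a natural-log PWM and likelihood e^score, scanned
forward-only in the strand-oriented TSS window; the likelihood difference
filter (> 5) reproduces the boundary case e^ln6 − e^0 = 5. The TATA-like
score is tiered: TATA = 4; single A↔T inversion = 2; two inversions = 1;
anything else 0, where "inversions" are defined only within {A, T} so any
C or G anywhere scores 0. Windows are the 21-bp region 40–20 bp upstream
of the nTSS on its strand (reverse-complemented for minus-strand nTSSs),
scored by the maximum over 4-mer offsets.

Match p-values P(random background sequence ≥ score) are computed by exact
dynamic programming on an integer-discretized score distribution (10⁻⁹
granularity, ties at the threshold counted as matches within L units of
rounding slack); when the support would exceed 500,000 states the
granularity coarsens automatically and the computation restarts. Agreement
with full 4^L enumeration is tested to 1e-9 for L ≤ 5. Motif-disruption
counting calls a variant disruptive for a motif when one allele matches
significantly (match p < 0.01) and the alleles differ by ≥ 0.5 bits;
disruption rates in QTLs are compared with random same-region SNPs
(±200 bp of midpoints), motifs with rate ratio > 1.2 flagged enriched.

## Synthetic data

The generator encodes the study design: 67 individuals with 8 replicate
pairs (replicates are independent negative-binomial draws from identical
means, modelling libraries grown from independent cultures); divergent
elements with nTSSs ±70 bp from the midpoint; read 5′ ends scattered with
two-sided geometric decay (scale 5 bp — a typical initiation-site spread);
negative-binomial totals with dispersion 0.2 (var = μ + 0.2μ², a typical
molecular-count reproducibility level; the real variance structure of such
data across individuals is not established, so this is a modelling
choice); baseline 100 counts per strand per element per individual.

Level effects act multiplicatively per allele as fold^(dosage/2) so the
homozygote ratio equals the configured ~2-fold. Directionality effects add
`di_logit_shift` (default 1.0 per allele — a clearly detectable but not
saturating shift) to the log-odds of plus-strand allocation of the
element's total, preserving total initiation and thereby isolating
directionality from level. Planted causal variants are placed where the
bipartite model says they act: level effects at the midpoint ± 25 bp,
directionality effects at an nTSS ± 25 bp (placement "any" is available).
Genotypes are independent Binomial(2, f) sites with f ~ U(0.05, 0.5);
expression is intercept + β·dosage + Gaussian noise for genes within
200 kb of their driver. Same seed, same bytes.

What the generator does **not** emulate: linkage disequilibrium (sites are
independent, so QTL localization is easier than in real cohorts), mapping
bias and mappability structure (the mask generator stands in), unpaired or
unidirectional elements, overlapping elements, batch effects, and any
relationship between element class and signal shape. Passing tests on
synthetic data therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on real libraries.

## Problem sizes and calibration

The end-to-end checks run the default conditions: 100 elements, 67
individuals, 2,000 variants on a 1-Mb contig — sizes chosen so a full
planted-plus-null pass completes in seconds while leaving every stage
statistically meaningful. Recovery thresholds for planted QTLs (ti ≥ 0.30,
di ≥ 0.90 at FDR 0.1) were frozen after a 16-seed calibration run of those
conditions (observed ti recovery 0.35–0.85, mean 0.70, the spread driven
by low-MAF draws at n = 67; di recovery 1.0 throughout).

## Known limitations

- No kinship/mixed-model correction and no conditional fine-mapping; the
  local-minimum filter is a heuristic primary-SNP proxy.
- The peak caller has no unidirectional-element rescue and no
  chromatin-mark integration.
- `classify_by_stability` assumes the stability track shares the signal's
  contig and depth conventions.
- Fisher tests treat SNPs as exchangeable units; LD would invalidate the
  independence behind the resampled bands on real data.
- The BED writer stores element class in the name field (`id|class`), a
  package convention rather than a BED standard.
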
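# Methods

This note records the models behind each stage, the conventions and
numerical choices the code commits to, and what the synthetic-data
experiments do and do not demonstrate.

## Data model and conventions

Genotypes are allele-1 dosages in {0, 1, 2} with −1 as the missing sentinel;
haplotypes are 0/1 with no missing values (phased-input contract). All
coordinates are 1-based inclusive internally, matching `.bim`; BED exports
convert to 0-based half-open. Genetic positions are centiMorgans; when a
`.bim` carries none, a uniform 1 cM/Mb map is applied (configurable), and
Morgans = cM/100. Every statistic defines its own complete-case rule, stated
on the operation.

## QC

The four filters run in a fixed order: (i) relatedness — from each pair with
IBS > 0.99 the member with the lower call rate is dropped, ties to the later
sample index; (ii) MAF < 0.01, computed on non-missing alleles after the
sample removals; (iii) call rates — SNPs below 95%, then samples below 90%;
(iv) unmapped SNPs (chromosome "0" or non-positive position). The order and
the tie-break are package decisions; the filter thresholds are the analysis
defaults and all are configurable. IBS(i,j) is the mean over jointly called
SNPs of 1 − |g_i − g_j|/2.

LD pruning is greedy within 50-SNP windows advanced 5 SNPs at a time: any
still-kept pair with r² > 0.5 loses its later member. r² here and everywhere
else is the squared Pearson correlation of diploid dosages over jointly
non-missing samples (composite/genotypic LD); haplotype-EM r² is out of
scope.

## Runs of homozygosity

A 50-SNP window passes if it holds ≤1 heterozygous and ≤5 missing calls. A
SNP is a homozygosity candidate when ≥5% of the windows covering it pass
*and the SNP itself is not heterozygous*. Maximal candidate runs are split
at inter-SNP gaps > 1 Mb, then filtered to ≥1 Mb, ≥80 SNPs and ≤100 kb per
SNP (length/n_snps). The non-het condition is a deliberate sharpening: with
hit-fraction smearing alone, segment edges extend tens of SNPs into
heterozygous flanking sequence and planted-segment boundary errors exceeded
100 kb; requiring the SNP itself to be non-heterozygous pins edges to
homozygous sequence while still tolerating isolated hets inside a run
through the window allowance. The 5% hit fraction is the common default for
this window scheme; it is a convention here, not a derived quantity.

F_ROH divides a sample's summed ROH length by 2.45 Gb of autosome (the
sheep autosomal genome length); samples without ROH get 0. The SNP-based
inbreeding coefficient is F = (O_hom − E_hom)/(L − E_hom) with
E_hom = Σ(1 − 2p(1−p)); it is undefined (NaN) when L = E_hom. H_E is the
uncorrected 2p(1−p) (no 2n/(2n−1) factor) by design; a corrected estimator
would shift the dataset mean by under 1% at study sample sizes.

## LD decay and N_e

Within-chromosome pairs up to a maximum distance (default 1 Mb) are binned
by bp distance; above a pair cap (default 5×10⁵) a seeded random subset is
scored. Sved's relation N_e = (1/4c)(1/r² − 1) converts a bin's mean r² at
its midpoint distance c (Morgans) into the effective size t = 1/(2c)
generations ago. An optional r² − 1/n sample-size correction exists but is
off by default, matching the plain form of the equation. r² = 0 yields no
finite N_e (NaN); zero-distance bins are dropped.

## PCA and admixture

PCA mean-imputes missing dosages, centres by 2p̂ and scales by
√(2p̂(1−p̂)) (Patterson scaling), drops monomorphic SNPs with a warning,
and takes the SVD; explained fractions are eigenvalue shares of the total
variance, so they are non-increasing and sum to ≤1.

The admixture likelihood is the standard binomial mixture
L = Σ_{il} [g ln f + (2−g) ln(1−f)], f = Σ_k q_ik p_kl, maximised by plain
EM block updates from a seeded Dirichlet/uniform start. Plain EM (not
quasi-Newton acceleration) is a deliberate simplicity trade: the likelihood
is identical and monotone convergence is guaranteed and asserted in tests;
slower convergence is acceptable at desk scale. Frequencies are clipped to
[1e−6, 1−1e−6]; iteration stops at ΔL < tol (default 1e−4) or max_iter.
Missing genotypes are skipped in the likelihood. K = 1 is closed form
(pooled frequencies).

Cross-validation masks a seeded 10% of called genotype entries per
replicate, fits on the remainder, and scores the mean squared error between
masked dosages and 2·QP. This is masked-entry CV in the spirit of the
standard admixture tool; the exact deviance loss of that tool is not
reproduced bit-for-bit, so CV error *values* are not comparable across
implementations — only the argmin over K is meaningful. Best K is the
lowest replicate-mean error.

## Selection scans

**ROH islands.** The per-SNP cohort ROH frequency counts each sample once
regardless of overlapping segments. Islands are maximal runs of SNPs at or
above the 50% cut-off; an island is cohort-specific when it shares zero bp
with every island of the other cohort (book-ended contact is not overlap).

**Windowed F_ST.** Per SNP, the Weir–Cockerham (1984) two-population
variance components a, b, c are computed from observed genotype and
heterozygote counts; SNPs with fewer than two called genotypes in a group
are NaN. Windows (100 kb, step 10 kb, ≥5 SNPs) aggregate as the ratio of
sums Σa/Σ(a+b+c) — lower variance than the mean of per-SNP ratios; the
per-SNP-mean alternative is one flag away. Window values are Z-standardised
*genome-wide* and the upper-tail threshold (default mass 0.001, i.e. the
0.1% normal tail) is applied chromosome by chromosome; overlapping or
book-ended significant windows merge into regions scored by their maximum
z. The tail mass is configurable because the conventional description of
this cut-off ("top 0.001%") selects essentially nothing at realistic window
counts if read literally; 0.001 is the default reading, the literal one is
selectable.

**XP-EHH.** EHH of a haplotype set is Σ C(n_h,2)/C(n,2) over distinct
extended haplotypes from the core to x. In cross-population mode the set is
one population's entire sample, with the core SNP's allele included in the
extension identity (so the curve drops to the core-site homozygosity at the
first step); the value *at* the core is defined as 1, which keeps every
curve non-increasing from 1. iHH integrates the curve by trapezoid over
Morgans on both sides, truncating where that population's EHH falls below
0.05 or at an inter-SNP gap above 200 kb — truncation is per-population,
which keeps the population swap exactly antisymmetric (raw score is
ln iHH_A − ln iHH_B, computed as a difference of logs so the sign flip is
bit-exact). Scores are standardised by the genome-wide mean/SD of scored
SNPs; p = 2(1 − Φ(|z|)) (two-sided by default; the one-sided option
exists). SNPs with a zero integral on either side stay unscored. Candidate
clustering is greedy: the smallest-p unassigned significant SNP (p < 0.05)
collects all unassigned significant SNPs within 100 kb on its chromosome.

**Case-control GWAS.** Logistic regression of case status on dosage with
standardized age and reference-coded region/breed dummies, fitted by IRLS
(statsmodels); the dosage Wald z gives the p-value and a 99% CI.
Non-convergence and (quasi-)separation (SE > 100 or non-finite) leave the
SNP unscored. The Fisher exact alternative tests the 2×2 allele-count
table (two-sided, hypergeometric); the two tests are separate operations
because the source analysis describes both, and the pipeline default is the
logistic Wald. Significance gates — Bonferroni-adjusted p < α (default
0.001) and −log₁₀ p_raw ≥ 4.25 — are independent and individually
disable-able, because the two published thresholds cannot be reconciled
into one rule. Significant SNPs fall into fixed 100 kb tiles; adjacent
significant tiles merge, and each region carries its minimum-p SNP.

## Consensus and annotation

Interval merging coalesces overlapping and (by default) book-ended
intervals; a strict-overlap mode exists. Consensus regions are the
connected components of all four methods' intervals under that relation:
each component gets a flag per method present, keeps the union extent of
its intervals, and survives if ≥2 distinct methods are flagged. Component
extent equals the union of all member intervals — in a connected chain
every interval overlaps the chain, so no separate "supporting intervals
only" trimming arises. Region size is (end − start)/1e6 rounded half-up to
three decimals, the convention that reproduces published region sizes
exactly; gene-overlap, by contrast, requires ≥1 shared bp (book-ended
contact does not annotate), and the two conventions are deliberately kept
in separate modules.

Enrichment is the plain upper-tail hypergeometric with BH-FDR over tested
terms (zero-hit terms skipped). The DAVID web service's modified score and
database are not reproduced — they are versioned external resources — so
enrichment p-values are comparable only within a run against the supplied
background and term map.

## Synthetic-data generator

Per chromosome: SNP positions uniform, sorted, deduplicated; cM = bp×1e−6.
Ancestral frequencies p ~ U(0.05, 0.95); cohort frequencies follow
Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F). Each cohort has a founder
pool (default 30 haplotypes) whose per-SNP allele *count* is the randomized
rounding of p_k × n_founders — pinning the pool frequency to the model
frequency, because iid Bernoulli founders would add ~1/n_founders of
spurious drift on top of F (measurably inflating null θ to ~0.03). Sample
haplotypes are Markov mosaics over the pool: the copy source switches
between adjacent SNPs with probability 1 − exp(−ρ·Δ Morgan), ρ = 100
switches/Morgan by default, giving LD that decays smoothly over ~1 Mb.
Sweeps overwrite a named interval with one fixed founder haplotype in a
carrier fraction of one cohort's haplotypes; ROH copy haplotype 1 onto
haplotype 2 over an exponential-length segment (min 1 Mb). Genotypes are
haplotype sums. All draws flow from one seed; identical configs are
byte-identical.

Defaults emulate the study conditions: 2 × 74 samples; 3 × 50 Mb
chromosomes at 1 SNP/10 kb (a desk-scale genome at a 600 K-chip-like
density per Mb); near-zero cohort divergence (F = 0.01), because
phenotype-extreme cohorts drawn from one population show no genome-wide
differentiation — experiments that need divergence set F explicitly
(0.10 for the F_ST calibration, 0.15/0.20 for structure recovery).

What the generator does *not* emulate: mutation and recombination history
(no coalescent), genotyping error, allele-frequency spectra skewed by chip
ascertainment beyond the uniform U(0.05, 0.95), and background LD stronger
than ~1/n_founders (r² ≈ 0.03 at short range, lower than a real chip's
0.15–0.3). Passing tests therefore demonstrate the estimators' correctness
and calibration under the stated models, not performance on real chip data.
Two test-design consequences: the frequency-recovery bound (3 binomial SDs)
is checked with a 150-founder pool, since a small pool adds ~1/(6 n_f²) of
quantization variance the binomial bound does not budget for; and
planted-ROH boundary recovery uses a 100-founder pool, since background
chance-autozygosity (both haplotypes copying one founder) can abut a
planted segment and make its "true" boundary ill-defined.

## Problem sizes and numerical choices

Simulation-based tests run at 2 chromosomes × 2,500–5,000 SNPs and 50–100
samples per cohort; the sweep-recovery experiment uses 20 seeded runs of
74 + 74 samples; the CV experiment fits K = 1…6 with 5 replicates on
4 × 35 samples × 2,000 SNPs. These sizes make every stochastic check
reproducible in minutes while keeping the estimators in their intended
regime (≥5 SNPs per F_ST window, ≥80 SNPs per ROH, ~100 SNPs per EHH
integral). Ties: related-pair removal drops the later index; top-SNP ties
take the smaller bp; closest-gene ties take the smaller start. Degenerate
inputs: chromosomes shorter than one ROH window warn and yield no calls;
zero-variance F_ST windows and constant labels raise; empty cohorts raise.

## Known limitations

The window-hit ROH caller is one fixed reading of the published window
parameters (the hit threshold itself is unstated in the source analyses;
0.05 is this package's recorded choice). The F_ST tail, the GWAS gates and
the XP-EHH truncation follow common practice where the upstream tools'
exact settings are unknowable; all are config-exposed. Real-data headline
counts (e.g. numbers of candidate regions) depend on those tool internals
and on the deposited genotypes, and are out of scope here.
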
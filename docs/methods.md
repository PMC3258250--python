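# Methods

## Scope and data model

`eqtlkit` operates on three containers: a `GenotypeMatrix` (samples × SNPs
minor-allele dosages in {0,1,2}, NaN for missing, with per-SNP chromosome,
1-based position, allele pair and minor-allele designation), an
`ExpressionMatrix` (features × samples, values used exactly as provided — no
internal log transform; fold changes are ratios of group summaries on the
given scale), and a `PhenotypeTable` (control = 0 / case = 1). The minor
allele is defined from the loaded cohort as the lower-frequency allele, ties
breaking to the lexicographically smaller letter; re-designating the other
allele maps dosage d → 2−d. All genomic coordinates are 1-based and region
queries are closed intervals. Missing genotypes are excluded pairwise per
statistical operation, never imputed; the EM and haplotype routines drop
samples with any missing call in the SNP set (complete-case).

Readers/writers cover PLINK text PED/MAP, a sample × SNP dosage TSV, a
feature × sample expression TSV, a HapMap-style genotype text dialect and a
two-column phenotype TSV. Writers emit deterministic column order, so a
fixed dataset round-trips byte-identically.

## cis-eQTL scan

The association statistic is the tie-corrected Spearman coefficient: the
Pearson correlation of mid-ranks, computed directly from standardized rank
vectors (`rho = z_rank(x) · z_rank(y)`). A constant vector makes the
correlation undefined; such SNPs are reported with an explicit flag and
excluded from significance calls rather than propagating NaN. The nominal
two-sided p uses the t approximation `t = rho·sqrt((n−2)/(1−rho²))` on n−2
degrees of freedom for all n (the empirical null supersedes exactness in the
small-n regime); |rho| = 1 maps to the smallest positive float, never 0.

Significance is gene-level and empirical. For each of `n_permutations`
(default 10,000) shuffles of the expression vector across samples, the scan
is repeated over all cis SNPs and the minimum nominal p recorded. A SNP is
significant at permutation threshold PT (default 1e-4) if its observed
nominal p is below the PT-quantile of the null minimum-p distribution — with
10,000 permutations and PT = 1e-4 this effectively requires undercutting
every null minimum. Per-SNP empirical p-values use the +1 correction,
`(1 + #{null min-p ≤ observed p}) / (N + 1)`, so they live in
[1/(N+1), 1] and are monotone in the nominal p. Thresholding on the null
distribution of the minimum p (rather than of the maximum |rho|) is our
standardization; requesting PT below the permutation resolution triggers a
warning that the call reduces to "observed p below all null minima". When no
genotype or expression values are missing the permutation scan runs as one
rank-then-matrix-multiply pass over all SNPs and permutations; with missing
data it falls back to a per-SNP masked path with the same definition.

Genotype-group summaries report per-dosage n / mean / median, fold changes
as ratios of arithmetic group means (mean rather than median is the
default, and the only implemented choice), and a tie-corrected
Kruskal–Wallis H with a χ² p on (groups − 1) degrees of freedom. Additive
vs dominant patterns are reported descriptively through the three group
means; no formal model-selection test is attempted.

## Population-genetic statistics

Haplotype frequencies over k ≤ 8 SNPs are estimated by EM over unobserved
phase: each multi-heterozygous genotype is distributed over its compatible
haplotype pairs proportionally to the product of current frequencies
(Hardy–Weinberg proportions within the E-step); the M-step re-estimates
frequencies from expected counts. Initialization is the product of
single-SNP allele frequencies, which makes the fit deterministic — no random
restarts; multimodality for the small SNP sets used here is rare and left
to the reported log-likelihood to expose. Convergence is max absolute
frequency change < 1e-6 or 1000 iterations; the log-likelihood trace is
retained and is non-decreasing by construction (asserted in tests).

Pairwise LD uses the two-SNP EM: with p1, q1 the minor-allele frequencies
and p11 the minor/minor haplotype frequency, D = p11 − p1·q1,
r² = D²/(p1(1−p1)q1(1−q1)), and D′ = |D|/Dmax with
Dmax = min(p1(1−q1), (1−p1)q1) for D > 0 and min(p1·q1, (1−p1)(1−q1)) for
D < 0; D = 0 gives D′ = 0. Both statistics are invariant to which allele is
labelled minor. The Hardy–Weinberg exact test conditions on allele counts
and sums the probabilities of all heterozygote counts whose point
probability does not exceed the observed configuration's (the common
two-sided convention; no mid-p variant), computed by the standard ratio
recurrence.

## Case-control association

The allelic test builds the 2×2 minor/major × case/control allele-count
table; OR is the cross product with a Haldane–Anscombe +0.5 on zero cells,
the 95% CI is exp(log OR ± 1.96·sqrt(Σ 1/cell)), and p comes from the χ²
test on the uncorrected table. "Conditioned" association is covariate
adjustment in an ordinary maximum-likelihood logistic model — status on
additive dosage terms for the test SNP plus conditioning SNPs — not a
matched-set conditional likelihood; the conditioned p/OR are the test SNP
term's Wald statistics. The fit guards against rank deficiency (e.g.
conditioning a SNP on itself or a perfect-LD partner), perfect separation,
non-convergence (log-likelihood tolerance 1e-8, 100 Newton iterations) and
classes smaller than 10 samples.

Haplotype association estimates EM frequencies separately in cases and
controls, converts them to expected chromosome counts (2n × frequency), and
tests each haplotype against all others in a 2×2 χ² with a cross-product OR
(+0.5 on small cells). This expected-count construction is simpler than a
score test over posterior phase probabilities and slightly understates
phase uncertainty — a documented limitation; it recovers simulated odds
ratios well (see validation). Haplotypes at pooled frequency ≤ 0.05
(configurable) are suppressed from reports, but their mass still counts in
normalization.

## Synthetic cohorts

The generator produces the structures the analyses assume, not a model of
any particular real dataset. A `HaplotypePool` is an exact discrete
haplotype distribution: blocks are built as two-state Markov chains in which
an adjacent SNP pair with minor-allele frequencies p, q and correlation r
gets haplotype frequency p11 = pq + D with D = r·sqrt(p(1−p)q(1−q)),
feasible only when |D| ≤ min(p(1−q), (1−p)q) — infeasible requests raise an
explicit error rather than clipping. For a block of length L with requested
within-block r² = c, adjacent pairs get r = c^(1/(2(L−1))); binary Markov
chains multiply correlations, so every within-block pair attains r² in
[c, c^(1/(L−1))]. Blocks are mutually independent. Because the pool is
exact, LD and allele frequencies have closed forms to compare estimates
against.

Individuals are two independent haplotype draws (no inbreeding,
no relatedness, no population admixture). Expression is
baseline × fold(dosage) × exp(ε), ε ~ N(0, noise_sd²): lognormal noise keeps
expression positive and makes effects multiplicative, matching how
fold changes are interpreted; additive mode multiplies by
`per_allele_fold` per copy, dominant mode once for any carrier. Case-control
cohorts are rejection-sampled: disease odds are multiplied by the odds
ratio per copy of a risk haplotype (log-additive), with `*` wildcards
allowing risk to attach to a single SNP allele; quotas that cannot be
filled raise after a bounded number of draws. Every operation takes its own
integer seed and there is no global random state, so identical seeds give
identical outputs down to written bytes.

Default settings mirror the study conditions the package is validated
under: cohorts of 45–120 samples for eQTL scans (the HapMap-population
range), MAFs around 0.17–0.31, per-allele expression folds near 1.8 with
lognormal noise sd 0.3, and case-control cohorts of 1000–2000 per arm with
haplotype ORs near 2–2.7. What the simulations do **not** emulate: batch and
normalization artifacts, probe cross-hybridization, relatedness or
population structure, genotyping error, and trans effects — so passing
validation demonstrates the statistics behave as designed under their own
assumptions, not that any real-data preprocessing is handled.

## Validation studies and sizes

`eqtlkit.validation` packages the end-to-end checks used by both the test
suite and `scripts/acceptance.py` (all sizes chosen to exercise the
asymptotics meaningfully while staying desk-scale):

- Spearman vs an independent implementation: 1000 random tied vectors,
  agreement to 1e-12.
- Permutation-threshold calibration: 200 independent null genes × 50 cis
  SNPs in LD blocks, n = 100, 1000 permutations, PT = 0.05; the fraction of
  genes with ≥ 1 significant SNP should sit in the 95% binomial band around
  0.05.
- Effect recovery: per-allele fold 1.8, n = 500, noise 0.3, 50 replicates;
  mean estimated homozygote fold change vs 3.24 and causal-SNP top-hit rate.
- EM haplotype recovery on a known two-SNP pool (0.4/0.1/0.3/0.2),
  n = 2000, plus the closed-form LD of the exact pool (D = 0.05,
  r² ≈ 0.0476, D′ = 1/3).
- Conditional-analysis logic: causal risk SNP (OR 2) with an r² = 0.8
  proxy, 2000/2000, 100 replicates; the proxy should be strongly associated
  unconditionally and null once conditioned.
- Haplotype OR recovery: risk haplotype frequency 0.15, OR 2.67, 2000/2000,
  100 replicates.
- Hardy–Weinberg exact test vs complete enumeration for all configurations
  with n ≤ 30 (5455 tables).
- Kruskal–Wallis worked example (H = 7.2).

## Known limitations

- No trans-eQTL scanning, covariate-adjusted expression residualization, or
  multi-tissue modelling; no VCF/BGEN/binary-PLINK input, imputation, or
  build liftover.
- The haplotype association differs in detail from score-test
  implementations that integrate over phase posteriors.
- Printed odds ratios in published association tables often come from
  models with unstated covariates; the allelic cross-product OR here is
  defined purely by the 2×2 allele counts and is not expected to reproduce
  such values.
- EM with deterministic initialization can in principle converge to a local
  optimum; the reported log-likelihood is the diagnostic.
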
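# Methods

`stratenrich` implements a stratified case/control pathway-enrichment
analysis for genotype data, together with a synthetic-cohort generator used
to validate the whole chain end to end. The pipeline has five stages:
quality control, per-SNP association, gene-level statistics, gene-set
enrichment, and a stratified orchestration that assembles a fixed 12-cell
report (3 phenotype contrasts x 4 enrichment tests).

## Study design

Cases belong to one of two radiologic strata — an "MLI/LA"-like stratum
(multiple lacunar infarcts or confluent leukoaraiosis) and an "ILI"-like
stratum (isolated lacunar infarct) — plus an optional unclassified group
that enters only the all-cases contrast. Every contrast compares one case
group against the full shared control set. The family of primary analyses
is fixed at 12 (3 contrasts x {top-1%, top-5%, top-10%, GSEA}); the
per-test significance threshold is alpha/12, i.e. 0.0042 at the default
family-wise alpha = 0.05. Subcomplex scans are follow-up analyses: they run
only in strata whose top-1% pathway test is significant, are reported with
raw p-values, and never enter the 12-test multiplicity family.

## Synthetic cohorts

The generator is first-class, tested code; its defaults define the study
conditions for the validation experiments.

**Genotypes.** SNPs are laid out in gene blocks (default 5 SNPs per 10 kb
gene, 30 kb intergenic gaps, 1,000 genes per synthetic chromosome). Each
haplotype of a gene block is a latent AR(1) Gaussian vector with lag-one
correlation `ld_rho` (default 0.8), thresholded at the allele-frequency
quantile; the two haplotypes of an individual are independent, so genotypes
are Hardy–Weinberg within each subpopulation, and LD decays geometrically
with SNP distance inside a block and vanishes across blocks. Allele
frequencies are uniform on `maf_range` (default 0.05–0.5). Population
structure, when requested, follows the Balding–Nichols model with
F = `structure_shift` over two subpopulations. A configurable fraction of
non-causal variants (default 5%) is written with A/T or C/G alleles to
exercise the strand-ambiguity filter; optional switches add exact-duplicate
samples (for the relatedness filter) and case-biased missingness (for the
differential-missingness filter). Base missingness is completely at random.

**Phenotypes.** Disease follows a logistic liability: log-odds =
alpha + log(OR) per alternate allele at each causal SNP, with alpha solved
numerically so the population prevalence equals `baseline_prevalence`
(default 0.1). Stratum-A cases are ascertained by accept/reject sampling
against this liability; stratum-B cases, unclassified cases and controls
are population draws with no genetic effect. This plants the pathway signal
exclusively in stratum A, the qualitative pattern the pipeline is meant to
recover. Causal genes (default 10) are a subset of the focal pathway
(default 20 genes); causal SNPs (default 1 per causal gene) are spread
evenly across the gene block, because adjacent picks are nearly redundant
under AR(1) LD. The per-allele odds ratio is a free parameter (default 2.0,
chosen so that cohorts of a few hundred cases give detectable aggregate
signal at desk scale).

**What the generator does not emulate:** realistic recombination-driven LD
(haplotype blocks with hotspots), a realistic allele-frequency spectrum,
imputation dosage uncertainty, relatedness beyond exact duplicates, or
continuous ancestry clines. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under a clean,
controllable genotype model — not robustness to every pathology of real
array data.

## Quality control

Variant filters (any failure excludes the variant, all inequalities
strict): MAF < 0.01 over non-missing calls across all samples; missingness
> 3%; Hardy–Weinberg exact p < 1e-6 in controls (Levene–Haldane two-sided
exact test, summing the probabilities of heterozygote counts no more
probable than the observed one, conditional on allele counts);
strand-ambiguous (A/T, C/G) alleles; differential missingness p < 0.05 by a
two-sided exact 2x2 test (missing/observed x case/control). The exact test
is used for differential missingness because per-SNP missing counts can be
tiny; an asymptotic chi-square would misbehave there.

Sample filters, applied in a fixed order so each removal has exactly one
primary reason: missingness > 3%; heterozygosity |z| > 3 SD of the sample
het-rate distribution (no standard cutoff exists; 3 SD is common GWAS
practice and configurable); pairwise pi-hat > 0.1875. Pi-hat is the
method-of-moments IBD estimate from IBS class counts and sample allele
frequencies; only the combined estimate P(IBD=2) + P(IBD=1)/2 is truncated
to [0, 1] — truncating the component probabilities individually would bias
unrelated pairs upward, which matters at desk-scale SNP counts. For a
flagged pair the member with higher missingness is removed (ties:
lexicographically later id), highest pi-hat first.

LD pruning is greedy over sliding windows (default 50 SNPs, step 5,
r² > 0.2 removes the later-position SNP), with optional caller-supplied
long-range-LD exclusion intervals (the canonical human list is meaningless
for synthetic chromosomes, so the intervals are an argument, not a
constant). Ancestry outliers are removed iteratively (up to 8 iterations):
PCs are computed on the pruned, EIGENSTRAT-standardised matrix (centre by
2p, scale by sqrt(2p(1-p)), missing to zero), samples beyond 6 SD on PC1 or
PC2 are dropped, and the loop stops early when nobody is removed. The final
PCs, recomputed on the retained samples, feed the association stage. All
downstream results are invariant to PC sign flips. A 6-SD rule can only
fire on outlier fractions below ~1/37 (the standardised deviation of a far
cluster of fraction f is sqrt((1-f)/f)); the test fixtures respect this.

## Association

Each SNP is tested with a 1-df logistic score test of the additive dosage
term: the null model (intercept + first 2 PCs) is fitted by IRLS, and
chi² = U²/V with U = g'(y - p̂) and V the efficient information of the
dosage term. The score test was chosen over Wald/LRT because it only
requires the null fit, is well behaved at low minor-allele counts, and
reduces exactly to the Cochran–Armitage trend test when the null model is
intercept-only — the test suite pins this equality to 1e-8. Samples with a
missing call are dropped for that SNP and the null model is refitted on the
SNP's observed subset (a batched, masked IRLS fits thousands of such nulls
simultaneously), so every statistic depends only on samples with observed
dosage. SNPs monomorphic in the analysis subset, or with fewer than two
cases or controls after the drop, are reported untestable and excluded from
gene sums — assigning them chi² = 0 would deflate gene statistics
non-informatively.

## Gene-level statistics

Genes collect the association chi-squares of SNPs within their body ±50 kb
(1-based inclusive bounds; a SNP may belong to several overlapping
windows). The observed gene statistic is the plain sum. Its null is
simulated: draw a zero-mean multivariate normal with covariance equal to
the gene's SNP–SNP dosage correlation (pairwise-complete Pearson, estimated
from the post-QC samples of the analysed contrast, since no external LD
reference exists for synthetic data), square and sum the coordinates. The
empirical p is the proportion of simulated sums >= the observed sum (ties
count as exceedance; a (r+1)/(n+1) variant is available behind a flag).
Correlation matrices are repaired to positive semi-definite by flooring
eigenvalues at 1e-8 and rescaling to unit diagonal — duplicated or
near-duplicate SNPs otherwise break the Cholesky factor. Simulation counts
escalate 1e3 -> 1e4 -> 1e5 while fewer than 10 exceedances have been seen,
bounding the relative error of small p-values. Each gene consumes an
independent child random stream keyed by its rank in the gene-id ordering,
so results are reproducible and invariant to input row order. Two analytic
limits anchor the machinery: identity correlation gives the chi-square_k
tail, and a perfectly correlated block of k SNPs collapses to k times a
single chi-square_1.

## Enrichment

Genes are ranked by ascending empirical p, ties broken by larger observed
sum and then lexicographic gene id. The top-q% cut is m = round(qN/100),
minimum 1. The percentile test counts focal-set members among the top m and
compares against random gene sets of the same size drawn uniformly without
replacement from the universe (genes with >= 1 testable SNP). Matching on
count only is deliberate — it mirrors sampling "gene sets of the same
length" — and leaves the known gene-size/SNP-count confounding of this
scheme uncorrected; the permutation null is then exactly hypergeometric,
which the tests exploit as a closed-form oracle. Permutations start at
1,000 and rerun at 10,000 (fresh derived seed) whenever the initial p is
below 0.05; both stages are recorded. Empirical p-values are plain
proportions and can reach 1.

The GSEA variant ranks genes by s = -log10(p) (empirical zeros replaced by
half their simulation resolution, 0.5/n_sims) and walks a running sum: hits
increment by s^w / sum of hit s^w (weight w = 1 by default), misses
decrement by 1/(N-k). The enrichment score is the signed maximum deviation
from zero, and its null comes from the same random-set draws (gene-score
permutation, not phenotype permutation — phenotype permutation would
require re-running the entire association and gene stage per draw).

## Validation problem sizes

The replicate-based checks run down-scaled cohorts chosen to keep the whole
suite at desk scale: null calibration uses 200 studies of 100 cases per
stratum, 200 controls, 400 genes x 4 SNPs; signal recovery uses 50 studies
of 150 cases per stratum, 300 controls, 400 genes, with 10 causal genes of
2 causal SNPs each at OR 2.0. Two design points matter:

- **Null calibration focal set of 4 genes.** The pct1 permutation p is
  discrete: with a 20-gene set, the achievable levels near 0.05 at the 1%
  cut are 0.186 and 0.0135, so "rejection rate at 0.05" is uninformative.
  With k = 4 (universe ~400, m = 4) the largest achievable level below 0.05
  is 1 - C(N-m,k)/C(N,k) ~ 0.040, and the realised type-I rate can
  meaningfully be compared with the nominal level.
- **Signal-recovery gap of 60 kb.** With the default 30 kb gap, ±50 kb
  windows overlap neighbouring genes, and planted signal legitimately
  propagates into non-pathway neighbours' gene statistics, diluting
  top-percentile membership. The recovery experiment isolates windows
  (gap > 2 x 50 kb padding is not needed; 60 kb > 50 kb suffices for
  body-to-body distance) so that gene-level hits identify the planted
  genes. The default gap is kept at 30 kb precisely so that ordinary runs
  exercise multi-gene SNP sharing.

## Numerical choices and degenerate inputs

IRLS: fitted probabilities clipped to [1e-12, 1-1e-12], Newton steps until
the max coefficient change is below 1e-9 (batched) / 1e-10 (single), tiny
ridge 1e-12 on the information matrix. Score tests with V <= 1e-12 are
untestable. Monomorphic variants are excluded from pi-hat and PCA
standardisation. Empty gene universes, empty strata, sets empty after
universe intersection, and all-zero genotype count triples raise errors
naming the offending stage or filter. A sex-check step is a documented
no-op: the synthetic genome is autosome-only.

## Known limitations

Gene windows use the supplied gene bounds (transcript-level windows are not
distinguishable in BED input). The LD reference for the gene simulation is
the study itself, not an external panel. Random gene sets are matched on
count, not SNP content. The GSEA null reuses the random-set scheme rather
than phenotype permutation. Cohorts at real GWAS scale (tens of
thousands of genes, thousands of samples) are not reproduced at desk scale;
the validation targets calibration and recovery properties instead.
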
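# Methods

This note records the models, conventions, parameter choices, and known
limitations behind each stage of the package. Statements about behaviour
are the ones the test suite and `scripts/acceptance.py` actually compute;
nothing here reports a number the code does not produce.

## Synthetic panel

The generator emulates a population proteogenomics panel of fully inbred
maize lines; it is first-class, tested code, and its defaults define the
conditions every recovery claim is made under.

**Genotypes.** `PopulationConfig` defaults: 98 lines split 20/10/70%
across NSS/SS/TST-like subpopulations, 5,000 biallelic SNPs, ancestral
allele frequencies uniform on [0.05, 0.5], F_ST = 0.2, LD blocks of 5
SNPs, seed 0. Differentiation follows the Balding–Nichols model: each
subpopulation's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), so
Var(p_s) = F·p(1−p) and the pairwise Hudson estimator recovers F (the
test suite checks 0.3 ± 0.05). Lines are fully inbred: one allele is
drawn per line and doubled, giving dosages in {0, 2} with no
heterozygotes. LD blocks copy a block-founder SNP and flip each line's
allele with probability 0.02, giving high but tunable within-block r²
without haplotype machinery — adequate for pruning and clumping tests,
not a model of recombination-driven LD decay. F_ST = 0.2 is of the order
of the differentiation between temperate and tropical maize groups;
block size and flip rate were fixed once for convenient r² and never
revisited.

**Expression.** `ExpressionArchitecture` defaults: 2,000 genes, five
modules of 80/70/60/50/40 genes sharing a latent factor per module
(shared-variance fraction 0.55, which yields within-module correlations
around 0.5 and between-module |r| below 0.1), mRNA→protein coupling
ρ = 0.6 for every gene, measurement noise SD 0.3 on both levels, 20%
missing protein cells (iTRAQ-style missingness, but missing completely
at random — real missingness is abundance-dependent), and 7 replicate
line pairs generated as independent noise draws around the same line
signal. The protein matrix is
ρ·(mRNA signal) + √(1−ρ²)·(independent component); the independent
component carries the same module memberships driven by *new* factors,
so protein coexpression modules exist in their own right, as protein
complexes do, and module preservation between the two levels is high by
construction. Per-gene subpopulation differential expression is drawn
N(0, 0.3²) per (gene, subpopulation) independently for the mRNA signal
and for the protein-specific component; because the protein inherits the
mRNA shifts through ρ *and* adds its own, the proteome tracks the
subpopulations at least as strongly as the transcriptome, which is the
regime the subtype and SOM stages are meant to probe. With ρ = 0.6
essentially all per-gene mRNA–protein correlations are positive; the
generator does not emulate the wide, partly negative correlation
landscape of real panels, so concordance-stage tests check recovery of
the planted ρ and null calibration, not any particular positive
fraction.

**Planted cis effects.** `plant_cis_effects` picks one SNP (MAF ≥ 0.1)
inside each chosen gene's ±200 kb window; classes are mRNA-only, direct
protein, both, or *mediated* (the SNP perturbs the mRNA and reaches the
protein only through the coupling term). The default effect size is
β = 2 SD in the {0,2} dosage coding, i.e. 1 trait-SD per allele dose: a
strong, clearly detectable cis effect. A power analysis of the scan →
BH → clump → conditional-LRT chain at n = 100 shows the chain's
direct-effect recovery saturates near this size, while at β = 1 SD
(0.5 SD per dose) single-SNP power at the BH-scale thresholds is only
~0.4–0.5; the default therefore represents the "detectable pQTL"
condition the discrimination claims are about, and was fixed from that
analysis, not adjusted afterwards.

**Gene models.** Two chromosomes; genes are evenly spaced two-exon
models (5′UTR, two CDS segments, an intron, 3′UTR) spanning the
SNP-covered coordinate range, written as GFF3. Coordinates are 1-based
inclusive on disk, 0-based half-open internally.

## Quantitation and QC

Protein abundance per gene and line is the median of that gene's
*unique* peptides' ratios in that line; shared peptides never contribute.
Medians are taken on the linear ratio scale and stored as log2; an even
count of peptides uses the mean of the two central values. Genes
observed in fewer than ceil(0.5·n_lines) lines are removed; the filter
is idempotent. Replicate concordance uses Spearman correlation on
pairwise-complete genes per line pair; the permutation null re-labels
which unordered line pairs are called "replicate" among all pairs, and
p = (1 + #{permuted mean ≥ observed})/(B + 1) with B = 100,000 by
default, so p is never zero. Line-level distribution summaries (mean,
SD, skewness, quartiles) use observed cells only; no named unimodality
test is performed.

## Concordance

Per-gene Pearson correlation over pairwise-complete lines, requiring at
least 10 complete pairs (fewer stabilizes nothing and produces wild
p-values); BH adjustment over all tested genes. Category shifts use the
two-sample KS test of member vs non-member correlations (members
compared against the complement rather than the pooled set, avoiding
member/pool dependence), BH across categories, with a direction sign
from the member median against the global median. MAD ranking omits the
1.4826 consistency constant since ranking is scale-invariant; ties break
by gene ID.

## Coexpression networks

Before network construction, expression is adjusted for population
stratification: per gene, OLS residuals on subpopulation indicators
(groups with fewer than two lines are dropped from the design), then a
rank-based inverse-normal transform with Blom offsets
((r − 3/8)/(n + 1/4)), which gives near-unit sample SD. Missing cells
are mean-imputed per gene before correlation/PCA, with the imputed
fraction logged.

Biweight midcorrelation standardizes by median and MAD with Tukey
biweights (zero weight beyond 9 MADs); a vector with zero MAD falls back
to Pearson centering, and a constant vector is an error. Signed
adjacency is ((1 + c)/2)^β with β = 9 fixed by configuration (no
scale-free fit scan). TOM follows
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
k_i = Σ_{u≠i} a_iu; a brute-force double loop is the test oracle.

Modules come from average-linkage clustering of 1 − TOM with a
fixed-height branch cut. The default height is chosen automatically as
the midpoint of the widest gap in the upper half of the merge-height
distribution: the noise genes merge in a narrow band just below the
dendrogram top while module branches complete lower, and any fixed
fraction of the maximum height is brittle against the absolute scale of
the dendrogram (0.95 of max recovers a small dense scenario but misses
the full 2,000-gene panel, whose merges concentrate above 0.99; the gap
rule recovers both). A fractional cut remains available via
`cut_height_frac`. Clusters under 30 genes join an "unassigned" pool.
Eigengenes are the first right-singular vector of the row-standardized
module block, sign-oriented to correlate positively with the module mean
profile; modules whose eigengenes correlate above 0.85 merge
iteratively (best pair first). kME is the bicor of a gene with an
eigengene; genes join every module with kME > 0.4 (multi-assignment).
Labels are size-ordered M1, M2, …

Preservation of reference modules in a test dataset computes, per
module: density statistics (mean within-module correlation, mean
adjacency, eigengene variance explained, mean kME — all in the test
data) and connectivity statistics (reference-vs-test correlation of
intramodular connectivity, of within-module adjacency entries, and of
kME). Each statistic is Z-scored against 200 permutations drawing random
same-size gene sets *within the test dataset only* (the reference
module stays fixed); Z-density and Z-connectivity are the medians of
their groups and Z-summary their mean. medianRank ranks modules by each
observed statistic (1 = best preserved) and takes the median. The
interpretation thresholds (Z > 10 high, 2–10 weak-to-moderate, < 2
none) are checked by self-preservation and label-shuffle controls. Note
that between *identical* datasets the connectivity correlations of any
gene set are exactly 1, so a random-gene "module" is only a valid
negative control between independent datasets.

## Subtypes

Consensus clustering resamples 80% of samples and features, clusters
each draw by average linkage on 1 − Pearson distance, and accumulates
co-clustering frequencies among co-sampled pairs for k = 2..8. The area
under the consensus CDF is computed per k; k is selected as the largest
k whose relative delta-area gain exceeds 0.1 — an automated elbow in
place of visual inspection of the consensus matrices, and overridable. Final labels cluster 1 − consensus at the chosen k. Core
samples have positive silhouette width on the consensus distance;
singleton-cluster samples have undefined width and are non-core.
Signatures are one-vs-rest two-sided Wilcoxon rank-sum tests with
Bonferroni control at 0.05, skipping genes observed in fewer than three
samples per side.

The nearest shrunken centroid classifier is implemented directly:
standardized centroid deviations d_kg = (x̄_kg − x̄_g)/(m_k(s_g + s0))
with m_k = √(1/n_k − 1/n) and s0 the median pooled SD, soft-thresholded
by Δ, with class-prior-corrected discriminant scores. LOOCV picks Δ on
each training fold by resubstitution error over a 30-point grid;
because resubstitution error is flat over wide shrinkage ranges and both
extremes are degenerate (no shrinkage overfits, near-maximal shrinkage
leaves an epsilon-sized deviation whose prediction is dominated by the
class priors), ties resolve to the *median* tied Δ. Subtype–
subpopulation association uses two-sided Fisher exact tests per
(subtype, subpopulation) 2×2 table on core samples; the Mantel test of
expression distance against genetic distance permutes sample identities
(999 permutations, via scikit-bio).

## SOM integration

The six per-gene measurements (median mRNA and protein within each of
NSS/SS/TST; genes lacking any of the six are dropped) are converted to
percentiles by each column's ECDF, F(x) = rank/n with average ranks for
ties, mapping to (0, 1]. The map is an 11 × 8 toroidal hexagonal lattice
(88 units; offset rows, row spacing √3/2, distances minimized over the
nine torus translations). Online training presents each gene 100 times
with the learning rate decaying linearly 0.05 → 0.01 and a Gaussian
neighbourhood whose radius shrinks from half the lattice diameter to 1
(the kernel and radius schedule are this package's choices). Training
restarts from random initializations (default 50; the restart count is
configuration, and the selection property — the kept map minimizes mean
quantization error — is what tests assert, not the count) and keeps the
best map. Codebook vectors are clustered by affinity propagation on
negative squared distances with preference at the 0.1-quantile of
off-diagonal similarities, damping 0.9, up to 1,000 iterations; an
all-identical codebook short-circuits to a single cluster since the
similarity scale degenerates.

## QTL mapping

Kinship is the centered genomic relationship matrix ZZᵀ/m on per-SNP
standardized dosages (monomorphic SNPs dropped). The association model
is a single-variance-component mixed model; variance components are
estimated once per trait by REML on the covariate-only model using the
eigendecomposition of K (EMMA-style, optimizing the restricted
likelihood over log δ = log σ²_e/σ²_g on a bounded interval) and reused
for every SNP — the P3D approximation. Each SNP then gets a weighted
(GLS) regression t-test with the residual scale re-estimated per SNP,
which makes the scan *exactly* equal to OLS when K = 0 (oracle test at
1e-9) and keeps the null well calibrated under strong structure
(λ ∈ [0.9, 1.1], KS uniformity, checked at 100 lines × 500 traits ×
100 SNPs). Missing dosage cells are mean-imputed within the scan; lines
missing the trait are dropped per trait; SNPs below 5% MAF in the used
lines, or collinear with the covariates, are excluded.

BH control pools all cis tests per measurement level (one printed
threshold per level); the trans suggestive cutoff is
min(1, 10/(pruned markers × traits)). LD pruning is greedy within
50-SNP windows advanced by 50: while any pair exceeds r² = 0.1 the
lower-MAF member is removed (ties: later position) — the survivor set
satisfies the r² bound by construction, though the removal order differs
in detail from PLINK's heuristic. Clumping visits significant SNPs by
increasing p; each lead absorbs all remaining significant SNPs with
r² ≥ 0.1 (dosage-correlation squared, complete pairs).

The conditional test compares Y = αX + βP + γM + ε against
Y = βP + γM + ε by maximum likelihood on shared complete cases
(LRT = n·log(RSS_reduced/RSS_full) ~ χ²₁); both are plain linear models
— no kinship term — exactly as written, with population structure as
fixed covariates. Bonferroni adjustment runs across the tested lead
SNP–gene pairs; a significant adjusted p calls the QTL
protein-specific. Under a fully mediated null (SNP → mRNA → protein)
the nominal-0.05 rejection rate sits in [0.02, 0.09] (500 simulations),
and on the default generator the chain labels ≳ 95% of planted direct
effects and ≤ a few percent of mediated effects protein-specific
(acceptance script, 10 panels × 30 effects each).

SNP annotation uses each gene's longest-CDS transcript with precedence
CDS > UTR > intronic within the transcript span; positions inside the
±200 kb window but outside the transcript are extragenic. Enrichment
per category is the upper-tail hypergeometric probability with totals
taken from the supplied count table, computed in log space
(scipy `hypergeom.logsf`, verified against exhaustive log-sum-exp tail
summation). The printed pQTL count table reproduces its published
p-values to three significant digits from the column sums; the
corresponding eQTL column does not reproduce from its printed marginals
under any consistent reading of the printed totals, and the package
reports the value its stated inputs imply rather than the printed one.

## Set enrichment

Odds ratios use the Haldane 0.5 correction when any 2×2 cell is zero;
raw p is the hypergeometric upper tail. Family-wise adjustment resamples
query sets of the same size uniformly from the *explicit* background
(no default universe) B = 1,000 times, records each permutation's
minimum raw p across terms, and sets adjusted
p = (1 + #{min p ≤ observed})/(B + 1) — monotone in the raw p by
construction. Significance requires OR > 2 and adjusted p < 0.05.

## Problem sizes and determinism

Default analysis and acceptance sizes — 98–100 lines, 2,000 genes,
4,000–5,000 SNPs, 200 preservation permutations, 100–250 consensus
resamplings, 50 SOM restarts, 10–20 simulation seeds per recovery claim
— were chosen as the package's standard desk-scale configuration; all
stages accept larger values through their configs. Every random stage
consumes a NumPy `default_rng` seed derived from a single global seed
(CRC-stream per stage), and identical seeds give identical outputs
(bitwise for integer matrices; SOM training is bit-reproducible under a
fixed seed).

## Known limitations

* Raw spectra, spectral search, iTRAQ reporter correction, MRM
  processing, and RNA-seq alignment/quantification are out of scope; the
  pipeline consumes derived matrices.
* Missingness is MCAR; real proteomics missingness is
  intensity-dependent, so detection-filter behaviour on real data may
  differ.
* LD blocks are copy-with-flips, not recombination-based; r² decays in
  steps, not with distance.
* The mixed model has a single genetic variance component and the
  conditional LRT ignores kinship (as specified by its written model);
  strongly related panels could inflate the conditional test.
* The consensus-clustering elbow is automated where the procedure is
  often done by eye; on data with hierarchical substructure it
  can choose larger k than the planted number while still producing
  well-separated cores.
* Passing recovery tests on this generator demonstrates correctness of
  the machinery under the stated statistical structure, not performance
  on real maize data (real correlation landscapes, module sizes, and
  QTL architectures are broader and messier).
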
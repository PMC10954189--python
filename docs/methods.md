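# Methods

## The problem

On the avian Z chromosome, dosage compensation is incomplete: ZZ males carry
twice the Z dose of ZW females, and male:female methylation and expression
ratios sit well above 1 across most of the chromosome.  Against that
background, discrete male hyper-methylated (MHM) regions — runs of adjacent
windows with several-fold elevated male methylation — and their
female-biased mirror (FHM) stand out, and genetic variation in methylation
can be mapped as methylation QTL in a pedigreed cross.  This package
implements the full analysis chain on that design: window methylation
phenotypes, sex-difference block discovery, interval mapping with a
hemizygous Z, trans-hotspot aggregation, methylation–expression association
and causal edge orientation — together with a synthetic-study generator so
every stage is testable end to end without the raw sequencing data.

## Synthetic advanced intercross

The generator emulates an F8 advanced intercross founded by one wild male
and three domestic females, phenotyped at the study's sample size
(n = 124; 69 ZZ males, 55 ZW females).  Founders are fixed for alternative
alleles, so markers are fully informative.  Each generation draws sires and
dams with replacement; gametes recombine under the Haldane map function with
independent crossovers per marker interval.  Z transmission follows ZW
rules: fathers pass one recombined Z to all offspring, mothers pass their
single Z intact to sons and their W to daughters; every female is therefore
hemizygous at every Z marker (dosage in {0, 1}).  Consequences used as test
oracles: autosomal wild-allele frequency is 1/2 in expectation (every F1 is
heterozygous), and the Z-pool frequency converges to 2/3, the conserved
combination (2·p_males + p_females)/3 of its F1 value.  At realistic
population sizes, pedigree drift — not binomial sampling — dominates the
spread of realized frequencies, so frequency checks average over seeds.

Methylation counts are gamma-Poisson (negative binomial) per window with
mean ~25 reads — the expected read count of a 1-kb window at ~3.4× depth
with ~136-bp reads — and overdispersion α = 0.2 (variance μ + αμ²; α = 0
gives Poisson, and an `exact` noise mode returns the deterministic
expectation for identity tests).  Z windows carry a male:female dose ratio
of 1.7, the chromosome-wide average ratio of the real data.  Two batches
with a 10% mean shift exercise the batch covariate.  The desk-scale default
genome is 3 autosomes + Z with 12 markers (~16 cM spacing) and 200 1-kb
windows each.

Planted folds are specified on the *normalized* scale the analysis sees.
Because per-individual total normalization divides male counts by a larger
total (males carry more Z reads), a raw fold f would be observed as roughly
f divided by the male:female total ratio.  The generator therefore
calibrates raw multipliers by a short fixed-point iteration on the expected
totals, so a planted 3.3× MHM block realizes 3.3× after normalization.  Two
further consequences of this normalization are worth knowing because they
are real, not bugs: (i) autosomal windows acquire a weak spurious *female*
bias (male autosomal values are deflated by their larger Z-inflated totals) —
in the real genome the Z is ~8% of windows and the artifact is small, but in
the desk-scale genome the Z is 25% and block scans should be Z-restricted as
in the study; (ii) with sex-imbalanced totals, even a sex-neutral QTL has
slightly different allelic slopes per sex on the normalized scale, so
null-interaction calibration experiments use a sex-balanced genome
(Z dose ratio 1) to make the null actually hold.

Expression is log-normal per gene (baseline 500 units, log-SD 0.3) with
planted eQTL (additive ± sex-interaction allelic effects on the log scale),
optional couplings to a methylation window in either causal direction
(methylation→expression adds the standardized window to the gene's log
expression; expression→methylation regenerates the window as a linear
response to realized expression), and MHM-style male suppression of genes
within 100 kb of a planted block (half the block's log fold).

## Window phenotypes

Windows are 0-based half-open `[start, start+1000)`, labelled
`chrom_start`; this convention matches the shipped block tables, where a
block's printed size equals last-start + 1000 − first-start.  Counts are
normalized per individual: `value = scale × count / total`, with the scale
constant configurable (default 10⁶).  All level thresholds (the MHM median
floor among them) are in these configured units, because the absolute scale
of the original report's thresholds is not recoverable from the printed
numbers alone.  Totals are retained, so normalization round-trips exactly
and per-individual values sum to the scale constant.

## Sex-difference scan and blocks

Per window, the male-vs-female comparison is a two-sided Wilcoxon rank-sum
test: exact enumeration when both groups have fewer than 8 untied values,
the normal approximation with tie and continuity corrections otherwise
(at n = 124 the approximation is what matters; the exact path keeps the
statistic testable against brute force).  The M:F ratio uses arithmetic
means.  Block criteria follow the calibration on the originally known MHM
region: window median above 8.52 (configured units), p below 1.75e-10, and
five or more adjacent windows, where adjacent means start-to-start distance
of exactly one window size — a single failing window breaks a run.  The FHM
direction uses p < 0.05 with M:F ratio below 1 and no median floor.  Genes
within 100 kb of a block (closed boundary) are reported with per-gene
rank-sum sex-difference p-values, Holm-adjusted across genes and capped
at 1.

## QTL mapping

Interval mapping uses Haley–Knott regression on conditional genotype
probabilities.  The founder-origin process along a chromosome is Markov;
with fully informative markers the haplotype-level transition over distance
d is: retain the allele with probability 1 − r(d), else redraw from the
chromosome's allele frequency (1/2 autosomes, 2/3 Z), with r(d) from the
Haldane map function.  Genotype (dosage) transitions are products of two
independent haplotype chains — three states on autosomes and the male Z, a
single two-state chain on the female Z.  Pseudomarker grids default to 1 cM
(analysis drivers use 2 cM); typed positions are degenerate on the observed
genotype, and probabilities elsewhere condition on the two flanking markers,
which is exact for a Markov chain with fully observed markers.

At each position the phenotype is regressed on the expected dosage plus
intercept, sex and batch; `LOD = (n/2)·log10(RSS_null/RSS_full)` with the
null retaining the covariates.  The sex-interactive model adds a
dosage × sex column; a QTL is flagged sex-interactive when the interactive
model exceeds the additive model by more than 1 LOD at the peak (strict
inequality).  Cross-sex Z scans use the additive dosage column only —
female designs never contain a heterozygote-dominance column.  Constant
phenotypes yield LOD 0 everywhere.

Permutation thresholds pool per-phenotype tails: for each sampled phenotype,
individual labels are permuted (optionally within sex strata), the
genome-wide maximum LOD is recorded per permutation, the phenotype's top 5%
of maxima are kept, and the pooled kept values give the significant (95th
percentile) and suggestive (80th percentile) thresholds.  An alternative
pooling over all per-position LODs is available behind a switch, since the
tail-pooling phrase in the original description is ambiguous.  Expression
scans use the fixed thresholds 4.0 (cis) and 6.0 (trans).

Support intervals are 1.5-LOD drops expanded outward to the nearest flanking
typed markers for base-pair reporting (the source report's interval method
is not stated; the 1.5-LOD drop is the field's default).  A QTL is cis when
its peak lies on the phenotype's chromosome within 50 cM (closed boundary,
nearest-marker interpolation of the phenotype's genetic position), trans
otherwise, and unplaced when the phenotype has no genomic location.  QC
drops records with fewer than 10 individuals in any peak-marker genotype
class and flags records whose peak LOD falls below the applicable threshold
once the single most extreme phenotype value is removed — an automated
surrogate for outlier inspection by eye.

## Hotspots

Trans QTL are grouped by peak marker; groups at consecutive markers merge
when every pairwise member-interval overlap is non-empty (the merge rule for
multi-marker hotspots is not stated in the source; mutual overlap is the
conservative reading).  Groups with ≥ 10 members are hotspots; the reported
span is the minimal shared overlap [max of member CI lows, min of member CI
highs], falling back to the union span with a warning if the intersection is
empty.  Summaries report the mean span in Mb (2 dp) and the Z/autosome
split.

## Integration and causal orientation

Expression and methylation QTL pairs with same-chromosome support-interval
overlap (closed endpoints, cM scale) are tested by OLS under three model
families — expression ~ methylation + sex over all individuals, and
expression ~ methylation within each sex — with Benjamini–Hochberg FDR
within each family; strata under 3 usable individuals are untestable.

Significant pairs are oriented with a single-anchor SEM comparison over
(G, E, M): the five candidate Gaussian path models are the two causal chains
G→E→M and G→M→E, the common-cause fork E←G→M, and the two colliders
G→E←M and G→M←E (the two-anchor orderings collapse to these when both QTL
share one anchor genotype).  Each model saturates all second moments except
one correlation — implied as a product of the other two for chains and the
fork, or zero for colliders — so the constrained Gaussian MLE is the
plug-in covariance and the fit statistic is χ² = (n−1)·F_ML with 1 df.  The
edge-orienting score is LEO.NB.OCA = log10(p_best/p_second best), significant
above 1.0 and suggestive above 0.8; the orientation is the best model's
implied E–M edge, reported only when the score clears the threshold.  In
this single-anchor setting the companion CPA score equals OCA by
construction.  A best-model fit p below 0.05 sets a caveat flag: competing
orderings cannot be ruled out.  Genotype enters as a numeric dosage.
Swapping the E and M inputs exchanges the chain models and the collider
models exactly — a property the tests assert to machine precision.

## Block-gene statistics

The shipped block-gene table repeats genes across adjacent blocks;
deduplication keys on the probe id (rows lacking a printed probe id carry
synthesized stable EST ids in the fixture), requires repeated expression
fields to agree, and resolves correlation counts to the per-gene maximum
where blocks disagree.  Genes are female-biased when the sex-difference
p < 0.05 with M:F ratio < 1, male-biased unbalanced when p < 0.05 with
ratio > 1, balanced otherwise (strict inequalities; 0.05 uniquely reproduces
the printed 14/22/2 split).  Group summaries are arithmetic means and
sample SDs (n−1), rounded to integers for report parity; the
balanced-vs-unbalanced comparison is a Welch two-sample t-test (the pooled
variance form gives a visibly different statistic on the same table, which
pins the choice).  The unbalanced-class and female-biased-class correlation
rates printed in the source are not reproducible from the table under any
single deduplication rule tried, so only the balanced-class rates
(0.95/0.77/0.18 per gene) are asserted.

## What the synthetic data does and does not show

The generator reproduces the design's statistical skeleton: ZW inheritance
and hemizygous dosages, AIL linkage on a marker skeleton, overdispersed
window counts with total-count normalization, a Z-wide male dose ratio,
block-like fold changes, sex-interactive allelic effects and directed
methylation–expression couplings.  It does not model CpG-density or
MeDIP enrichment bias, read-level error, LD beyond the pedigree, correlated
baselines between neighbouring windows, or per-window baseline variation —
so passing tests certify the statistical machinery and its calibration
under the stated model, not robustness to those real-data features.
Problem sizes in the shipped experiments (desk-scale genome, 50-seed
recovery studies, 2,000-window null scans) were chosen to make the full
suite reproducible on a laptop-class single core.

## Known limitations

- Single-QTL models only; no epistasis or polygenic background correction.
- The Haley–Knott approximation is used throughout rather than full-likelihood
  interval mapping; the two agree closely at these effect sizes.
- The AIL transition model treats the wild-allele frequency as a fixed
  per-chromosome constant rather than tracking map expansion per generation;
  genotype probabilities at pseudomarkers are correspondingly approximate
  between markers (exact at typed markers, which the scans mostly use).
- The SEM fitter covers the five canonical single-anchor models; latent
  confounders and multi-marker anchors are out of scope.
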
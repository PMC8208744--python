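# Methods

## Problem and model

Alternative polyadenylation (APA) produces transcript isoforms that differ
only in 3'UTR length. Given a list of candidate polyadenylation sites, each
transcript's 3'UTR is split at a proximal site into a *short* region (CDS
end to proximal site) and a *long* region (proximal site to the
transcript's 3'-most, *distal*, site). Reads in the long region can only
come from the long isoform, while short-region reads are ambiguous, so the
per-sample proportion

    R_ij = n_long_ij / (n_short_ij + n_long_ij)

is an identifiable proxy for long-isoform usage of pair i in sample j.
Genes with more than two sites contribute one pair per non-distal site,
each tested independently; all pairs share the single 3'-most site as the
distal site.

The per-pair model is a beta regression: R_j ~ Beta(mu_j phi, (1-mu_j) phi)
with logit(mu_j) = x_j' beta, where x_j holds an intercept, the condition
indicator of interest, and any known covariates (categorical covariates
treatment-coded). The single precision phi (> 0) absorbs biological and
technical dispersion of the ratio around its modelled mean; it is shared
across samples and estimated jointly with beta by maximum likelihood. A
beta response is a better error model for ratios in (0,1) than normal or
Poisson assumptions: its variance mu(1-mu)/(1+phi) shrinks near the
boundaries and it accommodates overdispersion relative to binomial
counting noise.

Ratios exactly 0 or 1 lie outside the beta support. By default a pair with
*any* boundary ratio is routed to a quasi-binomial GLM: a logistic-link
binomial GLM on the ratios with the per-sample totals as prior weights, a
free dispersion estimated as Pearson chi-square / (n - p), and t-based
inference on n - p degrees of freedom. A `routing="all_zero_long"` option
restricts the fallback to pairs with no long-region read anywhere (the
narrowest trigger); boundary ratios then still force the fallback, because
the beta likelihood is undefined there.

## Inference and small-sample behaviour

The condition coefficient is tested two-sided. For the beta path the
default is a small-sample-corrected Wald test: the ML estimate of phi
ignores the p mean parameters already spent, biasing phi upward and the
standard errors downward at small n, so standard errors are rescaled by
sqrt(n / (n - p)) and the statistic is referred to a t distribution on
n - p degrees of freedom. Measured on model-generated nulls this holds the
5% level from n = 6 up (e.g. 5.0% rejections at n = 20, KS uniformity
p = 0.80), whereas the uncorrected normal-reference Wald rejects ~20% of
nulls at the 5% level with n = 10 and three parameters. The uncorrected
test remains available (`inference="wald-normal"`), as does a
likelihood-ratio test (`test="lrt"` at the pipeline surface). The
quasi-binomial path always uses t inference, the GLM convention.

This calibration choice has a consequence worth stating plainly: some of
the "extra sensitivity at very small n" often attributed to beta
regression over quasi-binomial GLMs is an artifact of comparing a
normal-reference Wald z against a t reference. With both paths calibrated,
the depth-weighted quasi-binomial GLM is at least as powerful as the beta
fit whenever counts are truly binomial given totals (it is then the
correctly specified model); the beta model's advantage is robustness when
ratios are overdispersed relative to binomial sampling, not raw power on
clean binomial data.

Fitting: L-BFGS-B on (beta, log phi) with analytic gradients;
initialization from least squares on logit-transformed ratios (boundary
values nudged by machine epsilon only for initialization) and a
method-of-moments phi. Convergence is judged by the score at the solution
(max |gradient| below 1e-4 relative), not the optimizer's line-search exit
code. Standard errors come from the inverse observed information,
computed by central finite differences of the analytic gradient. The
implementation agrees with multi-start derivative-free maximization of
the same likelihood to ~1e-13 relative log-likelihood on random small
datasets, and with an independent ML implementation (statsmodels
`BetaModel`) to 1e-8.

Degenerate designs (condition confounded with a covariate, rank-deficient
design) are a hard error naming the collinear columns: silently dropping a
column would misattribute the covariate effect to the condition, the exact
failure mode covariate modelling exists to prevent.

## Filters and multiplicity

Pairs are excluded from testing (but retained, flagged, in the output)
when the short region carries too little information or the transcript
looks degraded:

- `low_short_reads`: mean n_short across samples < `min_short`
  (default 10). With no short-region reads the ratio saturates at 1 and
  carries no usage information.
- `low_tin`: median across samples of the per-sample Transcript Integrity
  Number < `min_tin` (default 40). TIN = 100 exp(H)/k, where H is the
  Shannon entropy of the per-base coverage distribution over the k exonic
  3'UTR positions: 100 for perfectly uniform coverage, 100/k for coverage
  concentrated on one base, 0 for no coverage. The median across samples
  is robust to a single degraded library. Both thresholds are explicit
  defaults, configurable, and a precomputed TIN table can be supplied in
  place of the coverage computation.
- `all_zero_long`: no long-region read in any sample; the quasi-binomial
  intercept diverges and the pair is reported untestable.

Tested p-values are adjusted by Benjamini-Hochberg across all tested pairs
in the run (pairs from the same gene included individually); default
significance threshold 0.05 on adjusted p.

## Read counting

A read (or properly paired fragment, counted once via the union of both
mates' aligned blocks) is assigned to the long region if >= 1 aligned base
overlaps it -- a read crossing the proximal boundary can only derive from
the long isoform -- otherwise to the short region on >= 1 base of overlap.
Each fragment counts at most once per pair. Secondary, supplementary,
duplicate and unmapped alignments are excluded, as are reads below a MAPQ
threshold (default 10). Library strandedness is an option (unstranded
default, as for the classic benchmark libraries in this field). Regions
are restricted to annotated exons, so intronic bases never contribute
counts or TIN coverage. Indexed BAM is accessed by region fetch; plain SAM
without an index is streamed in full, which keeps miniature text fixtures
first-class inputs.

All coordinates are 0-based half-open internally (BED convention); GTF
input is converted on read. A site list may associate sites to transcripts
by id, or sites are matched by same-strand overlap with a transcript's
3'UTR. The annotated transcript end can optionally stand in as the distal
site when absent from the list (off by default: the site list is taken as
the authority).

## Synthetic data generator

The generator works at the count level. For pair i and sample j the total
3'UTR depth is negative-binomial with mean 200 and dispersion 0.3
(var = mu + 0.3 mu^2), emulating expression variation across replicates;
per-pair means can be overridden to create low-expression tiers. The
long-region count is Binomial(T_ij, p_ij) with

    logit(p_ij) = logit(p0) + log(f_cond) I[group 2] + sum_c log(f_c) I[level c]

so effect sizes are odds fold changes on the long-isoform proportion,
additive on the logit scale and therefore consistent with both fitted
models; a helper converts a target proportion fold change at a given p0.
The baseline p0 defaults to 0.2 -- ratios above 0.5 arise only for long
regions longer than the short region or under strong 3' coverage bias, so
a baseline well below 0.5 is the realistic regime. An optional
`prop_logit_sd` adds Gaussian noise on the logit of p_ij per sample,
emulating biological replicate variability of the proportion itself;
default 0 (counts exactly binomial given totals). A truth ledger labels
every pair `null`, `condition-APA` (nonzero condition effect) or
`covariate-APA` (ratio moved only by a nuisance covariate -- null with
respect to the condition). All randomness flows from the single config
seed.

The imbalanced scenario reproduces covariate confounding: sex split 4M/1F
vs 1M/4F across two groups of five, no condition effect, and a male-only
odds fold change of 0.25 on the long-isoform proportion (males express the
short region relatively more). Group-mean ratios then differ between
conditions while per-sex means match across conditions, so a
condition-only analysis misattributes the sex effect.

Read-level SAM fixtures place n_short reads fully inside the short region
and n_long fully inside the long region, evenly spaced, one contig per
pair, with matching BED12/BED annotation, so counting the fixture
regenerates the count table exactly. This exercises the counting layer
end to end but deliberately omits boundary-spanning reads, sequencing
error, positional bias and multi-mapping; passing the round trip shows
coordinate bookkeeping is exact, not that counting is robust to those
artifacts.

What the generator does not emulate: 3' coverage bias, GC/positional
effects, isoforms beyond two per pair, correlated pairs within a gene,
unknown batch structure. Results on it therefore speak to the statistical
engine under the stated sampling model, not to alignment- or
library-specific artifacts in real data.

## Benchmark scenarios and measured behaviour

`scripts/acceptance.py` recomputes, from scratch at a given seed: the
null-specificity run (300 null pairs, n=10/group: zero BH-significant
calls), the imbalanced-covariate runs with and without sex in the design,
the brute-force likelihood oracle gap, parameter recovery (mean estimate
and 95% interval coverage for a log-odds effect of 1.0 at phi=50,
n=20/group), KS uniformity of null p-values, the small-n power comparison
between the two model paths, the SAM round trip, and a mixed benchmark
(20% true events at odds fold change 2.5) scored by sensitivity,
specificity and MCC (zero by convention when a confusion-matrix margin is
empty).

Two directional expectations from the field's lore are *not* reproduced by
a calibrated implementation, deliberately:

1. Omitting the confounded covariate from the imbalanced design does not
   flood the results with BH-significant false positives at n=5/group.
   The 4:1 imbalance converts a covariate log-odds effect L into an
   apparent condition shift of 0.6L while inflating within-group standard
   deviation by 0.4L, capping the standardized effect near d = 1.5
   regardless of L; with t inference on 8 df and BH across 200 tests the
   first rejection needs p < 2.5e-4, which such an effect essentially
   never reaches. Methods that average replicates per group discard that
   inflated within-group variance and do report many false positives in
   this design; a regression that models per-sample variance is protected
   even when misspecified. The covariate still matters: it restores the
   correct effect attribution and, at larger n, the confounded model's
   false positives return.
2. The beta path does not out-power the quasi-binomial path at n=3/group
   on clean binomial counts (see the inference section above).

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| `min_short` | 10 | minimum mean short-region count per pair |
| `min_tin` | 40 | minimum median TIN per transcript |
| `alpha` | 0.05 | BH-adjusted significance threshold |
| `min_mapq` | 10 | MAPQ threshold for counted reads |
| `strandedness` | unstranded | library orientation handling |
| `routing` | any_boundary | fallback trigger for the quasi-binomial path |
| `inference` | wald-t | small-sample-corrected Wald (beta path) |
| `nb_mean`, `nb_dispersion` | 200, 0.3 | simulated total-depth model |
| `p0` | 0.2 | simulated baseline long-isoform proportion |
| `prop_logit_sd` | 0 | simulated proportion overdispersion |

## Known limitations

- Constant precision phi across samples; no dispersion submodel, random
  effects or surrogate-variable estimation of unknown batches.
- Pairs are tested marginally; p-values of pairs sharing a gene are
  correlated and BH is applied across all of them without a gene-level
  aggregation step.
- TIN is computed over the 3'UTR span only, per sample, with the median
  across samples as the filter statistic; tools that integrate over whole
  transcripts will give different absolute values.
- The quasi-binomial path reports a pair untestable under separation or
  an all-boundary response rather than attempting penalized fits.
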
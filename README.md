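# apareg

Regression-based detection of **differential alternative polyadenylation
(APA)** between sample groups in standard RNA-seq data.

Alternative polyadenylation produces transcript isoforms that differ in
3'UTR length. Given coordinate-sorted alignments, a transcript annotation
and a list of candidate polyadenylation sites, `apareg` splits each 3'UTR
at a proximal site into a *short* region (CDS end → proximal site) and a
*long* region (proximal site → the transcript's 3'-most site), counts
reads per region and per sample, and asks: does the proportion of 3'UTR
reads falling in the long region,

```
R_ij = n_long_ij / (n_short_ij + n_long_ij),
```

depend on group membership? The per-pair model is a **beta regression**
with logit mean link and constant precision φ,

```
R_j ~ Beta(μ_j φ, (1 − μ_j) φ),    logit(μ_j) = x_j' β,
```

where the design x_j carries the condition of interest plus any known
covariates (sex, batch, ...), so confounders that would otherwise be
misread as APA are modelled rather than averaged away. Pairs with a ratio
exactly 0 or 1 (outside the beta support — e.g. no long-isoform reads in a
sample) fall back to a logistic-link **quasi-binomial GLM** with the
totals as prior weights. Two-sided tests on the condition coefficient use
small-sample-corrected Wald inference, and p-values are
Benjamini–Hochberg adjusted across all tested pairs. Filters remove pairs
with too few short-region reads or degraded transcripts (entropy-based
TIN score of 3'UTR coverage uniformity).

The package is aimed at transcriptomics analysts who have ordinary bulk
RNA-seq (not 3'-end sequencing) and a site catalogue, and need per-gene
APA calls with covariate adjustment. It also ships a synthetic-data
module (count-level generator with truth ledgers, plus miniature SAM
fixtures) and evaluation utilities (sensitivity, specificity, Matthews
correlation coefficient) for benchmarking.

## Worked example

```python
from apareg import SimulationConfig, simulate_counts, run_apa, evaluate

cfg = SimulationConfig(n_pairs=100, frac_apa=0.2, effect=2.5,
                       n_per_group=(8, 8), seed=7)
ds = simulate_counts(cfg)                      # counts + sample sheet + truth
results = run_apa(ds.counts, ds.samples, alpha=0.05)
print(results.head(5)[["pair_id", "method", "estimate", "std_error",
                       "p_value", "p_adjusted"]].round(4).to_string(index=False))
report = evaluate(results, ds.truth, alpha=0.05)
print(f"sensitivity={report.sensitivity:.3f} "
      f"specificity={report.specificity:.3f} MCC={report.mcc:.3f}")
```

prints

```
 pair_id method  estimate  std_error  p_value  p_adjusted
pair0014   beta    0.9412     0.0560      0.0         0.0
pair0001   beta    0.8623     0.0676      0.0         0.0
pair0019   beta    0.9883     0.0820      0.0         0.0
pair0010   beta    0.9920     0.0864      0.0         0.0
pair0004   beta    0.9798     0.0937      0.0         0.0
sensitivity=1.000 specificity=1.000 MCC=1.000
```

Here 20 of 100 simulated pairs carry a true odds fold change of 2.5 on
the long-isoform proportion between two groups of eight samples.
`estimate` is the fitted condition coefficient on the log-odds scale
(truth ln 2.5 ≈ 0.92 — the top hits recover it), `method` records which
model path tested the pair, and at adjusted p < 0.05 every true event is
found with no false calls, so sensitivity, specificity and MCC are all 1.

The model layer is also usable directly, sklearn-style:

```python
from apareg import BetaRegression
m = BetaRegression().fit(X, ratios)   # X: covariate matrix, ratios in (0,1)
m.coef_, m.phi_, m.pvalues_
```

## Command line

```bash
apareg run --bam s1=s1.bam --bam s2=s2.bam ... \
           --sites sites.bed --annotation transcripts.gtf \
           --samples samples.tsv --covariates sex --out results/
apareg simulate --n-pairs 300 --frac-apa 0.2 --effect 2.5 --seed 1 --out sim/
apareg evaluate --results results/results.tsv --truth sim/truth.tsv --out report.json
apareg regions  --sites sites.bed --annotation transcripts.bed12 --out pairs.tsv
```

`run` writes the derived region pairs, the count matrix, TIN table,
results TSV (one row per pair with method, estimate, p-values and filter
flags) and a manifest of all resolved options.

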
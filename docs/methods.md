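# Methods

## Statistical pipeline

### Correlation screen

All correlations are pairwise-complete Pearson. The two-sided p-value
uses the t-approximation t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom;
|r| = 1 is reported with p = 0. Screens require a configurable minimum of
10 pairwise-complete observations per pair (correlations at smaller n are
too unstable to rank); the bare `pearson` primitive allows n ≥ 3.
Zero-variance vectors raise rather than returning NaN.

The dual criterion is: stage 1, r ≥ r_min (default 0.2, **inclusive** —
the boundary has measure zero on real data and an inclusive comparison
keeps a gene printed as "0.2" in a report inside the hit set) and
p < 0.05 against the positive (mesenchymal) anchor; stage 2, p < 0.01
against the positive anchor together with r < 0 and p < 0.01 against the
negative (epithelial) anchor. No multiple-testing correction is applied
within a screen — the screen mirrors the hypothesis-generating procedure
it reimplements — but the output table records how many genes were
tested so users can post-correct. Output ordering is deterministic:
descending r against the positive anchor, then ascending p, then symbol.

### EMT metric

Weights are computed per cohort: wᵢ is signature gene i's Pearson r with
the anchor (CDH1) over that cohort's own samples. Consequences worth
stating explicitly:

* signature genes absent from the matrix — or with zero variance, whose
  correlation is undefined — are dropped with a warning and the weighted
  sum is **not** renormalised (the metric is a plain weighted sum; the
  output records n_used);
* the input matrix is taken as already normalised log2 expression; an
  optional per-gene z-scoring flag exists (default off) for users whose
  matrices mix scales;
* centred scores subtract the cohort grand mean, so their mean is zero to
  floating-point accuracy; a centred score of exactly 0 is classified
  "boundary" rather than forced into either phenotype.

The signature itself is always an input file — the original 76-gene list
is not distributed with the package — and the synthetic generator emits
its own signature for testing.

### Multi-cohort co-signature

The Benjamini–Hochberg family is the set of cohorts in one scan; because
adjusted p-values depend on the family size m, the report header records
m and α. Significance is called at adjusted p < α (default 0.01) and the
conventional 0.05 call is reported alongside. Ranking ties break by
ascending p then cohort label, so reports are reproducible byte for byte.

### Survival cut-point search

Kaplan–Meier estimation uses the product-limit estimator; the log-rank
test is the 1-df chi-square score form, with variance term
d·(n₁/n)·(n₂/n)·(n−d)/(n−1) at each distinct event time (event times
where only one subject remains at risk contribute zero variance).
"Upper and lower quantiles" is read as the quartiles (configurable);
candidate thresholds are the distinct expression values strictly inside
that window; dichotomisation is low ≤ threshold < high, which is
deterministic on ties; equal minimal p breaks to the smallest threshold.
The scan's minimal p is deliberately **not** corrected for the number of
thresholds tried — fidelity to the procedure being reimplemented — so
`CutpointResult` exposes `n_thresholds_scanned` and a caveat string; under
the null the minimal p of a scan is stochastically smaller than uniform,
and downstream consumers must account for that. An optional
minimum-expression prefilter (default off) supports analyses restricted
to samples expressing the gene.

Implementation notes: `km_estimate` is backed by lifelines'
KaplanMeierFitter; the log-rank statistic is computed directly with
vectorised numpy because the scan evaluates it at hundreds of thresholds
per gene, and is cross-checked in the test suite against both
lifelines' `logrank_test` and a from-first-principles O/E/V oracle.
`pearson` is backed by scipy and `bh_adjust` by statsmodels, each again
tested against independent brute-force oracles.

## Synthetic data model

A single latent factor tⱼ ~ N(0,1) per sample encodes position on the
epithelial (t < 0) to mesenchymal (t > 0) axis; gene g is emitted as
aᵍ·tⱼ + ε with ε ~ N(0, σ²) i.i.d. This is the minimal structure under
which every pipeline target has a closed form:

* corr(g, h) = aᵍaʰ/√((aᵍ²+σ²)(aʰ²+σ²)) — so unit loadings with unit
  noise give the planted family gene a population r of 0.5 to the
  VIM-like marker;
* each gene's variance is a² + σ²;
* the sign agreement between the CDH1-anchored score and the latent sign
  is ½ + arcsin(ρ)/π with ρ the score–latent correlation.

Defaults (chosen once as a realistic TCGA-like bulk cohort): n = 500
samples; marker loadings +1 (VIM-like) and −1 (CDH1-like); one planted
family gene with loading +1 among 99 nulls (loading 0); noise σ = 1;
a 20-gene signature with alternating-sign loadings of magnitude uniform
in [1.0, 2.5]. The signature magnitudes reflect that curated EMT
signature genes are selected for strong differential expression — on the
order of 1–2.5 log2 units per standard deviation of the EMT axis; by the
arcsine formula above this puts the score–phenotype sign agreement near
96% at n = 500, whereas weakly loaded signatures (|a| ≲ 1) cap agreement
near 91% no matter how many samples are drawn.

Survival: event times are exponential with rate λ₀·exp(β) for samples
whose hazard-gene expression exceeds its median (the planted threshold)
and λ₀ otherwise; defaults λ₀ = 10⁻³ per day and β = ln 3 (a 3-fold
hazard ratio). Censoring is independent exponential, its rate solved
numerically (Brent) so that the expected censored fraction across the
two hazard groups equals the configured value (default 0.2). With no
censoring the group-wise median survival times differ by the hazard
ratio (exponential median = ln2/λ), which the tests verify.

Determinism: every draw comes from a stream derived from the master seed
via `numpy.random.SeedSequence` spawn keys — one stream for the latent
factor, one per gene indexed by position, one for survival — so
regenerating with the same config is bit-identical and appending genes
never perturbs existing ones. Expression is emitted on the
log2-normalised scale the pipeline contracts for; `linear_scale=True`
instead emits shifted powers of two to exercise the log2 preprocessing
stage.

What the generator does **not** emulate: real TCGA covariance structure
(multiple biological axes, batch effects, library-size artefacts), heavy
tails, gene–gene correlation beyond the single factor, or informative
censoring. Passing tests therefore demonstrate correctness of the
procedures under the stated model, not robustness of the screen to real
cohort pathologies.

## Preprocessing conventions

* log2 transform: x → log2(x + pseudocount), default pseudocount 1
  (RSEM values can be exactly 0); negative inputs are a domain error.
  With pseudocount 1 the computation uses log1p for accuracy near zero.
* TCGA barcode filtering keeps sample-type codes 01–09 (tumour material),
  parsed from the fourth dash-separated barcode field; barcodes without
  a parseable code are dropped with a warning, preserving sample order.
  The filter is idempotent.
* Duplicate gene rows collapse to the first occurrence with a warning;
  duplicate sample columns are an error.
* Missing values stay as explicit NaN and all correlations are
  pairwise-complete; nothing is imputed.
* Whether cell-line (CCLE-style) matrices should be log-transformed
  before correlation is left to the caller: the transform is an explicit
  pipeline stage, never applied implicitly.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
cohorts at the scale the statistics require rather than the scale of the
original data: screens use 100-gene families at n = 500 over 100–200
seeds; co-signature scans use 10–20 cohorts of n = 100–300; cut-point
recovery uses n = 300 over 100 seeds; oracle-equivalence checks run
exhaustively over small tables (≤ 8 subjects, vectors ≤ 12). These sizes
give binomial error bars comfortably inside every asserted tolerance.

## Known limitations

* The optimal-cutpoint p-value is anti-conservative by construction (see
  above); the package reports the selection size but does not implement
  minimal-p-corrected inference (e.g. maximally selected rank statistics).
* The EMT metric's weights are cohort-internal; cross-cohort weight reuse
  is possible by passing a precomputed `EMTWeights`, but no calibration
  across cohorts is attempted.
* `bh_adjust` controls FDR across cohorts for one gene pair; scanning
  many gene pairs would require a larger family, which is the caller's
  responsibility.
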
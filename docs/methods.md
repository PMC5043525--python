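# Methods

## Problem setting and model

The package infers genes selectively expressed in a cell type from
expression matrices of heterogeneous (mixed-cell) samples. The premise is
compositional: if the proportion of a cell type varies across samples,
genes expressed predominantly in that type rise and fall together. The
supervision is minimal — one or a few *query genes* already known to mark
the target type. The output is a ranking of all other genes with
per-gene significance, not a full decomposition into cell-type profiles:
the method deliberately targets *differential* (relative) expression, the
classification problem, rather than estimating absolute expression per
type.

### SVD filter

Per platform, genes are standardized (mean 0, sd 1 across samples;
sample sd, divisor n−1 — chosen for consistency with the Pearson
correlation denominators downstream; the convention is otherwise
arbitrary) and the matrix factored by thin SVD, X = U Σ Vᵀ. Zero-variance
genes cannot be standardized and are removed and reported (tolerance
1e−12 on the sd). Three operations reshape the spectrum:

1. **Exponent α ∈ [0, 1]** compresses singular values, σ_k → σ_k^α,
   reducing the dominance of the leading components (α = 1 leaves the
   spectrum unchanged; α = 0 equalizes it). Default α = 0.5.
2. **Query weights** w_k = Σ_{g∈query} tanh(u_k^g), with each column of U
   standardized across all m genes (mean 0, sample sd 1) before the tanh.
   A vector on which the query loads unremarkably gets |w_k| small and is
   smoothly attenuated; tanh saturates so one query gene contributes at
   most ±1 per vector. The filtered spectrum is σ′_k = σ_k^α·|w_k|.
   Using |w_k| makes the filter invariant to the arbitrary sign of each
   singular-vector pair.
3. **Kaiser truncation** retains the L vectors with σ_k² strictly greater
   than (Σ_j σ_j²)/n — the components accounting for more variance than
   an average single sample. L is computed from the *original* spectrum,
   before query weighting, because the criterion is about variance in the
   data, not about the query; L ≥ 1 is enforced so the filtered matrix is
   never identically zero (this also settles the degenerate all-equal
   spectrum, where strict inequality retains nothing).

The filtered matrix is X′ = U_{:,1..L} diag(σ′_{1..L}) Vᵀ_{:,1..L}.

### Scoring and significance

Every gene's filtered profile is correlated (Pearson, across samples)
with each query gene's filtered profile; correlations are clamped to
±(1 − 1e−12) before the Fisher transform so exact duplicates stay finite,
and z̄_g is the mean of atanh(ρ_gQ) over the N query genes. Genes whose
filtered profile has zero variance get z̄ = 0 (neutral) and are flagged
rather than dropped, so the output covers the full gene universe. Query
genes are excluded from the ranked output (their self-correlation is 1)
and reported separately.

z̄ is heavy-tailed under enrichment, so location and scale are estimated
robustly: S_g = (z̄_g − median)/(1.4826·MAD), MAD being the unscaled
median absolute deviation. A MAD of 0 means the score distribution is
degenerate; the package fails loudly (DegenerateDistributionError) rather
than substituting a value. One-sided upper-tail standard-normal p-values
are used — the method looks for enrichment only, and depletion is not
interpreted. On structure-free data S_g is empirically standard normal
(QQ R² ≈ 0.9996 on a 5000 × 100 iid-normal matrix), which is what
licenses the analytic p-values in place of a permutation test.

Platforms are scored independently and pooled by Stouffer's method on the
normal quantiles of the one-sided p-values, Z = Σz_i/√k over the k
platforms where a gene is present (unweighted; platforms with none of the
query genes are skipped and recorded). Benjamini–Hochberg adjustment
(via statsmodels) controls FDR over the pooled p-values; predictions
default to FDR ≤ 0.01. Holm's step-down method is used where a
family-wise error rate is required (the GWAS phase-1 screen). Ranks use a
stable sort with ties broken by gene id, so output is deterministic.

### Evaluation

Gold standards are derived from purified-population profiles by a fold
threshold: a gene is positive when its mean in the target samples is at
least `fold_threshold`-fold its mean elsewhere ("at least" read as ≥; on
log2 input the rule is a difference of means ≥ log2(fold)). The
precision–recall curve is computed over every prefix of the ranked list
after restricting to the gold standard's universe, and AUPR uses the
interpolation-free average-precision estimator — the sum of precision at
each retrieved positive divided by the total number of positives, i.e.
Σ Δrecall·precision. This is stated explicitly because interpolation
conventions change AUPR values; note also that the expected AUPR of a
random ranking sits somewhat *above* prevalence at finite list length
(≈ 0.138 for 10 positives in 100, vs prevalence 0.10). Set enrichment
uses the one-sided Fisher's exact test (scipy), i.e. the exact
hypergeometric upper tail.

### GWAS candidate prioritization

Phase 1 (specificity): genes overlapping a 20 kb window centered on each
GWAS SNP (inclusive interval overlap; gene-body overlap with the window,
coordinates 1-based inclusive, BED converted on read) form the positional
candidate set. Each cell type whose top 200 predictions are enriched for
these candidates (Fisher's exact, Holm-adjusted p ≤ 0.05 across cell
types) is a data-driven priority cell type; literature-known cell types
can be supplied as additional priorities (a manual step by design).
Phase 2 (sensitivity): every gene whose interval lies within 250 kb of a
SNP — nearest-edge distance, inclusive at the boundary — and is predicted
for a priority cell type at FDR ≤ 0.1 is reported as a (SNP, gene,
cell type) triple. The 250 kb cap is a pure-distance proxy for linkage
disequilibrium; no LD reference panel is consulted, and the package makes
no claim about actual LD structure.

## Synthetic data generator

`simulate_mixture` emulates the compositional premise directly. Each gene
gets one background expression level b_g ~ Normal(0, 1) shared across the
K cell-type profiles; the markers of type t (disjoint sets of
`markers_per_type` genes) have their type-t profile raised by
`log2_fold_change`. Markers are therefore exactly the differentially
expressed genes, and with fold change 0 they are statistically
indistinguishable from background (the no-signal limit used in tests). A
variant (`background="independent"`) draws a separate background per gene
per type; it makes *every* gene differentially expressed between types,
so marker recovery is fundamentally ambiguous there — it is kept as a
stress test, not used in the benchmark.

Sample j draws mixing proportions from a Dirichlet and its expression is
the proportion-weighted combination of the type profiles (in log2 space
by default — a documented simplification: the pipeline standardizes each
gene, so only co-variation structure matters; `mixing="linear"` mixes
2^profile intensities instead), plus an additive per-gene batch offset
~ Normal(0, batch_sd) shared by the samples of a batch, plus
Normal(0, noise_sd) measurement noise. All draws come from one
seeded generator in a fixed order, so output is bit-reproducible.

### Default benchmark and why its knobs are what they are

`default_benchmark_design` fixes: m = 2000 genes, n = 200 samples, K = 5
cell types, 50 markers per type, fold change 2.0 (log2 units), noise sd
0.5, Dirichlet mean proportions (0.05, 0.2375, …) — the first type rare
at 5% — with total concentration 1.0, and 10 batches with offset sd 0.25.

- **Total concentration 1.0**: tissue compendia mix samples whose
  composition differs drastically (whole organs, dissections, purified
  fractions); concentration 1 gives exactly that regime — most samples
  nearly devoid of the rare type, a few with a substantial share. Large
  concentrations would make all samples compositionally similar, which is
  the regime where co-expression inference is impossible and which real
  compendia do not resemble.
- **Batch structure (10 × sd 0.25)**: multi-study compendia always carry
  study/hybridization structure. It is also what makes the filter's
  contribution *measurable*: on a perfectly clean low-rank mixture, raw
  correlation is already near-optimal and spectrum truncation can only
  discard information, so a benchmark without technical structure cannot
  show the filter's purpose. The batch sd is set at half the measurement
  noise — technical structure that is noticeable but subordinate.
- The problem sizes (2000 × 200; 5000 × 100 for the null) keep the full
  suite and the reproduction script in the seconds-to-minutes range while
  leaving the spectra rich enough (rank 200 and 100) for truncation and
  weighting to be non-trivial.

What passing on this generator does and does not show: it validates the
algebra, calibration, and the end-to-end ability to recover a coherent
rare-type module from compositional + batch covariation at a 4-fold
(2 log2 units) planted signal. It does not certify performance on real
microarray data, whose noise is non-Gaussian and probe-dependent, whose
"cell types" are hierarchically nested rather than disjoint, and whose
marker fold changes and sample counts differ by orders of magnitude.

## Numerical choices and degenerate inputs

- Zero-variance detection threshold: sample sd ≤ 1e−12.
- Correlation clamp: ±(1 − 1e−12) before atanh.
- p-value floor: the smallest positive normal double, to keep downstream
  logs and quantile transforms finite.
- Robust standardization requires ≥ 3 scores and MAD > 0 (hard error
  otherwise); correlations require ≥ 3 samples.
- Kaiser: strict inequality; floor L ≥ 1; ties in ranks broken by gene id
  (stable sorts throughout).
- Probe collapsing averages on the stored (log) scale and orders output
  rows by gene id, making it invariant to input row order; a mapping
  table in which one source id maps to two targets is rejected as
  malformed rather than resolved by any tie-break.
- Matrix loading rejects (and reports) rows containing non-numeric or
  missing cells rather than imputing; the algorithm assumes complete
  matrices.

## Known limitations

- A single query gene bounds how sharply the tanh weight can separate
  informative from uninformative singular vectors (|w_k| ≤ N); multiple
  query genes sharpen the filter.
- The filter's Kaiser truncation can hurt on data whose informative
  structure is *not* above the average-sample variance threshold.
- Stouffer pooling treats platforms as independent and equally reliable;
  there is no weighting by platform size or quality.
- GWAS phase 2's distance cap is not LD; candidate lists inherit every
  bias of the coordinate and prediction inputs.
- The simulator does not model probe effects, saturation, correlated
  (low-rank) technical factors, or nested cell-type hierarchies.
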
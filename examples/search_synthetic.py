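"""Recover planted cell-type markers from a synthetic mixed-tissue matrix.

Simulates the default benchmark — 2000 genes x 200 mixed samples, five
cell types, the first rare (mean proportion 5%), 50 planted markers per
type at +2 log2 fold — queries with a single marker of the rare type, and
measures how well the remaining 49 co-planted markers are recovered.
"""

from cellmapper import (
    GoldStandard,
    aupr,
    default_benchmark_design,
    precision_recall,
    search_platform,
    simulate_mixture,
)

matrix, truth = simulate_mixture(default_benchmark_design(seed=1))
markers = truth.markers_of("type_0")
query = markers[0]
print(f"matrix: {matrix.n_genes} genes x {matrix.n_samples} samples; "
      f"query gene: {query} (rare cell type, 49 hidden co-markers)")

result = search_platform(matrix, [query])
gold = GoldStandard(set(markers) - {query}, set(matrix.gene_ids) - {query})
ranked = list(result.table["gene_id"])

print(f"\nretained rank after Kaiser truncation: {result.retained_rank} "
      f"of {len(result.sigma)} singular vectors")
print("\ntop 10 predictions (s = robust z-score of the mean Fisher-z):")
for _, row in result.table.head(10).iterrows():
    is_marker = "marker" if row.gene_id in gold.positives else "background"
    print(f"  rank {row['rank']:>2}  {row.gene_id}  s={row.s:7.2f}  "
          f"fdr={row.fdr:.2e}  [{is_marker}]")

a = aupr(precision_recall(ranked, gold))
baseline = search_platform(matrix, [query], use_filter=False)
a_nf = aupr(precision_recall(list(baseline.table["gene_id"]), gold))
print(f"\nAUPR with SVD filter: {a:.4f}   filter bypassed: {a_nf:.4f}")
print("(1.0 = every hidden marker ranked above every background gene; "
      "a random ranking would sit near the 0.025 marker prevalence)")
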
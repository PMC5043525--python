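"""Collapse probeset rows to genes and map identifiers hierarchically.

Microarray matrices carry one row per probeset; multiple probesets can
interrogate the same gene and are averaged on the log scale. Identifiers
from another species are translated through an ordered hierarchy of
orthology tables — each id resolved by the most trusted table that knows
it.
"""

import numpy as np

from cellmapper import (
    ExpressionMatrix,
    MappingTable,
    collapse_probesets,
    map_identifiers_hierarchical,
)

matrix = ExpressionMatrix(
    gene_ids=["1001_at", "1002_at", "1003_at", "1004_at", "9999_at"],
    sample_ids=["s1", "s2", "s3"],
    values=np.array([[4.0, 5.0, 6.0],
                     [6.0, 7.0, 8.0],
                     [2.0, 2.5, 3.0],
                     [1.0, 1.0, 1.0],
                     [0.0, 0.1, 0.2]]),
)
probe_map = MappingTable({"1001_at": "GAD1", "1002_at": "GAD1",
                          "1003_at": "SLC6A2", "1004_at": "PDGFRA"},
                         name="platform annotation")
collapsed, report = collapse_probesets(matrix, probe_map)
print(f"{report.n_probes_in} probesets -> {report.n_genes_out} genes "
      f"({report.n_unmapped} unmapped dropped: {report.unmapped_probes})")
print(collapsed.to_dataframe().round(2))

tables = [MappingTable({"Gad1": "GAD1"}, name="curated orthologs", priority=0),
          MappingTable({"Gad1": "WRONG", "Slc6a2": "SLC6A2"}, name="name match",
                       priority=1)]
res = map_identifiers_hierarchical(["Gad1", "Slc6a2", "Xyz9"], tables)
print("\nhierarchical mapping (first table that knows an id wins):")
for src, tgt in res.mapping.items():
    print(f"  {src} -> {tgt}   (via {res.table_used[src]})")
print(f"unmapped: {res.unmapped}; per-table usage: {res.counts}")
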
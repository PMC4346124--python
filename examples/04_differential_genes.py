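"""Differential-CNA gene screen between lineage clusters.

Per gene, Welch's t-test compares averaged log2 ratios between clusters
for five contrasts (each pair of clusters plus the two pooled
comparisons); p-values are Bonferroni-corrected within each contrast, and
a gene is selected if significant in at least one contrast.  The selected
genes drive a two-dimensional supervised clustering whose viewer files
(Cluster 3.0 .cdt/.gtr/.atr) load in TreeView-compatible tools.
"""

from pathlib import Path

from cnalineage import (
    CohortConfig,
    average_probes_to_genes,
    call_cna,
    cna_burden,
    complete_linkage,
    find_differential_genes,
    label_lineages,
    simulate_cohort,
    supervised_2d_cluster,
)
from cnalineage.io import write_cdt_gtr

cohort = simulate_cohort(CohortConfig(seed=5))
matrix = average_probes_to_genes(cohort.probes, cohort.genome.genes_df())
tree = complete_linkage(matrix.filter_min_probes(4))
assignment = label_lineages(tree.cut(3), cna_burden(call_cna(matrix))["fraction"])

result = find_differential_genes(matrix, assignment.labels, alpha=0.05)
print(f"{len(result.selected)} of {matrix.n_genes} genes selected "
      f"(union over 5 contrasts) at alpha={result.alpha}")
print("significant genes per contrast:")
for name, genes in result.per_contrast.items():
    print(f"  {name:38s} {len(genes)}")
print(f"intersection of all contrasts: {len(result.intersection)} genes")

stree, gtree, sub = supervised_2d_cluster(matrix, result.selected)
out = Path("scratch/example_supervised")
out.parent.mkdir(exist_ok=True)
files = write_cdt_gtr(sub, stree, gtree, out)
print("\nviewer files:", *(f.name for f in files))
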
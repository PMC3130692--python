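"""From raw CNV interval calls to a scan-ready cohort.

CNV data usually arrive as genomic intervals with copy numbers.  The pipeline
keeps deletions (copy number 0 or 1), maps intervals onto gene loci (>= 1 bp
overlap, BED half-open coordinates), drops genes affected in too large a
fraction of subjects (the rare-CNV filter), and restricts to pathway genes.
"""

import numpy as np

from pathscan import (
    DiseaseModel,
    filter_deletions,
    filter_rare,
    generate_random_pathway,
    map_cnvs_to_genes,
    restrict_to_pathway,
    simulate_dataset,
    synthetic_cnv_calls,
    synthetic_gene_annotation,
)

graph = generate_random_pathway(120, 2, seed=3)
cluster = frozenset(sorted(graph.genes)[:12])
model = DiseaseModel.from_cluster(cluster, p=0.01, K=0.01, gamma=3.0)
truth = simulate_dataset(model, graph.genes, 60, 60, seed=4)

annot = synthetic_gene_annotation(graph.genes)
calls = synthetic_cnv_calls(truth, annot, np.random.default_rng(5))
print(f"raw CNV calls: {len(calls)} on {len(annot)} annotated genes")

calls = filter_deletions(calls)
gene_sets = map_cnvs_to_genes(calls, annot, subjects=truth.subject_ids)
gene_sets = filter_rare(gene_sets, threshold=0.10)
phenotypes = dict(zip(truth.subject_ids, truth.phenotypes))
cohort = restrict_to_pathway(gene_sets, phenotypes, graph)

print(f"cohort: m1={cohort.m1} cases, m0={cohort.m0} controls")
print(f"affected-gene incidences: n1={cohort.n1} (cases), n0={cohort.n0} (controls)")
print("-> n1 and n0 are the denominators of the locality statistic's")
print("   case/control proportions for every window.")
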
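"""Find tumor marker genes and rank tissue groups by marker score.

Wilcoxon rank-sum marker discovery (tumor vs the rest of the compendium),
per-sample marker scores (median transformed expression over the markers),
and pairwise Welch tests with Holm correction across groups. The tumor group
should rank first, its developmental context next, unrelated tissues last.
"""

import numpy as np
import pandas as pd

import ewstraj as e

cfg = e.SimConfig(seed=0)
counts, meta, truth = e.simulate_bulk_compendium(cfg)
filtered = e.filter_genes(counts, 0.10)
vst = e.vst(filtered, e.size_factors_median_ratio(filtered))

labels = pd.Series(np.where(meta["is_tumor"], "tumor", meta["tissue"]), index=meta.index)
# p-threshold appropriate to a ~400-sample cohort (the compendium-scale
# default of 1e-50 presumes tens of thousands of samples)
table = e.wilcoxon_markers(vst, labels.reindex(vst.sample_ids), "tumor",
                           min_log2fc=0.58, max_padj=0.05)
markers = list(table.index[table["passes"]])
true_markers = set(truth.genes.index[truth.genes["is_marker"]])
print(f"{len(markers)} marker genes pass (log2FC > 0.58, Bonferroni p < 0.05); "
      f"{len(set(markers) & true_markers)} are planted markers")

scores = e.marker_score(vst, markers)
ranking = e.rank_groups(scores, labels)
print("\ntissue groups ranked by median marker score:")
print(ranking.table)

comp = e.composition_enrichment(labels, e.louvain(
    e.knn_graph(e.pca(vst.subset_genes(e.select_variable_genes(vst, 1000)), 100)[0], 20),
    seed=0,
).reindex(labels.index))
print("\ntissue x cluster composition (column-scaled, not centered):")
print(comp.round(2))
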
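"""Project the bulk trajectory signature onto single cells.

Simulates tumor single cells with per-cell fusion-dosage heterogeneity (a
minority low-dosage subpopulation), damaged cells, and cell-cycle structure.
After QC and normalization, each cell's scaled expression is weighted by the
bulk signed-R^2 gene scores; the per-cell score is the median over expressed,
weighted genes. Low-dosage cells should score high (mesodermal-like), and
their cluster should rank first.
"""

import ewstraj as e
import ewstraj.workflows as w

chain = w.bulk_chain(e.SimConfig(seed=0))
sc = w.single_cell_projection(chain["cfg"], chain["traj_scores"], seed=0)

print("cluster ranking by median per-cell trajectory score:")
print(sc["cluster_ranking"].round(4))
print(f"\nSpearman rho between cell score and true fusion dosage: "
      f"{sc['score_dosage_spearman']:.3f} (expected <= -0.6: high dosage -> low score)")
print(f"low-dosage subpopulation's cluster ranks first: "
      f"{sc['low_dosage_cluster_ranks_first']}")
print(f"planted 'up-when-dosage-low' gene set enriched in that cluster's "
      f"positive markers: BH p = {sc['planted_set_padj']:.2e}")
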
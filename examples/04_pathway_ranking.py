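"""Filter DEGs and rank KEGG pathways by their up/down ratio.

Builds a DEG table and annotation by hand, applies the inclusion
filters (blast score strictly over 300 AND fold change strictly over
1.5), counts up- and down-regulated members per pathway, and ranks
pathways by the ratio of the larger direction count to the smaller
(denominator floored at 1). Pathways with fewer than 10 DEGs are
flagged as insufficient for inclusion.
"""

import numpy as np
import pandas as pd

from chordaseq import enrich

rng = np.random.default_rng(0)
pathways = ["ko04110 cell cycle", "ko04512 ECM-receptor", "ko04310 Wnt"]
weights = [(14, 3), (2, 12), (5, 4)]  # (up, down) members per pathway

rows_ann, rows_deg = [], []
gid = 0
for pw, (up, down) in zip(pathways, weights):
    for direction, n in (("up", up), ("down", down)):
        for _ in range(n):
            gid += 1
            rows_ann.append((f"g{gid}", f"s{gid}", float(rng.integers(301, 900)),
                             pw, ""))
            rows_deg.append((f"g{gid}", "sumT2-vs-sumT3",
                             float(rng.uniform(1.6, 6.0)), direction))
annotation = pd.DataFrame(rows_ann, columns=["gene_id", "symbol", "blast_score",
                                             "kegg_pathways", "go_terms"])
degs = pd.DataFrame(rows_deg, columns=["gene_id", "comparison", "fold_change",
                                       "direction"])

filtered = enrich.filter_degs(degs, annotation, min_blast=300, min_fc=1.5)
table = enrich.rank_pathways(filtered, annotation, min_pathway_degs=10)
print(table)
print("\nup-regulated ranking (ratio > 1, >= 10 DEGs):")
print(enrich.ranked_pathways(table, "up")[["pathway_id", "ratio"]])
print("\ndown-regulated ranking:")
print(enrich.ranked_pathways(table, "down")[["pathway_id", "ratio"]])
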
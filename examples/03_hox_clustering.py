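"""Fuse, cluster and pattern-classify hox-like expression profiles.

The simulated dataset plants 12 hox-like genes with collinear
anterior-posterior gradients (alternating anterior-high and
posterior-high at a 4x max/min ratio). This script fuses rows by
annotation symbol (on the linear scale, before the log transform),
k-means clusters the log2 profiles, and classifies each symbol's
anterior/mid/posterior/flat pattern from its per-segment means.
"""

import tempfile
from pathlib import Path

import pandas as pd

from chordaseq import cluster, io, simdata
from chordaseq.quantify import quantify_libraries

config = simdata.SimulationConfig(seed=2, n_genes=16, n_contigs=4,
                                  contig_length=40_000, reads_per_library=2000)
with tempfile.TemporaryDirectory() as tmp:
    paths = simdata.generate_dataset(config, tmp)
    models = io.load_gene_models(paths["gff"])
    design = io.load_design(paths["design"])
    annotation = io.load_annotation(paths["annotation"])
    truth = simdata.GroundTruth.from_json(paths["truth"])
    reads = {lib: io.iter_sam_reads(Path(tmp) / f"{lib}.sam")
             for lib in design["library"]}
    result = quantify_libraries(models, reads, read_length=config.read_length)

fused = cluster.fuse_by_symbol(result.matrix.counts, annotation)
hox = fused.loc[[s for s in fused.index if str(s).startswith("hox")]]
profiles = cluster.log2_profiles(hox, epsilon=0.01)
assignment = cluster.kmeans_profiles(profiles, k=2, seed=0, restarts=25)
patterns = cluster.ap_patterns(hox, design)

summary = pd.DataFrame({"cluster": assignment.labels, "pattern": patterns})
print(summary.sort_values(["cluster", "pattern"]))
sym = annotation.set_index("gene_id")["symbol"]
truth_pat = {sym[g]: p for g, p in truth.pattern_labels.items()}
agree = sum(patterns[s] == truth_pat[s] for s in truth_pat)
print(f"\npattern calls agreeing with simulated polarity: {agree}/{len(truth_pat)}")
print("(k-means groups follow overall expression level, G1 lowest; the "
      "pattern column reads the anterior-posterior polarity directly)")
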
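# chordaseq

RNA-seq quantification and no-replicate differential expression for a
9-library developmental design — three stages (T1, T2, T3) × three
anterior–posterior segments (A, M, P) of the teleost notochord —
against a fragmented draft genome with CDS-only gene predictions.

The package is aimed at anyone who needs to analyse (or audit an
analysis of) bulk RNA-seq in a non-model organism where the reference
is a contig assembly, gene models have no UTRs, and each condition was
sequenced once, without biological replicates. It provides, as a
library with a thin CLI:

* **Identity-weighted fractional counting** — a read's identity is
  `w = (r − NM)/r`; reads below `w = 0.90` are removed, and a
  surviving read adds `w · o/r` to a gene, with `o` its CDS-overlapping
  bases. Per-gene expression is `e = c·r/L` (coverage of the predicted
  coding length `L`), libraries are normalized to equal totals, and
  genes need ≥ 3 mapped reads to enter the raw gene list.
* **Genomic-compartment classification** of every read into coding
  exon, 1000-bp strand-aware downstream window (a stand-in for the
  missing 3′ UTR), intron or intergenic, with coding-exon priority.
* **Pooled no-replicate DE calling** — libraries are summed into
  pseudo-replicates (sumT1..sumT3 or sumA..sumP) and an M–D exceedance
  statistic against simulated multinomial technical replicates
  (nss = 5, pnr = 0.2, v = 0.02) calls a gene DE when its probability
  exceeds q = 0.8.
* **Hox-style clustering** — fusion of same-symbol paralogs before the
  log transform, seeded k-means on log2 profiles, and
  anterior/mid/posterior/flat pattern classification.
* **KEGG/GO summaries** — DEG filtering at blast score > 300 and fold
  change > 1.5, pathway ranking by up/down ratio (pathways with < 10
  DEGs flagged insufficient), and GO-retrieved ECM panels floored at
  > 100 reads.
* **A synthetic-data generator** that emulates the full design —
  fragmented genome, GFF3 gene models, per-library SAM with NM tags and
  mate flags, annotation and design tables — with exact ground truth
  for every stage, used by the test suite and usable for method
  calibration.

## Worked example

```bash
python examples/01_simulate_and_quantify.py
```

simulates 16 genes × 9 libraries (2000 paired 100-bp reads each),
quantifies them, and prints:

```
fractional counts (first 4 genes, first 3 libraries):
            T1A    T1M    T1P
gene0001  36.94  23.52  13.73
gene0002  22.41  21.67  78.92
gene0003  67.70  30.80  19.62
gene0004   9.88  19.51  50.45

read compartments (% of identity-passing reads):
     coding_exon  downstream_window  intron  intergenic
T1A         36.2               29.7     5.2        28.8
T1M         33.8               33.1     4.1        29.0
T1P         35.4               30.3     4.3        29.9

raw gene list: 16 of 16 genes have >= 3 reads in at least one library
normalized library totals (all equal): [659.21]
```

Each matrix cell is an identity-weighted fractional read count (a
perfect fully-CDS read adds 1.0, a 90 %-identity one adds 0.9); the
compartment table shows that reads land roughly at the configured
mix — about a third in coding exons, a third in downstream windows —
and after normalization every library carries the same total, so
values are comparable across libraries. The other examples cover DE
calling (`02`), hox fusion/clustering/patterns (`03`) and pathway
ranking (`04`); each prints the numbers it computes with a line on
what they mean.

The same pipeline runs end-to-end from the shell:

```bash
chordaseq run-all --seed 11 --out results/demo
```

writing per-stage artifacts (counts, region tallies, DEG tables, venn
counts, hox clusters/patterns, pathway ranking, ECM panels) plus a
manifest with the config hash; all tables carry provenance headers.

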
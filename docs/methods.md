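# Methods

`chordaseq` re-implements, as a tested library, an RNA-seq analysis
built for a difficult but common situation in non-model organisms: a
fragmented draft genome, CDS-only gene predictions (no annotated UTRs),
single libraries without biological replicates, and a 9-library design
of three developmental stages (T1, T2, T3) crossed with three
anterior–posterior segments (A, M, P) of the notochord. This note
records the model behind each stage, the defaults and why they are what
they are, what the synthetic data does and does not emulate, and the
numerical choices made where the procedure was underdetermined.

## Quantification model

**Identity weighting.** Each mapped read carries an alignment identity
`w = (r − NM) / r`, with `r` the full read length and `NM` the edit
distance tag. Reads with `w < 0.90` are removed from every tally —
counts, read tallies and compartment statistics alike. A surviving read
adds `w · o / r` to each gene whose coding sequence it overlaps, where
`o` is the number of aligned bases falling inside the gene's CDS
intervals: a 100-bp read entirely inside a CDS at 90 % identity
contributes exactly 0.9, and a perfect read half in CDS, half
downstream contributes 0.5. The identity denominator is the full read
length rather than the aligned length; the 0.9-for-90 %-match rule is
stated against the read, and the simulator emits full-length alignments
so the two coincide there anyway.

**Expression and normalization.** Per-gene expression is
`e = c · r / L` with `L` the predicted coding-sequence length — an
identity-weighted coverage, so a gene tiled once by perfect reads has
`e ≈ 1` regardless of its length. Libraries are normalized by scaling
each library's fractional-count total to the mean of the library totals
(the target is configurable); normalization acts on the count layer,
and the expression layer is recomputed from normalized counts so
`e = c·r/L` holds cell-wise before and after. Within-library ratios are
untouched and the grand total is conserved.

**Raw gene list.** A gene enters the analysis set when at least
`min_reads = 3` distinct identity-passing reads overlap its CDS by one
or more bases in at least one library. "Reads" here is the unweighted
tally, not the fractional count, since the rule is stated in whole
reads. The library scope is configurable (`any` / `global`); the
permissive any-library reading is the default.

**Compartment classification.** Every identity-passing read gets
exactly one label with priority coding_exon > downstream_window >
intron > intergenic. The downstream window is 1000 bp past the gene's
last coding base, on the 3′ side given the strand; it stands in for the
un-annotated 3′ UTR of CDS-only predictions. Counting itself is
unstranded (random-hexamer libraries); strand is used only to orient
the window. Compartments are tallied after the identity filter; the
below-floor read count is reported separately in QC. A read overlapping
two genes' CDS contributes to both (multi-gene reads are a QC metric,
not an exclusion); mates of a pair are counted independently, since
pairing in a fragmented assembly is only verifiable when both mates hit
the same contig.

## Differential expression without replicates

Libraries are pooled into summed pseudo-replicates along one design
axis: sumT1–sumT3 (three segments summed per stage) or sumA–sumP
(three stages per segment). For a pair of pooled conditions the caller:

1. simulates `nss = 5` technical replicates per condition by
   multinomial resampling: each replicate draws `pnr·total` reads
   (`pnr = 0.2`), jittered uniformly by `±v·pnr·total` (`v = 0.02`),
   with per-gene probabilities proportional to the pooled counts —
   pure counting noise, no biological dispersion;
2. builds a noise cloud of (|M|, D) over all within-condition replicate
   pairs, where `M` is the log2 ratio and `D` the absolute difference,
   with zeros replaced by a pseudocount `k = 0.5` before the log;
3. computes each gene's signal (M, D) between the condition means of
   the simulated replicates and scores
   `p = fraction of noise points with |M_n| ≤ |M_s| and D_n ≤ D_s`;
4. declares differential expression when `p > q` with `q = 0.8`.

The nss/pnr/v defaults are the documented defaults of the no-replicate
simulation scheme this follows; the acceptance surface is parameter
recovery on simulated truth, not bit-compatibility with any particular
implementation. The input is the library-normalized count matrix, so
pooled condition totals are equal by construction and D is not
confounded by depth.

Numerical details worth knowing:

* `M` is computed as `log2(a) − log2(b)`, not `log2(a/b)`: the
  difference form negates bit-exactly under operand exchange, making
  `p` exactly invariant when the two condition labels are swapped
  (only the sign of M, hence the reported direction, flips). Each
  condition's replicate stream is seeded from a stable hash of its
  label for the same reason.
* Dominance is non-strict on both coordinates, so boundary ties favour
  a DE call — with one exception: noise points at exactly
  (|M|, D) = (0, 0) come from replicate pairs that happened to agree
  perfectly for that gene and carry no information about technical
  variability; they are dropped. Keeping them would give every gene,
  including one identical in both conditions, a floor probability
  equal to their share of the cloud; dropping them makes the identical
  gene's probability exactly 0.
* Genes with zero counts in both conditions are skipped (probability
  NaN, never called); their number is logged.
* Direction is read along the comparison: in `a-vs-b`, "up" means
  up-regulated from `a` to `b` (M = log2(b) − log2(a) > 0). The
  reported `fold_change` is `2^|M|`.

Measured on the synthetic design (1000 genes, mean count 200, 200
Monte-Carlo repetitions), planted 8-fold genes are called in every
repetition at `q = 0.8` and the null call rate is ≈ 3 %; power is
non-decreasing in planted fold change over {1.5, 2, 4, 8} and the
declared DEG count is non-increasing in `q`.

## Clustering and anterior–posterior patterns

Rows sharing an annotation symbol are fused by summation on the linear
scale, before the log transform — summing after a log would not equal
the expression of the combined loci. Profiles are transformed as
`log2(x + ε)` with `ε = 0.01`; the procedure names no pseudocount, and
0.01 is two decades below the typical per-gene expression of ~1, so it
only separates true zeros from small values. k-means uses the best of
`restarts = 25` seeded runs by within-cluster sum of squares; `k = 5`
by default, mirroring the five groups of the published hox heatmap
(the original never states k). Clusters are relabelled G1..Gk by
ascending centroid mean so labels are deterministic, with G1 the
lowest-expressed group.

The anterior–posterior pattern of a profile is the argmax of its
per-segment means (averaged over stages), with "flat" declared when the
max/min ratio is below 1.25. The rule is a deliberately simple,
scale-invariant proxy for what the original assessed visually; the
package additionally exposes a rank correlation between hox cluster
position and pattern score as a quantitative collinearity proxy,
without claiming it reproduces the published figure.

## Pathway ranking and ECM retrieval

For pathway mapping a DEG must have blast score strictly over 300 and
fold change strictly over 1.5; a gene annotated to several KEGG
pathways counts once in each. Each pathway's ratio is
`max(n_up, n_down) / max(min(n_up, n_down), 1)` — the denominator
floor of 1 keeps pathways with zero genes in one direction finite and
comparable (configurable to infinite-first ordering). Up- and
down-regulated rankings list majority-side pathways with ratio above 1,
sorted by ratio, ties broken by total DEG count descending then pathway
id (so output order is deterministic). Pathways with fewer than 10
DEGs are flagged `included = False`.

ECM genes are retrieved by flat GO lookup — exact term id or exact
name, case-insensitive, no ontology-graph propagation — and floored at
strictly more than 100 reads in the highest-coverage library, using raw
read tallies by default (whether the original floor was raw or
normalized is unstated; a flag switches). Qualifying genes are joined
against the stage-axis DEG list to form up- and down-regulated panels.

## Synthetic data: what it emulates, what it does not

The generator emulates the study conditions at desk scale: 9 libraries
(T1–T3 × A–M–P); 100-bp reads whose mates are two independent records
on the same contig; a fragmented multi-contig reference; CDS-only gene
models on both strands, separated by more than the downstream window
plus a read margin so compartments never collide; per-read identity
drawn from a discrete profile (default 55 % perfect down to 2 % at
0.80, i.e. ~5 % of reads below the 0.90 floor); reads distributed over
compartments at the study-like mix 34.8 / 32.1 / 4.1 / 29.0 %
(coding / downstream / intron / intergenic); log-normal baseline
expression; 12 hox-like genes with alternating anterior/posterior
gradients at 4× max/min ratio; and planted DE genes at stated fold
changes. Mismatches are substitutions only, so `identity = 1 − NM/r`
is exact and the counting oracle is unambiguous.

Per-library depth is exact by construction: the compartment totals are
drawn multinomially at the configured depth and the coding-compartment
total is split across genes multinomially with probabilities
proportional to the design means — i.e. the Poisson gene-count model
conditioned on its total, which keeps marginal gene counts
Poisson-like while making "reads per library" exact. Reads are placed
entirely inside a single compartment element, so every read's true
compartment label and every gene's expected fractional count (the sum
of its reads' realized identities) are exact, not approximate.

Deliberately not modelled: base-quality structure (qualities are
uninformative), indels and soft-clipping, splice-aware alignment
artefacts, insert-size structure (irrelevant to mate-independent
counting), overdispersion beyond Poisson, isoforms sharing reads, and
paralogous multi-mapping. Passing tests therefore demonstrate that the
pipeline's rules are implemented exactly and that the caller recovers
planted structure under counting noise; they do not show robustness to
biological overdispersion or mapping ambiguity, which the no-replicate
design cannot distinguish from signal in any case.

Default sizes (6 contigs × 60 kb, 40 genes, 6000 reads/library; the
DE studies use 1000-gene count matrices at mean 200) are chosen so a
full pipeline run and the Monte-Carlo suites complete in well under a
minute each on one core while keeping per-gene tallies in the tens to
hundreds — the regime where the identity and ≥3-read rules actually
bite.

## Degenerate inputs and error behaviour

Infeasible genome layouts (genes that cannot fit with margins) raise a
sizing error; a mapped record without an NM tag is a format error,
never a silent default; an unknown contig in classification is a
lookup error; empty libraries cannot be normalized; `pnr` outside
(0, 1], region mixes not summing to 1, non-positive fold changes and
unknown config keys are all rejected at validation. All randomness
flows from explicit seeds; seeded runs are byte-reproducible across
the whole generator, and output tables carry the config hash and seed
in their headers.
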
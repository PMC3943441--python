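"""Self-contained synthetic dataset emulating the 9-library notochord design.

The generator produces everything downstream stages consume — genome
FASTA, CDS-only gene models as GFF3, an annotation table, the library
design table and per-library SAM alignments — together with exact
ground truth for every stage: per-gene per-library expected fractional
counts, differential-expression labels, anterior–posterior pattern
labels for the hox-like genes, and a compartment label for every read.

What it emulates: a fragmented multi-contig draft genome; 100-bp
paired-end reads whose mates are independent records on the same
contig; per-read alignment identity drawn from a configurable profile
(substitutions only, so identity = 1 - NM/read_length exactly); reads
distributed over genomic compartments with the study-like mix
coding-exon 34.8% / downstream-window 32.1% / intron 4.1% / intergenic
29.0%; stage x segment expression gradients including collinear
"hox-like" anterior/posterior profiles; and planted differentially
expressed genes at chosen fold changes.

Reads placed in a compartment lie entirely inside one element of that
compartment (one CDS exon, one downstream window, one intron, one safe
intergenic interval), so the expected fractional count of a gene is the
sum of its CDS reads' realized identities and the compartment label of
every read is unambiguous under the classifier's priority rule.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quantify import COMPARTMENTS, GeneModel

STAGES = ("T1", "T2", "T3")
SEGMENTS = ("A", "M", "P")
DEFAULT_DESIGN = tuple((t, s) for t in STAGES for s in SEGMENTS)

# study-like compartment mix for mapped reads
DEFAULT_REGION_MIX = {
    "coding_exon": 0.348,
    "downstream_window": 0.321,
    "intron": 0.041,
    "intergenic": 0.290,
}

# mostly-high identities with a tail below the 0.90 floor
DEFAULT_IDENTITY_PROFILE = {
    1.00: 0.55,
    0.98: 0.15,
    0.95: 0.12,
    0.92: 0.08,
    0.90: 0.05,
    0.85: 0.03,
    0.80: 0.02,
}

_HOX_CLUSTERS = "abcd"


def _library_name(stage: str, segment: str) -> str:
    return f"{stage}{segment}"


@dataclass(frozen=True)
class DEGene:
    """A planted differentially expressed gene.

    ``comparison`` is e.g. ``"T1-vs-T3"`` (stage axis) or ``"A-vs-P"``
    (segment axis); the gene's mean is multiplied by ``fold_change`` in
    the libraries of the second condition.
    """

    gene_id: str
    comparison: str
    fold_change: float


@dataclass
class SimulationConfig:
    seed: int
    n_contigs: int = 6
    contig_length: int = 60_000
    n_genes: int = 40
    read_length: int = 100
    n_libraries: int = 9
    design: tuple = DEFAULT_DESIGN
    reads_per_library: int = 6000
    de_genes: tuple[DEGene, ...] = ()
    identity_profile: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_PROFILE))
    region_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MIX))
    downstream_window: int = 1000
    n_hox: int = 12
    gradient_strength: float = 4.0  # max/min segment ratio for hox-like genes

    def validate(self) -> None:
        if len(self.design) != self.n_libraries:
            raise ConfigError("design must have exactly n_libraries entries")
        if len(set(self.design)) != len(self.design):
            raise ConfigError("stage x segment combinations must be unique")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("region_mix must sum to 1.0")
        unknown = set(self.region_mix) - set(COMPARTMENTS)
        if unknown:
            raise ConfigError(f"unknown region_mix compartments: {sorted(unknown)}")
        for w in self.identity_profile:
            if not (0.0 <= w <= 1.0):
                raise ConfigError(f"identity fraction {w} outside [0, 1]")
        for d in self.de_genes:
            if d.fold_change <= 0:
                raise ConfigError("true fold changes must be > 0")
        if self.reads_per_library % 2:
            raise ConfigError("reads_per_library must be even (paired mates)")
        if self.n_hox > self.n_genes:
            raise ConfigError("n_hox cannot exceed n_genes")

    @property
    def libraries(self) -> list[str]:
        return [_library_name(t, s) for t, s in self.design]


@dataclass
class SimulatedGenome:
    contigs: dict[str, str]
    models: list[GeneModel]
    intergenic_safe: dict[str, list[tuple[int, int]]]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        """CDS-only models; GFF3 1-based inclusive coordinates."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in self.models:
                gs, ge = m.span
                fh.write(f"{m.contig}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                         f"ID={m.gene_id}\n")
                for j, (s, e) in enumerate(m.cds, 1):
                    fh.write(f"{m.contig}\tsim\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                             f"ID={m.gene_id}.cds{j};Parent={m.gene_id}\n")


@dataclass
class SimRead:
    read_id: str
    contig: str
    start: int  # 0-based leftmost reference position
    length: int
    nm: int
    is_read2: bool
    region: str
    gene_id: str | None  # set for coding_exon reads

    @property
    def identity(self) -> float:
        return (self.length - self.nm) / self.length

    def to_aligned_read(self):
        """The counting-layer view of this simulated record."""
        from .quantify import AlignedRead

        return AlignedRead(
            read_id=f"{self.read_id}/{2 if self.is_read2 else 1}",
            contig=self.contig, blocks=((self.start, self.start + self.length),),
            read_length=self.length, nm=self.nm)


@dataclass
class GroundTruth:
    """Exact per-stage truth for the generated dataset."""

    expected_counts: pd.DataFrame  # genes x libraries, expected fractional counts
    tallies: pd.DataFrame          # genes x libraries, identity-passing CDS reads
    de_labels: dict[str, list[tuple[str, float]]]  # gene -> [(comparison, fc)]
    pattern_labels: dict[str, str]  # hox-like gene -> anterior/posterior
    read_regions: dict[str, dict[str, str]]  # library -> read key -> compartment

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_counts": self.expected_counts.to_dict(),
            "tallies": self.tallies.to_dict(),
            "de_labels": self.de_labels,
            "pattern_labels": self.pattern_labels,
            "read_regions": self.read_regions,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            expected_counts=pd.DataFrame(payload["expected_counts"]),
            tallies=pd.DataFrame(payload["tallies"]),
            de_labels={g: [tuple(x) for x in v] for g, v in payload["de_labels"].items()},
            pattern_labels=payload["pattern_labels"],
            read_regions=payload["read_regions"],
        )


def _rng(seed: int, *salt: str) -> np.random.Generator:
    """Deterministic child generator; label-salted so streams are stable."""
    salted = [seed] + [zlib.crc32(s.encode()) for s in salt]
    return np.random.default_rng(np.random.SeedSequence(salted))


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out non-overlapping genes on a fragmented multi-contig reference.

    Genes are separated by more than the downstream window plus a read
    margin, so no gene's 1000-bp 3' window can reach a neighbour; both
    strands are used. Raises ConfigError when the requested genes do
    not fit on the requested contigs.
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    rlen = config.read_length
    margin = config.downstream_window + rlen + 200
    contig_names = [f"contig{i + 1}" for i in range(config.n_contigs)]

    cursors = {c: margin for c in contig_names}
    placements: dict[str, list] = {c: [] for c in contig_names}
    models: list[GeneModel] = []
    ci = 0
    for g in range(config.n_genes):
        gid = f"gene{g + 1:04d}"
        # first two genes always multi-exon so introns exist for placement
        n_exons = 2 if g < 2 else int(rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3]))
        exon_lens = rng.integers(rlen + 60, 400, size=n_exons)
        intron_lens = rng.integers(rlen + 150, 500, size=max(n_exons - 1, 0))
        glen = int(exon_lens.sum() + intron_lens.sum())
        placed = False
        for _ in range(config.n_contigs):
            contig = contig_names[ci % config.n_contigs]
            pos = cursors[contig]
            if pos + glen + margin <= config.contig_length:
                strand = "+" if rng.random() < 0.5 else "-"
                cds = []
                p = pos
                for j in range(n_exons):
                    cds.append((p, p + int(exon_lens[j])))
                    p += int(exon_lens[j])
                    if j < n_exons - 1:
                        p += int(intron_lens[j])
                models.append(GeneModel(gid, contig, strand, tuple(cds)))
                placements[contig].append(models[-1])
                cursors[contig] = p + margin
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise ConfigError(
                f"genes do not fit: placed {g} of {config.n_genes} on "
                f"{config.n_contigs} x {config.contig_length} bp contigs")

    bases = np.array(list("ACGT"))
    contigs = {c: "".join(rng.choice(bases, size=config.contig_length))
               for c in contig_names}

    # safe intergenic intervals: outside every gene span and 3' window,
    # with a read-length buffer so partial overlaps cannot occur
    safe: dict[str, list[tuple[int, int]]] = {}
    for contig in contig_names:
        blocked = []
        for m in placements[contig]:
            gs, ge = m.span
            ws, we = m.downstream_window(config.downstream_window)
            lo = min(gs, ws) - rlen
            hi = max(ge, we) + rlen
            blocked.append((max(0, lo), min(config.contig_length, hi)))
        blocked.sort()
        merged = []
        for lo, hi in blocked:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        gaps, prev = [], 0
        for lo, hi in merged:
            if lo - prev >= rlen:
                gaps.append((prev, lo))
            prev = hi
        if config.contig_length - prev >= rlen:
            gaps.append((prev, config.contig_length))
        safe[contig] = gaps

    return SimulatedGenome(contigs=contigs, models=models, intergenic_safe=safe)


def _hox_symbols(n: int) -> list[str]:
    out = []
    i = 0
    while len(out) < n:
        cluster = _HOX_CLUSTERS[i % 4]
        number = i // 4 + 1
        out.append(f"hox{cluster}{number}a")
        i += 1
    return out


def gene_design_means(config: SimulationConfig, gene_ids: list[str]) -> tuple[pd.DataFrame, dict, dict]:
    """Per-gene per-library relative expression means plus truth labels.

    Baseline means are log-normal across genes. The first ``n_hox``
    genes carry collinear anterior-posterior gradients (alternating
    anterior-high / posterior-high at ``gradient_strength`` max/min
    ratio). Planted DE genes have the second condition's libraries
    scaled by the stated fold change.
    """
    rng = _rng(config.seed, "means")
    base = np.exp(rng.normal(np.log(30.0), 0.8, size=len(gene_ids)))
    means = pd.DataFrame(
        np.tile(base[:, None], (1, config.n_libraries)),
        index=gene_ids, columns=config.libraries)

    pattern_labels: dict[str, str] = {}
    g = config.gradient_strength
    seg_factors = {"anterior": {"A": g, "M": np.sqrt(g), "P": 1.0},
                   "posterior": {"A": 1.0, "M": np.sqrt(g), "P": g}}
    for i in range(config.n_hox):
        gid = gene_ids[i]
        pattern = "anterior" if i % 2 == 0 else "posterior"
        pattern_labels[gid] = pattern
        for (stage, seg) in config.design:
            means.loc[gid, _library_name(stage, seg)] *= seg_factors[pattern][seg]

    de_labels: dict[str, list[tuple[str, float]]] = {}
    for d in config.de_genes:
        a, b = d.comparison.split("-vs-")
        for (stage, seg) in config.design:
            if b in (stage, seg):
                means.loc[d.gene_id, _library_name(stage, seg)] *= d.fold_change
        de_labels.setdefault(d.gene_id, []).append((d.comparison, d.fold_change))

    return means, de_labels, pattern_labels


def _mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_alignments(
    config: SimulationConfig, genome: SimulatedGenome,
) -> tuple[dict[str, list[SimRead]], GroundTruth]:
    """Place paired 100-bp reads per the compartment mix and gene means.

    Each fragment yields two mate records in the same compartment
    element on the same contig. Every read's NM is realized from the
    identity profile (substitutions only) and both mates are placed
    entirely inside their element, so ground-truth fractional counts
    and compartment labels are exact.
    """
    config.validate()
    models = genome.models
    gene_ids = [m.gene_id for m in models]
    by_gene = {m.gene_id: m for m in models}
    means, de_labels, pattern_labels = gene_design_means(config, gene_ids)

    cds_exons = {g: [iv for iv in by_gene[g].cds if iv[1] - iv[0] >= config.read_length]
                 for g in gene_ids}
    intron_elems = []
    for m in models:
        for (s0, e0), (s1, _) in zip(m.cds, m.cds[1:]):
            if s1 - e0 >= config.read_length:
                intron_elems.append((m.contig, e0, s1))
    window_elems = [(m.contig, *m.downstream_window(config.downstream_window))
                    for m in models]
    window_elems = [(c, max(0, s), e) for c, s, e in window_elems if e - s >= config.read_length]
    intergenic_elems = [(c, s, e) for c, ivs in genome.intergenic_safe.items()
                        for s, e in ivs]
    if config.region_mix.get("intron", 0) > 0 and not intron_elems:
        raise ConfigError("region_mix requests intron reads but no intron is long enough")
    if config.region_mix.get("intergenic", 0) > 0 and not intergenic_elems:
        raise ConfigError("no safe intergenic interval available")

    id_vals = np.array(sorted(config.identity_profile))
    id_probs = np.array([config.identity_profile[v] for v in id_vals])
    id_probs = id_probs / id_probs.sum()
    rlen = config.read_length
    min_identity_exact = 0.90  # truth bookkeeping mirrors the default filter

    reads: dict[str, list[SimRead]] = {}
    exp_counts = pd.DataFrame(0.0, index=gene_ids, columns=config.libraries)
    tallies = pd.DataFrame(0, index=gene_ids, columns=config.libraries)
    read_regions: dict[str, dict[str, str]] = {}

    region_names = list(COMPARTMENTS)
    mix = np.array([config.region_mix.get(r, 0.0) for r in region_names])

    def _elem_weights(elems):
        w = np.array([e - s for _, s, e in elems], dtype=float)
        return w / w.sum()

    intron_w = _elem_weights(intron_elems) if intron_elems else None
    window_w = _elem_weights(window_elems)
    inter_w = _elem_weights(intergenic_elems)

    for lib in config.libraries:
        rng = _rng(config.seed, "reads", lib)
        n_frags = config.reads_per_library // 2
        frag_regions = rng.multinomial(n_frags, mix)
        lib_reads: list[SimRead] = []
        lib_regions: dict[str, str] = {}
        frag_no = 0
        for region, n_region in zip(region_names, frag_regions):
            if region == "coding_exon":
                p = means[lib].to_numpy()
                gene_counts = rng.multinomial(n_region, p / p.sum())
                jobs = [(g, c) for g, c in zip(gene_ids, gene_counts) if c > 0]
            else:
                jobs = [(None, n_region)]
            for gid, n in jobs:
                for _ in range(n):
                    frag_no += 1
                    if region == "coding_exon":
                        exons = cds_exons[gid]
                        contig = by_gene[gid].contig
                        elems = [(contig, s, e) for s, e in exons]
                        ew = _elem_weights(elems)
                    elif region == "downstream_window":
                        elems, ew = window_elems, window_w
                    elif region == "intron":
                        elems, ew = intron_elems, intron_w
                    else:
                        elems, ew = intergenic_elems, inter_w
                    contig, es, ee = elems[int(rng.choice(len(elems), p=ew))]
                    for mate in (False, True):
                        start = int(rng.integers(es, ee - rlen + 1))
                        w = float(rng.choice(id_vals, p=id_probs))
                        nm = round((1.0 - w) * rlen)
                        key = f"{lib}:frag{frag_no:06d}/{2 if mate else 1}"
                        lib_reads.append(SimRead(
                            read_id=f"{lib}:frag{frag_no:06d}", contig=contig,
                            start=start, length=rlen, nm=nm, is_read2=mate,
                            region=region, gene_id=gid))
                        lib_regions[key] = region
                        if region == "coding_exon":
                            w_real = (rlen - nm) / rlen
                            if w_real >= min_identity_exact:
                                exp_counts.loc[gid, lib] += w_real
                                tallies.loc[gid, lib] += 1
        reads[lib] = lib_reads
        read_regions[lib] = lib_regions

    truth = GroundTruth(expected_counts=exp_counts, tallies=tallies,
                        de_labels=de_labels, pattern_labels=pattern_labels,
                        read_regions=read_regions)
    return reads, truth


def write_sam(path: str | Path, lib_reads: list[SimRead],
              genome: SimulatedGenome, rng_seed: int) -> None:
    """Emit a SAM v1 file with @SQ headers, NM tags and mate flags.

    Read sequences are reference substrings with NM substitutions; the
    CIGAR is always full-length M so identity recomputes exactly from
    NM and the read length.
    """
    import pysam

    rng = _rng(rng_seed, "seq", Path(path).name)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(genome.contigs[name])}
               for name in sorted(genome.contigs)],
    }
    tid = {name: i for i, name in enumerate(sorted(genome.contigs))}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in lib_reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            ref = genome.contigs[r.contig][r.start:r.start + r.length]
            a.query_sequence = _mutate(ref, r.nm, rng)
            a.flag = 0x1 | (0x80 if r.is_read2 else 0x40) | (0x10 if r.is_read2 else 0x20)
            a.reference_id = tid[r.contig]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{r.length}M"
            a.next_reference_id = tid[r.contig]
            a.next_reference_start = r.start
            a.template_length = 0
            a.set_tag("NM", r.nm)
            out.write(a)


def make_annotation(config: SimulationConfig, genome: SimulatedGenome) -> pd.DataFrame:
    """Gene annotation table: symbol, blast score, KEGG pathways, GO terms.

    The first ``n_hox`` genes get hox symbols; two pairs of non-hox
    paralogs share a symbol (exercising annotation-level fusion); a
    quarter of non-hox genes are GO-tagged "extracellular matrix".
    """
    rng = _rng(config.seed, "annotation")
    gene_ids = [m.gene_id for m in genome.models]
    n = len(gene_ids)
    symbols = _hox_symbols(config.n_hox) + [
        f"gene{i}" for i in range(config.n_hox + 1, n + 1)]
    # shared-symbol paralog pairs among non-hox genes
    if n - config.n_hox >= 4:
        symbols[config.n_hox + 1] = symbols[config.n_hox]
        symbols[config.n_hox + 3] = symbols[config.n_hox + 2]

    kegg_pool = [f"ko{4000 + 10 * i:05d}" for i in range(12)]
    rows = []
    for i, gid in enumerate(gene_ids):
        blast = float(rng.integers(50, 900))
        n_pw = int(rng.integers(1, 4))
        pws = sorted(rng.choice(kegg_pool, size=n_pw, replace=False))
        go = []
        if i >= config.n_hox and rng.random() < 0.25:
            go.append("GO:0031012|extracellular matrix")
        go.append("GO:0008150|biological_process")
        rows.append({"gene_id": gid, "symbol": symbols[i], "blast_score": blast,
                     "kegg_pathways": ";".join(pws), "go_terms": ";".join(go)})
    return pd.DataFrame(rows)


def design_table(config: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [{"library": _library_name(t, s), "stage": t, "segment": s}
         for t, s in config.design])


def simulate_count_matrix(
    n_genes: int,
    base_mean: float,
    de_genes: list[DEGene],
    seed: int,
    design: tuple = DEFAULT_DESIGN,
    gene_prefix: str = "gene",
) -> tuple[pd.DataFrame, dict[str, list[tuple[str, float]]]]:
    """Poisson counts around design means, skipping read-level simulation.

    A convenience for differential-expression power studies: each cell
    is Poisson(mean), with planted genes' second-condition libraries
    scaled by the stated fold change. Returns (counts, de_labels).
    """
    rng = _rng(seed, "countsim")
    libraries = [_library_name(t, s) for t, s in design]
    gene_ids = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    means = pd.DataFrame(base_mean, index=gene_ids, columns=libraries, dtype=float)
    de_labels: dict[str, list[tuple[str, float]]] = {}
    for d in de_genes:
        if d.fold_change <= 0:
            raise ConfigError("true fold changes must be > 0")
        a, b = d.comparison.split("-vs-")
        for (stage, seg) in design:
            if b in (stage, seg):
                means.loc[d.gene_id, _library_name(stage, seg)] *= d.fold_change
        de_labels.setdefault(d.gene_id, []).append((d.comparison, d.fold_change))
    counts = pd.DataFrame(rng.poisson(means.to_numpy()).astype(float),
                          index=gene_ids, columns=libraries)
    return counts, de_labels


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic dataset to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    reads, truth = simulate_alignments(config, genome)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "design": outdir / "design.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "ground_truth.json",
    }
    genome.write_fasta(paths["fasta"])
    genome.write_gff3(paths["gff"])
    design_table(config).to_csv(paths["design"], sep="\t", index=False)
    make_annotation(config, genome).to_csv(paths["annotation"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    for lib, lib_reads in reads.items():
        p = outdir / f"{lib}.sam"
        write_sam(p, lib_reads, genome, config.seed)
        paths[f"sam:{lib}"] = p
    return paths
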
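"""Readers and writers for the standard formats the pipeline consumes.

GFF3 gene models are loaded through gffutils (in-memory db), SAM/BAM
through pysam. Tables are plain TSV; written tables carry a
``#``-prefixed provenance header with the config hash and seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import InputFormatError
from .quantify import AlignedRead, GeneModel


def load_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Read CDS-only gene models from GFF3 (1-based inclusive coordinates).

    CDS features are grouped by their Parent attribute (falling back to
    the feature ID's prefix); strand comes from the strand column.
    """
    import gffutils

    try:
        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # sqlite/parse failures
        raise InputFormatError(f"cannot parse GFF3 {gff_path}: {exc}") from exc

    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        gid = parents[0] if parents else cds.id.split(".cds")[0]
        entry = grouped.setdefault(gid, {"contig": cds.seqid, "strand": cds.strand,
                                         "intervals": []})
        if entry["contig"] != cds.seqid or entry["strand"] != cds.strand:
            raise InputFormatError(f"gene {gid}: CDS features disagree on contig/strand")
        entry["intervals"].append((cds.start, cds.end))
    if not grouped:
        raise InputFormatError(f"no CDS features found in {gff_path}")
    models = [GeneModel.from_gff_intervals(gid, e["contig"], e["strand"], e["intervals"])
              for gid, e in grouped.items()]
    models.sort(key=lambda m: m.gene_id)
    return models


def iter_sam_reads(sam_path: str | Path) -> Iterator[AlignedRead]:
    """Yield mapped alignment records as AlignedRead.

    Aligned reference blocks come from the CIGAR M/=/X operations; the
    NM tag is mandatory — a mapped record without it is a format error,
    never silently defaulted.
    """
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise InputFormatError(
                    f"{sam_path}: read {rec.query_name} lacks the NM tag")
            length = rec.infer_read_length() or rec.query_length
            if not length:
                raise InputFormatError(
                    f"{sam_path}: read {rec.query_name} has no determinable length")
            suffix = "/2" if rec.is_read2 else "/1" if rec.is_paired else ""
            yield AlignedRead(
                read_id=rec.query_name + suffix,
                contig=rec.reference_name,
                blocks=tuple(rec.get_blocks()),
                read_length=int(length),
                nm=int(rec.get_tag("NM")),
            )


def sam_reference_contigs(sam_path: str | Path) -> set[str]:
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        return set(fh.references)


def load_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", comment="#")
    required = {"library", "stage", "segment"}
    if not required.issubset(design.columns):
        raise InputFormatError(f"design table needs columns {sorted(required)}")
    return design


def load_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "symbol", "blast_score", "kegg_pathways", "go_terms"}
    if not required.issubset(ann.columns):
        raise InputFormatError(f"annotation table needs columns {sorted(required)}")
    return ann


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None,
                index_label: str | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines (UTF-8, tab-delimited)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
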
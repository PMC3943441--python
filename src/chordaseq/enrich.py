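"""DEG filtering, KEGG pathway up/down ratio ranking and ECM gene retrieval.

Implements the pathway-level summary applied to the notochord DEG
lists: only genes with blast score over 300 and fold change over 1.5
count as DEGs for pathway mapping; each pathway's up- and
down-regulated member counts give a ratio (larger count over smaller,
with a denominator floor of 1) used to rank up- and down-regulated
pathways; pathways with fewer than 10 DEGs are flagged as insufficient
for inclusion. Separately, extracellular-matrix genes are retrieved by
flat GO annotation lookup, floored at more than 100 reads in the
highest-coverage library, and cross-checked against the DEG list.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import InputFormatError

logger = logging.getLogger(__name__)


def _indexed(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation


def filter_degs(degs: pd.DataFrame, annotation: pd.DataFrame,
                min_blast: float = 300.0, min_fc: float = 1.5) -> pd.DataFrame:
    """Keep DEGs with blast_score > min_blast AND fold_change > min_fc.

    Both inequalities are strict: a blast score of exactly 300 or a
    fold change of exactly 1.5 is excluded. Genes without an
    annotation entry are excluded and logged.
    """
    ann = _indexed(annotation)
    if "fold_change" not in degs.columns:
        raise InputFormatError("DEG table lacks a fold_change column")
    known = degs["gene_id"].isin(ann.index)
    if (~known).any():
        logger.info("filter_degs: %d DEGs lack annotation and are excluded",
                    int((~known).sum()))
    degs = degs[known].copy()
    blast = degs["gene_id"].map(ann["blast_score"])
    keep = (blast > min_blast) & (degs["fold_change"] > min_fc)
    return degs[keep.to_numpy()]


def rank_pathways(filtered_degs: pd.DataFrame, annotation: pd.DataFrame,
                  min_pathway_degs: int = 10,
                  zero_denominator: str = "floor1") -> pd.DataFrame:
    """Per-pathway up/down counts, ratio and inclusion flag.

    A gene annotated to several pathways counts once in each. The
    ratio is max(n_up, n_down) / max(min(n_up, n_down), 1) — the
    denominator floor of 1 keeps one-sided pathways finite
    (``zero_denominator='inf'`` switches to infinite-first ordering).
    ``direction`` is the majority side; pathways with n_up == n_down
    have ratio 1 and direction "tie". ``included`` flags pathways with
    at least ``min_pathway_degs`` DEGs. Rows are sorted by ratio
    descending, ties broken by n_deg descending then pathway id.
    """
    ann = _indexed(annotation)
    counts: dict[str, dict[str, int]] = {}
    for _, row in filtered_degs.iterrows():
        pws = ann.loc[row["gene_id"], "kegg_pathways"]
        if not isinstance(pws, str) or not pws:
            continue
        for pw in pws.split(";"):
            c = counts.setdefault(pw, {"up": 0, "down": 0})
            c[row["direction"]] += 1
    rows = []
    for pw, c in counts.items():
        up, down = c["up"], c["down"]
        hi, lo = max(up, down), min(up, down)
        if zero_denominator == "inf" and lo == 0:
            ratio = float("inf")
        else:
            ratio = hi / max(lo, 1)
        rows.append({
            "pathway_id": pw, "n_up": up, "n_down": down, "n_deg": up + down,
            "ratio": ratio,
            "direction": "up" if up > down else ("down" if down > up else "tie"),
            "included": up + down >= min_pathway_degs,
        })
    table = pd.DataFrame(rows, columns=["pathway_id", "n_up", "n_down", "n_deg",
                                        "ratio", "direction", "included"])
    if len(table):
        table = table.sort_values(
            ["ratio", "n_deg", "pathway_id"], ascending=[False, False, True],
        ).reset_index(drop=True)
    return table


def ranked_pathways(table: pd.DataFrame, direction: str,
                    include_all: bool = False) -> pd.DataFrame:
    """The up- or down-regulated ranked list: majority-side pathways with
    ratio above 1, included pathways only unless ``include_all``."""
    sel = (table["direction"] == direction) & (table["ratio"] > 1)
    if not include_all:
        sel &= table["included"]
    return table[sel].reset_index(drop=True)


def _go_match(go_terms: str, wanted: str) -> bool:
    if not isinstance(go_terms, str):
        return False
    w = wanted.lower()
    for term in go_terms.split(";"):
        for part in term.split("|"):
            if part.strip().lower() == w:
                return True
    return False


def ecm_genes(tallies: pd.DataFrame, annotation: pd.DataFrame,
              degs: pd.DataFrame | None = None,
              go_term: str = "extracellular matrix",
              min_reads: int = 100) -> dict[str, list[str]]:
    """GO-retrieved ECM genes above the read floor, split by DE direction.

    A gene qualifies when its flat GO annotation contains ``go_term``
    (matched case-insensitively against term ids or names, no ontology
    propagation) and its highest per-library read tally is strictly
    above ``min_reads``. When a DEG table is given, qualifying genes
    are joined against it to form up- and down-regulated panels.
    """
    ann = _indexed(annotation)
    is_ecm = ann["go_terms"].apply(_go_match, wanted=go_term)
    ecm_ids = [g for g in tallies.index
               if g in ann.index and bool(is_ecm.get(g, False))]
    passing = [g for g in ecm_ids if tallies.loc[g].max() > min_reads]
    out = {"genes": passing, "up": [], "down": []}
    if degs is not None and len(degs):
        de = degs[degs["gene_id"].isin(passing)]
        out["up"] = sorted(de.loc[de["direction"] == "up", "gene_id"].unique())
        out["down"] = sorted(de.loc[de["direction"] == "down", "gene_id"].unique())
    return out
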
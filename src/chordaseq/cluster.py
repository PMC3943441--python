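"""Annotation-level gene fusion, k-means profile clustering and A–P patterns.

Supports the hox-style analysis: rows sharing a gene symbol are fused
(summed on the linear scale, before any log transform), profiles are
log2-transformed with a small pseudocount and grouped by k-means, and
each gene's anterior–posterior pattern is classified from its
per-segment means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigError, InputFormatError


def fuse_by_symbol(values: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Sum linear-scale library profiles of rows sharing an annotation symbol.

    Fusion happens before log transformation. Genes without an
    annotation entry pass through singly under their own gene id.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    symbols = values.index.to_series().map(ann["symbol"])
    symbols = symbols.fillna(pd.Series(values.index, index=values.index))
    fused = values.groupby(symbols).sum()
    fused.index.name = "symbol"
    return fused


def log2_profiles(values: pd.DataFrame, epsilon: float = 0.01) -> pd.DataFrame:
    """Display/clustering transform log2(x + eps); eps defaults to 0.01."""
    if epsilon <= 0:
        raise ConfigError("epsilon must be > 0")
    return np.log2(values + epsilon)


@dataclass
class ClusterAssignment:
    labels: pd.Series          # row id -> "G1".."Gk"
    centroids: pd.DataFrame    # cluster x libraries
    inertia: float             # total within-cluster sum of squares

    @property
    def k(self) -> int:
        return len(self.centroids)


def kmeans_profiles(profiles: pd.DataFrame, k: int, seed: int = 0,
                    restarts: int = 25) -> ClusterAssignment:
    """Best-of-``restarts`` k-means on (already log-transformed) profiles.

    Clusters are relabelled G1..Gk by ascending centroid mean so the
    labelling is deterministic (G1 = lowest-expressed group). Identical
    inputs with the same seed give identical assignments.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(profiles):
        raise ConfigError(f"k={k} exceeds the {len(profiles)} available profiles")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(profiles.to_numpy())
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): f"G{rank + 1}" for rank, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=[f"G{i + 1}" for i in range(k)],
                             columns=profiles.columns)
    return ClusterAssignment(labels=labels, centroids=centroids,
                             inertia=float(km.inertia_))


def segment_means(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average profiles over stages, yielding one column per segment A/M/P."""
    d = design.set_index("library") if "library" in design.columns else design
    missing = [c for c in values.columns if c not in d.index]
    if missing:
        raise InputFormatError(f"design lacks libraries {missing}")
    return values.T.groupby(d.loc[values.columns, "segment"]).mean().T[["A", "M", "P"]]


def ap_pattern(profile, flat_ratio: float = 1.25) -> str:
    """Classify an (A, M, P) profile as anterior / mid / posterior / flat.

    The label is the argmax segment; profiles whose max/min ratio falls
    below ``flat_ratio`` are "flat". Scale-invariant by construction.
    """
    a = np.asarray(profile, dtype=float)
    if a.shape != (3,):
        raise InputFormatError("ap_pattern expects exactly the three segment means (A, M, P)")
    if a.max() <= 0:
        return "flat"
    lo = a.min()
    if lo > 0 and a.max() / lo < flat_ratio:
        return "flat"
    return ("anterior", "mid", "posterior")[int(a.argmax())]


def ap_patterns(values: pd.DataFrame, design: pd.DataFrame,
                flat_ratio: float = 1.25) -> pd.Series:
    seg = segment_means(values, design)
    return pd.Series({idx: ap_pattern(row.to_numpy(), flat_ratio)
                      for idx, row in seg.iterrows()}, name="pattern")


def position_pattern_correlation(patterns: pd.Series) -> float:
    """Spearman rank correlation between hox cluster position and A-P pattern.

    A quantitative proxy for collinearity: symbols are ranked by the
    numeric part of their hox name (genomic 3'->5' position) and
    patterns by anterior(0) < mid/flat(1) < posterior(2).
    """
    import re

    from scipy.stats import spearmanr

    rows = []
    score = {"anterior": 0, "flat": 1, "mid": 1, "posterior": 2}
    for sym, pat in patterns.items():
        m = re.match(r"hox[a-d](\d+)", str(sym))
        if m:
            rows.append((int(m.group(1)), score[pat]))
    if len(rows) < 3:
        return float("nan")
    pos, pat = zip(*rows)
    rho = spearmanr(pos, pat).statistic
    return float(rho)
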
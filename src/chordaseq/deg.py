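"""No-replicate differential expression via simulated technical replicates.

The study design has nine libraries and no biological replicates, so
libraries are pooled into summed pseudo-replicates — the three
segments of each stage (sumT1, sumT2, sumT3) or the three stages of
each segment (sumA, sumM, sumP) — and differential expression between
two pooled conditions is called with an M–D exceedance statistic:

* technical replicates are simulated for each condition by multinomial
  resampling of the pooled counts (``nss`` replicates of size
  ``pnr * total``, jittered by ``±v * pnr * total``);
* the noise distribution collects (|M|, D) over all within-condition
  replicate pairs, where M = log2 ratio and D = absolute difference
  (zeros replaced by a pseudocount k before the log);
* the signal (M, D) for each gene is computed between condition means
  of the simulated replicates, and the DE probability is the fraction
  of noise points the signal exceeds on both coordinates (non-strict,
  so ties favour DE);
* a gene is declared differentially expressed when p > q (default 0.8).

Defaults nss=5, pnr=0.2, v=0.02 follow the documented no-replicate
defaults of the NOISeq-sim scheme; all are exposed. Condition
replicate streams are seeded from a stable hash of the condition
label, making the probability exactly invariant under exchanging the
two condition labels (only the sign of M, hence the direction, flips).
"""

from __future__ import annotations

import itertools
import logging
import zlib

import numpy as np
import pandas as pd

from .errors import ConfigError, InputFormatError

logger = logging.getLogger(__name__)

AXES = {"stage": ("T1", "T2", "T3"), "segment": ("A", "M", "P")}


def pool(matrix: pd.DataFrame, design: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Sum libraries into pooled pseudo-replicates along one design axis.

    ``axis='stage'`` yields sumT1..sumT3 (three segments summed per
    stage); ``axis='segment'`` yields sumA..sumP. Pooled value = sum of
    member values, so pooling conserves totals exactly.
    """
    if axis not in AXES:
        raise ConfigError(f"axis must be 'stage' or 'segment', got {axis!r}")
    design = design.set_index("library") if "library" in design.columns else design
    pools = {}
    for level in AXES[axis]:
        members = design.index[design[axis] == level]
        if len(members) != 3:
            raise InputFormatError(
                f"design incomplete: {axis}={level} has libraries {list(members)}")
        missing = [m for m in members if m not in matrix.columns]
        if missing:
            raise InputFormatError(f"matrix missing libraries {missing}")
        pools[f"sum{level}"] = matrix[list(members)].sum(axis=1)
    return pd.DataFrame(pools)


def _condition_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def simulate_technical_replicates(
    counts: pd.Series, nss: int, pnr: float, v: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial technical replicates of one pooled library.

    Each of the ``nss`` replicates draws ``round(pnr * total)`` reads
    (jittered uniformly by ±v of that size) with per-gene probabilities
    proportional to the pooled counts. Returns a genes x nss array.
    """
    if not (0.0 < pnr <= 1.0):
        raise ConfigError(f"pnr must be in (0, 1], got {pnr}")
    if v < 0:
        raise ConfigError(f"v must be >= 0, got {v}")
    total = float(counts.sum())
    if total <= 0:
        raise ConfigError("pooled library total must be > 0")
    p = counts.to_numpy(dtype=float) / total
    base = pnr * total
    out = np.empty((len(counts), nss))
    for j in range(nss):
        size = int(round(base + rng.uniform(-v, v) * base))
        out[:, j] = rng.multinomial(max(size, 1), p)
    return out


def _md(a: np.ndarray, b: np.ndarray, k: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Signed M (log2 ratio, zeros replaced by k) and D (absolute difference)."""
    ak = np.where(a == 0, k, a)
    bk = np.where(b == 0, k, b)
    # log difference (not log of ratio) so exchanging a and b negates M
    # bit-exactly; |M| is then invariant under condition-label exchange
    return np.log2(ak) - np.log2(bk), np.abs(a - b)


def _exceedance(m_sig: np.ndarray, d_sig: np.ndarray,
                m_noise: np.ndarray, d_noise: np.ndarray,
                chunk: int = 512) -> np.ndarray:
    """P(signal dominates noise) per gene: fraction of noise points with
    |M_n| <= |M_s| and D_n <= D_s (non-strict on both coordinates)."""
    n = len(m_sig)
    out = np.empty(n)
    if len(m_noise) == 0:
        out.fill(0.0)
        return out
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dom = (m_noise[None, :] <= m_sig[lo:hi, None]) & \
              (d_noise[None, :] <= d_sig[lo:hi, None])
        out[lo:hi] = dom.mean(axis=1)
    return out


def de_probability(
    pools: pd.DataFrame, cond1: str, cond2: str,
    nss: int = 5, pnr: float = 0.2, v: float = 0.02, k: float = 0.5,
    q: float = 0.8, seed: int = 0,
) -> pd.DataFrame:
    """M–D differential-expression probabilities between two pooled conditions.

    Returns one row per gene with columns M, D, prob, de, direction and
    fold_change for comparison ``{cond1}-vs-{cond2}``. M is
    log2(cond2 / cond1), so direction "up" means up-regulated from
    cond1 to cond2. Genes with zero counts in both conditions are
    skipped (prob NaN) and their number logged.
    """
    for c in (cond1, cond2):
        if c not in pools.columns:
            raise InputFormatError(f"condition {c!r} not among pools {list(pools.columns)}")
    reps = {c: simulate_technical_replicates(
        pools[c], nss, pnr, v, _condition_rng(seed, c)) for c in (cond1, cond2)}

    m_noise, d_noise = [], []
    for c in (cond1, cond2):
        for i, j in itertools.combinations(range(nss), 2):
            m, d = _md(reps[c][:, i], reps[c][:, j], k)
            m_noise.append(np.abs(m))
            d_noise.append(d)
    m_noise = np.concatenate(m_noise)
    d_noise = np.concatenate(d_noise)
    # drop no-change noise points (replicate pair identical for the gene):
    # they are non-strictly dominated by every signal, including (0, 0),
    # and carry no information about technical variability
    keep = ~((m_noise == 0.0) & (d_noise == 0.0))
    m_noise, d_noise = m_noise[keep], d_noise[keep]

    mean1 = reps[cond1].mean(axis=1)
    mean2 = reps[cond2].mean(axis=1)
    m_sig, d_sig = _md(mean2, mean1, k)

    both_zero = (pools[cond1].to_numpy() == 0) & (pools[cond2].to_numpy() == 0)
    if both_zero.any():
        logger.info("%s-vs-%s: skipped %d genes with zero counts in both conditions",
                    cond1, cond2, int(both_zero.sum()))

    prob = _exceedance(np.abs(m_sig), d_sig, m_noise, d_noise)
    prob = np.where(both_zero, np.nan, prob)
    de = prob > q
    out = pd.DataFrame({
        "gene_id": pools.index,
        "comparison": f"{cond1}-vs-{cond2}",
        "M": m_sig,
        "D": d_sig,
        "prob": prob,
        "de": de,
        "direction": np.where(m_sig >= 0, "up", "down"),
        "fold_change": np.exp2(np.abs(m_sig)),
    }).set_index("gene_id")
    out.loc[both_zero, "de"] = False
    return out


def pairwise_deg(
    pools: pd.DataFrame, q: float = 0.8,
    nss: int = 5, pnr: float = 0.2, v: float = 0.02, k: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """All three pairwise comparisons among three pooled conditions.

    Returns the concatenated DEG table (declared genes only) and a
    summary dict with per-comparison up/down tallies and the 3-set
    Venn region counts of the DEG sets.
    """
    conds = list(pools.columns)
    if len(conds) != 3:
        raise InputFormatError(f"expected three pooled conditions, got {conds}")
    tables = []
    sets: dict[str, set] = {}
    updown: dict[str, dict[str, int]] = {}
    for a, b in itertools.combinations(conds, 2):
        t = de_probability(pools, a, b, nss=nss, pnr=pnr, v=v, k=k, q=q, seed=seed)
        called = t[t["de"]]
        comp = f"{a}-vs-{b}"
        sets[comp] = set(called.index)
        updown[comp] = {
            "up": int((called["direction"] == "up").sum()),
            "down": int((called["direction"] == "down").sum()),
            "total": int(len(called)),
        }
        tables.append(called.reset_index())
    deg_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()

    comps = list(sets)
    venn = {}
    for mask in range(1, 8):
        inset = [comps[i] for i in range(3) if mask & (1 << i)]
        outset = [comps[i] for i in range(3) if not mask & (1 << i)]
        region = set.intersection(*(sets[c] for c in inset))
        for c in outset:
            region -= sets[c]
        venn["&".join(inset)] = len(region)
    summary = {"per_comparison": updown, "venn": venn}
    return deg_table, summary
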
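"""Classical per-term enrichment: counts, hypergeometric tails, BH and Bonferroni.

The hypergeometric null assumes genes are drawn independently: the chance
that an in-interval gene carries a term depends only on the term's genome-wide
frequency K/N.  This is the assumption the cyclic permutation engine relaxes;
here it is computed exactly as the classical baseline.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationMap, GeneCatalog, IntervalSet, genes_in_intervals, merge_intervals

__all__ = [
    "term_counts",
    "hypergeom_upper_tail",
    "bh_adjust",
    "bonferroni_adjust",
    "enrich",
]


def term_counts(inclusion: np.ndarray, ann: AnnotationMap, cat: GeneCatalog) -> dict[str, int]:
    """Per-term count k of included genes annotated (post-closure) with the term.

    Terms with K = 0 in the universe do not appear.
    """
    inclusion = np.asarray(inclusion)
    if inclusion.shape[0] != cat.n:
        raise ValueError(f"inclusion length {inclusion.shape[0]} != catalog size {cat.n}")
    return {t: int(inclusion[pos].sum()) for t, pos in ann.term_positions.items()}


def hypergeom_upper_tail(k: int, K: int, n_drawn: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n_drawn); 1 when k = 0."""
    if not (0 <= K <= N and 0 <= n_drawn <= N):
        raise ValueError(f"inconsistent arguments K={K}, n_drawn={n_drawn}, N={N}")
    if not (0 <= k <= min(K, n_drawn)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n_drawn={n_drawn})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n_drawn))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def bonferroni_adjust(pvals, m: int) -> np.ndarray:
    """Multiply by the hypothesis count ``m`` and cap at 1."""
    p = np.asarray(pvals, dtype=float)
    if m < 1:
        raise ValueError(f"hypothesis count m={m} < 1")
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p-values ({p.size})")
    return np.minimum(p * m, 1.0)


def enrich(iv: IntervalSet, cat: GeneCatalog, ann: AnnotationMap) -> pd.DataFrame:
    """Hypergeometric enrichment of every term with K >= 1.

    Returns a frame with columns term, k, K, n_drawn, N, p_hyper, q_fdr,
    sorted by (p_hyper, term).  q_fdr is BH-adjusted across all tested terms.
    An empty interval set is valid: all k = 0 and all p = 1.
    """
    merged = iv if iv.merged else merge_intervals(iv)
    inclusion = genes_in_intervals(cat, merged)
    n_drawn = int(inclusion.sum())
    N = cat.n
    counts = term_counts(inclusion, ann, cat)
    terms = sorted(counts)
    k = np.array([counts[t] for t in terms], dtype=np.int64)
    K = np.array([ann.K(t) for t in terms], dtype=np.int64)
    # vectorised upper tail P(X >= k); sf(k-1) handles k = 0 giving exactly 1
    p = stats.hypergeom.sf(k - 1, N, K, n_drawn) if terms else np.array([])
    # sf can underflow to exactly 0 for extreme counts; keep p in (0, 1]
    p = np.clip(p, 5e-324, 1.0)
    p[k == 0] = 1.0
    out = pd.DataFrame(
        {
            "term": terms,
            "k": k,
            "K": K,
            "n_drawn": n_drawn,
            "N": N,
            "p_hyper": p,
        }
    )
    out["q_fdr"] = bh_adjust(out["p_hyper"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_hyper", "term"], kind="mergesort").reset_index(drop=True)
    return out
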
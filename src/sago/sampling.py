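"""Seeded sampling of random genomic interval sets and the null experiment.

Random interval draws are the negative control of the whole method: by
construction no term should be genuinely enriched in them, so any recurrent
enrichment exposes the spatial clustering of a term's genes.  Placement is
uniform over all admissible start positions genome-wide: a chromosome is
chosen with probability proportional to its placeable length
(length − interval length + 1), then a start uniformly within it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import bonferroni_adjust, enrich
from .genome import AnnotationMap, ChromosomeSizes, GeneCatalog, IntervalSet, genes_in_intervals

__all__ = [
    "SamplerConfig",
    "sample_intervals",
    "run_null_experiment",
    "run_residual_experiment",
    "NullExperiment",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Random-interval sampler settings.

    n_intervals: how many intervals to draw; length: interval length in bp;
    allow_overlap: whether sampled intervals may overlap each other (default
    True); max_attempts: rejection budget when disjointness is requested.
    """

    n_intervals: int
    length: int
    seed: int = 0
    allow_overlap: bool = True
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def sample_intervals(
    sizes: ChromosomeSizes,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Draw ``cfg.n_intervals`` intervals of ``cfg.length`` bp uniformly over
    placeable genome positions.  Chromosomes shorter than the interval length
    are excluded (warned via ValueError if none remain).  With
    ``allow_overlap=False``, overlapping draws are rejected and resampled up
    to ``cfg.max_attempts`` times each."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed]))
    placeable = np.array(
        [length - cfg.length + 1 for length in sizes.lengths], dtype=np.int64
    )
    admissible = placeable > 0
    if not admissible.any():
        raise ValueError(f"no chromosome can hold an interval of length {cfg.length}")
    if not cfg.allow_overlap:
        total = int(cfg.n_intervals) * int(cfg.length)
        if total > sizes.total_length:
            raise ValueError("requested total interval length exceeds the genome")
    weights = np.where(admissible, placeable, 0).astype(float)
    weights /= weights.sum()

    chosen: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for _ in range(cfg.n_intervals):
        for attempt in range(cfg.max_attempts):
            ci = int(rng.choice(len(sizes.names), p=weights))
            start = int(rng.integers(0, placeable[ci]))
            chrom = sizes.names[ci]
            end = start + cfg.length
            if cfg.allow_overlap:
                break
            clash = any(s < end and start < e for s, e in occupied.get(chrom, []))
            if not clash:
                break
        else:
            raise RuntimeError(
                f"could not place a disjoint interval after {cfg.max_attempts} attempts"
            )
        chosen.append((chrom, start, end))
        occupied.setdefault(chrom, []).append((start, end))
    df = pd.DataFrame(chosen, columns=["chrom", "start", "end"])
    return IntervalSet(df)


@dataclass
class NullExperiment:
    """Per-term p-values across repeated random-interval draws.

    ``raw_p`` / ``adj_p``: term × repeat frames of hypergeometric p-values,
    raw and Bonferroni-adjusted within each repeat (m = #tested terms).
    """

    raw_p: pd.DataFrame
    adj_p: pd.DataFrame
    alpha_family: float
    n_repeats: int

    def frequency(self, alpha: float = 0.05) -> pd.Series:
        """Per-term fraction of repeats with per-run Bonferroni-adjusted
        p < ``alpha`` (the chance score of each term)."""
        return (self.adj_p < alpha).mean(axis=1)

    def frequency_raw_threshold(self) -> pd.Series:
        """Per-term fraction of repeats with raw p below
        alpha_family / n_repeats (the repeat-wise Bonferroni convention)."""
        return (self.raw_p < self.alpha_family / self.n_repeats).mean(axis=1)

    def min_p_per_repeat(self, adjusted: bool = True) -> pd.Series:
        frame = self.adj_p if adjusted else self.raw_p
        return frame.min(axis=0)

    def summary(self) -> pd.DataFrame:
        """Per-term table: enrichment frequency and minimum adjusted p."""
        return pd.DataFrame(
            {
                "term": self.adj_p.index,
                "frequency": self.frequency().to_numpy(),
                "frequency_raw_threshold": self.frequency_raw_threshold().to_numpy(),
                "min_adj_p": self.adj_p.min(axis=1).to_numpy(),
            }
        ).reset_index(drop=True)


def run_null_experiment(
    cat: GeneCatalog,
    ann: AnnotationMap,
    sizes: ChromosomeSizes,
    cfg: SamplerConfig,
    n_repeats: int = 100,
    alpha_family: float = 0.05,
) -> NullExperiment:
    """Repeatedly sample random intervals and record per-term enrichment.

    Each repeat r uses a generator derived from (cfg.seed, r) so individual
    repeats are reproducible in isolation.  Returns all raw and per-repeat
    Bonferroni-adjusted hypergeometric p-values.
    """
    terms = ann.terms
    raw = np.ones((len(terms), n_repeats))
    adj = np.ones((len(terms), n_repeats))
    index = {t: i for i, t in enumerate(terms)}
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, r]))
        iv = sample_intervals(sizes, cfg, rng=rng)
        table = enrich(iv, cat, ann)
        p = table["p_hyper"].to_numpy()
        a = bonferroni_adjust(p, len(table))
        rows = [index[t] for t in table["term"]]
        raw[rows, r] = p
        adj[rows, r] = a
    cols = list(range(n_repeats))
    return NullExperiment(
        raw_p=pd.DataFrame(raw, index=pd.Index(terms, name="term"), columns=cols),
        adj_p=pd.DataFrame(adj, index=pd.Index(terms, name="term"), columns=cols),
        alpha_family=alpha_family,
        n_repeats=n_repeats,
    )


def run_residual_experiment(
    cat: GeneCatalog,
    ann: AnnotationMap,
    sizes: ChromosomeSizes,
    cfg: SamplerConfig,
    n_repeats: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chance score vs spatial residual over repeated random interval draws.

    For each repeat, every term's cyclic and random permutation p-values are
    computed against a fresh random interval draw and the residual regression
    is fitted within the repeat; each term's residual is then averaged over
    repeats and the term is assigned to a residual bin.  The chance score is
    the fraction of repeats in which the term's per-repeat
    Bonferroni-adjusted hypergeometric p fell below ``alpha``.

    Returns a frame with columns term, mean_residual, bin_center,
    chance_score.
    """
    from .permutation import (
        _term_digest,
        cyclic_counts_all_shifts,
        empirical_pvalue,
        random_permutation_pvalue,
    )
    from .spatial import fit_residuals, residual_bin

    terms = ann.terms
    n = cat.n
    resid_sum = np.zeros(len(terms))
    enriched = np.zeros(len(terms))
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, r]))
        iv = sample_intervals(sizes, cfg, rng=rng)
        inclusion = genes_in_intervals(cat, iv)
        p_cyc = np.empty(len(terms))
        p_rnd = np.empty(len(terms))
        for i, t in enumerate(terms):
            membership = ann.membership_vector(t)
            p_cyc[i] = empirical_pvalue(cyclic_counts_all_shifts(membership, inclusion))
            p_rnd[i] = random_permutation_pvalue(
                membership, inclusion, n - 1,
                np.random.SeedSequence([cfg.seed, r, _term_digest(t)]),
            )
        fitted = fit_residuals(
            pd.DataFrame({"term": terms, "p_cyclic": p_cyc, "p_random": p_rnd}),
            p_floor=1.0 / n,
        )
        resid_sum += fitted["residual"].to_numpy()
        table = enrich(iv, cat, ann)
        adj = pd.Series(
            bonferroni_adjust(table["p_hyper"].to_numpy(), len(table)),
            index=table["term"].to_numpy(),
        )
        enriched += (adj.reindex(terms).to_numpy() < alpha).astype(float)
    mean_residual = resid_sum / n_repeats
    return pd.DataFrame(
        {
            "term": terms,
            "mean_residual": mean_residual,
            "bin_center": residual_bin(mean_residual),
            "chance_score": enriched / n_repeats,
        }
    )
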
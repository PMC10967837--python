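"""Residual metric for per-term spatial clustering, plus its diagnostics.

For a spatially dispersed term, order-preserving (cyclic) and order-destroying
(random) permutations are equally surprising, so its −log₁₀ p-values fall on
a common trend line.  A clustered term reaches a given in-interval count far
more easily under rotations than under shuffles: its random-permutation p is
much smaller than the cyclic trend predicts, giving a large positive residual
from the OLS fit of y = −log₁₀ p_random on x = −log₁₀ p_cyclic.  The residual
is therefore a per-term score of spatial dependency; the chance score (how
often the term is enriched in repeated random interval draws) and the
fraction of terms the two-step test eliminates are its external validators.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fit_residuals",
    "residual_bin",
    "chance_score",
    "bin_and_summarize",
    "fraction_corrected",
]


def residual_bin(residual) -> np.ndarray:
    """Bin center = residual rounded to the nearest multiple of 0.5 (half-width
    0.25); ties at bin edges round half up."""
    r = np.asarray(residual, dtype=float)
    return np.floor(2.0 * r + 0.5) / 2.0


def fit_residuals(
    pairs: pd.DataFrame | Sequence[tuple[float, float]],
    p_floor: float | None = None,
) -> pd.DataFrame:
    """OLS of y = −log₁₀ p_random on x = −log₁₀ p_cyclic; residual = y − ŷ.

    ``pairs`` is a frame with columns p_cyclic and p_random (extra columns
    such as term are carried through) or a sequence of (p_cyclic, p_random)
    tuples.  P-values are floored at ``p_floor`` (default: their observed
    minimum) before the log transform so no infinities arise.  Requires at
    least two distinct x values; positive residual ⇔ spatial clustering.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        df = pd.DataFrame(pairs, columns=["p_cyclic", "p_random"])
    if len(df) < 2:
        raise ValueError("need at least two (p_cyclic, p_random) pairs")
    pc = df["p_cyclic"].to_numpy(dtype=float)
    pr = df["p_random"].to_numpy(dtype=float)
    if np.any((pc <= 0) | (pc > 1)) or np.any((pr <= 0) | (pr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p_floor is not None:
        pc = np.maximum(pc, p_floor)
        pr = np.maximum(pr, p_floor)
    x = -np.log10(pc)
    y = -np.log10(pr)
    if np.allclose(x, x[0]):
        raise ValueError("all p_cyclic identical: regression slope undefined")
    fit = stats.linregress(x, y)
    df["x"] = x
    df["y"] = y
    df["residual"] = y - (fit.intercept + fit.slope * x)
    df["bin_center"] = residual_bin(df["residual"].to_numpy())
    df.attrs["slope"] = float(fit.slope)
    df.attrs["intercept"] = float(fit.intercept)
    return df


def chance_score(term: str, runs: Iterable[dict | pd.Series]) -> float:
    """Fraction of random-interval runs in which ``term`` was enriched.

    Each run is a mapping term → Bonferroni-adjusted hypergeometric p (terms
    absent from a run count as not enriched); enrichment means adjusted
    p < 0.05.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    hits = sum(1 for run in runs if float(run.get(term, 1.0)) < 0.05)
    return hits / len(runs)


def bin_and_summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of chance_score per residual bin.

    ``records`` must carry residual and chance_score columns; bins with a
    single record get a NaN standard error (undefined).
    """
    df = records.copy()
    if "bin_center" not in df:
        df["bin_center"] = residual_bin(df["residual"].to_numpy())
    grouped = df.groupby("bin_center")["chance_score"]
    out = grouped.agg(mean_chance_score="mean", sem_chance_score="sem", n_terms="size")
    return out.reset_index()


def fraction_corrected(records: pd.DataFrame) -> pd.DataFrame:
    """Per residual bin, the fraction of gated terms the two-step test
    eliminated (verdict == 'eliminated'); order-invariant."""
    df = records.copy()
    if "bin_center" not in df:
        df["bin_center"] = residual_bin(df["residual"].to_numpy())
    def _frac(sub: pd.Series) -> float:
        return float((sub == "eliminated").mean())
    out = df.groupby("bin_center")["verdict"].agg(fraction_corrected=_frac, n_terms="size")
    return out.reset_index()
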
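"""Model/Results interface over the two-step spatially adjusted enrichment.

``SagoModel`` bundles the data (intervals, gene catalog, annotations);
``fit()`` runs the two-step procedure and returns ``SagoResults`` carrying
the per-term estimates, verdicts, the spatial residual diagnostics and a
text ``summary()``.

Example
-------
>>> from sago import SagoModel
>>> from sago.synthetic import make_scenario
>>> sc = make_scenario("spurious_clustered", seed=0)
>>> res = SagoModel(sc.intervals, sc.catalog, sc.annotation).fit(seed=0)
>>> print(res.summary())          # doctest: +SKIP
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .genome import (
    AnnotationMap,
    ChromosomeSizes,
    GeneCatalog,
    IntervalSet,
    TermDAG,
    ancestral_closure,
    genes_in_intervals,
    merge_intervals,
    read_annotation_pairs,
    read_bed,
    read_chrom_sizes,
    read_gene_table,
)
from .permutation import SagoRun, run_sago
from .spatial import fit_residuals

__all__ = ["SagoModel", "SagoResults"]


class SagoModel:
    """Spatially adjusted gene-ontology enrichment model.

    Parameters
    ----------
    intervals : IntervalSet
        The measured genomic intervals (merged internally).
    catalog : GeneCatalog
        All genes with TSS coordinates; defines the circular genome order
        and the universe size N.
    annotation : AnnotationMap
        Post-closure gene→term annotations bound to the catalog.
    """

    def __init__(
        self,
        intervals: IntervalSet,
        catalog: GeneCatalog,
        annotation: AnnotationMap,
    ) -> None:
        self.intervals = intervals if intervals.merged else merge_intervals(intervals)
        self.catalog = catalog
        self.annotation = annotation

    @classmethod
    def from_files(
        cls,
        intervals: str | Path,
        genes: str | Path,
        sizes: str | Path,
        annotations: str | Path,
        obo: str | Path | None = None,
    ) -> "SagoModel":
        """Build the model from standard files: BED3+ intervals, a gene table
        (TSV), a two-column chromosome sizes file, gene→term annotations
        (TSV or GAF), and optionally an OBO ontology for ancestral closure."""
        chrom_sizes = read_chrom_sizes(sizes)
        catalog = read_gene_table(genes, chrom_sizes)
        iv = read_bed(intervals, chrom_sizes)
        dag = TermDAG.from_obo(obo) if obo is not None else None
        ann = ancestral_closure(read_annotation_pairs(annotations), dag, catalog)
        return cls(iv, catalog, ann)

    @property
    def inclusion(self) -> np.ndarray:
        """0/1 vector in genome order flagging genes whose TSS is covered."""
        return genes_in_intervals(self.catalog, self.intervals)

    def fit(
        self,
        fdr_gate: float = 0.1,
        alpha: float = 0.05,
        seed: int = 0,
        n_random_perms: int | None = None,
    ) -> "SagoResults":
        """Run the two-step procedure and return the results object.

        fdr_gate : BH q-value threshold of the hypergeometric pre-filter.
        alpha : significance level on the Bonferroni-adjusted cyclic p.
        n_random_perms : random permutations per gated term (default n − 1,
        matching the number of cyclic rotations).
        """
        if not (0 < fdr_gate < 1) or not (0 < alpha < 1):
            raise ValueError("fdr_gate and alpha must lie in (0, 1)")
        run = run_sago(
            self.intervals,
            self.catalog,
            self.annotation,
            fdr_gate=fdr_gate,
            alpha=alpha,
            seed=seed,
            n_random_perms=n_random_perms,
        )
        return SagoResults(self, run)


class SagoResults:
    """Fitted results of the two-step spatially adjusted enrichment.

    Attributes
    ----------
    table : DataFrame
        One row per gated term: counts, hypergeometric p and q, cyclic and
        random permutation p-values, Bonferroni-adjusted cyclic p, verdict.
    enrichment : DataFrame
        The step-1 hypergeometric table for every tested term.
    """

    def __init__(self, model: SagoModel, run: SagoRun) -> None:
        self.model = model
        self._run = run
        self.table = run.table
        self.enrichment = run.enrichment

    # -- scalar descriptors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self._run.n_genes

    @property
    def n_drawn(self) -> int:
        return self._run.n_drawn

    @property
    def floor(self) -> float:
        """Lowest attainable cyclic p-value, 1/n."""
        return self._run.floor

    @property
    def retained(self) -> list[str]:
        return self._run.retained

    @property
    def eliminated(self) -> list[str]:
        return self._run.eliminated

    @property
    def params(self) -> dict:
        return {
            "fdr_gate": self._run.fdr_gate,
            "alpha": self._run.alpha,
            "seed": self._run.seed,
            "n_random_perms": self._run.n_random_perms,
        }

    def manifest(self) -> dict:
        return self._run.manifest()

    # -- diagnostics --------------------------------------------------------
    def spatial_metrics(self) -> pd.DataFrame:
        """Residual diagnostics for the gated terms: OLS of −log₁₀ p_random
        on −log₁₀ p_cyclic, residual and residual bin.  Needs ≥ 2 gated
        terms with distinct cyclic p-values."""
        if len(self.table) < 2:
            raise ValueError("need at least two gated terms for the residual regression")
        cols = ["term", "p_cyclic", "p_random", "verdict"]
        return fit_residuals(self.table[cols].copy(), p_floor=self.floor)

    # -- output -------------------------------------------------------------
    def _config_hash(self) -> str:
        payload = json.dumps(self.params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_tsv(self, path: str | Path) -> None:
        """Write the gated-term table as TSV with a commented header line."""
        with open(path, "w") as fh:
            fh.write(f"# sago {_version} config={self._config_hash()}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def save_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)
            fh.write("\n")

    def summary(self) -> str:
        """Human-readable run summary and gated-term table."""
        man = self.manifest()
        lines = [
            "Spatially adjusted GO enrichment (two-step cyclic permutation test)",
            "=" * 68,
            f"genes (N): {man['n_genes']:>8}    genes in intervals (n_drawn): {man['n_drawn']}",
            f"terms tested: {man['n_terms_tested']:>5}    cyclic permutations: {man['n_cyclic_perms']}",
            f"FDR gate: {man['fdr_gate']:<6}   alpha: {man['alpha']:<6}   p floor (1/n): {man['p_floor']:.3g}",
            f"gated: {man['n_gated']}   retained: {man['n_retained']}   "
            f"eliminated (spatial): {man['n_eliminated']}",
            "-" * 68,
        ]
        if len(self.table):
            show = self.table.copy()
            for col in ("p_hyper", "q_fdr", "p_cyclic", "adj_p_cyclic", "p_random"):
                show[col] = show[col].map("{:.3g}".format)
            lines.append(show.to_string(index=False))
        else:
            lines.append("no term passed the FDR gate")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        man = self.manifest()
        return (
            f"<SagoResults: {man['n_gated']} gated, {man['n_retained']} retained, "
            f"{man['n_eliminated']} eliminated>"
        )
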
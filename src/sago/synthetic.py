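"""Synthetic genomes, ontologies and annotations with controlled spatial structure.

The generator emulates the one feature of real genomes that the method
exists for: some functional terms annotate genes that sit in a handful of
contiguous genomic blocks (the olfactory-receptor geometry), while others
annotate genes scattered uniformly along the genome.  Everything else —
gene density, DAG topology — is kept deliberately simple: genes at jittered
regular spacing, a one-root ontology so ancestral closure is exercised.

Default desk scale: 5,000 genes on 4 chromosomes at 100 kb mean spacing
(~505 Mb), so the cyclic-permutation floor 1/5,000 sits far below the usual
significance levels while a full rotation sweep takes milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    AnnotationMap,
    ChromosomeSizes,
    GeneCatalog,
    IntervalSet,
    TermDAG,
    ancestral_closure,
)
from .sampling import SamplerConfig, sample_intervals

__all__ = [
    "TermSpec",
    "SyntheticSpec",
    "Scenario",
    "make_genome",
    "make_annotation",
    "make_scenario",
    "write_fixture",
    "ROOT_TERM",
]

ROOT_TERM = "SYN:0000000"


@dataclass(frozen=True)
class TermSpec:
    """One synthetic term.

    ``layout`` is 'clustered' (members in ``n_blocks`` contiguous runs of
    genome order) or 'dispersed' (uniform without replacement).  Clustered
    blocks are placed either at random non-adjacent positions
    (``placement='random'``) or at exactly equal spacing n/n_blocks around
    the circular genome with a random phase (``placement='periodic'``).
    Periodic placement makes the term's membership vector invariant under
    rotation by n/n_blocks, so its all-shifts count vector is exactly
    periodic and every count value — including the observed one — ties at
    least n_blocks times: the term's cyclic p-value has a hard floor of
    n_blocks/n.  This is the stylised multi-locus (olfactory-receptor-like)
    geometry used by the spurious-enrichment fixtures.
    """

    name: str
    K: int
    layout: str = "dispersed"
    n_blocks: int = 1
    placement: str = "random"

    def __post_init__(self) -> None:
        if self.layout not in ("clustered", "dispersed"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.placement not in ("random", "periodic"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.K < 1 or self.n_blocks < 1 or self.n_blocks > self.K:
            raise ValueError(f"invalid K={self.K}, n_blocks={self.n_blocks}")
        if self.placement == "periodic" and self.K % self.n_blocks:
            raise ValueError("periodic placement needs K divisible by n_blocks")


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 5000
    n_chromosomes: int = 4
    gene_spacing: int = 100_000
    terms: tuple[TermSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        for t in self.terms:
            if t.K > self.n_genes:
                raise ValueError(f"term {t.name}: K={t.K} exceeds n_genes")


def make_genome(spec: SyntheticSpec) -> tuple[ChromosomeSizes, GeneCatalog]:
    """Genes at jittered regular spacing; deterministic under spec.seed.

    Gene j on a chromosome gets TSS in [j·spacing, j·spacing + 0.8·spacing),
    so TSSs stay sorted and inside the chromosome.  Chromosome length is
    (genes + 1) · spacing.
    """
    jitter_span = int(0.8 * spec.gene_spacing)
    if jitter_span < 1:
        raise ValueError(f"gene_spacing {spec.gene_spacing} too small to jitter")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    names, lengths, rows = [], [], []
    gid = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        names.append(chrom)
        lengths.append(int((per_chrom[c] + 1) * spec.gene_spacing))
        offsets = rng.integers(0, jitter_span, size=per_chrom[c])
        strands = rng.choice(["+", "-"], size=per_chrom[c])
        for j in range(per_chrom[c]):
            rows.append(
                (f"g{gid:05d}", chrom, int(j * spec.gene_spacing + offsets[j]), strands[j])
            )
            gid += 1
    sizes = ChromosomeSizes(tuple(names), tuple(lengths))
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return sizes, GeneCatalog.from_frame(frame, sizes)


def _place_blocks(
    rng: np.random.Generator, n_genes: int, K: int, n_blocks: int
) -> np.ndarray:
    """Choose ``n_blocks`` contiguous runs of order indices totalling K genes,
    separated from each other by at least one block length (non-adjacent
    multi-locus clusters)."""
    base = K // n_blocks
    blk_sizes = np.full(n_blocks, base)
    blk_sizes[: K % n_blocks] += 1
    gap = int(blk_sizes.max())
    for _ in range(200):
        starts = np.sort(rng.integers(0, n_genes - blk_sizes.max(), size=n_blocks))
        spans = [(s, s + b) for s, b in zip(starts, blk_sizes)]
        ok = all(spans[i + 1][0] >= spans[i][1] + gap for i in range(n_blocks - 1))
        if ok and spans[-1][1] <= n_genes:
            return np.concatenate([np.arange(s, e) for s, e in spans])
    raise ValueError(
        f"cannot place {n_blocks} non-adjacent blocks of ~{base} genes in {n_genes}"
    )


def _place_blocks_periodic(
    rng: np.random.Generator, n_genes: int, K: int, n_blocks: int
) -> np.ndarray:
    """Equal blocks of K/n_blocks genes every n_genes/n_blocks positions
    (random phase, wrapping the circle), giving exact rotational period
    n_genes/n_blocks."""
    if n_genes % n_blocks:
        raise ValueError(f"n_genes={n_genes} not divisible by n_blocks={n_blocks}")
    period = n_genes // n_blocks
    size = K // n_blocks
    if size > period:
        raise ValueError(f"blocks of {size} genes exceed the period {period}")
    phase = int(rng.integers(0, period))
    pos = (
        phase
        + np.arange(n_blocks)[:, None] * period
        + np.arange(size)[None, :]
    ) % n_genes
    return np.sort(pos.ravel())


def make_annotation(
    spec: SyntheticSpec, cat: GeneCatalog
) -> tuple[TermDAG, AnnotationMap]:
    """Assign each term's member genes per its layout and close annotations
    over a one-root DAG (every term is_a ROOT_TERM)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA11071]))
    gene_ids = cat.frame["gene_id"].to_numpy()
    pairs: list[tuple[str, str]] = []
    for t in spec.terms:
        if t.layout == "clustered" and t.placement == "periodic":
            pos = _place_blocks_periodic(rng, cat.n, t.K, t.n_blocks)
        elif t.layout == "clustered":
            pos = _place_blocks(rng, cat.n, t.K, t.n_blocks)
        else:
            pos = rng.choice(cat.n, size=t.K, replace=False)
        pairs.extend((gene_ids[p], t.name) for p in np.sort(pos))
    dag = TermDAG.from_edges(
        [ROOT_TERM] + [t.name for t in spec.terms],
        [(t.name, ROOT_TERM) for t in spec.terms],
    )
    ann = ancestral_closure(pairs, dag, cat)
    return dag, ann


@dataclass
class Scenario:
    """A complete fixture: genome, ontology, annotations and one interval draw,
    plus which terms were planted clustered/dispersed."""

    name: str
    spec: SyntheticSpec
    sizes: ChromosomeSizes
    catalog: GeneCatalog
    dag: TermDAG
    annotation: AnnotationMap
    intervals: IntervalSet
    sampler: SamplerConfig
    clustered_terms: list[str] = field(default_factory=list)
    dispersed_terms: list[str] = field(default_factory=list)
    planted_term: str | None = None
    clustering_level: dict[str, int] = field(default_factory=dict)

    def resample_intervals(self, seed: int) -> IntervalSet:
        """A fresh random interval draw over the same genome (the planted
        true_dispersed windows, if any, are not re-created)."""
        return sample_intervals(self.sizes, replace(self.sampler, seed=seed))


def _default_sampler(seed: int) -> SamplerConfig:
    # 80 intervals x 500 kb ~ 8% of the ~505 Mb default genome, the coverage
    # regime of large-domain experiments
    return SamplerConfig(n_intervals=80, length=500_000, seed=seed)


def _spurious_clustered(seed: int) -> Scenario:
    # olfactory-like terms: 4-6% of all genes spread over many multi-gene
    # loci (periodic placement, so each term's cyclic p has a hard tie
    # floor of n_blocks/n); intervals are few and large, the regime of
    # broad heterochromatin domains, so spurious enrichment of the
    # clustered terms is frequent while genuinely dispersed terms stay null
    terms: list[TermSpec] = []
    i = 0
    K_by_blocks = {
        10: (200, 220, 240, 260, 280, 300),
        20: (200, 220, 240, 260, 280, 300),
        25: (200, 225, 250, 275, 300),
        40: (200, 240, 280),
    }
    for n_blocks, Ks in K_by_blocks.items():
        for j in range(75):
            terms.append(
                TermSpec(f"clustered_{i:03d}", Ks[j % len(Ks)], "clustered", n_blocks, "periodic")
            )
            i += 1
    disp_K = np.geomspace(20, 300, 100).astype(int)
    terms += [TermSpec(f"dispersed_{j:03d}", int(K), "dispersed") for j, K in enumerate(disp_K)]
    spec = SyntheticSpec(terms=tuple(terms), seed=seed)
    sizes, cat = make_genome(spec)
    dag, ann = make_annotation(spec, cat)
    sampler = SamplerConfig(n_intervals=8, length=8_000_000, seed=seed)
    iv = sample_intervals(sizes, sampler)
    return Scenario(
        name="spurious_clustered",
        spec=spec,
        sizes=sizes,
        catalog=cat,
        dag=dag,
        annotation=ann,
        intervals=iv,
        sampler=sampler,
        clustered_terms=[t.name for t in terms if t.layout == "clustered"],
        dispersed_terms=[t.name for t in terms if t.layout == "dispersed"],
    )


def _true_dispersed(seed: int) -> Scenario:
    planted = TermSpec("planted_dispersed", 50, "dispersed")
    terms = [planted]
    terms += [
        TermSpec(f"clustered_{i:03d}", 200, "clustered", nb)
        for i, nb in enumerate((3, 4, 5, 5))
    ]
    disp_K = np.geomspace(20, 200, 60).astype(int)
    terms += [TermSpec(f"dispersed_{j:03d}", int(K), "dispersed") for j, K in enumerate(disp_K)]
    spec = SyntheticSpec(terms=tuple(terms), seed=seed)
    sizes, cat = make_genome(spec)
    dag, ann = make_annotation(spec, cat)
    # the "experiment" genuinely captures the planted term: 20 kb windows
    # around 40 of its 50 member TSSs, plus random background intervals
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A12]))
    pos = ann.term_positions["planted_dispersed"]
    picked = np.sort(rng.choice(pos, size=40, replace=False))
    genes = cat.frame
    rows = []
    for p in picked:
        g = genes.iloc[int(p)]
        length = sizes.length_of(g["chrom"])
        s = max(0, int(g["tss"]) - 10_000)
        e = min(length, int(g["tss"]) + 10_000)
        rows.append((g["chrom"], s, e))
    background = sample_intervals(
        sizes, SamplerConfig(n_intervals=40, length=500_000, seed=seed)
    )
    iv = IntervalSet(
        pd.concat(
            [pd.DataFrame(rows, columns=["chrom", "start", "end"]), background.frame],
            ignore_index=True,
        )
    )
    return Scenario(
        name="true_dispersed",
        spec=spec,
        sizes=sizes,
        catalog=cat,
        dag=dag,
        annotation=ann,
        intervals=iv,
        sampler=SamplerConfig(n_intervals=40, length=500_000, seed=seed),
        clustered_terms=[t.name for t in terms if t.layout == "clustered"],
        dispersed_terms=[t.name for t in terms if t.layout == "dispersed"],
        planted_term="planted_dispersed",
    )


def _mixed_gradient(seed: int) -> Scenario:
    # clustering levels from a single block (maximal clustering) to fully
    # dispersed; level recorded as n_blocks (0 = dispersed) for monotonicity
    # checks
    terms: list[TermSpec] = []
    level: dict[str, int] = {}
    i = 0
    for n_blocks in (1, 2, 3, 5, 10, 20):
        for _ in range(6):
            name = f"grad_{i:03d}"
            terms.append(TermSpec(name, 120, "clustered", n_blocks))
            level[name] = n_blocks
            i += 1
    disp_K = np.geomspace(10, 400, 60).astype(int)
    for j, K in enumerate(disp_K):
        name = f"dispersed_{j:03d}"
        terms.append(TermSpec(name, int(K), "dispersed"))
        level[name] = 0
    spec = SyntheticSpec(terms=tuple(terms), seed=seed)
    sizes, cat = make_genome(spec)
    dag, ann = make_annotation(spec, cat)
    sampler = SamplerConfig(n_intervals=8, length=8_000_000, seed=seed)
    iv = sample_intervals(sizes, sampler)
    return Scenario(
        name="mixed_gradient",
        spec=spec,
        sizes=sizes,
        catalog=cat,
        dag=dag,
        annotation=ann,
        intervals=iv,
        sampler=sampler,
        clustered_terms=[t.name for t in terms if t.layout == "clustered"],
        dispersed_terms=[t.name for t in terms if t.layout == "dispersed"],
        clustering_level=level,
    )


_SCENARIOS = {
    "spurious_clustered": _spurious_clustered,
    "true_dispersed": _true_dispersed,
    "mixed_gradient": _mixed_gradient,
}


def make_scenario(name: str, seed: int = 0) -> Scenario:
    """Build one of the named fixtures: 'spurious_clustered' (clustered terms
    under random intervals — enrichments are spatial artifacts),
    'true_dispersed' (intervals genuinely capture a dispersed term) or
    'mixed_gradient' (terms spanning clustering levels)."""
    try:
        builder = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        ) from None
    return builder(seed)


def write_fixture(directory: str | Path, sc: Scenario) -> dict[str, Path]:
    """Write the scenario as standard files (sizes TSV, gene TSV, BED,
    annotation TSV, minimal OBO) so it doubles as a CLI integration input."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sizes": directory / "chrom.sizes",
        "genes": directory / "genes.tsv",
        "intervals": directory / "intervals.bed",
        "annotations": directory / "annotations.tsv",
        "obo": directory / "ontology.obo",
    }
    sc.sizes.to_frame().to_csv(paths["sizes"], sep="\t", header=False, index=False)
    sc.catalog.frame[["gene_id", "chrom", "tss", "strand"]].to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    sc.intervals.to_bed(paths["intervals"])
    # raw (pre-closure) pairs: the root is re-derived by closure at load time
    with open(paths["annotations"], "w") as fh:
        gene_ids = sc.catalog.frame["gene_id"].to_numpy()
        for term, pos in sorted(sc.annotation.term_positions.items()):
            if term == ROOT_TERM:
                continue
            for p in pos:
                fh.write(f"{gene_ids[p]}\t{term}\n")
    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\n\n")
        fh.write(f"[Term]\nid: {ROOT_TERM}\nname: synthetic root\n\n")
        for t in sc.spec.terms:
            fh.write(f"[Term]\nid: {t.name}\nname: {t.name}\nis_a: {ROOT_TERM}\n\n")
    return paths
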
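"""Genome model: chromosome sizes, gene catalog, interval sets and GO annotations.

Everything downstream of this module works on two aligned vectors in *genome
order*: a 0/1 inclusion vector (is the gene's TSS inside the measured
intervals?) and, per ontology term, a 0/1 membership vector (does the gene
carry the term after ancestral closure?).  Genome order is the concatenation
of chromosomes in the order they appear in the sizes table, genes sorted by
TSS within each chromosome; it defines the circle used by the cyclic
permutation null.

Coordinates are 0-based half-open throughout (BED convention).  A gene is
placed by its transcription start site only: ``start`` for a +-strand gene,
``end - 1`` for a −-strand gene.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("sago")

__all__ = [
    "InputError",
    "ChromosomeSizes",
    "GeneCatalog",
    "IntervalSet",
    "TermDAG",
    "AnnotationMap",
    "read_chrom_sizes",
    "read_gene_table",
    "read_bed",
    "read_annotation_pairs",
    "merge_intervals",
    "ancestral_closure",
    "genes_in_intervals",
]


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# chromosome sizes


@dataclass(frozen=True)
class ChromosomeSizes:
    """Ordered chromosome names and lengths; file order defines chromosome rank."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise InputError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise InputError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in zip(self.names, self.lengths):
            if int(length) <= 0:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def rank(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.rank[name]]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self.rank

    def __len__(self) -> int:
        return len(self.names)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.names, "length": self.lengths})


def read_chrom_sizes(path: str | Path) -> ChromosomeSizes:
    """Read a two-column (name, length) tab-separated chromosome sizes file."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: length {parts[1]!r} is not an integer") from None
            if name in names:
                raise InputError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise InputError(f"{path}:{lineno}: non-positive length for {name!r}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise InputError(f"{path}: no chromosomes found")
    return ChromosomeSizes(tuple(names), tuple(lengths))


# ---------------------------------------------------------------------------
# gene catalog


@dataclass(frozen=True)
class GeneCatalog:
    """Genes in genome order.

    ``frame`` columns: gene_id, chrom, tss, strand, order_index; the frame is
    sorted by order_index (a bijection onto 0..n−1 induced by sorting on
    (chromosome rank, tss, gene_id)).
    """

    frame: pd.DataFrame
    sizes: ChromosomeSizes

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.frame["gene_id"])

    def position_of(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Map gene ids to order indices."""
        lookup = pd.Series(self.frame["order_index"].values, index=self.frame["gene_id"].values)
        return lookup.loc[list(gene_ids)].to_numpy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sizes: ChromosomeSizes) -> "GeneCatalog":
        """Validate a (gene_id, chrom, tss, strand) frame and assign genome order."""
        df = frame.loc[:, ["gene_id", "chrom", "tss", "strand"]].copy()
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise InputError(f"duplicate gene id {dup!r}")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise InputError(f"unknown strand symbol {df.loc[bad_strand, 'strand'].iloc[0]!r}")
        known = df["chrom"].isin(sizes.names)
        if not known.all():
            dropped = df.loc[~known, "chrom"].unique()
            logger.warning(
                "dropping %d gene(s) on chromosome(s) absent from sizes: %s",
                (~known).sum(), ", ".join(map(str, dropped)),
            )
            df = df.loc[known].copy()
        df["tss"] = df["tss"].astype(np.int64)
        chrom_len = df["chrom"].map(sizes.rank).map(dict(enumerate(sizes.lengths)))
        out_of_range = (df["tss"] < 0) | (df["tss"] >= chrom_len)
        if out_of_range.any():
            row = df.loc[out_of_range].iloc[0]
            raise InputError(
                f"gene {row['gene_id']!r}: TSS {row['tss']} outside chromosome {row['chrom']!r}"
            )
        df["_rank"] = df["chrom"].map(sizes.rank)
        df = df.sort_values(["_rank", "tss", "gene_id"], kind="mergesort").drop(columns="_rank")
        df = df.reset_index(drop=True)
        df["order_index"] = np.arange(len(df), dtype=np.int64)
        return cls(df, sizes)


def read_gene_table(path: str | Path, sizes: ChromosomeSizes) -> GeneCatalog:
    """Read a gene table: id, chrom, start, end, strand (BED-like, 5 cols) or
    id, chrom, tss, strand (4 cols).  The TSS of a −-strand gene given as a
    start/end pair is ``end − 1``."""
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"{path}: cannot parse gene table ({exc})") from exc
    if raw.shape[1] >= 5:
        df = raw.iloc[:, :5].copy()
        df.columns = ["gene_id", "chrom", "start", "end", "strand"]
        try:
            start = df["start"].astype(np.int64)
            end = df["end"].astype(np.int64)
        except ValueError as exc:
            raise InputError(f"{path}: non-integer coordinate in gene table ({exc})") from None
        bad = start >= end
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise InputError(f"{path}: gene {row['gene_id']!r} has start >= end")
        df["tss"] = np.where(df["strand"] == "+", start, end - 1)
    elif raw.shape[1] == 4:
        df = raw.copy()
        df.columns = ["gene_id", "chrom", "tss", "strand"]
        try:
            df["tss"] = df["tss"].astype(np.int64)
        except ValueError as exc:
            raise InputError(f"{path}: non-integer TSS in gene table ({exc})") from None
    else:
        raise InputError(f"{path}: expected 4 or 5 tab-separated columns, got {raw.shape[1]}")
    return GeneCatalog.from_frame(df[["gene_id", "chrom", "tss", "strand"]], sizes)


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True)
class IntervalSet:
    """Genomic intervals, 0-based half-open.  ``frame`` columns: chrom, start, end."""

    frame: pd.DataFrame
    merged: bool = False

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_bases(self) -> int:
        if len(self.frame) == 0:
            return 0
        return int((self.frame["end"] - self.frame["start"]).sum())

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int]] | pd.DataFrame,
        sizes: ChromosomeSizes | None = None,
    ) -> "IntervalSet":
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, ["chrom", "start", "end"]].copy()
        else:
            df = pd.DataFrame(list(records), columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        for i, row in enumerate(df.itertuples(index=False)):
            if row.start < 0 or row.start >= row.end:
                raise InputError(
                    f"interval {i}: {row.chrom}:{row.start}-{row.end} violates 0 <= start < end"
                )
            if sizes is not None:
                if row.chrom not in sizes:
                    raise InputError(f"interval {i}: unknown chromosome {row.chrom!r}")
                if row.end > sizes.length_of(row.chrom):
                    raise InputError(
                        f"interval {i}: {row.chrom}:{row.start}-{row.end} exceeds chromosome "
                        f"length {sizes.length_of(row.chrom)}"
                    )
        return cls(df.reset_index(drop=True))

    def to_bed(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, sizes: ChromosomeSizes) -> IntervalSet:
    """Read a BED3+ file; columns beyond the third are ignored.

    Records on chromosomes absent from ``sizes`` are dropped with a warning;
    inverted coordinates or records running past the chromosome end are errors.
    """
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected >=3 BED columns, got {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates in {line!r}") from None
            if chrom not in sizes:
                logger.warning("%s:%d: dropping interval on unknown chromosome %r", path, lineno, chrom)
                continue
            if start < 0 or start >= end:
                raise InputError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            if end > sizes.length_of(chrom):
                raise InputError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} exceeds chromosome length "
                    f"{sizes.length_of(chrom)}"
                )
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return IntervalSet(df)


def merge_intervals(iv: IntervalSet) -> IntervalSet:
    """Coalesce overlapping or book-ended intervals per chromosome (idempotent)."""
    if len(iv) == 0:
        return IntervalSet(iv.frame.copy(), merged=True)
    out = []
    for chrom, sub in iv.frame.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return IntervalSet(df.reset_index(drop=True), merged=True)


def genes_in_intervals(cat: GeneCatalog, iv: IntervalSet) -> np.ndarray:
    """0/1 inclusion vector in genome order: 1 iff the gene's TSS lies inside
    some interval [start, end) on its chromosome."""
    if not iv.merged:
        iv = merge_intervals(iv)
    inclusion = np.zeros(cat.n, dtype=np.int8)
    if len(iv) == 0 or cat.n == 0:
        return inclusion
    by_chrom = {chrom: sub for chrom, sub in iv.frame.groupby("chrom", sort=False)}
    genes = cat.frame
    for chrom, sub in genes.groupby("chrom", sort=False):
        ivs = by_chrom.get(chrom)
        if ivs is None:
            continue
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        tss = sub["tss"].to_numpy()
        idx = np.searchsorted(starts, tss, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(tss), dtype=bool)
        hit[ok] = tss[ok] < ends[idx[ok]]
        inclusion[sub["order_index"].to_numpy()[hit]] = 1
    return inclusion


# ---------------------------------------------------------------------------
# ontology


@dataclass(frozen=True)
class TermDAG:
    """Ontology term DAG; edges point child → parent (is_a / part_of only)."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise InputError(f"ontology graph contains a cycle: {cycle}")

    @classmethod
    def from_edges(cls, terms: Iterable[str], edges: Iterable[tuple[str, str]]) -> "TermDAG":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in edges:
            if child not in g or parent not in g:
                raise InputError(f"edge ({child!r}, {parent!r}) references unknown term")
            g.add_edge(child, parent)
        return cls(g)

    @classmethod
    def from_obo(cls, path: str | Path) -> "TermDAG":
        import obonet

        multi = obonet.read_obo(str(path))
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes)
        for child, parent, key in multi.edges(keys=True):
            if key in ("is_a", "part_of"):
                g.add_edge(child, parent)
        return cls(g)

    def ancestors(self, term: str) -> set[str]:
        """All ancestral parents of ``term`` (term itself excluded)."""
        if term not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term))  # child→parent edges

    def __contains__(self, term: object) -> bool:
        return term in self.graph


@dataclass(frozen=True)
class AnnotationMap:
    """Gene → term sets after ancestral closure, bound to a catalog.

    ``term_positions`` maps each term with K ≥ 1 to the sorted order indices
    of its member genes — the sparse form of the membership vectors that the
    permutation engine rotates.
    """

    gene_to_terms: Mapping[str, frozenset[str]]
    term_positions: Mapping[str, np.ndarray]
    universe: frozenset[str]
    n_genes: int

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_positions)

    def K(self, term: str) -> int:
        return len(self.term_positions[term])

    def membership_vector(self, term: str) -> np.ndarray:
        vec = np.zeros(self.n_genes, dtype=np.int8)
        vec[self.term_positions[term]] = 1
        return vec


def ancestral_closure(
    raw: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]],
    dag: TermDAG | None,
    cat: GeneCatalog,
) -> AnnotationMap:
    """Close each gene's term set under the parent relation and bind to the catalog.

    Annotations for genes absent from the catalog are dropped with a warning;
    terms absent from the DAG are kept without ancestors (warned).  Without a
    DAG the closure step is skipped (warned).
    """
    if isinstance(raw, Mapping):
        pairs = [(g, t) for g, ts in raw.items() for t in ts]
    else:
        pairs = list(raw)

    catalog_ids = set(cat.frame["gene_id"])
    unknown_genes = {g for g, _ in pairs if g not in catalog_ids}
    if unknown_genes:
        logger.warning("dropping annotations for %d gene(s) absent from the catalog", len(unknown_genes))
        pairs = [(g, t) for g, t in pairs if g not in unknown_genes]

    if dag is None:
        logger.warning("no ontology DAG supplied; ancestral closure skipped")
        anc_cache: dict[str, set[str]] = {}
    else:
        missing = sorted({t for _, t in pairs if t not in dag})
        if missing:
            logger.warning(
                "%d annotation term(s) absent from the ontology DAG (kept without ancestors): %s%s",
                len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
            )
        anc_cache = {}

    gene_terms: dict[str, set[str]] = {}
    for g, t in pairs:
        closed = gene_terms.setdefault(g, set())
        closed.add(t)
        if dag is not None:
            if t not in anc_cache:
                anc_cache[t] = dag.ancestors(t)
            closed.update(anc_cache[t])

    order = pd.Series(cat.frame["order_index"].values, index=cat.frame["gene_id"].values)
    term_members: dict[str, list[int]] = {}
    for g, terms in gene_terms.items():
        pos = int(order[g])
        for t in terms:
            term_members.setdefault(t, []).append(pos)
    term_positions = {
        t: np.array(sorted(ps), dtype=np.int64) for t, ps in term_members.items()
    }
    return AnnotationMap(
        gene_to_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        term_positions=term_positions,
        universe=frozenset(catalog_ids),
        n_genes=cat.n,
    )


def read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read gene→term pairs from a two-column TSV or a GAF 2.x file.

    GAF is detected by the ``!gaf-version`` header or a 15+-column body; the
    DB Object Symbol/ID (column 2) and GO ID (column 5) are extracted and
    qualifiers/evidence codes ignored.
    """
    pairs: list[tuple[str, str]] = []
    is_gaf = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("!"):
                if "gaf-version" in line:
                    is_gaf = True
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_gaf or len(parts) >= 15:
                if len(parts) < 5:
                    raise InputError(f"{path}:{lineno}: truncated GAF record")
                pairs.append((parts[1], parts[4]))
            elif len(parts) >= 2:
                pairs.append((parts[0], parts[1]))
            else:
                raise InputError(f"{path}:{lineno}: expected two columns, got {line!r}")
    return pairs
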
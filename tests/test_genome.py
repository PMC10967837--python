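"""Genome model: parsing, interval algebra, TSS assignment, closure."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sago.genome import (
    ChromosomeSizes,
    GeneCatalog,
    InputError,
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

from conftest import annotate, build_catalog


# ---------------------------------------------------------------------------
# chromosome sizes


def test_read_chrom_sizes_parses_and_ranks(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chr2\t1000000\nchr1\t500000\n")
    sizes = read_chrom_sizes(p)
    assert sizes.names == ("chr2", "chr1")  # file order = rank
    assert sizes.length_of("chr1") == 500_000
    assert sizes.rank == {"chr2": 0, "chr1": 1}


@pytest.mark.parametrize(
    "content, match",
    [
        ("chr1\t100\nchr1\t200\n", "duplicate"),
        ("chr1\t0\n", "non-positive"),
        ("chr1\n", "two columns"),
        ("chr1\tabc\n", "not an integer"),
    ],
)
def test_read_chrom_sizes_rejects_bad_input(tmp_path, content, match):
    p = tmp_path / "sizes.tsv"
    p.write_text(content)
    with pytest.raises(InputError, match=match):
        read_chrom_sizes(p)


def test_malformed_line_error_names_line_number(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chr1\t100\nchr2\n")
    with pytest.raises(InputError, match=":2:"):
        read_chrom_sizes(p)


# ---------------------------------------------------------------------------
# gene table


def test_tss_strand_convention(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("a\tchr1\t100\t500\t+\nb\tchr1\t100\t500\t-\n")
    sizes = ChromosomeSizes(("chr1",), (1000,))
    cat = read_gene_table(p, sizes)
    tss = dict(zip(cat.frame["gene_id"], cat.frame["tss"]))
    assert tss == {"a": 100, "b": 499}


def test_order_index_sorted_by_position(tmp_path):
    p = tmp_path / "genes.tsv"
    p.write_text("a\tchr1\t200\t+\nb\tchr1\t100\t+\n")
    sizes = ChromosomeSizes(("chr1",), (1000,))
    cat = read_gene_table(p, sizes)
    order = dict(zip(cat.frame["gene_id"], cat.frame["order_index"]))
    assert order == {"b": 0, "a": 1}


def test_gene_on_unknown_chromosome_dropped(tmp_path, caplog):
    p = tmp_path / "genes.tsv"
    p.write_text("a\tchr1\t100\t+\nb\tchrUn\t100\t+\n")
    sizes = ChromosomeSizes(("chr1",), (1000,))
    with caplog.at_level("WARNING", logger="sago"):
        cat = read_gene_table(p, sizes)
    assert list(cat.frame["gene_id"]) == ["a"]
    assert any("chrUn" in rec.message for rec in caplog.records)


@pytest.mark.parametrize(
    "row", ["a\tchr1\t100\t*", "a\tchr1\t5000\t+"],
    ids=["unknown-strand", "tss-outside-chromosome"],
)
def test_gene_table_errors(tmp_path, row):
    p = tmp_path / "genes.tsv"
    p.write_text(row + "\n")
    with pytest.raises(InputError):
        read_gene_table(p, ChromosomeSizes(("chr1",), (1000,)))


def test_order_index_bijection_and_tie_break():
    sizes, cat = build_catalog({"chr1": [100, 100, 50], "chr2": [10]})
    idx = cat.frame["order_index"].to_numpy()
    assert sorted(idx) == list(range(4))
    # ties at tss=100 broken by gene id; chr2 ranks after chr1
    resorted = cat.frame.sort_values(["chrom", "tss", "gene_id"])
    assert list(resorted["order_index"]) == list(range(4))


# ---------------------------------------------------------------------------
# BED intervals


def test_read_bed_accepts_bed6_ignores_extras(tmp_path):
    p = tmp_path / "iv.bed"
    p.write_text("chr1\t0\t500000\nchr1\t10\t20\tname\t960\t+\n")
    sizes = ChromosomeSizes(("chr1",), (1_000_000,))
    iv = read_bed(p, sizes)
    assert len(iv) == 2
    assert iv.frame.loc[0, "end"] == 500_000


@pytest.mark.parametrize(
    "row", ["chr1\t500\t100", "chr1\t0\t2000000"],
    ids=["inverted", "past-chromosome-end"],
)
def test_read_bed_rejects_invalid_records(tmp_path, row):
    p = tmp_path / "iv.bed"
    p.write_text(row + "\n")
    with pytest.raises(InputError, match=":1:"):
        read_bed(p, ChromosomeSizes(("chr1",), (1_000_000,)))


@pytest.mark.parametrize(
    "records, expected",
    [
        ([("chr1", 0, 100), ("chr1", 50, 150)], [(0, 150)]),
        ([("chr1", 0, 100), ("chr1", 100, 200)], [(0, 200)]),
        ([("chr1", 0, 10), ("chr1", 20, 30)], [(0, 10), (20, 30)]),
    ],
    ids=["overlap", "book-ended", "disjoint"],
)
def test_merge_intervals(records, expected):
    merged = merge_intervals(IntervalSet.from_records(records))
    assert list(zip(merged.frame["start"], merged.frame["end"])) == expected
    again = merge_intervals(merged)
    pd.testing.assert_frame_equal(again.frame, merged.frame)


# ---------------------------------------------------------------------------
# TSS-in-interval assignment


def test_inclusion_half_open_boundaries():
    sizes, cat = build_catalog({"chr1": [100, 200]})
    iv = IntervalSet.from_records([("chr1", 100, 200)], sizes)
    assert genes_in_intervals(cat, iv).tolist() == [1, 0]


def test_inclusion_empty_interval_set():
    sizes, cat = build_catalog({"chr1": [100, 200]})
    iv = IntervalSet.from_records([])
    assert genes_in_intervals(cat, iv).tolist() == [0, 0]


def _naive_inclusion(cat, iv):
    out = np.zeros(cat.n, dtype=np.int8)
    for _, g in cat.frame.iterrows():
        for _, r in iv.frame.iterrows():
            if g["chrom"] == r["chrom"] and r["start"] <= g["tss"] < r["end"]:
                out[g["order_index"]] = 1
    return out


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.data())
def test_inclusion_matches_naive_double_loop_and_merge_invariance(data):
    """Production searchsorted assignment equals the per-gene, per-interval
    double loop, and merging never changes membership."""
    rng_seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    n = int(rng.integers(1, 60))
    tss = np.sort(rng.choice(10_000, size=n, replace=False))
    sizes, cat = build_catalog({"chr1": tss.tolist(), "chr2": [5]}, chrom_length=20_000)
    k = int(rng.integers(0, 8))
    recs = []
    for _ in range(k):
        s = int(rng.integers(0, 19_000))
        e = s + int(rng.integers(1, 3000))
        recs.append(("chr1", s, min(e, 20_000)))
    iv = IntervalSet.from_records(recs, sizes)
    got = genes_in_intervals(cat, iv)
    assert got.tolist() == _naive_inclusion(cat, iv).tolist()
    assert got.tolist() == genes_in_intervals(cat, merge_intervals(iv)).tolist()


# ---------------------------------------------------------------------------
# ontology and closure


def test_ancestral_closure_transitive_and_idempotent():
    sizes, cat = build_catalog({"chr1": [0, 100]})
    dag = TermDAG.from_edges(["A", "B", "root"], [("A", "B"), ("B", "root")])
    ids = cat.frame["gene_id"].tolist()
    ann = ancestral_closure([(ids[0], "A")], dag, cat)
    assert ann.gene_to_terms[ids[0]] == {"A", "B", "root"}
    assert ann.K("root") == 1
    # idempotent: closing the closed pairs changes nothing
    pairs = [(g, t) for g, ts in ann.gene_to_terms.items() for t in ts]
    again = ancestral_closure(pairs, dag, cat)
    assert again.gene_to_terms == ann.gene_to_terms


def test_closure_root_is_fixed_point():
    sizes, cat = build_catalog({"chr1": [0]})
    dag = TermDAG.from_edges(["root"], [])
    g = cat.frame["gene_id"].iloc[0]
    ann = ancestral_closure([(g, "root")], dag, cat)
    assert ann.gene_to_terms[g] == {"root"}


def test_cycle_in_dag_rejected():
    with pytest.raises(InputError, match="cycle"):
        TermDAG.from_edges(["A", "B"], [("A", "B"), ("B", "A")])


def test_closure_skipped_without_dag(caplog):
    sizes, cat = build_catalog({"chr1": [0]})
    g = cat.frame["gene_id"].iloc[0]
    with caplog.at_level("WARNING", logger="sago"):
        ann = ancestral_closure([(g, "A")], None, cat)
    assert ann.gene_to_terms[g] == {"A"}
    assert any("closure skipped" in r.message for r in caplog.records)


def test_obo_round_trip(tmp_path):
    obo = tmp_path / "mini.obo"
    obo.write_text(
        "format-version: 1.2\n\n"
        "[Term]\nid: T:0\nname: root\n\n"
        "[Term]\nid: T:1\nname: child\nis_a: T:0 ! root\n\n"
        "[Term]\nid: T:2\nname: part\nrelationship: part_of T:1 ! child\n\n"
    )
    dag = TermDAG.from_obo(obo)
    assert dag.ancestors("T:2") == {"T:1", "T:0"}


def test_read_annotation_pairs_tsv_and_gaf(tmp_path):
    tsv = tmp_path / "ann.tsv"
    tsv.write_text("g1\tT:1\ng2\tT:2\n")
    assert read_annotation_pairs(tsv) == [("g1", "T:1"), ("g2", "T:2")]
    gaf = tmp_path / "ann.gaf"
    cols = ["DB", "g1", "sym", "", "T:1", "ref", "IEA", "", "P", "", "", "protein", "taxon:9606", "20240101", "DB"]
    gaf.write_text("!gaf-version: 2.2\n" + "\t".join(cols) + "\n")
    assert read_annotation_pairs(gaf) == [("g1", "T:1")]
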
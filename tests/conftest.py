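import numpy as np
import pandas as pd
import pytest

from sago.genome import ChromosomeSizes, GeneCatalog, IntervalSet, ancestral_closure


def build_catalog(tss_by_chrom, chrom_length=None, strand="+"):
    """Catalog from {chrom: [tss, ...]}; chromosome length defaults to
    max TSS + 1000."""
    names, lengths, rows = [], [], []
    gid = 0
    for chrom, tss_list in tss_by_chrom.items():
        names.append(chrom)
        lengths.append(chrom_length or max(tss_list) + 1000)
        for tss in tss_list:
            rows.append((f"g{gid:03d}", chrom, int(tss), strand))
            gid += 1
    sizes = ChromosomeSizes(tuple(names), tuple(lengths))
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return sizes, GeneCatalog.from_frame(frame, sizes)


def annotate(cat, term_to_gene_orders, dag=None):
    """AnnotationMap assigning each term to the genes at the given order
    indices (no DAG closure unless one is passed)."""
    ids = cat.frame["gene_id"].to_numpy()
    pairs = [(ids[i], t) for t, idx in term_to_gene_orders.items() for i in idx]
    import logging

    logging.disable(logging.WARNING)
    try:
        return ancestral_closure(pairs, dag, cat)
    finally:
        logging.disable(logging.NOTSET)


@pytest.fixture
def toy12():
    """12 genes at 1 kb spacing on one chromosome; term T annotates the
    first three genes; one interval covers exactly their TSSs."""
    sizes, cat = build_catalog({"chr1": list(range(0, 12000, 1000))})
    ann = annotate(cat, {"T": [0, 1, 2]})
    iv = IntervalSet.from_records([("chr1", 0, 2001)], sizes)
    return sizes, cat, ann, iv
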
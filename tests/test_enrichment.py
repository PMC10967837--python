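"""Hypergeometric enrichment, BH and Bonferroni corrections."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sago.enrichment import (
    bh_adjust,
    bonferroni_adjust,
    enrich,
    hypergeom_upper_tail,
    term_counts,
)
from sago.genome import IntervalSet, genes_in_intervals

from conftest import annotate, build_catalog


def _exact_upper_tail(k, K, n, N):
    """Exact rational tail by binomial-coefficient enumeration."""
    total = comb(N, n)
    return Fraction(sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)), total)


class TestHypergeomUpperTail:
    def test_zero_observed_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 6, 20) == 1.0

    def test_known_exact_values(self):
        # 5090/38760 by direct enumeration of the tail
        assert hypergeom_upper_tail(3, 5, 6, 20) == pytest.approx(5090 / 38760, rel=1e-12)
        # single-term tail 1/C(12,3)
        assert hypergeom_upper_tail(3, 3, 3, 12) == pytest.approx(1 / 220, rel=1e-12)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(1, 30), st.data())
    def test_matches_exact_enumeration(self, N, data):
        """Agreement with the exact rational oracle over the support, N <= 30."""
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        for k in range(0, min(K, n) + 1):
            expected = float(_exact_upper_tail(k, K, n, N))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected, rel=1e-9, abs=1e-12)


def _bh_bruteforce(p):
    """Step-up: adj_(i) = min_{j >= i} p_(j) * m / j, in original order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestAdjustments:
    def test_bh_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]).tolist() == pytest.approx([0.03, 0.03, 0.04])

    def test_bh_single_and_ties(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert bh_adjust([0.3, 0.3, 0.3]).tolist() == pytest.approx([0.3, 0.3, 0.3])

    def test_bh_empty(self):
        assert bh_adjust([]).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=25))
    def test_bh_matches_bruteforce_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert adj.tolist() == pytest.approx(_bh_bruteforce(p))
        assert (adj >= np.asarray(p) - 1e-15).all()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=15), st.randoms(use_true_random=False))
    def test_bh_order_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        adj = bh_adjust(p)
        adj_shuffled = bh_adjust(shuffled)
        assert [adj[i] for i in perm] == pytest.approx(adj_shuffled.tolist())

    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni_adjust([0.01], 5).tolist() == pytest.approx([0.05])
        assert bonferroni_adjust([0.5], 10).tolist() == [1.0]

    def test_bonferroni_family_threshold_equivalence(self):
        # a raw p at the 0.0005 per-test threshold is exactly borderline for
        # a family-wise 0.05 over 100 hypotheses
        assert bonferroni_adjust([0.0005], 100)[0] == pytest.approx(0.05)
        assert 0.05 / 100 == pytest.approx(0.0005)

    def test_bonferroni_rejects_bad_m(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)


class TestEnrich:
    def test_toy_exact_pvalue(self, toy12):
        sizes, cat, ann, iv = toy12
        table = enrich(iv, cat, ann)
        row = table.set_index("term").loc["T"]
        assert row["k"] == 3 and row["K"] == 3
        assert row["n_drawn"] == 3 and row["N"] == 12
        assert row["p_hyper"] == pytest.approx(1 / 220, rel=1e-12)

    def test_empty_intervals_all_p_one(self, toy12):
        sizes, cat, ann, _ = toy12
        table = enrich(IntervalSet.from_records([]), cat, ann)
        assert (table["p_hyper"] == 1.0).all()
        assert (table["k"] == 0).all()

    def test_two_terms_share_n_drawn_and_N(self):
        sizes, cat = build_catalog({"chr1": list(range(0, 10000, 1000))})
        ann = annotate(cat, {"A": [0, 1], "B": [5, 6]})
        iv = IntervalSet.from_records([("chr1", 0, 1500)], sizes)
        table = enrich(iv, cat, ann)
        assert table["n_drawn"].nunique() == 1
        assert table["N"].nunique() == 1
        assert set(table["term"]) == {"A", "B"}

    def test_saturated_inclusion_gives_k_equals_K(self):
        sizes, cat = build_catalog({"chr1": list(range(0, 10000, 1000))})
        ann = annotate(cat, {"A": [0, 1, 2], "B": [4]})
        inclusion = np.ones(cat.n, dtype=np.int8)
        counts = term_counts(inclusion, ann, cat)
        assert counts == {"A": 3, "B": 1}

    def test_term_counts_all_zero_inclusion(self):
        sizes, cat = build_catalog({"chr1": [0, 1000]})
        ann = annotate(cat, {"A": [0]})
        assert term_counts(np.zeros(2, dtype=np.int8), ann, cat) == {"A": 0}


def test_type_one_error_control_under_random_intervals():
    """With one term per gene and random intervals the hypergeometric
    p-values are super-uniform: P(p <= 0.05) stays at or below 0.05."""
    from sago.sampling import SamplerConfig, sample_intervals

    rng = np.random.default_rng(7)
    n = 60
    sizes, cat = build_catalog({"chr1": list(range(0, n * 1000, 1000))}, chrom_length=n * 1000)
    # random (spatially dispersed) partition of genes into terms, so the
    # independence assumption of the hypergeometric null actually holds
    perm = rng.permutation(n)
    ann = annotate(cat, {f"t{j}": perm[j * 10 : (j + 1) * 10].tolist() for j in range(6)})
    hits = 0
    trials = 0
    for r in range(1200):
        iv = sample_intervals(sizes, SamplerConfig(n_intervals=3, length=4000, seed=r))
        inclusion = genes_in_intervals(cat, iv)
        counts = term_counts(inclusion, ann, cat)
        nd = int(inclusion.sum())
        for t, k in counts.items():
            p = hypergeom_upper_tail(k, ann.K(t), nd, n)
            hits += p <= 0.05
            trials += 1
    rate = hits / trials
    se = np.sqrt(0.05 * 0.95 / trials)
    assert rate <= 0.05 + 3 * se
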
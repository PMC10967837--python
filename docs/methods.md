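# Methods

## The problem

Gene-set enrichment of *large genomic intervals* — replication-timing
domains, lamina-associated domains, broad H3K9me3/H3K27me3 domains, Hi-C
compartments, copy-number-altered regions — is usually done by collecting
the genes whose TSS falls inside the intervals and testing each functional
term with a hypergeometric (Fisher) test. That test assumes genes enter the
set independently. In large intervals they do not: functionally related
genes are often physically clustered (olfactory-receptor arrays are the
canonical case), so one interval can swallow a whole cluster and a term
looks enriched for purely positional reasons.

## The cyclic permutation null

Genes are ordered by chromosome and TSS, chromosomes concatenated in the
order of the sizes table, and the order closed into a circle (the last gene
adjacent to the first). The measured intervals define a fixed 0/1
*inclusion* vector over the n gene slots; each term defines a 0/1
*membership* vector. A cyclic permutation by shift s relabels slot i with
the gene from slot (i + s) mod n: every inter-gene adjacency, and hence
every cluster, survives the permutation, while the relationship between
genes and intervals is randomised. There are exactly n − 1 non-identity
rotations and all are enumerated:

    counts[s] = Σ_i membership[(i + s) mod n] · inclusion[i]

The empirical p-value counts the observed configuration as one of the n
configurations, with ties counting against significance:

    p_cyclic = (1 + #{s ∈ 1..n−1 : counts[s] ≥ counts[0]}) / n

so p_cyclic ≥ 1/n always, with equality only when the observed count
strictly beats every rotation (5 × 10⁻⁵ for a 20,000-gene genome). The
counting is exact integer arithmetic: sparse accumulation over
(member position − included position) mod n for ordinary workloads, an FFT
circular correlation rounded back to integers — and checked against the
conservation identity Σ_s counts[s] = K · n_drawn — for very dense ones.

A matched *random* (order-destroying) permutation p-value is computed per
term as a contrast. A uniform shuffle of the membership labels makes the
in-interval count exactly Hypergeometric(N, K, n_drawn), so these
permutation counts are drawn from that law with a seeded generator
(default n − 1 draws, matching the number of rotations) rather than by
materialising each shuffled genome; the result is distributionally
identical and deterministic given the seed. Per-term streams are derived
from (run seed, SHA-256 of the term id), so results do not depend on term
iteration order.

## Two-step multiple-testing scheme

The cyclic p-value's floor 1/n cannot survive a correction across the
thousands of terms in an ontology. The procedure therefore runs in two
steps with defaults:

1. hypergeometric enrichment for every term with K ≥ 1, BH-FDR across all
   tested terms, gate at **q < 0.1**;
2. the exhaustive cyclic test on gated terms only, Bonferroni-corrected
   over the number of gated terms, verdict at **adjusted p < 0.05**:
   *retained* (enrichment survives the spatial null) or *eliminated*
   (enrichment attributable to gene clustering).

On fully random data step 1 gates nothing, so the expensive step never
runs; on real interval sets it reduces the hypothesis family by orders of
magnitude. Both thresholds are exposed everywhere (`fdr_gate`, `alpha`).

## The spatial residual metric

For each term, x = −log₁₀ p_cyclic and y = −log₁₀ p_random (p-values
floored at their permutation minimum before the log). An OLS line of y on x
is fitted across terms; the residual y − ŷ is the term's spatial-dependency
score: dispersed terms sit on the line (the two nulls agree), clustered
terms reach their counts far more easily under rotations than under
shuffles, giving a large positive residual. Residuals are binned to the
nearest multiple of 0.5 (half-width 0.25, ties rounding half up). Two
external validators are computed over repeated random interval draws:

- **chance score** — the fraction of draws in which the term is enriched
  (per-draw Bonferroni-adjusted hypergeometric p < 0.05); it increases with
  the residual bin;
- **fraction corrected** — the fraction of gated terms per bin that the
  two-step test eliminates.

## Random interval sampling

Intervals are placed uniformly over admissible start positions genome-wide:
a chromosome is chosen with probability proportional to its placeable
length (length − interval length + 1), then a uniform start. Overlaps among
sampled intervals are allowed by default; a flag enforces disjointness by
rejection sampling. Repeat r of an experiment uses a generator seeded from
(base seed, r) so any repeat is reproducible in isolation. No
assembly-gap/blacklist masking is applied.

## Synthetic data: what it emulates and what it does not

The generator builds genomes with genes at jittered regular spacing
(default 5,000 genes, 4 chromosomes, 100 kb mean spacing ≈ 505 Mb — large
enough that the permutation floor 1/5,000 sits far below working
significance levels, small enough that a full rotation sweep takes
milliseconds), a one-root ontology so ancestral closure is exercised, and
terms that are either *dispersed* (uniform without replacement) or
*clustered* (contiguous runs of genome order). Clustered blocks are placed
either at random non-adjacent positions or at exactly equal spacing n/b
around the circle with a random phase ("periodic"). Periodic placement is a
stylisation of multi-locus clusters with a useful exact property: the
term's membership is invariant under rotation by n/b, so its all-shifts
count vector is periodic and every count value ties at least b times —
the term's cyclic p-value has a hard floor of b/n, which makes spurious
enrichments of such terms provably removable once a dozen terms are gated
together.

Three named scenarios cover the pipeline's behaviours:

- **spurious_clustered** — 300 periodic clustered terms (b ∈ {10, 20, 25,
  40}, K 200–300 ≈ 4–6% of genes, the scale of the olfactory repertoire)
  plus 100 dispersed terms, measured by 8 random 8 Mb intervals (~13%
  coverage, the broad-domain regime). Naive enrichment flags clustered
  terms in essentially every draw; the cyclic test eliminates them.
- **true_dispersed** — intervals deliberately containing 40 of a dispersed
  term's 50 TSSs (plus random background intervals): genuine enrichment
  that the cyclic test retains at its p floor.
- **mixed_gradient** — clustered terms with block counts 1–20 plus
  dispersed terms of varying size, spanning the residual spectrum.

What the generator does **not** emulate: realistic GO DAG topology (one
root only), gene-density heterogeneity (no deserts/hotspots), chromosome
size asymmetry, overlapping/nested real GO term structure, and
assembly gaps. Passing tests therefore show the statistical machinery is
correct under controlled spatial structure, not that any particular real
dataset will behave identically.

## Numerical and design choices

- Coordinates are 0-based half-open; the TSS of a −-strand gene given as a
  start/end pair is end − 1; gene membership is decided by TSS only.
- The hypergeometric tail includes the observed value, P(X ≥ k), and
  returns exactly 1 for k = 0; underflowed tails are floored at the
  smallest positive double before BH.
- The universe N is the full catalog, including unannotated genes: they
  occupy genome slots and must participate in rotations; removing them
  would distort spacing in the cyclic null.
- Terms with K = 0 are never tested; FDR is computed across all tested
  terms of a run (no namespace stratification).
- Step-2 Bonferroni uses m = number of gated terms of that run; each run
  corrects independently.
- Exceedance conventions use ≥ (ties count against significance) in both
  permutation tests.
- Rotation counting switches from sparse accumulation to the FFT transform
  above 2 × 10⁷ (member, included) position pairs; FFT output is rounded
  and verified against the conservation identity.
- Chromosome order is the sizes-file order; TSS ties are broken by gene id;
  all outputs are deterministic functions of (inputs, config, seed).
- Degenerate inputs are valid where the statistics still make sense: empty
  interval sets give all-p = 1 tables; an all-covering interval set gates
  nothing; a residual regression needs ≥ 2 distinct cyclic p-values.

## Known limitations

- The circular concatenation introduces O(#chromosomes) artificial
  adjacencies at chromosome junctions; they affect only boundary rotations.
- Statistical power of the cyclic test is bounded by the floor 1/n; at
  desk scale (n = 5,000) the smallest achievable adjusted p is m/5,000.
- The residual metric needs enough gated terms to fit a line; runs gating
  fewer than two terms yield no residuals.
- Random permutations resample all genes (annotated or not), mirroring the
  cyclic null's universe.
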
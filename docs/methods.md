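# Methods

## Data model

A repertoire is one sample's clonotype table: rows of
`(count, freq, cdr3nt, cdr3aa, v, d, j)`. Counts are authoritative.
Frequencies are recomputed as `count / Σcount` unless the supplied column
already sums to 1 within 1e-3 — that tolerance absorbs upstream rounding
while still catching genuinely inconsistent frequency columns. After
normalization every sample satisfies Σfreq ∈ 1 ± 1e-6.

Duplicate rows with the same `(cdr3nt, v, d, j)` are merged by summing
counts; `cdr3aa` is determined by `cdr3nt`, so the first value is kept.
Rows are ordered by descending count, then lexicographic `cdr3nt` — the
deterministic tie rule used by every "top-k" operation in the package.
Missing V/D/J calls become the literal category `unresolved` and stay in
usage analyses as their own category: renormalizing them away would
silently inflate the usage of resolved segments. Non-coding CDR3s
(`*` or `_` in the amino-acid string) are assumed to have been filtered by
the upstream profiler; the parser warns but does not drop them.

Dialect conversion (MiXCR, ImmunoSEQ, custom column maps) is a pure column
rename followed by the same canonicalization, so a converted file and a
hand-renamed file produce identical tables. If a dialect lacks `cdr3aa`,
it is derived by standard-genetic-code translation of `cdr3nt`;
amino-acid-only tables are rejected rather than given fabricated
nucleotide sequences.

## Metric conventions

* All entropy-based indices use the natural log; the Jensen–Shannon
  divergence of V-usage vectors uses log₂ so its range is [0, 1].
* The geometric mean frequency is computed as exp(mean(log p)) to avoid
  underflow at realistic repertoire sizes (the defining product form is
  kept in the test oracles, where n ≤ 8).
* Clonality is defined as 1.0 for a single-clonotype sample: entropy is 0
  and ln n = 0, and a repertoire consisting of one clone is maximally
  clonal by any reading.
* The "normalized Shannon–Wiener index" is e^H/ln n. This is a
  tool-specific convention, not Pielou's evenness, and unlike evenness it
  is not bounded by 1; `entropy_normalization=True` gives the conventional
  H/ln n for parity with other repertoire tools. No monotonic
  "higher = more diverse" reading is asserted for the default form.
* Abundance bands are half-open `(lower, upper]`, contiguous, covering
  (0, 1]; the default five bands are rare (0, 1e-5], small (1e-5, 1e-4],
  medium (1e-4, 1e-3], large (1e-3, 1e-2], hyperexpanded (1e-2, 1].
  Half-open intervals make band assignment a partition: a clone at exactly
  0.01 belongs to "large".
* Chao1 variance uses the classical f₂-form
  f₂(r²/2 + r³ + r⁴/4), r = f₁/f₂, and is reported as NaN when f₂ = 0
  rather than silently switching to a bias-corrected alternative.
* The Gini coefficient integrates the Lorenz polyline of ascending
  frequencies with the trapezoid rule, which is exact for discrete step
  distributions; it is invariant to record order and uniform count scaling.
* D50 and clonal proportion accumulate counts in canonical (descending
  count) order with an absolute guard of 1e-9 on the threshold comparison
  so integer-exact cases do not flip on float rounding.

## Overlap

Repertoire pairs are joined on an explicit clonotype key, default
`(cdr3nt, v, j)`. No universal convention exists for clonotype identity in
overlap analyses, so the key is always carried in the result; `cdr3aa`-only
matching is one argument away. The join aggregates each table into a hash
table keyed by the key tuple and probes the smaller structure — O(|a|+|b|)
expected lookups, with a module-level lookup counter so the linear contract
is asserted by instrumentation rather than wall clock.

Morisita–Horn runs over the shared clonotypes' read counts with
whole-sample totals X, Y; the Σx², Σy² terms also run over shared
clonotypes, matching the index definitions of the printed symbols
(`mh_all_clonotypes=True` switches to whole-sample sums). Cosine and
Pearson operate on shared-clonotype frequency vectors; Pearson is NaN when
fewer than two clonotypes are shared or a shared vector is constant. F and
F2 use whole-sample frequencies (not renormalized over the intersection).
The cosine denominator is computed as √(ΣA²·ΣB²), which keeps
cosine(a, a) exactly 1 in binary arithmetic. JSD uses union support with
0·log 0 = 0; intersect-and-renormalize would break the [0, 1] bound.

## Statistics

The routing rule is Shapiro–Wilk on each group at α = 0.05; both groups
must pass for Student's t-test (equal variances — Welch behind a flag),
otherwise the Wilcoxon rank-sum test. Shapiro–Wilk is undefined for
constant data, so a constant group routes non-parametrically; two identical
constant groups yield a degenerate sentinel (NaN p) instead of a fabricated
p-value. Groups need at least 3 values for the normality test to exist.
Bonferroni's m is the number of simultaneous tests in the call — the
number of segment labels for a per-gene usage comparison, 1 for a scalar
metric — not a global experiment-wide count.

Under a seeded Gaussian null (n = 20 per group, 1000 replicates) the routed
pipeline's empirical rejection rate at 0.05 is computed by both the test
suite and the acceptance script; the binomial tolerance band used in the
test is [0.03, 0.07].

## Synthetic data

The generator emulates post-processed TCR-beta clonotype tables:

* **Abundance.** Ideal proportions come from the chosen model — uniform,
  geometric(r) with proportions rⁱ, or power_law(s) with Zipf proportions
  i⁻ˢ — and are largest-remainder-rounded so counts sum exactly to
  `total_reads` with every clonotype keeping ≥ 1 read. Defaults are
  power_law with s = 1.5, 1000 clonotypes, and 100 000 reads per sample:
  a heavy-tailed profile of the kind bulk TCR-Seq shows, at a desk-scale
  size where whole-cohort analyses run in seconds.
* **Sequences.** CDR3 nucleotide sequences are built codon-wise from the
  61 sense codons, 8–20 codons long (24–60 nt, within the observed CDR3
  length range), unique within a sample; `cdr3aa` is always their
  standard-genetic-code translation, mirroring the assumption that inputs
  are pre-filtered for non-coding CDR3s.
* **Segments.** V/D/J labels are drawn uniformly from fixed TRB allele
  lists (12 V, 2 D plus `unresolved`, 13 J).
* **Cohorts.** Per-sample seeds are spawned deterministically from the
  master seed; an optional two-level group label can override read depth
  per group, giving constructions with exactly known effect sizes (e.g. a
  group-mean read-count ratio of exactly 2).

What the generator does **not** model — and hence what passing tests do not
establish about real data: the abundance curve is deterministic for a fixed
model, so replicate samples differ in sequences and segment assignments but
share the same count profile (real biological replicates also vary in
abundance); there is no V(D)J junctional insertion/deletion structure, no
positional sequence biases, and no public-clonotype sharing, so synthetic
samples are essentially disjoint under sequence-level overlap keys.
Overlap metrics are therefore validated on constructed tables with known
intersections rather than on generator output.

## Numerical and testing notes

Closed-form checks use repertoire sizes that are powers of two (n = 16),
where frequencies, Simpson sums, and Lorenz cumulative sums are exact in
binary floating point: inverse Simpson, Gini–Simpson, clonality, Gini
coefficient, and D50 then hit their textbook values exactly, and exp-Shannon
equals n up to the rounding of exp(log n) (asserted at 1e-12 relative).
The brute-force oracle suite re-derives every metric with loop-based literal
transcriptions of the defining formulas (naive quadratic scans for overlap)
and agrees with the optimized implementations to better than 1e-12 on 200
random small repertoires. Problem sizes throughout the suite (tables of
≤ 8 clonotypes for oracles, cohorts of ≤ 12 samples, 1000-replicate null
calibration) were chosen so the whole battery — including the acceptance
script — completes in well under a minute on one CPU.
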
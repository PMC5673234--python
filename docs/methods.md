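# Methods

## Mutation-rate estimation

**Model.** Cultures grow from `n_initial` cells by synchronous doubling for
G = ⌊log₂(n_final/n_initial)⌋ generations, so the realized saturation
census is n_initial·2^G (the largest power-of-two multiple not exceeding
the requested `n_final`). Mutations arise once per cell division with
probability μ; there is no back-mutation, no mutant fitness cost, no
phenotypic lag, and plating efficiency is 100% apart from the explicit
dilution factors.

**Estimator.** The rate is the root of the implicit median-based equation
μ·ln(N·μ) = f, with f the median across cultures of
(selective count − verified silenced count)·selective dilution divided by
the per-culture census (permissive count × permissive dilution), and N a
summary of the per-culture censuses — the median by default, switchable to
the mean (`n_summary`). The even-length median is the mean of the two
central order statistics. The root is unique on (e/N, f] because
g(μ) = μ·ln(Nμ) is strictly increasing there; it is found by Brent's
method with a Newton polish to a relative residual below 1e-10 (tests hold
it below 1e-12·f). The equation has no root when N ≤ e/f — fewer than ~e
expected mutants per culture — and that case raises rather than returning a
number.

**Zero-mutant convention.** When the median frequency is zero, the
reported rate is the upper bound obtained from one hypothetical mutant,
f_min = 1/N, and the estimate is flagged `is_upper_bound`. The same
one-pseudocount convention produces the flagged upper bounds for zero-count
spectrum categories in rate partitioning.

**Confidence interval.** No distributional form is assumed: the largest
symmetric pair of order statistics (k, n+1−k) whose binomial(n, ½) coverage
reaches the nominal level brackets the median frequency, and both bounds
are mapped through the (monotone) rate solve with the same N. Below six or
so cultures no symmetric pair reaches 95%; the widest available pair is
used and the result flagged. A bound frequency at or below the solvable
bracket maps conservatively to min(f, e/N); a zero bound maps to zero.

**Known limitation — estimator bias at small N·μ.** The median formula
implies a median mutant count of m·ln m for m = N·μ expected mutations per
culture, whereas the Luria–Delbrück median is closer to m·(ln m + 1.24).
The formula therefore overestimates μ when m is small: on this package's
own simulator the asymptotic estimate is ≈1.3× truth at m = 5 and is
unbiased within ~1% by m ≈ 100 (see `tests/test_simulate.py`). The
order-statistic CI attains its nominal coverage for the quantity it
targets — the rate at the population median frequency (measured 96.7% at
nominal 95%) — so at small m it inherits the same offset relative to the
true μ and its coverage of truth drops (measured ~72% at m = 5 with 18
cultures). This is a property of the median-based estimator itself, not of
the implementation; analyses run at small m should treat the estimate as
an upper-leaning approximation. Likelihood-based estimators are out of
scope.

## Synthetic fluctuation assays

The generator draws, per generation, new mutations ~ Poisson(μ·cells born);
each mutation founds a lineage that doubles for the remaining generations,
which reproduces the jackpot skew (mean mutant frequency > median, tested
at 500 cultures). Plating applies binomial thinning at 1/selective-dilution
to mutant counts and a Poisson draw of census/permissive-dilution to the
permissive plates. Silenced false positives — colonies that resist
selection because the reporter is epigenetically silenced, not mutated —
are drawn as Binomial(A, s) where A is an independent replicate of the same
plating process and s (`silencing_fraction`, 0–0.7 in practice) is the
verification-positive fraction; they are added to the selective count and
recorded as `verified_silenced_count`, so downstream exclusion exactly
recovers the true-mutant counts. One global seed feeds three
`SeedSequence`-spawned substreams (growth, false positives, permissive
plating); fixed seeds reproduce outputs byte-identically.

What the generator does *not* emulate: stochastic (non-synchronous) growth,
culture-to-culture variation in final census beyond Poisson plating noise,
mutant fitness effects, phenotypic lag, and plating inefficiency. Passing
recovery tests therefore show correctness of the estimator arithmetic under
the model's assumptions, not robustness to those real-data effects.

Default study conditions used in tests: inoculum 200–763 cells (the
protocol's inoculum size is not specified by the assay description; it is
config-exposed), saturation ~1e8 cells, 18 cultures per assay (matching the
9–18-culture design), silencing fraction 0.3 (mid-range of the observed
5–70%), recovery checks at 1000 cultures.

## Spectrum classification and run context

Coordinates are 1-based, inclusive, on the plus strand of the reference
ORF. Exactly one of ref/alt may be empty (empty alt = deletion; empty ref =
insertion before the stated position). Categories: single-base
substitution; 1-bp deletion; 1-bp insertion; **complex** when two or more
events in one isolate lie within 10 bp of each other (`complex_window`,
configurable) — a complex cluster counts once per isolate in spectrum
tallies; **other** for any remaining single event (multi-bp indels,
duplications, MNVs). Classification is invariant to the order in which an
isolate's events are listed.

1-bp indels are left-normalized — shifted to the leftmost equivalent
placement within a run of the deleted/inserted base — before run
annotation, so every equivalent placement reports the same run length and
position (exhaustively verified for runs up to length 8). Substitutions get
the run length of the reference base at their site; sites outside any run
report run length 1. Reference FASTA must be single-record ACGTN.

## Rate partitioning and derived quantities

Per-category rate = total rate × category count / spectrum size; the
non-bound categories sum to the total exactly before rounding. Reporting
rounds rates and ratios to 2 significant figures and repair efficiencies to
the nearest integer percent; full precision is retained on every object.
Relative rates divide by the matching category of a reference partition
(undefined and warned when the reference category rate is zero). The
synergy index is (μ_ab/μ_wt)/(μ_a/μ_wt + μ_b/μ_wt), invariant under common
rescaling; values above 1 indicate super-additivity.

## Spectrum comparison

**Asymptotic.** Pearson χ² without continuity correction; all-zero rows
and columns are dropped before df = (r−1)(c−1). The asymptotic p-value is
used even when expected counts fall below 5 (with a logged warning): this
is the convention under which spectra of ~50 mutations are conventionally
compared, and the package reproduces published 4-decimal p-values under
it. p-values below 0.00005 print as "< .0001". Bonferroni adjustment is
min(1, m·p) applied to the 4-decimal-rounded p; in `pairwise_compare` the
family m counts all unordered pairs plus, for three or more spectra, the
overall all-genotypes test (m = 7 for four genotypes).

**Monte Carlo.** The null fixes both margins — each mutation keeps its
category and is randomly reassigned a genotype — sampled by Patefield's
algorithm (`scipy.stats.random_table`). The add-one estimator
p = (1 + #{sim ≥ obs})/(1 + n_iter) never returns exactly zero; with no
exceedances the result prints as "< 1/n_iter" (default n_iter = 1e5, so
"< 1e-5"). The 5% critical value is the empirical 95th percentile of the
simulated statistics. Ties with the observed statistic count as
exceedances (within 1e-12). Note the exact conditional null differs from
the χ² reference by O(1/N) — its statistic has mean df·N/(N−1) — so
Monte-Carlo and asymptotic p-values on the same table agree to ~0.005–0.01
at a few hundred observations, not to Monte-Carlo error alone.

## Numerical and formatting choices

- Rate solver bracket (e/N·(1+1e-12), f]; relative tolerance 1e-10 with
  Newton polish; unique-root argument above.
- `round_sig` rounds to significant figures via base-10 exponent; ties
  follow Python's banker-free decimal rounding of `round`.
- Serialized tables are tab-delimited UTF-8 with header rows; upper bounds
  are a numeric column plus an `is_upper_bound` flag rather than a "<23"
  string, keeping files machine-readable.
- Problem sizes in the test suite (1000-culture recovery runs, 1000
  CI-coverage replicates at 18 cultures, 1e5 Monte-Carlo iterations) were
  chosen as the smallest sizes at which the tested properties are stable.
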
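# Methods

## The analysis in one paragraph

`coexsig` tests whether a gene set derived from a perturbation experiment
(genes higher in a reference condition than in a knockdown of the reference
gene) is coexpressed with that reference gene across an independent tumor
compendium. The compendium's genes are ranked by Pearson distance `1 − r`
to the reference profile; the signature's positions in that ranking are
summarized by a one-sided running-sum KS statistic; significance is the
upper-tail frequency of that statistic under random same-size gene sets.
The output is the KS score, a plain and a conservative permutation p-value,
and the k signature genes closest to the reference.

## Differential expression model

Intensities are modeled on the log2 scale. For gene *g* with group sizes
n₁, n₂ (residual df d = n₁ + n₂ − 2), the pooled sample variance s² is
shrunk toward an empirical-Bayes prior (d₀, s₀²) from the conjugate
scaled-inverse-χ² model:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)
    t   = Δ / (s̃ · sqrt(1/n₁ + 1/n₂)),   two-sided p from t with d₀ + d df

where Δ is the difference of group mean log2 intensities. The prior is fit
by moment matching on log s²: with e = log s² − ψ(d/2) + log(d/2), d₀ solves
ψ′(d₀/2) = var(e) − ψ′(d/2) (Newton inversion of the trigamma function) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When var(e) does not exceed its
theoretical minimum ψ′(d/2) the moment estimate diverges (effectively a
common variance); a finite ceiling d₀ = 10·d is substituted and flagged.
This fit agrees with the Bioconductor reference implementation (limma's
`fitFDist`/`eBayes`) to ~1e-8 on finite-prior fixtures; that agreement is a
test, not the implementation path. BH-FDR adjustment is delegated to
statsmodels and checked against a brute-force step-up oracle.

Two fold-change conventions are reported side by side, because they serve
different purposes:

* `log2fc` — the difference of group mean log2 intensities, i.e. the
  log-scale effect the t-statistic actually tests, so `sign(t) =
  sign(log2fc)` always;
* `signed_fc` — the array-era convention on raw-scale group means: the
  ratio r reported as r when r ≥ 1 and −1/r otherwise (so −4 means 4-fold
  down). Signature selection thresholds (`fold_min`, default 2) apply to
  `signed_fc`; whether a 2-fold rule should act on raw or log-scale means is
  genuinely open, so the raw-scale choice is a documented default, not a
  claim.

Signature selection keeps genes with `p_adj < 0.05` and `signed_fc ≥ 2`
(up in the reference condition) and always excludes the reference gene
itself — its self-coexpression would be circular.

## Filtering rules

* **Variation filter** (cell-line matrix): keep a gene iff the IQR of its
  log2 intensities (values floored at 1 before the log) exceeds 0.5 *and*
  at least one sample exceeds 100 relative units. The IQR threshold is
  interpreted on the log2 scale — on raw relative units a 0.5 cutoff would
  keep essentially everything — and the scale is configurable
  (`log_scale=False`). Quantiles use linear interpolation (NumPy default,
  R type 7), fixed for reproducibility.
* **Compendium filter**: remove a gene when a *strict* majority
  (fraction > 0.5) of arrays sit below 50 or above 15,000 relative units;
  of the survivors, remove genes with `max / max(min, 1) < 2` or
  `max − min < 50`. The denominator clamp at 1 guards against zero or
  negative values that average-difference array processing can produce.
  Removals are tagged `low` / `high` / `fold` / `diff` in that check order,
  and `n_in = n_kept + removed` is enforced structurally.

Both filters are idempotent and order-preserving.

## Identifier mapping

Signatures are mapped onto the compendium by exact case-insensitive symbol
match. When several target rows share a symbol (multiple probe sets per
gene), the `max_mean` policy keeps the brightest probe (greatest mean
intensity); `first` and `error` are alternatives. Unmatched ids are dropped
and reported; an empty intersection warns instead of crashing. No annotation
databases or network services are involved — symbol intersection is the
whole mechanism, so mapped counts depend entirely on the id universes
supplied.

## Neighbor ranking

Pearson distance is `1 − r` (range [0, 2]); low means coexpressed. This
convention (rather than `(1 − r)/2`) matches the published distance scale of
classical gene-neighbors outputs. Correlation is computed on raw filtered
intensities by default — the historical gene-neighbors practice — with a
`log2` switch exposed. Constant-profile genes have undefined correlation and
are excluded with a warning; ties are broken lexicographically by gene id,
making rankings fully deterministic.

## KS statistic and permutation null

For k hit positions p₁ < … < p_k in a ranked list of n genes, the running
sum gains 1/k at hits and loses 1/(n−k) elsewhere; the score is the maximum
over all prefixes including the empty one, hence

    KS = max(0, max_j [ j/k − (p_j − j)/(n − k) ])   ∈ [0, 1],

the one-sided D⁺ distance between the hit-position distribution and the
discrete uniform (implementation uses the closed form; tests use the
explicit walk as an independent oracle). A shift of any hit to an earlier
position never decreases the score (property-tested).

The null draws uniform k-subsets of the *post-filter* ranked universe
(equivalently, of positions {1..n}), excluding the reference gene — the
universe choice is exposed because it is not canonical. Two p-values are
always reported: the plain frequency `count_ge / n_perm` (faithful to the
historical definition; can be exactly 0) and the add-one
`(count_ge + 1)/(n_perm + 1)` (never 0, super-uniform under the null,
property-tested). "Equal or exceed" is applied with an absolute tolerance
of 1e-12 so float summation order cannot flip ties. An exhaustive mode
enumerates all C(n, k) subsets when that count is below 10⁶ and returns the
exact tail fraction. The sampler draws each subset by ranking n i.i.d.
uniform keys and taking the k smallest — exactly uniform, vectorized in
memory-bounded chunks, deterministic under the seed.

`k_select` (default 14) applies to the *mapped* signature and is capped at
the mapped size with a logged warning.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical shape the analysis relies on, at
desk scale:

* **Two-group experiment** (default triplicates per condition): gene-level
  log2 means ~ N(9, 1.5), replicate noise sd 0.35 — a typical
  post-normalization array noise level — exponentiated to a positive,
  right-skewed intensity scale. Planted genes shift one group's mean by
  ±log2(fold), fold drawn log-uniformly from (2, 8), spanning the fold range
  printed for top differential genes in array studies of this design. With
  no planted genes, per-gene t-test p-values are uniform (tested).
* **Compendium** (default 2,000 genes × 190 samples, 14 tumor-type labels):
  the reference gene gets a broad log2-normal profile; module genes are
  built on the standardized scale as `rho·z_ref + sqrt(1−rho²)·ε` — giving
  exact control of the expected Pearson r, which is affine-invariant — then
  mapped with positive slope into [100, ceiling/2], which also guarantees
  they survive every compendium filter rule. Background genes are
  independent log2-normals inside the filter-surviving band, saturated at
  the 15,000-unit ceiling (emulating scanner saturation). Violator genes are
  constructed to fail, respectively, the majority-low, majority-high and
  flatness rules. Tumor-type labels are decorative by default (the ranking
  ignores them, as the analysis does); `type_effect_log2_sd` adds per-type
  mean shifts to stress the ranking.
* **Linked study**: renames the compendium's module genes to the cell-line
  experiment's up-planted genes so a derived signature maps onto the
  compendium exactly as a real symbol intersection would.

All randomness flows through NumPy's PCG64 generator with explicit integer
seeds; identical configs give identical matrices.

Not emulated: probe-level data and normalization artifacts, batch effects,
correlated background gene-gene structure, heavy-tailed outlier arrays, and
realistic tumor-type covariance. Passing recovery tests therefore shows the
pipeline's statistics behave as designed under their own assumptions — not
that any particular biological signature would replicate.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at 1,000 cell-line
genes / 2,000 compendium genes × 190 samples with 10,000 permutations, and
calibrate the null at n = 500, k = 14, n_perm = 2,000 over 2,000
replicates — sizes chosen so the whole suite completes in about a minute
while keeping Monte-Carlo error well inside the asserted bands. Degenerate
inputs fail loudly and early: fewer than 2 replicates per class, all-zero
variances with a zero prior, constant reference profiles, k outside
[1, n−1], exhaustive enumeration beyond 10⁶ subsets.

## Known limitations

* The moderated model covers the two-group contrast only — no general
  design matrices, array weights, or duplicate-correlation.
* Mapping is symbol intersection; real cross-platform mapping (probe set →
  gene translation) loses genes in ways this package does not model, so
  mapped counts are not comparable across id conventions.
* The unweighted positional KS statistic ignores correlation magnitudes;
  weighted enrichment scores and multi-signature FDR are out of scope.
* The plain permutation p-value has granularity 1/n_perm and can be 0; use
  the conservative variant when a strictly positive bound is needed.
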
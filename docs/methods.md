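# Methods

This note records the statistical models the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Differential expression

Counts from each assay (miR or mRNA) are filtered to features expressed in
at least one experimental condition: a feature is kept iff in some
sex × condition cell the fraction of samples with count strictly greater
than `filter_min_count` (default 5 reads) is at least
`filter_min_fraction` (default 0.8). Filtering precedes everything else;
"neutral" downstream always means *analyzed but not differentially
expressed*, never *filtered out*.

Counts are transformed to log₂ counts-per-million with the usual offsets,
`log2((count + 0.5) / (libsize + 1) × 1e6)`. Normalization is plain
library-size CPM; no compositional adjustment (e.g. TMM) is applied. The
`lib_size` argument of `log_cpm` accepts externally adjusted sizes for
callers who want one.

Precision weights follow the voom recipe: unweighted gene-wise fits give
residual standard deviations; a LOWESS trend (span 0.5, the tool's
published default) of √SD against average log₂ count captures the
mean–variance relationship; each observation's fitted log₂ count is mapped
through the trend by monotone interpolation, clamped at the trend's range
ends, and the weight is the predicted √SD to the power −4. One pass only —
no iterative reweighting.

The linear model uses the group-means (cell-means) parameterization of the
2 × 2 sex × condition factorial rather than main-effects + interaction
coding; the fits are identical for a saturated model and contrast
bookkeeping is simpler. Default contrasts are the within-sex stress
effects, `stress_in_males = μ(male.stress) − μ(male.control)` and the
female analogue. Weighted least squares is solved gene-wise from the
normal equations (batched 4 × 4 systems); residual df = n − 4.

Variance moderation is the standard empirical-Bayes scheme: the prior
(d₀, s₀²) is fitted by moment-matching on log s² (mean and variance of
log s² against the theoretical moments of a scaled chi-squared variable;
the trigamma inverse is solved by Newton iteration). Posterior variances
are the convex combination s̃² = (d₀s₀² + d·s²)/(d₀ + d); moderated
t = β/(s̃·√v_c) is referred to a t distribution on d₀ + d df. Two
degenerate cases are handled explicitly: when the observed spread of
log s² is no larger than its chi-squared sampling variance, d₀ = ∞ and
every posterior variance collapses to s₀² (normal reference distribution);
when all sample variances are *exactly* equal the common value itself is
used as s₀², so shrinkage toward an already-common value is a no-op.

Direction calls use the study's rule: up iff p < 0.05 (uncorrected) and
log₂FC ≥ log₂(1.3); down symmetric; else neutral. Both assays run through
the identical code path with their own backgrounds.

## Overlap tests

`fisher_overlap(n_a, n_b, k, N)` is the one-sided enrichment tail
P(X ≥ k), X ~ Hypergeometric(N, n_a, n_b), evaluated via the scipy
survival function (tests verify agreement with direct
binomial-coefficient enumeration to 1e-10 across every instance with
N ≤ 30). One-sided enrichment was chosen because it reproduces the
published values and is standard overlap practice. No multiple-testing
correction is applied across the pairwise family; raw p-values are
reported with significance at p < 0.05. `pairwise_overlaps` defaults to
all unordered pairs of the supplied lists and accepts an explicit pair
selection, since the published count of "unique comparisons" is not
derivable from the list structure alone.

## Per-miR chi-squared target-direction enrichment

The background is the trichotomy (n_up, n_down, n_neutral) over the whole
analyzed universe for one sex's contrast. For each differentially
expressed miR, its predicted targets (intersection of all required
prediction sources, restricted to the analysis universe — restriction is
required for the frequencies to be comparable) are classified with the
same trichotomy, and a chi-squared goodness-of-fit statistic
Σ(obs − exp)²/exp with expected counts proportional to the background is
referred to the upper tail of χ²(2). A 2 × 3 contingency variant (targets
vs the rest of the universe) is available as `mode="contingency"`; the
goodness-of-fit form is the default because the background here is a
fixed reference composition, not a second sample.

miRs need ≥ `min_targets` (default 5) in-universe targets to be tested —
below that the chi-squared approximation is meaningless — and tests with
any expected cell below 1 are computed but flagged (`low_expected`).
Selection is Benjamini–Hochberg step-up at α = 0.05 with the family being
all tested miRs within one sex, matching the per-sex reporting of
surviving counts. The BH implementation (sort, p·m/rank, cumulative
minimum from the largest rank, cap at 1) is ten lines of code written here
because its exact contract is load-bearing for the selection step; a test
cross-checks it against `statsmodels.stats.multitest.multipletests`.

Network edges connect each surviving miR to its differentially expressed
targets only; the association sign is negative iff the directions are
opposite. Neutral features can never enter the network (asserted by
`MiRGeneNetwork.validate`). The SIF export keeps only negative
(repressive) edges by default — mirroring the convention of drawing only
the canonical association — while the edge-TSV and GraphML dialects retain
everything.

## Overrepresentation

Standard one-sided Fisher ORA of a query list in GMT sets, sharing
`fisher_overlap` with the overlap module. The default universe is the
sex's filtered analysis universe rather than a whole-genome background:
the query derives from that universe, so conditioning on it is the
defensible choice; callers can pass any universe. Significance is the raw
−log₁₀(p) ≥ 1.3 rule; BH-adjusted values are reported alongside but do
not drive the flag.

## qPCR relative quantification

ΔCt is the target Ct minus the arithmetic mean of the reference-gene Cts
(equivalently the geometric mean in linear expression space; the
combination rule is a convention, stated here because sources differ).
ΔΔCt subtracts the control-group mean ΔCt; folds are 2^−ΔΔCt rescaled so
the control-group mean fold is exactly 1 (re-applied after outlier
removal). Outliers are screened per group by a two-sided Grubbs test with
the t-quantile critical value, one removal per group by default; a "2sd"
mode (drop points beyond two standard deviations) is provided because the
two descriptions of the screen in common use are not the same test, and
both are logged. Group comparison: a two-sided F-test on the variances at
0.05 gates between a pooled-variance two-tailed t-test and a two-tailed
Mann–Whitney U. The F-test is our choice of variance gate; the rule
"nonparametric when variances are unequal" does not itself name a test.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- **Design**: 2 sexes × 2 conditions × 3 replicate libraries per assay,
  each library a pool of 5 animals; both assays share one design table
  (the two RNA fractions derive from the same pooled libraries). Female
  libraries carry only estrus/proestrus animals.
- **Counts**: a library's count is the sum of `pool_size` independent
  animal-level negative-binomial draws — summation is the natural count
  analogue of pooling at homogenization. Animal depth is a log-normal
  size factor (mean 1, CV 0.25). Per-animal dispersion follows
  α(m) = a₀ + a₁/m with defaults (0.05, 2.0): biological CV ≈ 0.26 for a
  moderately expressed feature, which pooling reduces by ≈ √5 at the
  library level — the replicate-to-replicate variability expected of
  pooled bulk RNA-seq.
- **Baselines**: per-animal feature means are 10^Normal(1, 1), spanning
  roughly four orders of magnitude. No tissue-specific expression atlas
  informs this; it is a stand-in distribution and results should be read
  accordingly.
- **Effects**: per sex, 5 % of genes and 5 % of miRs receive a
  ±1 log₂-unit stress effect, with direction splits skewed downward more
  strongly in males than females (mirroring the direction asymmetry of
  the emulated study); male and female effect sets are disjoint, making
  the sexes' responses largely non-overlapping by construction. Effects
  are planted only on features with baseline mean ≥ 5 counts/animal:
  features below the expression filter could never be called, and
  stress-regulated genes are by definition expressed genes.
- **Coupling**: each regulated miR's true targets independently (default
  probability 0.5; recovery tests use 0.8) receive the opposite-sign
  effect attenuated by 0.5 — a single miR–target interaction is expected
  to shift its target modestly. Ground-truth coupled edges are recorded
  only where the net gene-level effect really is anti-correlated with the
  miR (a gene coupled to several miRs, or carrying its own direct effect,
  can end up with any net sign), so the invariant "every recorded coupled
  edge has a negative miR × gene effect product" holds by construction
  and honestly.
- **Predictions**: every miR gets 30 true targets drawn from expressed
  genes; each source reports each true edge with its sensitivity (0.85 /
  0.80) and adds false edges at 20 % / 25 % of the true-edge count, so
  the dual-source intersection genuinely denoises.
- **Scale**: defaults are 5,000 genes and 400 miRs, a deliberate
  scale-down of the full 19,827 / 781 candidate universes; full size is a
  config change. All randomness flows from one seed through named
  substreams, and identical config + seed reproduces identical bytes.

What the generator does **not** emulate: compositional library effects
(all size variation is a scalar factor, which is why plain CPM suffices),
correlated expression between co-regulated genes, miR-family shared seed
sequences (prediction errors are independent across sources), batch or
lane effects, and estrous-stage dynamics. Passing recovery tests
therefore demonstrate that the statistical machinery does what it claims
under the assumed generative model — not that the thresholds would have
the same operating characteristics on any real tissue.

## Numerical and degenerate-input choices

- Weights must be finite and strictly positive; the trend prediction is
  floored at 1e-6 before the −4 power.
- `fisher_overlap` rejects impossible configurations (k > min list size,
  list larger than background) rather than clamping.
- Chi-squared tests skip miRs with zero in-universe targets (warning) and
  refuse nothing else; low-expected-count tests are flagged, not dropped.
  Under a null of targets drawn *without replacement* from the universe the
  goodness-of-fit p-values are very slightly conservative (the hypergeometric
  cell variances are a factor 1 − n/N below the multinomial ones the test
  assumes); at realistic target-set-to-universe ratios the effect is within
  Kolmogorov–Smirnov noise.
- Grubbs screening with n < 3 or zero spread returns the data unchanged
  with a warning; the identical-groups t-test comparison returns p = 1.
- BH on an empty vector returns empty arrays.
- Readers never coerce silently; every rejection names the file, the
  offending value, and its coordinates.

## Known limitations

- The moderated tests are this package's own implementation of the
  moment-matching empirical-Bayes scheme; they are not bit-identical to
  any particular R release of the corresponding tools (no quantile
  normalization, no robust prior fitting, no duplicate-correlation).
- Multi-way (>2 list) exact intersection distributions are not
  implemented; overlaps are strictly pairwise.
- Amplification-efficiency correction (Pfaffl-style) is out of scope for
  the qPCR module; 2^−ΔΔCt assumes ~100 % efficiency.
- The overrepresentation module ships no curated knowledgebase; users
  supply GMT files, and the analysis drivers build labelled synthetic
  collections.
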
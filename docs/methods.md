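# Methods

## Problem and model

Given `n` samples genotyped at `m` biallelic markers (categories 0 =
major homozygote, 1 = heterozygote, 2 = minor homozygote) and a
quantitative trait `y`, trait prediction is the linear model

    y = β₀ + Σᵢ βᵢ Xᵢ + e,

optionally augmented with pairwise interaction columns (the epistasis
model). Because the genotypes are categories, the numeric values `Xᵢ`
takes are an encoding choice. Under *unpenalized* least squares with an
intercept, adding any per-marker constant to an encoding changes only the
intercept and error term, so fitted values are invariant (this is tested
to 1e-8); under penalized or kernelized predictors the encoding changes
the effective prior, which is exactly why it matters.

## Encodings

All trait-aware encodings are fitted on training samples only and applied
to new samples as pure table lookups.

- *ordinal*: `{0,1,2}` (or `{−1,0,1}` via the `base` option); the flipped
  variant swaps 0↔2 at markers whose training Pearson correlation with the
  trait is negative (a zero-variance side defines the correlation as 0).
- *target*: `E(i,g)` = mean training trait of samples with category `g` at
  marker `i`.
- *hybrid one*: homozygotes as in target; `E(i,1)` = mean trait over all
  samples with an observed call at marker `i`.
- *hybrid two*: homozygotes as in target; `E(i,1) = (E(i,0)+E(i,2))/2`.

Hybrid Two's heterozygote value lies between the homozygote values by
construction. Hybrid One's does whenever the heterozygote *group mean*
lies between the homozygote means — true in expectation for additive
signals but not a theorem: a weighted mean of three group means can leave
the homozygote interval when the heterozygote group mean does. The order
property is therefore asserted over simulated markers carrying additive
per-marker signal (maf ≥ 0.2, h² = 0.8, n = 300), the regime the claim
presumes, not over arbitrary data.

Degenerate cases, decided once and applied everywhere:

- a category unseen in training encodes as the overall training-trait
  mean (the no-information value), with a warning; Hybrid Two's midpoint
  is taken *after* this substitution;
- monomorphic markers thus collapse to a constant column under all
  trait-aware schemes, keeping matrix shapes stable;
- a missing genotype at transform time is imputed with the marker's mean
  encoded value over the training rows, so downstream matrices are dense;
- note `Hybrid Two` is exactly affine in allele dosage per marker
  (`E0, midpoint, E2` are equally spaced), so under ridge its difference
  from ordinal is purely a per-marker rescaling by the estimated
  homozygote gap — an adaptive-shrinkage effect.

### Pair grids

For a marker pair `(i,j)` the 3×3 grid `E(i,j,a,b)` is fitted from
training cells: corners `(a,b∈{0,2})` are plain cell means; Hybrid One
fills edges with pooled marginal means (e.g. `E(i,j,1,0)` is the mean
trait of samples with category 0 at `j`, any category at `i`) and the
center with the overall mean; Hybrid Two averages the two corners adjacent
to each edge and the four edges for the center. The printed form of the
Hybrid Two edge rule nests a fitted value inside a trait average, which is
not well-formed; the direct arithmetic mean of adjacent fitted cells is
the interpretation consistent with the single-marker scheme, and on data
whose cell means are additive in rows and columns the two hybrids agree
exactly. Empty training cells fall back to the overall training mean, as
do samples with a missing genotype at either member at transform time.
Pairs are unordered, deduplicated and stored with the lower-index marker
first. Because all-pairs construction is quadratic in `m`, it is refused
above a cap (default 200 markers); `top_t_by_correlation` screening
(default t = 50 markers ranked by absolute encoded correlation with the
training trait) and explicit pair lists cover larger panels without
changing any fitted value for a given pair.

## Allele orientation

"2 counts the minor allele" is a property of a reference sample set, not
of a file. `orient_major_allele` swaps 0↔2 at every marker whose
counted-allele frequency among the reference rows exceeds 0.5 (missing
calls excluded; an exact tie keeps the file's orientation; an all-missing
marker is left alone with a warning). In cross-validation the reference
set is the training fold and the decision is applied unchanged to the
fold's test rows. The operation is idempotent for a fixed reference set.

## rrBLUP

The mixed model `y = 1β₀ + Xβ + e`, `β ~ N(0, σ²_β I)`,
`e ~ N(0, σ²_e I)` is fitted by REML. After centering, the data are
projected onto an orthonormal complement of the intercept (a QR-derived
basis), and `X_c X_c'` is diagonalized once; each evaluation of the
restricted likelihood in the variance ratio `δ = σ²_e/σ²_β` then costs
O(n). `log₁₀ δ` is optimized by bounded scalar search over [−8, 8] with
absolute tolerance 1e-6 — derivative-free and deterministic. A solution
at either box edge sets a `boundary` flag (a noiseless trait legitimately
drives `δ` to the lower bound). Effects solve the dual system
`(X_c X_c' + λI)α = y_c`, `β = X_c'α`, identical to the primal ridge
solution at `λ = δ`.

Penalty convention: `ridge_solve` minimizes
`‖y − β₀ − Xβ‖² + λ‖β‖²` with the intercept handled by centering and
never penalized. In this convention the BLUP penalty is exactly
`σ²_e/σ²_β`; scaling the squared-error term (e.g. by 1/2n) would only
reparametrize λ. The ridge↔BLUP identity is pinned by a 50-instance test
at 1e-8.

SVR delegates to scikit-learn's ε-SVR after standardizing features on the
training data (zero-variance columns keep scale 1). Defaults where the
literature gives none: C = 1, ε = 0.1, γ = 1/m, coef0 = 0.

## Cross-validation

Folds are a seeded shuffle cut into contiguous blocks (sizes differ by at
most one). Per fold: orient alleles on the training rows, fit the encoding
(and pair grids, if requested) on training rows only, transform both
sides, fit the predictor, predict the test rows. The reported score is the
*mean of per-fold r²* (squared Pearson correlation), matching common
practice, rather than r² of pooled predictions; a fold with a constant
test trait contributes a missing value, excluded from the mean with a
warning. Comparisons across encodings share one fold assignment. No
statistic of any test fold enters any fitted object for that fold; this is
asserted bitwise by perturbing test-fold traits.

## Diagnostics

- *top-k mean absolute correlation* (k = 100): markers ranked by absolute
  Pearson correlation of their encoded column with the trait, ties by
  marker order; absolute values are averaged because the sign is arbitrary
  under flipping. Zero-variance columns count as 0.
- *within-group distance*: samples are binned by the trait's population
  z-score (`(x−μ)/δ`, thresholds at ±1 → bins −1/0/+1); marker columns are
  standardized to population z-scores (constant columns → 0); all pairwise
  Euclidean distances between same-bin samples are pooled across the three
  bins and averaged. Pooling pairs (rather than averaging per-bin means)
  is the fixed convention. Per-marker standardization makes the statistic
  invariant to per-marker affine rescaling (asserted to 1e-8), which is
  what allows comparing encodings of different scales. Two printed
  variants of these z-scores in the source literature divide by a variance
  or square the deviation; both would break scale invariance, so the
  standard z-score forms are used.

Because Hybrid Two is affine in dosage per marker, both diagnostics
coincide exactly with the ordinal encoding's values — the informative
contrasts are ordinal/hybrid-two vs target vs hybrid-one.

## Synthetic data

`simulate_genotypes` draws each marker's minor-allele frequency uniformly
from `maf_range` (default 0.05–0.5, the usual post-QC range) and samples
categories independently in Hardy–Weinberg proportions
`((1−q)², 2q(1−q), q²)`. `simulate_trait` parameterizes signal as
*category means* per causal marker: homozygotes at ∓a with half-effect
`a = additive_scale·|N(0,1)|` (sign randomized when `sign_mixing`), the
heterozygote at the additive midpoint except for a `dominance_degree`
fraction of causal markers, whose heterozygote mean is perturbed by
`N(0, (dominance_scale·a)²)`. Optional epistatic pairs among causal
markers add `w·(gᵢ−1)(gⱼ−1)` cell values with `w ~ N(0, epistasis_scale²)`.
Noise is scaled as `σ²_e = var(g)(1−h²)/h²` so realized heritability
matches the target (within 0.02 at n = 2000). Defaults (n = 300, m = 200,
60 causal markers, dominance degree 0.5, sign mixing on, h² = 0.6) define
the package's reference benchmark. Genotypes and trait use separate child
seed streams, so either can be regenerated independently.

What the generator does *not* emulate: linkage disequilibrium (markers
are independent), population structure and relatedness, genotyping error,
and allele-frequency drift between training and test sets. Passing tests
therefore demonstrate correctness of the machinery and the direction of
encoding effects under clean architecture, not performance on structured
real panels.

## Problem sizes and observed behavior

Test and benchmark sizes (n ≈ 100–300 samples, m ≈ 30–400 markers,
10 folds, 10–20 replicates) were chosen so the full pipeline exercises
every code path in seconds while keeping group-mean estimates meaningful.
Two observations from the reference benchmark worth knowing:

- the hybrid-two-over-ordinal accuracy gap is positive on average but
  small relative to replicate noise at these sizes (roughly +0.01 r²,
  s.d. ≈ 0.04 across seeds); it strengthens markedly when minor-homozygote
  classes are well populated (maf ≥ 0.2) or when markers far outnumber
  what ridge can learn per sample (larger m at fixed n), because the
  mechanism is per-marker scaling by an estimated homozygote gap, whose
  noise is governed by the rarest genotype class;
- with dominance in the architecture, the target encoding — the only
  scheme whose heterozygote value can track a dominance deviation — tends
  to lead the benchmark, while in the additive limit all encodings
  perform equivalently (mean gap well under 0.05).

## Known limitations

- Biallelic, unphased markers only; no multi-allelic or pedigree support.
- The REML search is a 1-D profile over the variance ratio; heteroscedastic
  residuals or correlated effects are out of scope.
- Pair-grid cells for rare-allele pairs are often empty at desk-scale n
  and fall back to the overall mean, which flattens their contribution.
- The k-way grid generalization (k > 2) is not implemented.
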
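# genoenc

Genotype encodings for quantitative genetic trait prediction.

Genomic selection predicts a quantitative trait (yield, growth, disease
resistance) from thousands of biallelic SNP genotypes at once. The standard
pipeline treats the genotype categories — major homozygote, heterozygote,
minor homozygote — as the fixed numbers 0/1/2 and fits a penalized linear
model. `genoenc` treats the problem instead as *multiple regression on
categorical data*, where the choice of number assigned to each category is
itself a modeling decision, and implements the encoding family built around
that view:

- **ordinal** — the fixed labels {0,1,2} (or {−1,0,1}), identical for every
  marker; a flipped variant swaps 0 and 2 at markers negatively correlated
  with the trait;
- **target-based** — each category at marker *i* encoded as the mean
  training trait of the samples carrying it,
  `E(i,g) = Ave(trait(i,g))`;
- **Hybrid One** — homozygotes target-encoded, heterozygote encoded as the
  overall training mean, `E(i,1) = Ave(trait(i,{0,1,2}))`;
- **Hybrid Two** — homozygotes target-encoded, heterozygote the exact
  midpoint `E(i,1) = (E(i,0) + E(i,2)) / 2`, which preserves the category
  order by construction.

Both hybrids extend to pairwise epistasis as a fitted 3×3 grid per marker
pair `E(i,j,a,b)`: the four double-homozygote corners are cell means of the
training trait, and the heterozygote-involving cells come from pooled
marginal means (Hybrid One) or from averaging adjacent fitted cells
(Hybrid Two). Traditional product features `X_i·X_j` are also available.

Prediction uses **rrBLUP**: ridge regression
`y = β₀ + Xβ + e`, `β ~ N(0, σ²_β I)`, with penalty `λ = σ²_e / σ²_β`
estimated by REML through a single spectral decomposition — equivalent to
the best linear unbiased predictor of random marker effects. An ε-SVR
predictor (any of the four classic kernels) is available behind the same
interface. A leakage-safe k-fold cross-validation harness re-derives allele
orientation and every encoding inside each training fold, and a synthetic
generator (Hardy–Weinberg genotypes; additive, dominance and epistatic
category-mean effects at a target heritability) makes the whole pipeline
testable without external data.

## Worked example

```python
import genoenc as ge

cfg = ge.SimulationConfig(seed=1)          # n=300, m=200, 60 causal, h2=0.6
G, y, truth = ge.simulate_dataset(cfg)
reports = ge.compare_encodings(
    G, y, ["ordinal", "target", "hybrid_one", "hybrid_two"],
    predictor="rrblup", k=10, seed=1,
)
for name, rep in reports.items():
    print(f"{name:12s} mean r2 = {rep.mean_r2:.4f}")
```

prints

```
ordinal      mean r2 = 0.2370
target       mean r2 = 0.2572
hybrid_one   mean r2 = 0.2111
hybrid_two   mean r2 = 0.2643
```

Each number is the mean over 10 folds of the squared Pearson correlation
between out-of-fold predictions and observed traits; folds are shared
across methods, so the differences reflect the encodings, not fold luck.
On this replicate the order-preserving, trait-adaptive Hybrid Two encoding
improves on the fixed ordinal coding by about 11 % relative.

The same pipeline is scriptable from a shell:

```sh
genoenc simulate --seed 1 -o data/run1
genoenc cv -g data/run1.genotypes.tsv -t data/run1.traits.tsv \
    --methods ordinal,hybrid2 --k 10 --seed 1 -o data/run1.cv.tsv
genoenc diagnose -g data/run1.genotypes.tsv -t data/run1.traits.tsv \
    -o data/run1.diag.tsv
```

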
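# latdiv

Macrogenetics of latitudinal genetic diversity gradients from georeferenced
COI alignments.

`latdiv` is for population geneticists and macroecologists who want to ask,
reproducibly, whether mitochondrial genetic diversity in a regional species
assemblage tracks latitude, and which environmental variables drive it.  It
takes per-species aligned COI sequences with per-individual coordinates,
pools them into one-degree latitudinal bands, estimates band-level
nucleotide diversity (π) and haplotype diversity (Hd), fits
maximum-likelihood random-intercept polynomial models of diversity against
latitude with AIC-based selection, and screens environmental covariates for
collinearity before exhaustive AICc subset ranking and model averaging.  A
synthetic-data generator with known ground truth makes every stage
verifiable without any sequence downloads.

## The model

Per (species *s*, band *b*) cell with haplotype counts *c₁…c_H* (n = Σcᵢ,
frequencies *xᵢ = cᵢ/n*) over *L* usable alignment columns (complete
deletion of any column with a gap or non-ACGT symbol in the species):

- π = Σ_{i<j} cᵢcⱼ d_ij / C(n,2), with d_ij the per-site difference
  proportion between haplotypes (equivalently (n/(n−1)) Σ xᵢxⱼ d_ij);
- Hd = (n/(n−1)) (1 − Σ xᵢ²).

The pooled (total diversity) trend model is a Gaussian random-intercept
mixed model on the z-scored band latitude *z*:

    y_sb = β₀ + β₁ z + … + β_q z^q + a_s + ε_sb,
    a_s ~ N(0, σ²_α),  ε_sb ~ N(0, σ²_ε)

fitted by full maximum likelihood: β and σ²_ε are profiled out analytically
and Nelder–Mead minimises the remaining one-dimensional profiled deviance in
log(σ²_α/σ²_ε).  Orders q = 0…4 are compared by AIC: the lowest-AIC model
wins outright only when ΔAIC > 2 against all others; otherwise the least
complex model within ΔAIC < 2 of the minimum is selected.  Marginal and
conditional R² (fixed effects alone / fixed plus random) and a full
parametric bootstrap of the fixed effects are reported for the selected
model.  Intraspecific trends use the same ladder with OLS per species.

The environmental-driver analysis z-scores the covariates, flags collinear
pairs (Pearson |r| > 0.7, VIF > 5), builds candidate variable sets that keep
one member of each flagged pair, retains sets by global-model AIC, ranks all
2^p subsets of each retained set by AICc, and averages coefficients over the
ΔAICc < 2 top set (full averaging: absent terms contribute zero) with
Burnham–Anderson unconditional standard errors, 95% CIs and per-term
importance weights.

## Worked example

Simulate a study-shaped dataset (23 species, one-degree bands inside
36°N–32°S, an equatorial diversity hump injected on the log scale) and run
the pooled trend analysis:

```python
from latdiv import (SimConfig, simulate_sequences, build_cells,
                    apply_species_filters, estimate_all,
                    multispecies_band_filter, polynomial_ladder)

ds = simulate_sequences(SimConfig(), seed=7)          # 1827 sequences, 23 species
cells, report = apply_species_filters(build_cells(ds.records))
table = estimate_all(cells, ds.records)               # 196 cells, 67 unique bands
pooled = multispecies_band_filter(table)
ladder = polynomial_ladder(pooled["pi"], pooled["band"],
                           groups=pooled["species_id"])
print(ladder.rows[["order", "k", "AIC"]])
```

```
 order  k          AIC
     0  3 -1586.936306
     1  4 -1584.936756
     2  5 -1605.666092
     3  6 -1603.860724
     4  7 -1609.517682
selected order: 4 -- unique best by delta rule
quadratic term: -0.00360 (SE 0.00078, t -4.62)
R2m 0.328  R2c 0.453
```

The quartic model wins this replicate outright (ΔAIC > 2), and its negative
quadratic term confirms the injected equatorial hump: band-level π declines
away from the equator.  The marginal R² (0.33) is the share of variance
explained by latitude alone; the conditional R² (0.45) adds the
between-species intercept variance.

The same analysis runs from a shell via the bundled CLI:

```bash
latdiv all --config run.yaml --seed 7 --out results/
```

which chains simulate → diversity → total-trend → drivers → intraspecific
and writes TSV/JSON artifacts plus a manifest with row counts at every
filtering step.

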
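# Methods

## Scope and data model

`latdiv` analyses georeferenced, per-species aligned COI sequences.  Each
individual is a (accession, species/lineage id, latitude, longitude,
sequence) record; cryptic lineages carry distinct ids and are treated as
separate species throughout.  Sampling locations are pooled into
one-degree latitudinal bands before any estimation, so the analysis unit is
the (species, band) cell.

Bands are *signed* integer degrees by default: band = sign(lat)·floor(|lat|),
so 23°34′S and 23°12′S share band −23, and sub-degree locations of either
hemisphere share band 0.  Retaining the hemisphere is what lets a
north–south study region span more bands than its absolute range and lets a
quadratic trend peak at an interior latitude; an `--absolute-bands` switch
folds the hemispheres for sensitivity analyses.

Inclusion filters (configurable, defaults `min_n = 3`, `min_bands = 4`):
cells with fewer than 3 sequences are dropped first, then species with
fewer than 4 surviving distinct bands.  The pooled (total diversity)
analysis additionally keeps only bands represented by ≥ 2 species; the
intraspecific analysis never drops bands.  Every exclusion is recorded with
a reason in the filter report, and the run manifest tracks row counts after
each step.

## Diversity estimation

Alignment columns containing a gap or any non-ACGT symbol in *any* sequence
of a species are removed for *all* sequences of that species (complete
deletion).  Filtering is done once per species — not per band — so all band
estimates of a species share one site set and remain comparable.  Haplotype
identity is exact string equality on the retained columns; no
ambiguity-code matching (deterministic and testable, at the cost of
treating partially ambiguous sequences as distinct until their ambiguous
columns are deleted).

π is computed from haplotype counts as Σ_{i<j} cᵢcⱼ d_ij / C(n,2), which is
arithmetically identical to enumerating all unordered sequence pairs; the
test suite verifies this identity against explicit enumeration to 1e-12.
Hd = (n/(n−1))(1 − Σxᵢ²).  Both use the unbiased n/(n−1) correction by
default, with plug-in variants behind a flag for cross-checks.  Distances
are raw per-site difference proportions — no substitution-model correction,
matching the raw-difference definitions of both estimators.

## Mixed-model machinery

The pooled trend and driver models are Gaussian random-intercept models
fitted by full ML (never REML), because models with different fixed-effect
structures are compared by information criteria.  For a fixed variance
ratio λ = σ²_α/σ²_ε the marginal covariance is block compound-symmetric, so
the GLS coefficients, the profiled σ²_ε and the log-determinant all have
closed per-group forms.  Nelder–Mead minimises the one-dimensional profiled
deviance in t = log λ from three starts (λ = 0.01, 1, 100) with deviance
tolerance 1e-10; t ≤ −30 is clamped to the σ²_α = 0 boundary, which is an
admissible fit flagged `singular` and retained in model comparison.
Coefficient covariance is σ̂²_ε (XᵀV₀⁻¹X)⁻¹ at the optimum.  The engine is
checked in the tests against (a) a dense 200×200 log-grid over both
variance components and (b) an independent mixed-model implementation.

Parameter counts follow the lme4-style df convention: fixed effects + 2
variance components (an intercept-only mixed model has k = 3; polynomial
orders 0–4 give k = 3–7).  OLS fits count fixed effects + 1.
AIC = −2ℓ + 2k; AICc adds 2k(k+1)/(N−k−1).

Latitude is z-scored (mean 0, sample SD 1) before building *raw* powers
[1, z, …, z⁴].  Raw rather than orthogonal polynomials: centering and
scaling already curb the collinearity among powers, and raw powers keep the
quadratic coefficient directly interpretable; an orthogonal mode is a
possible extension but is not needed for selection, which depends only on
likelihoods.

Marginal/conditional R² use the variance decomposition
σ²_f = Var_N(Xβ̂) (population denominator), R²m = σ²_f/(σ²_f+σ²_α+σ²_ε),
R²c = (σ²_f+σ²_α)/(σ²_f+σ²_α+σ²_ε).

The parametric bootstrap resimulates *both* the species intercepts and the
residuals from the fitted variances (full parametric; holding the
intercepts fixed would understate variability), refits each replicate, and
reports per-coefficient bias and SE; non-converged replicates are excluded
and counted, with > 20% failures flagging the summary unreliable.

## Selection rules

Polynomial ladder: lowest AIC wins outright only with ΔAIC > 2 over all
competitors; otherwise the least complex model within ΔAIC < 2 of the
minimum is selected.  Candidate environmental sets are compared the same
way on their global-model AICs, and *all* sets within ΔAIC < 2 are carried
forward.

Collinearity screen: pairwise Pearson r (|r| > 0.7 flags a pair) and
VIF_j = 1/(1−R²_j) from regressing each covariate on the others
(VIF > 5 flags a variable; perfect collinearity reports VIF = ∞).
Candidate sets drop one member of each flagged pair in every combination
(Cartesian choice), deduplicated, with strict subsets of other candidates
removed — with a single flagged pair this yields exactly two sets.

All-subsets ranking fits every subset of a retained set (intercept-only
included) as a mixed model, ranks by AICc and computes Akaike weights over
the full ranking.  Model averaging renormalises the weights over the
ΔAICc < 2 top set and uses *full* (zero-substitution) averaging with
Burnham–Anderson unconditional variance Σ w_m (se²_m + (β̂_m − β̄)²); a
term's importance is the summed renormalised weight of top-set models
containing it (1 exactly when it is in every top model), and the
full-ranking importance is also emitted since published weight tables
sometimes use that normalisation.  Conditional averaging is available
behind a flag.  CIs use the normal approximation with multiplier 1.96.

The sample-size QC regresses each diversity metric on cell n by OLS,
iteratively excluding rows with |externally studentized residual| > 3
(configurable, every exclusion logged) — a reproducible stand-in for visual
residual inspection — and reports the slope with its two-sided p-value.

## Synthetic data

The generator's defaults describe a tropical-Atlantic-shaped study:
23 species/lineages, contiguous one-degree band ranges inside 36°N–32°S,
4–12 bands per species (mean ≈ 8, ≈ 184 cells), 3–15 sequences per band,
COI-length alignments (L = 600).

*Band-level responses* are drawn directly from the assumed mixed model.
Defaults for π — β = (0.012, 0, −0.004), σ²_α = 9e-4, σ²_ε = 3e-4 — were
chosen so the variance partitioning resembles empirical pooled analyses
(marginal R² of a few percent, conditional R² dominated by the species
intercepts) at realistic mitochondrial diversity magnitudes; Hd uses
β = (0.80, 0, −0.08) with correspondingly larger variances.  Optional
`env_effects` add linear terms in the z-scored environmental covariates to
the π response for driver-recovery experiments.

*Sequence-level data* come from a star genealogy, not a coalescent: per
cell, a Chinese-restaurant partition with concentration
θ = θ₀·μ/exp(β₀) sets haplotype frequencies, and each distinct haplotype
receives Poisson(μL/2) private substitutions from a species reference
(collision re-draws approximate infinite sites on finite L), where
μ(s, b) = exp(β₀ + β₁z + β₂z² + a_s) is the latent diversity surface.
The log link keeps μ positive; consequently the sequence-level recovery
tests compare signs and orderings (selected order, sign of the quadratic),
while exact-coefficient recovery is tested on the band-level path.  The
defaults β_seq = (log 0.008, 0, −0.5), σ²_α,seq = 0.09, θ₀ = 1.5 produce a
clearly humped surface (edge cells at ≈ 20% of equatorial diversity) with
realistic π ≈ 0.001–0.01.  What this generator does *not* emulate: genuine
coalescent genealogies, recombination, migration, selection, sequencing
error, or spatially autocorrelated sampling — so green tests demonstrate
correctness of the estimators and inference machinery under the assumed
model, not robustness of the scientific conclusions to real-data
violations.

Environmental fields: SST declines linearly in |latitude| with noise;
dissolved oxygen is a negative affine function of SST redrawn until the
realized r(SST, DO) ≤ −0.7 (error after 100 redraws with advice to change
parameters); salinity, current velocity and pH are weak independent noise
kept pairwise |r| < 0.5; chlorophyll-a can be coupled to the diversity
surface.  Every simulated artifact embeds the config hash and seed, and
regeneration is bit-identical.

## Numerical choices and degenerate inputs

- σ²_ε is floored at 1e-12, so noiseless responses fit cleanly with the
  coefficients recovered exactly.
- Ladder orders whose design is rank deficient (too few distinct
  latitudes) or leaves no residual df are skipped and logged, never fatal;
  a species where nothing beyond the null model is estimable is skipped
  with a log entry in the intraspecific analysis.
- n < 2 cells are an error for both estimators; the inclusion filters
  guarantee n ≥ 3 upstream.
- Zero usable alignment columns after complete deletion is a hard error.
- Ties in the selection rules resolve to the less complex model by
  construction; equal AICc models share Akaike weight exactly.

## Problem sizes used in the checks

The verification suite and `scripts/acceptance.py` use: 1000 random
haplotype samples (n ≤ 12) for the estimator-vs-enumeration identity; 50
simulated datasets of 20 groups × 10 for the ML-vs-grid comparison
(200×200 log-spaced grid); 200 study-sized band-level simulations for
coverage/bias of the quadratic coefficient; and 100 sequence-level
simulations each for hump detection and null selection.  These sizes give
stable Monte-Carlo estimates at desk scale.

## Known limitations

- The star-genealogy generator understates the variance of realized π
  relative to a coalescent, so power estimates from it are optimistic.
- Full model averaging with a 1.96 multiplier ignores small-sample t
  quantiles; with ~170 rows the difference is negligible.
- The collinearity screen's candidate sets grow combinatorially with the
  number of flagged pairs; this is intended for the single-digit covariate
  panels typical of this analysis.
- Banding ignores longitude entirely; coastal distance or spatial
  autocorrelation corrections are out of scope.
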
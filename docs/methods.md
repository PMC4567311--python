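# Methods

## Damage scoring

Crown condition is recorded in seven ordinal percentage classes per
variable and viewing side. Classes are resolved to their interval
midpoints (0, 0.75, 6.75, 18.75, 37.75, 62.75, 87.75 %; the open top class
is taken to span 75.5–100 %), and where viewing sides disagree the
per-side midpoints are averaged *before* the damage equations are applied.
The class table is configurable (`AssessmentClasses`).

All crown quantities are proportions in [0, 1] internally; percentages
appear only at I/O boundaries. Leaf-gall incidence is conventionally a
percentage and carries a `_pct` suffix.

Two deliberate asymmetries of the scoring are preserved rather than
"fixed": the total-damaged-crown quantity adds dead branches in the sunlit
part only (shaded branch loss is confounded with self-pruning in a
heliophilous species), and a fully dead crown makes the living-crown light
fraction undefined — such trees are flagged and excluded with a warning,
never silently zeroed.

## Neighborhoods and apparency

Crowns are modelled as circles with radius √(area/π) around the stem.
Two trees are neighbors when their crown circles come within 3 m edge to
edge (configurable gap); the criterion includes overlapping crowns, and
the relation is symmetric by construction. Digitized crown polygons would
be preferable where available; the circular model is the natural fallback
when only crown projection areas are measured.

A focal tree whose crown circle plus the neighbor gap extends beyond the
plot boundary has a partially unobservable neighbor set and is excluded
from neighborhood analyses. Coppice clumps collapse to a single tree
before any neighborhood computation: tallest stem height, summed crown
area, summed basal area (equivalent DBH = √Σdᵢ²), basal-area-weighted
centroid position. The collapse rules beyond "one tree per clump" are this
package's choice.

Apparency ΔH is the focal height minus the mean neighbor height, computed
over all neighbors regardless of species (a `heterospecific-only` variant
would be a one-line filter on the neighbor set; the default follows the
definition of ΔH, which does not restrict species). ΔH is undefined
without neighbors; such trees are dropped from neighborhood models with a
warning.

## Diversity covariates

Shannon *H′* (natural log) and chestnut proportion are computed on
relative stem basal area, π(DBH/2)². Taxonomic diversity is Clarke &
Warwick's Δ — Σ₍ᵢ<ⱼ₎ dᵢⱼxᵢxⱼ / [n(n−1)/2], n = Σxᵢ — with unit step
lengths per Linnaean rank (species→genus→family→order) and the path
doubled for the descent. The plot pipeline feeds Δ basal areas in cm², so
n ≫ 1 and the finite-n denominator correction is negligible, making the
index effectively independent of the abundance unit. Δ is cross-checked
against vegan's `taxondive` in the test suite. Under this classification
the three *Quercus* species are exactly equidistant from *C. sativa* and
from *O. carpinifolia*; the index inherits that degeneracy by design, which
caps the variation the taxonomic covariate can express in these stands.

Neighborhood covariates are computed over the neighbor set *plus* the
focal tree: the host-proportion covariate is meant to measure resource
concentration around and including the focal resource.

The oak-gall covariate averages tree-level incidences (per-branch
percentages of leaves with ≥ 1 cynipid gall, averaged per tree) across all
sampled oaks of a plot; oak-free plots score 0.

## Outlier screen

Candidate outliers in raw (untransformed) defoliation are checked against
1,000 simulated Gaussian samples with the observed n, mean and SD. The
default envelope is the pooled 2.5th/97.5th percentile of all simulated
values — a per-point 5 % criterion that expects ≈ 3.5 flags at n = 70 and
converges to mean ± 1.96 SD. An `extremes` envelope (percentiles of
per-sample minima/maxima) is available for a family-wise reading of the
interval; it flags ≈ 0 points under the null. The pooled variant is the
default because a screen that removes a handful of extreme trees at this
sample size matches how the protocol is used in practice. The screen is
seeded and its report records seed, envelope and flags; analyses can be
redone with outliers reincorporated (`--keep-outliers`).

## Mixed models and model comparison

Models are random-intercept LMMs of log defoliation (natural log of the
percentage) fitted by statsmodels `MixedLM`. Reported estimates, SEs and
t statistics come from REML fits; the likelihoods entering AICc come from
ML fits, since REML likelihoods are not comparable across fixed-effect
structures (`aicc_on` is configurable). AICc = −2logL + 2K +
2K(K+1)/(n−K−1) with K = slopes + intercept + two variance components
(null K = 3, univariate K = 4, additive K = 5, interaction K = 6).
t-test p-values use residual degrees of freedom n − rank(X); no
Satterthwaite approximation is attempted, which makes the printed p-values
slightly liberal for between-plot predictors. All models in a comparison
are refit on the common complete-case row set so AICc is comparable;
failed fits are dropped with a warning and weights renormalized.
Interaction models always contain their main effects.

The minimum adequate model is the lowest-K model within 2 AICc units of
the AICc-best model, ties broken by lower AICc. A fit whose plot variance
lands on the zero boundary is returned flagged `singular`, not raised.
The `ols` method pins the plot variance at zero, which reduces the model
to the pooled linear model — used as the degenerate-case path and tested
against hand-solved normal equations.

Sequential variance decomposition fits the ML sequence null → +first →
+both in both predictor orders, reporting likelihood-ratio χ²₁ p-values
per added term plus the joint-model REML estimates (identical across
orders by construction). Near-duplicate predictors (|r| > 0.99) are
rejected.

## Synthetic stands

The generator reproduces the comparative design: 15 plots of 30 m × 30 m
with richness 1–4 in counts (2, 3, 5, 5); every plot contains chestnut,
companions drawn from {*Q. cerris*, *Q. ilex*, *Q. petraea*,
*O. carpinifolia*}; 40 stems per plot at ≥ 2 m spacing via rejection
sampling; heights ~ N(15.2, 3.3²) m, DBH lognormal around 19 cm
(basal area ≈ 0.03 m²), crown areas lognormal around 14 m², with height
and DBH sharing a latent size factor (r ≈ 0.6). Focal chestnuts are the
largest-DBH chestnuts: six per monoculture, three per mixed plot
(51 focal trees).

Damage follows log T_D(%) = β₀ + β_richness·richness + β_ΔH·ΔH + b_plot +
ε with defaults β_richness = −0.26, β_ΔH = 0.15, σ_plot = 0.2,
σ_resid = 0.4 — the magnitudes the analysis is designed to detect — and
β₀ = 2.7 chosen so mean defoliation lands near the observed 12.7 % at this
design's richness/apparency mix. The generator computes ΔH over all mapped
trees (it is omniscient; margin exclusion is an analyst-side limitation).
Latent defoliation is decomposed into the five crown proportions
(P_CL ~ Beta(6,4); dead-branch fractions Beta(1,11) and Beta(1.2,8),
independent of gall load; P_DS = 0.8·P_DL with P_DL solved so the
defoliation equation inverts exactly), then discretized to the class scale
with small lognormal per-side jitter. The decomposition is arbitrary
beyond its round-trip consistency, which is what the tests check
(resolved vs latent defoliation within one class width, r > 0.8).

Leaf samples are binomial (2 branches × 30 leaves) with gall probability
0.10 + 0.8·T_D plus tree-level Gaussian scatter (SD 0.10), giving a
positive but noisy damage–leaf-incidence correlation as in real crown vs
branch-level measurements. Oak cynipid incidence is a per-plot Beta(2, 8)
draw — it is *not* linked to the diversity gradient, so the synthetic
oak-gall covariate behaves as a null predictor; inferences about the
natural-enemies mechanism cannot be rehearsed on synthetic data, only the
machinery around them.

What passing tests show, and don't: the pipeline recovers generating
effects of the stated magnitude at the design's sample sizes, with
calibrated intervals and outlier-screen error rates. They do not show that
real crown scoring is unbiased, that circular crowns approximate real
crown projections well, or that the predictors' field correlation
structure (where all five plot covariates are strongly mutually
correlated) is reproduced — the synthetic covariates correlate through the
richness gradient but more weakly.

## Problem sizes and numerics

Tests and the acceptance script use the native study size (15 plots,
51 focal trees) — small enough that everything runs in seconds. Estimator
calibration uses 200 replicates at 15 plots × 5 trees; screen calibration
uses 400–2,000 null replicates at n = 70. MixedLM convergence warnings are
suppressed and surfaced instead through the `singular`/`converged` flags.
With ~20–30 rows at the neighborhood level, the interaction models
(K = 6) are near the edge of identifiability; they fit, but their SEs are
wide and they never win — as expected.

A subtle degeneracy of class-resolved responses: because resolved
defoliation is quantized to class-midpoint combinations, two trees in the
same plot can carry *exactly* equal log responses. When, at a small
neighborhood sample, every multi-tree plot happens to be internally tied,
the REML residual variance legitimately collapses to zero and the fixed
slopes degenerate (lme4 and statsmodels agree on this boundary solution).
Such fits are flagged `singular` in the comparison table rather than
patched over; at the plot-level sample size the tie pattern never spans
all plots and the issue does not arise.

## Known limitations

- Circular crown projections; no terrain or slope correction.
- No Satterthwaite/Kenward–Roger degrees of freedom.
- Taxonomic distances are rank counts, not branch lengths; the oak
  degeneracy limits the index's resolution.
- The generator does not model spatial aggregation of species (species are
  assigned independently of position) or gall-wasp dispersal dynamics.
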
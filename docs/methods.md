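# Methods

This note records the models implemented in `farmscape`, the choices
made where the design was genuinely open, and what the synthetic-world
experiments do and do not establish.

## Farming propensity from ordinal subsistence codes

Each society carries five Murdock codes in 0–9, one per subsistence
activity, with code → percentage ranges 0: 0–5, 1: 6–15, …, 8: 76–85,
9: 86–100. Percentages are rounded to the nearest integer before
encoding so the ten ranges tile [0, 100] without gaps.

Decoding is stochastic: a draw samples each activity uniformly inside
its code's range and then moves onto the sum-100 hyperplane by
distributing the deficit (surplus) proportionally to each part's
remaining upward (downward) slack. Because a feasible box has total
slack at least as large as the deficit, a single proportional step lands
exactly on the hyperplane without leaving the box; feasibility
(Σ lower ≤ 100 ≤ Σ upper) is checked per society and an infeasible code
combination is a hard error naming the row.

Each replicate of the decoded percentage matrix is clr-transformed
(zeros floored at 0.1% — far below the coarsest 6-point category
resolution — and re-closed) and eigen-decomposed via the covariance of
the clr rows (Aitchison geometry; covariance, not correlation, since clr
parts share a scale). PC1's sign is fixed per replicate so the summed
agriculture + pastoralism loading is positive, making "higher = more
farming" deterministic. The propensity score is the per-society mean PC1
score over `n_draws` (default 1,000) replicates; the PC1 variance
fraction is reported with its spread over replicates, which is small
(s.d. ≈ 1–2% of the mean) because the draw noise is bounded by the
category widths.

## Maximum-entropy niche models

Occurrence records are thinned to one seeded random record per grid
cell; species with fewer than `min_records` (default 15) occupied cells
are dropped. The remaining cells are split 70/30 into training and test
(seeded, disjoint, training size rounded up).

Features over the five bioclimatic variables (annual mean temperature,
temperature annual range, precipitation of wettest month, driest month,
warmest quarter) are built on min–max standardized values frozen from
the fit background: 5 linear, 5 quadratic, 10 pairwise products, 10
quantile-knot step functions per variable, and 10 forward + 10 reverse
hinge ramps per variable — 170 features, all mapping into [0, 1].
Prediction-period values outside the frozen envelope are clamped.

The model is the Gibbs distribution over background cells minimizing

    −(1/m) Σ_presences λ·f(x) + ln[(1/N) Σ_background exp(λ·f(z))] + Σ_j β_j |λ_j|

with per-feature penalty `β_j = r · max(s_j, 0.05)/√m`, where `s_j` is
the feature's standard deviation over presences, 0.05 is 5% of the
feature range, `m` the presence count, and `r` the regularization
multiplier (default 1). This single analytic schedule replaces reference
Maxent's per-feature-class interpolation tables; it keeps the
sample-size-dependent shrinkage that motivates them. The optimizer
splits λ into non-negative parts and runs bound-constrained L-BFGS with
restarts until the first-order condition
`|empirical mean − model expectation| ≤ β_j` holds to ≤ 1e-6 for every
feature (typical achieved slack ~1e-8); failure to reach it raises. The
choice of L-BFGS-on-the-split over proximal/coordinate steps is purely
practical — it is deterministic, subgradient-safe, and satisfies the
same KKT conditions it is tested against.

Output suitability is the raw Gibbs density. No logistic/cloglog
post-transform is applied: every downstream consumer (non-omission
threshold, AUC, Pearson sweep on ranked counts) is invariant under
strictly monotone transforms, a property the tests assert directly.
AUC is computed with ties counted half. Binarization uses the
non-omission threshold — the minimum suitability over training-presence
cells of the surface being thresholded — so training presences are never
omitted.

Background: all valid cells on desk-scale grids, or a seeded 10,000-cell
sample on larger ones. Cell membership everywhere uses half-open
[west, east) × [south, north) intervals; geodesy is spherical haversine
with R = 6,371 km.

## Dispersal-constrained richness

A species' realized availability is its binarized range intersected with
the great-circle disc of radius `R` around its domestication origin
(distances measured cell-center to origin). Stacked counts give the
historical-ecological-opportunity surface. `R` is selected by sweeping a
strictly increasing radius grid and maximizing the Pearson correlation
(complete cases) between society-level richness and propensity; ties go
to the smallest radius (parsimony). The full 10–40,000 km, 10 km-step
sweep is the default of the library function; tests and the acceptance
script use a 250 km step to keep sweeps cheap, which only coarsens the
resolution of the selected radius.

## Transmission proxies

Horizontal: the unweighted mean propensity of the `k` nearest other
societies (haversine; distance ties broken by society id, making scores
independent of row order). Vertical: the language-family label, consumed
as a grouping factor — no phylogeny is inferred. When `k` is not fixed,
it is chosen to minimize the mean |Moran's I| across the 12 classes of
the residual correlogram of propensity ~ horizontal score; that
aggregate was picked because the correlogram is the diagnostic the
analysis ultimately reports, and smallest-`k` wins ties.

## Mixed model, commonality analysis, spatial diagnostics

The mixed model is Gaussian with a single random intercept per language
family, estimated by REML. With one variance ratio γ = σ²_fam/σ²_e the
likelihood is profiled analytically per group (block inverses in closed
form) and γ located by a deterministic bounded scalar search on log γ,
always compared against the γ = 0 boundary; fixed effects are z-scored
first so coefficients are comparable. The implementation is
cross-checked in the tests against an independent mixed-model routine.
The recorded optimizer trace is the best-so-far REML objective, which is
non-decreasing by construction.

Commonality analysis computes OLS R² (with intercept; family dummies
form the Ver block, mammal + plant richness the CEO block) for all 15
non-empty block subsets and solves the inclusion–exclusion system
R²(S) = Σ_{T∩S≠∅} C(T). The solution is verified at run time against
the Möbius closed form (tolerance 1e-10); negative shared components
(suppression) are reported as-is, not truncated. R² of the empty subset
is defined as 0.

Moran's I uses the standard double-sum form with zero diagonal.
Correlograms rank all n(n−1)/2 great-circle pair distances (stable
sort; tied distances fall to the lower class) and split them into 12
classes of equal pair count ±1; each class's binary symmetric weights
feed Moran's I. Duplicate coordinates that empty a class raise.

## The synthetic world

Climate: five-layer fields on a regular grid, each a latitudinal
gradient plus seeded Gaussian-smoothed noise clipped to configured
bounds (annual mean temperature −15…30 °C, temperature range 5…45 °C,
driest-month precipitation 0…120 mm, wettest = driest + 0…380 mm excess,
warmest-quarter 0…900 mm); the historical period adds a small smooth
offset (4% of span). Wettest ≥ driest holds by construction in both
periods. Desk-scale worlds use 2° cells over a 60° × 180° window so that
multi-thousand-km dispersal radii are resolvable at low cost; cell size
is a free parameter.

Species: Gaussian climatic niches with means inside the observed
envelope, per-variable s.d. 18% of the envelope range, and random
low-rank correlation (always SPD). Origins sit in the top decile of the
species' own suitability. Occurrences are sampled with replacement
proportional to density with sub-cell jitter; optional duplication
emulates reporting bias.

Ground-truth presence is density ≥ 1% of the species' peak. That cut is
the self-consistency point of the design rather than a free dial: with
records sampled proportional to density, the expected minimum sampled
density over m ≈ 10² records — exactly the non-omission threshold the
estimation side will use — is of order max/m ≈ 1% of the peak. A truth
definition far from that value would make the generative world
internally inconsistent with its own sampling model.

Societies: latent propensity = β_heo·z(richness) + β_ceo·z(CEO) +
family effect + noise, optionally mixed with the k_true-nearest
neighbours' values; contemporary mammal/plant richness are Poisson
counts with climate-driven log-rates. The latent value maps to a
five-part budget through a softmax link with agriculture and pastoralism
logits shifted by the latent value (any monotone link suffices; softmax
guarantees a valid composition), then budgets are Murdock-encoded.
Hidden truth columns (latent value, true percentages, true richness) are
kept for validation. Defaults (β_hor 0.3, β_heo 0.5, β_ceo 0.2,
family s.d. 0.5, noise s.d. 1.0, 20 families, k_true 5, clustered
families with 3° spread) give a world where all four forces are present
at moderate, realistic strength.

The generator emulates the *structure* of the real data, not its
geography: there are no continents or oceans (every cell is valid land),
no observation error in coordinates, no missing codes, and language
families are exchangeable labels rather than products of descent.
Passing recovery tests therefore demonstrates that the estimation
machinery is correct and identifiable under the stated generative model
— not that the real-world datasets would yield any particular answer.

## Problem sizes and experiment configurations

Chosen as the package's standard desk-scale study conditions:

- Propensity validity: 1,000 draws × 500 societies.
- Niche models: 5–10 species, 200–250 records each, 2,700-cell grids.
- Radius recovery: 20 independent worlds, true R\* = 3,000 km,
  β_heo = 1, other effects muted (β_hor = β_ceo = 0, family s.d. 0.1,
  noise s.d. 0.3), uniformly placed societies, 250 km sweep; success is
  selection within one step. This is a scaled-down analogue of the fine
  10 km sweep the library also supports.
- Neighbourhood recovery: 400 societies, k_true = 5, mixing weight 0.8.
- Mixed-model recovery: 100 simulations of n = 1,000, 20 families,
  β = (0.5, 0.3), both variances 1; success is all coefficients within
  3 reported SEs, demanded in ≥ 95% of runs.
- Confounded demonstration world: 1,000 societies, 15 families nested in
  tight (1°) spatial clusters, richness-driven propensity
  (β_heo = 1, family s.d. 0.05, noise s.d. 2.0), pipeline run with
  k = 1. Nesting families inside richness clusters makes vertical
  transmission and historical opportunity jointly explain the structured
  variance, so the largest commonality component is their shared term —
  the qualitative signature of ecology acting through human-assisted
  dispersal. The heavy per-society noise keeps the spatial-lag proxy
  from absorbing that shared signal.

## Known limitations

- The Maxent penalty schedule and knot placement are principled
  simplifications; fitted λ will not numerically match reference Maxent
  even on identical data (rank-based outputs are comparable).
- Great-circle dispersal ignores coastlines and least-cost paths.
- The mixed model supports exactly one random intercept; no spatial
  error models (spatial structure is diagnosed, not modelled).
- Commonality components are descriptive; no uncertainty is attached.
- The clr zero-floor (0.1%) is a pragmatic choice; alternative
  compositional transforms (ilr/alr) are out of scope.
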
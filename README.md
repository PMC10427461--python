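# farmscape

Ecological opportunity, cultural transmission, and the geography of
reliance on agriculture — a tested, fully reproducible analysis pipeline
exercised end to end on synthetic worlds with known ground truth.

Traditional societies differed enormously in how much of their
subsistence came from farming. One long-standing hypothesis is that this
geography was shaped not only by cultural transmission (inheriting
practices from linguistic ancestors, or adopting them from neighbours)
and by present-day ecology, but also by *historical ecological
opportunity*: how suitable a society's environment was for the specific
set of species first domesticated by humans, given that those species
had to disperse from their centres of domestication. `farmscape`
implements the statistical machinery needed to ask that question —
and, because the real cross-cultural, occurrence and climate datasets
are not redistributable as one accession, ships a first-class synthetic
world generator so every stage can be validated against known truth.

The package is aimed at quantitative anthropologists, macroecologists
and methodologists who want the full chain as reusable, tested parts.

## The analysis chain

1. **Farming propensity** (`farmscape.propensity`). Ethnographic
   subsistence budgets are recorded on Murdock's 0–9 ordinal scale for
   five activities (hunting, gathering, fishing, agriculture,
   pastoralism), each code bounding a percentage range. Percentage
   budgets summing to 100 are stochastically re-drawn inside those
   ranges many times; each draw is clr-transformed
   (`clr(x)_i = ln(x_i / g(x))`) and run through a covariance PCA; PC1
   is sign-aligned so higher scores mean more agriculture + pastoralism;
   a society's propensity is its mean PC1 score across draws.
2. **Niche models** (`farmscape.niche`). Per-species maximum-entropy
   (Maxent-family) models: the Gibbs distribution
   `P(cell) ∝ exp(λ·f(climate))` over background cells, with linear,
   quadratic, product, threshold and hinge features of five bioclimatic
   variables and an L1 penalty `β_j = r·s_j/√m`. Models are fit on a 70%
   training split of cell-thinned occurrence records, cross-validated by
   ROC AUC on the held-out 30%, projected onto an earlier climate
   period, and binarized at the *non-omission threshold* (the minimum
   suitability over training presences).
3. **Dispersal-constrained richness** (`farmscape.richness`). Each
   species' binary range is clipped to cells within a great-circle
   radius `R` of its domestication origin; ranges are stacked into a
   per-cell count of available domesticates; `R` is chosen by sweeping a
   grid and maximizing the Pearson correlation with farming propensity.
4. **Transmission proxies** (`farmscape.transmission`). Horizontal: the
   mean propensity of the `k` nearest neighbouring societies (`k` fixed
   or chosen to minimize residual spatial autocorrelation). Vertical:
   language-family membership.
5. **Inference** (`farmscape.inference`). A Gaussian mixed model of
   propensity (random intercept per language family, REML via a profiled
   deterministic search); commonality analysis partitioning the model
   R² into the 2⁴−1 unique and shared components of the four predictor
   blocks (Hor, Ver, CEO, HEO); Moran's I correlograms over 12
   equal-pair great-circle distance classes as the spatial diagnostic.

The synthetic generator (`farmscape.synthetic`) produces the two-period
five-layer climate rasters, Gaussian-niche species pools with origin
points, suitability-biased occurrence records, and society tables whose
latent propensity has a known dependence on richness, contemporary
ecology, family effects and neighbourhood mixing — then encodes the
budgets back to Murdock codes, so recovery can be tested end to end.

## Worked example

```python
from farmscape.pipeline import PipelineConfig, run_pipeline, simulate_world

paths = simulate_world("world", n_societies=200, n_species=8, seed=11)
cfg = PipelineConfig(**paths, out_dir="run", n_draws=200, k_range=(1, 15),
                     master_seed=42)
manifest = run_pipeline(cfg)
for stage, info in manifest["stages"].items():
    print(stage, {k: v for k, v in info.items() if k != "seconds"})
```

prints (about 4 s on a laptop):

```
propensity {'pc1_var_fraction': 0.7622626065174417, 'pc1_var_fraction_sd': 0.014071407066943677}
niche {'n_modelled': 8, 'n_dropped': 0, 'mean_auc': 0.9362506459686696}
richness {'selected_radius_km': 2750.0, 'max_correlation': 0.19055912375066625}
transmission {'k': 3}
inference {'n_complete_cases': 200, 'full_r2': 0.48054896197901464,
           'largest_component': 'Hor&Ver', 'largest_component_value': 0.26673682039395785,
           'max_abs_residual_moran': 0.05755133537306705}
```

Reading the numbers: PC1 of the clr-transformed subsistence budgets
carries ~76% of their variance, so a single farming-propensity axis is a
faithful summary. The eight synthetic domesticates are modelled with
mean held-out AUC 0.94. This world was generated with a true dispersal
limit of 3,000 km, and the sweep selects 2,750 km — one 250 km step
away. The mixed model and the commonality partition then quantify how
that richness signal, contemporary richness, and the two transmission
proxies share the explained variance of propensity.

Every stage is also exposed on the command line (`farmscape simulate`,
`farmscape propensity`, `farmscape niche`, `farmscape richness`,
`farmscape transmission`, `farmscape fit`, `farmscape run --config
config.yaml`); outputs are plain CSV/JSON plus NetCDF rasters, with a
manifest recording input checksums, per-stage seeds and timings.

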
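# soildiv

Spatial analysis of plant species diversity and its soil drivers on gridded
quadrat surveys: **minimum data set (MDS) selection** of soil indicators via
PCA and norm values, **per-quadrat diversity indices**, **semivariograms and
ordinary kriging**, and **random-forest vs. linear-regression prediction**
of diversity from the soil MDS. Built for the 1-ha / 400-quadrat desert
riparian forest design (100 m × 100 m plot, 5 m × 5 m quadrats) but
parameterised for any rectangular quadrat lattice.

Intended users: spatial ecologists and soil scientists who want the full
soil-reduction → diversity → geostatistics → prediction chain as one tested,
scriptable pipeline instead of a mix of GS+, SPSS and ad-hoc R.

## The methods in brief

- **Diversity** per quadrat: Shannon–Wiener `H′ = −Σ Pᵢ ln Pᵢ`, Simpson
  `D = 1 − Σ Pᵢ²`, Pielou `J = H′/ln S`.
- **MDS selection**: K-S (Lilliefors) screening with log transforms → PCA of
  the correlation matrix (components with λ ≥ 1 retained) → norm values
  `Nᵢ = √(Σₖ Uᵢₖ² λₖ)` → per-group top-10% rule → |r| ≥ 0.5 correlation
  pruning. The reduced set is validated by regressing the full-set soil
  property index `SPI = Σ Wᵢ F(Xᵢ)` (communality weights, linear membership
  scores) on the reduced-set SPI.
- **Geostatistics**: binned isotropic semivariogram
  `γ(h) = Σ[Z(xᵢ)−Z(xᵢ+h)]² / 2N(h)`, least-squares fits of exponential /
  gaussian / spherical / linear models, nugget-to-sill classification
  (< 25% strong, 25–75% moderate, > 75% weak), ordinary kriging with
  weights summing to one.
- **Prediction**: backward-AIC multiple linear regression vs. a 500-tree
  random forest (out-of-bag explained variance, permutation importance with
  response-permutation significance), compared by RMSE and mean relative
  error with reverse-cumulative residual curves.
- **Synthetic surveys**: Cholesky-exact Gaussian/lognormal random fields
  with chosen variogram models and cross-correlation, plus a tunable
  (linear / threshold / interaction) soil-driven community model — so the
  entire pipeline runs and is testable without any field data download.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from soildiv import simulate as sim, diversity as dv, mds, models as ml, geostat as gs

table = sim.simulate_quadrat_table(seed=7)          # 400 quadrats, 9 soils, 14 species
div   = dv.diversity_indices(table)
res   = mds.select_minimum_data_set(table)
print("MDS:", res.selected)
print("SPI validation R2: %.3f" % res.validation_r2)

y = div["shannon"].to_numpy(); m = np.isfinite(y)
x = table[res.selected][m]
mlr    = ml.fit_mlr(x, y[m])
rf, _  = ml.fit_rf(x, y[m], n_trees=500, seed=7, n_permutations=0)
print("MLR  R2=%.2f  RMSE=%.3f  MRE=%.3f" % (mlr.r2_or_varex, mlr.rmse, mlr.mre))
print("RF   varex=%.1f%%  RMSE=%.3f  MRE=%.3f" % (rf.r2_or_varex, rf.rmse, rf.mre))

emp  = gs.empirical_semivariogram(table[["x", "y"]].to_numpy(), y)
best = gs.select_best_model(gs.fit_all_models(emp))
print("variogram: %s  nugget/sill=%.1f%%  (%s)" %
      (best.model, best.ratio_percent, best.dependence_class))
```

prints

```
MDS: ['SWC', 'SAN', 'SNN', 'STP', 'SAP']
SPI validation R2: 0.791
MLR  R2=0.28  RMSE=0.654  MRE=0.295
RF   varex=30.5%  RMSE=0.237  MRE=0.102
variogram: gaussian  nugget/sill=91.4%  (weak)
```

Reading it: five of the nine soil properties carry ~79% of the full soil
signal (SPI R²); the forest predicts Shannon diversity much more accurately
than the stepwise linear model (RMSE 0.237 vs 0.654) because the synthetic
community responds to soil through thresholds; and this realisation's
Shannon surface is noise-dominated spatially (nugget/sill 91%), reflecting
the generator's iid demographic noise.

The same run, end to end with all artifacts and a Markdown report:

```bash
soildiv report --seed 7 --outdir run7        # writes run7/report.md + CSVs
soildiv verify                               # replay published-table checks
```

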
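# stmort

Spatio-temporal downscaling and longitudinal trend modeling of metropolitan
age-specific mortality rates.

Health agencies typically publish mortality as annual rates per 1,000 for
coarse administrative areas (boroughs). Epidemiologists who want to compare
neighbourhoods, or look at within-year dynamics, face the modifiable areal
unit problem: conclusions change with the arbitrary aggregation unit. This
package implements a two-stage pipeline for that situation:

1. **Space-time kriging downscaling.** Treat the area/annual rates as
   point-referenced observations at area representative points, estimate the
   joint spatio-temporal semivariogram γ(h, u), select a joint covariance
   structure, and interpolate with global ordinary kriging onto finer areas
   and quarter-year ("trimester") time steps.
2. **Longitudinal trend modeling.** Fit the rates y<sub>ijk</sub> (age group
   α<sub>i</sub>, area β<sub>j</sub>, centered time t<sub>k</sub>) with the
   fixed-effects model

   y<sub>ijk</sub> = μ + α<sub>i</sub> + β<sub>j</sub> + γt<sub>k</sub> +
   δt<sub>k</sub>² + ζt<sub>k</sub>³ + (all double and triple interactions) +
   ε<sub>ijk</sub>,

   where within each (α, β) series the errors are AR(1) with coefficient φ
   and var(ε<sub>ijk</sub>) = σ²g²(α<sub>i</sub>) with one variance
   multiplier per age group (varIdent). Estimation is by REML; inference uses
   Type III marginal F tests, ML likelihood-ratio back-step selection,
   estimated marginal means and Fisher's-LSD pairwise tests with Bonferroni
   correction summarised as compact letter displays.

Model selection in stage 1 is exhaustive: five joint structures — metric,
separable, productSum, sumMetric, simpleSumMetric — crossed with every
exponential/Gaussian/spherical component permutation each structure admits
(75 candidates), fitted by box-constrained quasi-Newton minimisation of the
pair-count-weighted mean squared error, every parameter bounded below by
0.001.

## Worked example

`examples/03_trend_model.py` simulates a 5-age × 16-area × 68-time panel
with known truth (φ = 0.6, variance weights (1, 2, 0.5, 1, 3)) and fits it:

```
phi estimate: 0.603  (truth 0.6)
variance weights (reference Infant = 1):
  Infant           1.000
  Pre-school       1.953
  School           0.514
  Productive       0.983
  Post-productive  3.058
```

φ and the weight ratios are recovered to within a few percent; the letter
display that follows separates all five age groups (letters A–E), meaning
every pairwise difference of marginal means survives the Bonferroni
correction at α = 0.05.

`examples/01_variogram_selection.py` runs the 75-candidate grid search on a
simulated borough-scale field, and `examples/02_kriging_downscaling.py`
downscales a parent-area annual field to 36 child areas at trimester
resolution, printing

```
data-point RMSE (exact-interpolator check): 2.10e-13
```

— ordinary kriging reproduces the observations it was given; the RMSE at
data points measures pure numerical error.

The `stmort` console command exposes the same capabilities as verbs
(`simulate`, `variogram`, `krige`, `trend`, `run-all`) for shell use;
`examples/04_full_pipeline.py` shows the equivalent library call.

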
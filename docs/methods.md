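# Methods

## Geometry and distances

Areal units are polygons in geographic lon/lat degrees, read from GeoJSON.
A two-level hierarchy (child area → parent area) is formed by dissolving
children on a parent identifier; dissolution is a shapely unary union and
conserves total area for non-overlapping children. Each area is represented
by its area centroid when the centroid lies inside the polygon, otherwise by
a guaranteed-interior point (shapely's point on surface); multi-part areas
use their largest part. All metric distances are haversine great-circle
kilometres on a sphere of radius 6371.0088 km. No planar projection is ever
applied: at city scale (≲ 50 km) the spherical error is far below the
variogram bin width, and a single distance convention avoids CRS bookkeeping.

## Empirical spatio-temporal variogram

For every unordered observation pair, half the squared rate difference is
accumulated into a (spatial bin, temporal lag) cell: γ cell = Σ(z_a − z_b)² /
(2·n_pairs). Spatial bins are equal-width on [0, cutoff] (default: 15 bins,
cutoff = maximum inter-site distance); temporal lags sit on the native data
spacing (1 year on annual input). Same-site pairs at different times fall in
the first spatial bin, giving the purely temporal margin; the origin cell
(lag 0, bin 0) is empty by construction and flagged missing, as is any cell
with no pairs.

Initial parameter guesses follow simple marginal heuristics: the nugget per
axis is the median of the first three marginal means of the variogram
matrix, the sill the median of the last five, the spatial range one third of
the maximum lagged spatial value, the temporal range the maximum lag, and
joint values average the two marginals. Marginal means average over the full
other dimension (not only small lags). When a margin is shorter than the
heuristic window, all available means are used. The space-time anisotropy
stAni (km per year) is the ratio of the least-squares slopes of the purely
temporal and purely spatial margins, falling back to range_s/range_t when
the ratio is non-positive; the slope-ratio reading is one faithful
implementation of a linear-model anisotropy estimate, recorded here because
the estimator is not otherwise pinned down in formula form.

## Joint covariance structures and fitting

Components are Exp, Gau, Sph with γ(0) = 0 and, for h > 0,
nugget + psill·f(h/range); `range` is the sill distance for Sph and the
e-folding scale for Exp/Gau (effective ranges 3·range and √3·range — the
gstat convention; beware when comparing ranges across software). The five
joint structures:

- **metric**: γ_j(√(h² + (stAni·u)²));
- **separable**: sill·(γ̄_s + γ̄_t − γ̄_s·γ̄_t) with unit-sill marginals;
- **productSum**: (k·sillT + 1)γ_s + (k·sillS + 1)γ_t − k·γ_s·γ_t;
- **sumMetric**: γ_s + γ_t + γ_j(metric distance);
- **simpleSumMetric**: sumMetric with nugget-free components plus one global
  nugget away from the origin.

Fitting minimises the weighted MSE between model and empirical
semivariances over non-missing cells, weights = pair counts (configurable to
equal weights). The optimizer is L-BFGS-B with every free parameter bounded
below at 0.001 and unbounded above, followed by a short Nelder-Mead polish
(finite-difference gradients flatten near the optimum of smooth Gaussian
components; the polish reliably reaches the 1e-8 self-consistency level).
Two validity bounds are the only exceptions to "no upper bound": the
productSum k is reparameterized as kfrac/max(sillS, sillT) with
kfrac ≤ 0.999, and separable relative nuggets stay ≤ 0.999 — both are
requirements for the induced covariance to exist, not tuning choices.
Optimizer failure is reported through a `converged` flag, never raised, so a
bad candidate cannot abort the 75-model grid search. Candidates are ranked
by weighted MSE with ties broken by fewer parameters, then by structure
order (metric, separable, productSum, sumMetric, simpleSumMetric).

## Ordinary kriging

The predictor uses the semivariogram form of the global ordinary-kriging
system (no covariance conversion, so unbounded components remain usable):
the bordered matrix [Γ 1; 1ᵀ 0] is LU-factorized once and reused for every
target — the intended scale is thousands of child areas × dozens of
trimesters against a few hundred data points. Predictions honour the
observations exactly; kriging variances within −1e-8 of zero are clamped to
0, larger negatives raise an error (a symptom of an invalid model). A
singular system gets one logged ridge retry (1e-10 on the data diagonal).
Quarter q of year y is timestamped y + (q−1)/4 + 0.125 (mid-quarter).
The data-point RMSE diagnostic predicts each observation from the full
dataset (not cross-validation) and therefore measures numerical error only.

## Longitudinal model

Time is centered at the midpoint of the observed span and scaled to unit
steps before forming t, t², t³, taming cubic collinearity; coefficients are
reported on that scale. Factors use sum-to-zero contrasts, so the Type III
marginal test of a term is the Wald F of its contrast block given all other
terms, with denominator df = n − p (GLS residual df). Mixed-model software
uses various denominator-df conventions; exact F-value agreement with such
tools is not expected, though the fitted variance structure is (the test
suite cross-checks φ, the variance weights and fitted values against R's
nlme `gls` with corAR1 + varIdent).

REML estimates (φ, g) with β profiled out by GLS at each candidate; φ is
kept in (−1, 1) by a tanh map (search bounded at |φ| ≤ 0.9993) and variance
multipliers are optimized on the log scale with the first age level
(Infant, also first alphabetically) as reference g = 1 — only ratios are
identified. The AR(1) whitening uses the exact stationary transform per
series, so each objective evaluation is O(n·p²). One φ is shared across
areas by default: the model family allows an area-indexed φ_{β_j}, but a
single coefficient is what the reported quantity is, and a per-area φ at
J ≈ 16 areas costs identifiability on short series.

Back-step selection removes one term at a time: among terms whose removal
preserves the marginality hierarchy, the one with the largest Type III p is
tried first, and the removal is accepted when the ML likelihood-ratio test
(each competitor's ML log-likelihood evaluated at its own REML variance
structure) is non-significant at α. Candidates are tried in descending
Type III p order and the procedure stops when none can be removed — this is
the "remove while the LRT finds no difference" reading of an otherwise
ambiguous stopping rule, and every comparison is recorded in the trace for
audit. REML variance estimation with ML-based selection tests is the
standard reconciliation when comparing fixed-effect structures.

Estimated marginal means average model predictions over a balanced grid of
the other factor's levels and the observed time points; standard errors
come from the averaging contrast and the fixed-effect covariance. Fisher's
LSD tests all pairs with two-sided t tests on df = n − p, multiplies
p-values by the number of pairs within the requested term (capped at 1),
and builds the compact letter display by insert-and-absorb on levels sorted
by descending mean; the letter-sharing relation is exactly the thresholded
pairwise-test relation, which the tests audit exhaustively.

## Synthetic data

`simulate_grf` draws Gaussian random fields with covariance
C(h, u) = sill_total − γ(h, u) by dense Cholesky (with up to 1e-10 jitter);
dense factorization is the deliberate choice at the target sizes (≤ 5000
points). `simulate_trend_data` generates the longitudinal model exactly:
fixed effects plus per-series AR(1) errors with stationary initialization
scaled by σ²g²(α). The default scene is 16 sites on a perturbed grid in a
~30 km box with 17 annual times — sized so that a field with a ~13 km
spatial and ~12 year temporal correlation range is neither trivial nor
unidentifiable — and five age groups whose variance multipliers keep the
infant and post-productive groups noisiest, echoing the empirical ordering
in city mortality panels.

What the generators do not emulate: rate denominators (populations and live
births), count noise (rates are Gaussian, not Poisson-derived), missing
records, and non-stationary spatial trend. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data artifacts.

## Numerical choices and limitations

- Variogram fit: ftol 1e-14 on the objective, ≤ 500 iterations; recovery of
  a generating model among the candidates reaches wMSE < 1e-8.
- Kriging exactness at data points is limited only by the conditioning of
  the bordered system; with the 0.001 parameter floor acting as an implicit
  nugget the observed RMSE at 272 data points is ~1e-13–1e-12.
- Problem sizes used in the shipped tests and the acceptance script —
  16 sites × 17 years for the spatial stage, 5 × 16 × 68 panels (20
  replicates) for variance-parameter recovery — are the package's reference
  study scale.
- Kriged values enter the trend model as exact observations; the kriging
  variance is not propagated into stage 2. On near-noiseless kriged
  surfaces the trend model's φ therefore tends toward its upper bound,
  correctly signalling that a smooth interpolated surface has almost
  perfectly autocorrelated residuals.
- Letter displays beyond 52 distinct groups recycle the alphabet.
- Shapefile input is not supported; convert to GeoJSON first.
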
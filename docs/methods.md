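# Methods

## The model

The analysis treats a species' expected density along an elevational
gradient as a unimodal function of temperature.  Writing the density,
scaled to the species' observed maximum, as a proportion μ ∈ [0, 1], the
Gaussian response is equivalent to a quadratic on the logit scale,

    logit μ(z) = b0 + b1 z + b2 z²,   b2 < 0,

whose peak sits at z* = −b1/(2 b2).  Two subregions sharing the species
pool but offset in temperature provide a space-for-time contrast: under
temperature tracking, z*_north − z*_south should equal the isotherm
displacement implied by the regional lapse models T(z) = a + b z, namely
(a_n − a_s)/(−b) when the lapses are parallel.

The pipeline estimates each piece separately and only then combines them,
so every stage can be validated on its own.

## Density calibration

Detectability decays with perpendicular distance r from the transect line;
we model it as half-normal, g(r) = exp(−r²/2σ²), truncated at the transect
half-width w.  σ is estimated by maximising the truncated likelihood
(equivalently minimising n·log ESW(σ) + Σr²/2σ², a 1-D bounded
optimisation), and the effective strip width is the closed form
ESW = σ√(π/2)·erf(w/(σ√2)) ≤ w.  Density is mean count per survey (zeros
included) divided by the effectively surveyed area 2·ESW·L, reported per
hectare.

Species with fewer than `min_detections` (default 30) distances at a site
are pooled with the elevationally nearest site of the same region,
repeatedly, until every pool reaches the threshold; a species below the
threshold region-wide is excluded from calibration and logged.  The
default of 30 balances fit stability against data volume at desk scale;
the pooling rule (nearest neighbour by elevation, ties toward the lower
site, smallest pool merged first) is deterministic.

## Thermal gradients

Per region and temperature parameter (MAT, T_max, T_min), temperature is
regressed on elevation by OLS; slopes must be negative (gradients cool
upward) or the fit is rejected.  Parallelism of the two regional lapses is
judged by the elevation × region interaction term of the pooled model at
α = 0.05.  For parallel lapses the displacement uses the mean of the two
fitted slopes; for crossing lapses a single number is ill-defined, so the
displacement is reported at a reference elevation (default: midpoint of
the pooled fitted range) as z_n(T_s(z_ref)) − z_ref, alongside the full
translation map z ↦ (a_s + b_s z − a_n)/b_n.  Standard errors propagate
the two fits' coefficient covariances to first order (delta method),
treating the fits as independent because the regions use disjoint sites;
a test verifies the delta SE against a parametric bootstrap within 15%.

## HOF response classification

Five nested bounded-logistic shapes (flat I, monotonic II, plateau III,
symmetric unimodal IV, skewed V; 1–4 parameters) are fitted to each
species' scaled profile by minimising the binomial deviance
2Σ[y log(y/μ) + (1−y) log((1−y)/(1−μ))] with unit weights — proportions
may be non-integer, so this is a quasi-likelihood deviance.  The gradient
is standardised to [0, 1]; parameters are bounded at ±100 (a logistic rate
of 100 on a unit interval is already a step function).  AIC = deviance +
2k selects the type, ties going to the simpler model.

These deviance surfaces are multimodal.  Each fit therefore runs L-BFGS-B
from 20 seeded random restarts, one heuristic start, and warm starts that
embed the simpler types' optima (I→II via b = 0; II→III/IV via c at the
lower bound, where the second logistic factor is 1; IV→V via d = b and
II→V via d = 0).  The warm starts make the nested-deviance inequality
dev(V) ≤ dev(IV) ≤ dev(II) ≤ dev(I) hold by construction up to optimizer
tolerance, and the whole procedure is deterministic under a fixed seed and
independent of data ordering.

Classification defaults to the temperature axis with both regions pooled
(a species' thermal response is assumed shared between regions), with
per-region elevation profiles available via a flag.

## Optimum estimation and Fieller intervals

The quadratic-logit model is fitted by IRLS (a binomial GLM on the
internally [0,1]-scaled gradient, coefficients and covariance
back-transformed to metres).  Optional per-point binomial trial counts
(`weights`) scale the covariance correctly when the data are true
binomial proportions; profile data scaled to a maximum are fitted
unweighted in the quasi-likelihood sense.

The optimum −b1/(2b2) is a ratio of correlated estimates, so its interval
uses Fieller's construction on the Wald covariance of (b1, b2): the set of
u with (b1 + 2b2u)² ≤ z²·Var(b1 + 2b2u), a quadratic inequality that
yields a finite interval when its leading coefficient and discriminant are
positive and is otherwise flagged unbounded (never silently clipped —
published tables from this kind of analysis contain bounds far outside
the gradient, and the package reports such bounds verbatim).  The default
level is 84% (z = 1.4051): non-overlap of two 84% intervals approximates a
5%-level two-sample comparison, whereas 95% intervals would be
conservative.  A coverage simulation (500 binomial datasets, 40 trials at
each of 30 sites) checks the interval empirically; Wald-based Fieller runs
1–3 points below nominal at this information level, within the ±4-point
band we require.  A profile-likelihood variant was considered and left
out: the Wald form is closed-form, testable, and reproduces the
qualitative behaviour (finite but occasionally wildly asymmetric
intervals) that motivates Fieller here.

Species enter the shift comparison only if unimodal (IV/V), with ≥10
profile points and occupancy at ≥3 sites per region, and with a fitted
optimum ≥100 m inside the region's observed elevational span — optima near
a domain edge are poorly identified by this family of models.

## Shift inference

Per species the shift is north minus south optimum; significance is
non-overlap of the 84% intervals on the side of the shift (south upper vs
north lower for upslope shifts, the mirror for downslope).  Note that a
direction-aware rule can flag a downslope species that a one-sided
"south-upper vs north-lower" reading would miss; summaries therefore report
both the total and the upslope-only significant counts.

Assemblage-level tests are one-sample Wilcoxon signed-rank tests of the
shifts against zero and against each parameter's predicted displacement.
Zeros are dropped; the exact null distribution is used for n ≤ 49 without
ties and the normal approximation with tie and continuity corrections
beyond — the convention of R's `wilcox.test`, which matters because
published p-values from analyses of this size come from the exact branch.
RMSE of the OLS regression of observed on predicted northern optima
(√(mean squared residual)) ranks the temperature parameters as predictors;
predictions are per species, each southern optimum translated along the
parameter's isotherms.

## Synthetic community

The generator emulates the sampling design the analysis was built for:
two subregions, sites assigned round-robin to elevation bands 200 m apart
over 0–1600 m (so 48 sites per region means replicate transects per band,
as in real survey arrays), 9 repeat surveys per site, 150-m transects
truncated at 75 m.  Default lapses: MAT 24.0 − 0.0051z (south) and
24.41 − 0.0051z (north) — a +0.41 °C offset, i.e. a true displacement of
80.39 m; T_max and T_min lapses are non-parallel with offsets −0.38 °C and
+1.77 °C, so only MAT predicts the truth (the crossed-gradient scenario).
T_max/T_min slopes are plausible inventions; only their intercept offsets
and non-parallelism are anchored.

Species have Gaussian thermal responses on the MAT axis (optionally
skewed — a type-V curve —, monotonic, or flat); the default community is
30 Gaussian species with optima evenly spaced over 17.5–22.4 °C (mid-
gradient elevations), breadth 1.2 °C (≈235 m), peak density 8/ha and
detection σ = 30 m — typical desk-scale values for vocal forest birds.
Detected counts are Poisson around peak_density × Gaussian factor ×
2·ESW·L (the count model is a stand-in; the field protocol does not
specify survey noise), and distances follow the truncated half-normal by
inverse-CDF sampling.  One integer seed drives everything; identical
configurations give byte-identical tables.

What the generator does *not* emulate: spatial autocorrelation, seasonal
(wet/dry) effects, observer differences, inter-species interactions, and
detection heterogeneity across sites.  Passing recovery tests therefore
demonstrates the estimators' correctness under the stated noise model, not
robustness to these real-data complications.

## Numerical choices and degenerate inputs

- ESW and the half-normal MLE use the erf closed form; quadrature is the
  test oracle only.
- Gradient axes are scaled to [0, 1] inside HOF and GLM fits; everything
  reported is back-transformed to metres.
- All-zero profiles are flagged "absent"; all-equal proportions are
  degenerate for the GLM and rejected; b2 ≥ 0 routes a species to
  "no interior optimum" rather than producing a spurious extremum.
- AIC ties (rounded at 1e-9) break toward fewer parameters.
- Problem sizes in tests and the acceptance script — 500 Fieller
  replicates, 100 classifier replicates, 30-species communities on
  96 sites — were chosen as the smallest sizes at which the Monte-Carlo
  error is well under each check's tolerance.

## Known limitations

- Only the half-normal detection key is implemented (no hazard-rate or
  series expansions, no covariates, no cluster-size corrections).
- Fieller intervals are Wald-based; at very low information they can be
  mildly anti-conservative.
- The skew of type-V responses is ignored when optima are compared (the
  Gaussian-logit optimum is used for all unimodal species); skewed fits
  tend to put the optimum in nearly the same place, but strongly skewed,
  poorly sampled profiles could bias shifts.
- The non-parallel displacement depends on the chosen reference elevation;
  the full translation curve should be consulted when lapses cross.
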
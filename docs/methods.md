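# Methods

This note records the modelling choices behind `wetlandch4`, their
assumptions, and what the synthetic recovery tests do and do not
demonstrate.

## Transport model

The column model solves $\partial_t C = \partial_z(D\,\partial_z C) + R$
on a uniform cell-centered finite-volume grid (default 20 layers × 2.8 cm,
matching a peeper's window spacing). Interface diffusivities are harmonic
means of the adjacent cells, so fluxes between cells cancel pairwise and
total mass is conserved to round-off. The bottom face carries zero flux;
the surface flux enters layer 1's balance directly as `-flux/Δz` — the
finite-volume form of a Fick's-1st-law flux boundary — so the prescribed
chamber flux is honored exactly in the discrete budget.

Time stepping is backward Euler. It is first-order accurate but
unconditionally stable and monotone (no oscillations or negative
concentrations from the transport operator), which matters because the
inversion exercises it with month-long intervals at dt = 0.1 d and the
initial coarse guess with a single 30-day step. Diffusivity and the
interpolated surface flux are evaluated at each step's end time, consistent
with the implicit discretization. The convergence and oracle tests verify
observed order ≥ 1 and < 1% RMS deviation from a 200×-finer explicit
scheme.

**Units.** Internal canonical units are cm, days, nmol cm⁻³ (numerically
equal to µmol L⁻¹) and nmol cm⁻² d⁻¹. Positive surface flux = emission;
positive R = net production; depths are cm below the soil surface,
positive downward.

**Diffusivity.** $D(T)$ is a quadratic polynomial in temperature (°C)
times a constant tortuosity/porosity factor. The default polynomial is a
free-water CH₄ diffusivity normalized to 1 at 15 °C with magnitude
1.319 cm² d⁻¹; the tortuosity factor (default 1.0, 0.6 in the synthetic
scenarios) absorbs the sediment correction. Whether concentrations are per
porewater or bulk volume, and whether porosity belongs inside D, are left
to the user via this factor and the fixed-profile override — none of the
recovery tests depend on a literature constant, because the same D is used
to simulate and to invert.

## Source-term inversion

The estimator follows a minimize-by-MCMC design: symmetric Gaussian
random-walk proposals on the 20-vector R (all layers perturbed each
iteration; a single-layer mode is available), acceptance probability
$\min(1, \exp((E_\text{old}-E_\text{new})/2\sigma^2))$ with E the sum of
squared concentration misfits over layers with data. This is
Metropolis–Hastings on the Gaussian pseudo-posterior
$\propto e^{-E/2\sigma^2}$; as $\sigma \to 0$ it reduces to stochastic
minimization. Missing peeper windows are masked, not interpolated.

Key numerical device: backward Euler is linear in R, so the end-of-interval
concentration is an affine function $c_\text{end} = v_0 + M R$ of the
interval-constant R. $(v_0, M)$ are accumulated once through the same
tridiagonal solves the stepping solver performs (agreement verified to
1e-12), after which each of the 40,000 proposals costs one 20×20
matrix–vector product. This makes the exact prescribed chain cheap instead
of approximating it.

**Parameters.**

- `n_iterations` = 40,000 and `top_fraction` = 0.10: the estimate is the
  layer-wise mean over the 4,000 lowest-error sampled states, its
  uncertainty the 1 s.d. over the same selection. Ties at the selection
  boundary keep earlier iterations (stable sort). No burn-in is discarded:
  ranking by error makes early high-error states selection-irrelevant.
- `error_scale` σ (nmol cm⁻³, default 5.0): the assumed measurement error
  of a peeper window; it sets posterior width. The default equals the
  synthetic generator's peeper noise; with real data it should be set from
  replicate variability.
- `proposal_scale` (nmol cm⁻³ d⁻¹, default 0.2): chosen by the standard
  random-walk scaling heuristic — target ≈ 23% acceptance; the default
  scenario runs at ≈ 0.26. Retune if acceptance leaves the 0.15–0.5 range.
- Seeds: each interval and ecosite derives its own chain seed from the run
  seed, so results are jointly reproducible and bit-identical per seed.

**A caveat on the uncertainty.** Ranking states by SSE is equivalent to
ranking by posterior Mahalanobis distance, so the kept 10% is the central
core of the posterior and its s.d. *understates* the full posterior spread
(for a 20-layer Gaussian core the shrink factor is ≈ 0.7). Consequently
"truth within 2 s.d." holds at roughly 83% of layers on average — not the
95% a calibrated 2σ interval would give. The reported band should be read
as the spread of well-performing solutions, not a credible interval.

## Oxic horizon

DO profiles are fit with $\mathrm{DO}(z) = a e^{-bz}$ by bounded nonlinear
least squares (a, b > 0; log-linear starting values). The horizon is the
closed-form crossing $\ln(a/\text{threshold})/b$ of the 20 µmol O₂ kg⁻¹
threshold; profiles whose maximum reading is below the threshold are
flagged all-anoxic with horizon 0. A two-parameter offset variant is
deliberately not the default: the plain decay has a clean closed-form
crossing and fits the near-surface-oxic geometry of these soils.

Bounds are the 2.5/97.5 percentiles of the crossing depth over 1,000
parametric-bootstrap draws of (a, b) from the fit covariance. Draws are
multivariate-t with n−2 degrees of freedom rather than normal: the
covariance's residual-variance estimate is itself uncertain at n ≈ 12
points, and normal draws produce a measurably anticonservative envelope
(≈ 89% observed coverage vs ≈ 95% nominal in simulation; the t correction
restores 93–96%). If the covariance is unusable, a fit-residual bootstrap
(refitting on resampled residuals) takes over when the raw data are at
hand. Percentile bands are forced to bracket the point estimate. Horizons
and bounds are interpolated linearly in time between months, held constant
outside the span (with a warning), mirroring how the chamber ratios are
interpolated.

## Budget

Footprint decomposition substitutes the chamber ratios into the tower
mixing equation and solves for $F'_\text{op}$ per day; days with a
non-positive footprint denominator are flagged and excluded. The oxic
share $p$ of an interval's production is the ratio of the column integral
of R above the (daily-interpolated) horizon to the full-column integral,
with the straddled layer apportioned linearly — consistent with
piecewise-constant finite-volume R. A strict variant uses the deep
(97.5th percentile) horizon bound. $p$ is reported unclamped: oxic layers
can be a net sink (negative p) or the anoxic column can consume (p > 1),
both of which occur in late-season mud conditions; a clamped convenience
value accompanies the site-level result. When the column-total production
is below a configurable floor the ratio is undefined and that interval is
flagged rather than reported.

Only open water and mud enter the site-level scaling (the diffusion model
excludes vegetated ecosites because plant aerenchyma transport violates
its diffusion-only assumption); their area fractions must sum to 1.
Uncertainty propagation is Monte Carlo: per-layer R draws from
(mean, s.d.) map to daily p draws, summarized by the 16–84% half-width
(equal to the s.d. for a normal but finite under the heavy tails a
near-zero denominator produces); at the site level the daily p errors of
an ecosite are treated as fully correlated, since they descend from the
same monthly inversions — the conservative choice against the false
averaging-out that independent daily draws would give.

## Synthetic scenarios

`make_scenario` builds a 90-day season with 4 monthly campaigns (days
0/30/60/90), daily tower/footprint series, and interval-constant true R
fields per ecosite:

- `surface_source`: production peaking at ~4 cm (4 nmol cm⁻³ d⁻¹), an
  oxidation band at 10–20 cm (−1.5), weak deep production (0.6 below
  25 cm); true horizons 8–16 cm. The true site-level oxic fraction is
  ≈ 0.71, sitting mid-range of field-reported oxic contributions.
- `deep_source`: production confined near 40 cm with mild near-surface
  oxidation; the true oxic fraction is slightly negative (oxic layers a
  net sink).
- `null`: zero activity, zero fluxes, uniform static profiles; the oxic
  fraction is undefined and flagged.

Peeper "measurements" are forward-model output plus i.i.d. Gaussian noise
(σ = 5 nmol cm⁻³, ~1–10% of typical values), floored at zero; DO, chamber
and tower series get their own Gaussian noise (σ = 8 µmol kg⁻¹ and
1 nmol cm⁻² d⁻¹). Surface emission is set to 85% of column production so
profiles drift realistically without going negative. All truths (R,
horizon, F′, p, f_oxic) are stored or closed-form on the Scenario.

What passing recovery tests show: the estimators correctly invert data
generated by their own assumed physics at field-like magnitudes and noise.
What they do not show: robustness to ebullition, plant transport, peeper
equilibration smoothing, autocorrelated sensor noise, footprint-model
error, or D(T) misspecification — none of which the generator emulates.

## Problem sizes and determinism

Default runs use the full 40,000-iteration chains (six inversions per
season, ~3 s total thanks to the affine propagator), 1,000-draw bootstrap
envelopes, 200-draw p-uncertainty Monte Carlo, and a 200-replicate
coverage simulation in the acceptance script; the whole test suite runs in
well under a minute. Every stochastic component draws from
`numpy.random.default_rng` seeded from a single run seed (per-stage
offsets keep streams independent), so identical seeds give bit-identical
outputs, recorded alongside a config hash in each run's manifest.
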
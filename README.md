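# wetlandch4

**Where in the soil column is a wetland's methane made — and how much of it
comes from oxic layers?**

Methanogenesis is classically an anaerobic process, yet bulk-oxic soils and
surface waters repeatedly show net methane production (the "methane
paradox"). Settling whether oxic layers matter for a wetland's emission
budget requires depth-resolved *rates*, which no instrument measures
directly. `wetlandch4` infers them from routine field measurements:

- monthly **peeper** (porewater dialysis) CH₄ concentration profiles
  (20 windows × 2.8 cm over the top 56 cm),
- **chamber** surface fluxes per ecosite (open water, *Typha*, *Nelumbo*,
  mud flat),
- **dissolved-oxygen** depth profiles,
- soil **temperature** profiles, and
- daily **eddy-covariance** tower fluxes with per-ecosite footprint
  fractions.

## The model

Porewater methane in a 1D soil column obeys a diffusion equation with a
net source/sink term

$$\frac{\partial C}{\partial t} = \frac{\partial}{\partial z}\!\left(D(t,z)\,\frac{\partial C}{\partial z}\right) + R(z),$$

where $C$ is porewater CH₄ (nmol cm⁻³), $D$ a temperature-dependent
diffusivity, and $R$ the net microbial production (+) or oxidation (−)
rate. The column is closed at the bottom (no-flux Neumann) and loses the
chamber-measured surface flux at the top (Fick's 1st law at the face).
Time stepping is implicit backward Euler (dt = 0.1 d) on a cell-centered
finite-volume grid, which conserves mass exactly.

For each month-to-month transition, $R(z)$ (held constant over the
interval) is estimated by Metropolis–Hastings: starting from a one-step
algebraic guess, 40,000 random-walk proposals are scored by the sum of
squared differences between the modeled and measured next-month profile,
targeting $\pi(R) \propto \exp(-\mathrm{SSE}/2\sigma^2)$. The reported
activity is the layer-wise mean of the 4,000 best-performing states (the
lowest-error 10%), with 1 s.d. over that selection as uncertainty.
Because the discretization is linear in $R$, the month-long forward map is
precomputed once as an exact affine operator, so a full chain runs in
under a second.

The oxic/anoxic horizon comes from fitting $\mathrm{DO}(z) = a e^{-bz}$ to
each month's oxygen profile; the horizon is where the curve crosses
20 µmol O₂ kg⁻¹, with 2.5/97.5-percentile bounds from a parametric
bootstrap of the fit. Tower fluxes are decomposed with daily footprint
fractions $e$ and chamber-derived ratios $m_i$,

$$F_\mathrm{tower} = F'_\mathrm{op} e_\mathrm{op} + F'_\mathrm{ty} e_\mathrm{ty} + F'_\mathrm{ne} e_\mathrm{ne} + F'_\mathrm{mu} e_\mathrm{mu},\qquad m_1 = F_\mathrm{ty}/F_\mathrm{op},\ \ldots$$

and the seasonal site-level oxic fraction is the flux-weighted average of
each modeled ecosite's share $p$ of column-integrated production above its
horizon:

$$f_\mathrm{oxic} = \frac{\sum_t\left(f_\mathrm{op} F'_\mathrm{op} p_\mathrm{op} + f_\mathrm{mu} F'_\mathrm{mu} p_\mathrm{mu}\right)}{\sum_t\left(f_\mathrm{op} F'_\mathrm{op} + f_\mathrm{mu} F'_\mathrm{mu}\right)}.$$

## Worked example

Generate a synthetic growing season with known ground truth and run the
full pipeline:

```bash
wetlandch4 run-all --preset surface_source --seed 0 --outdir demo_out
```

or equivalently, in Python:

```python
import wetlandch4 as w
from wetlandch4.pipeline import run_all

scenario = w.make_scenario("surface_source", seed=0)
# ... write/read the six CSVs (see wetlandch4.simulate_measurements) ...
report = run_all(tables, w.InversionConfig(rng_seed=0),
                 scenario.do_threshold, scenario.areas,
                 grid=scenario.grid, dmodel=scenario.dmodel, seed=0)
print(report.inversions["open"][0].summary())
```

```
Source-term inversion - open [0, 30] d
======================================
states selected: 4000   acceptance rate: 0.259   best SSE: 153
depth (cm)       mean R       s.d.   (nmol cm^-3 d^-1)
       1.4       1.7018     0.4681
       4.2       5.9494     0.8054
       7.0       0.6229     0.9619
       9.8       0.3061     1.0315
      12.6      -0.6130     0.9805
       ...
column-integrated net production: 33.786 nmol cm^-2 d^-1
```

The June–July open-water column produces strongly in the top ~7 cm
(well above the ~15 cm oxic horizon), oxidizes mildly mid-column, and the
whole column is a net source of 33.8 nmol CH₄ cm⁻² d⁻¹. Scaling all
intervals and both modeled ecosites to the site level:

```python
print(report.budget.summary())
```

```
Site-level oxic methane production fraction
===========================================
f_oxic            : 68.4 %
f_oxic (clamped)  : 68.4 %
s.d. (propagated) : 18.8 pp
window            : day 0 to 90 (91 days)
```

i.e. an estimated 68% of the methane this synthetic wetland emits over the
season was produced *above* the oxic horizon — the generating truth for
this scenario is 71.3%, well within the propagated uncertainty.

`run-all` writes `r_profiles.csv`, `horizon.csv`, `flux_strengths.csv`,
`budget.json`, depth×time activity heatmaps and the seasonal oxic-fraction
plot, plus a `manifest.json` recording the config hash, seed and library
versions.

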
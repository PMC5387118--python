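# Methods

This document records the modelling assumptions, default parameters, the
design of the synthetic data generators, and the numerical choices made in
`cellspray`. Everything quantitative stated here is computed by the package
and exercised by the test suite; no empirical claims are made beyond what the
code demonstrates on synthetic data.

## 1. Impact survival model (`cellspray.impact`)

### Physical picture

A cell suspended in a droplet impacting a substrate is treated as a small
liquid droplet itself: it spreads with the carrier fluid, flattens into an
oblate spheroid, and its membrane area grows. Survival is governed by the
relative membrane-area expansion γ = A_max / (π D_c²); moderate expansion is
tolerated, large expansion ruptures the membrane.

### Assumptions

- The cell behaves as a Newtonian droplet with effective viscosity μ_c,
  density ρ_c and surface tension σ_c; elastic and viscoelastic membrane
  mechanics are absorbed into these effective properties.
- Spreading follows the capillary-regime scaling D_max/D = We^{1/4}, valid
  for We ≤ Re^{4/5}. Violations of this bound are counted and a warning is
  issued once per run, but evaluation proceeds: impacting cells are viscous
  enough that strict validity is routinely exceeded, and the scaling remains
  the best available closed form there.
- Below We = 5 the spreading ratio is held at the constant plateau 5^{1/4}:
  surface tension dominates and deformation becomes velocity-independent.
  The two branches join continuously (the plateau is the threshold value).
- The flattened cell is a volume-conserving oblate spheroid: equatorial
  diameter D_max, polar height h = D_c³ / D_max² from (π/6) D_max² h =
  (π/6) D_c³.
- Deformation is measured by the Taylor-type parameter
  M₀ = (D_max − h)/(D_max + h) = (r³ − 1)/(r³ + 1), r = D_max/D_c,
  which is 0 for a sphere and tends to 1 for a plane.
- Compression does not damage the membrane: γ is floored at 1, so slow
  impacts saturate at η = 1 rather than overshooting.

### Chain of operations

For droplet (D₀, V₀) on a substrate of stiffness S:

1. **Effective impact.** D_eff = (2 − S) D₀, V_eff = (1 + S) V₀ / 2.
   S = 0 is a deep liquid pool (the impact is softened: the drop behaves as
   if twice as large and half as fast on a hard wall); S = 1 is a rigid
   substrate (identity). S = min(1, C₁ C_g) for gelatin-coated substrates
   with mass fraction C_g, so S saturates at C_g = 1/C₁ = 0.2.
2. **Dimensionless numbers** for the cell and the droplet at (D_eff, V_eff).
3. **Bare spreading** of both, via the We^{1/4} law with the low-We plateau.
4. **Bare deformation** M₀ of the cell from its bare spreading ratio.
5. **Cushioning.** Inside a droplet the cell is decelerated over the
   droplet's deformation length rather than stopped abruptly, so it deforms
   less: M = M₀^k with

       k = 1 + C₀ (1 − D_c / D_eff) / (1 + μ₀ / μ_c),   C₀ = 5.

   Since 0 ≤ M₀ < 1, any k > 1 reduces deformation. The exponent grows with
   droplet size (more cushioning fluid) and shrinks with ink viscosity
   (a viscous ink couples the cell more rigidly to the impact). A bare cell
   (D_eff = D_c) gives k = 1 exactly, recovering M = M₀. This form was
   chosen over additive/divisor alternatives because it is the only simple
   candidate that (a) keeps M in [0, 1), (b) reduces to the bare case
   exactly, (c) makes viability increase with droplet size and decrease
   with ink viscosity, and (d) still allows lethal impacts at realistic
   velocities (tens of m/s).
6. **Back to geometry.** The cushioned M is inverted to a spreading diameter
   r = ((1+M)/(1−M))^{1/3}, which is then clamped from above by both the
   bare-cell spreading diameter and the droplet's own maximal extent — the
   cell cannot spread further than it would unprotected, nor further than
   the fluid that carries it. (`ModelConstants(literal_clamp=True)` switches
   to a two-argument clamp without the droplet bound, for sensitivity
   studies.)
7. **Membrane expansion and survival.** The oblate area
   A = 2πa² [1 + ((1−e²)/e) artanh e], a = D_max/2, e² = 1 − (h/D_max)²,
   gives γ = A/(π D_c²), and

       η(γ) = clip((γ_cr + Δγ − max(γ, 1)) / (2 Δγ), 0, 1)

   with γ_cr = 1.5, Δγ = 0.5: full survival up to γ = 1, one half at the
   critical expansion 1.5, certain death beyond γ = 2.

### Default parameters

| symbol | meaning | default |
|---|---|---|
| D_c | cell diameter | 13 µm |
| μ_c | cell effective viscosity | 12 mPa·s |
| ρ_c | cell density | 1015 kg/m³ |
| σ_c | cell surface tension | 0.072 N/m |
| μ₀, ρ₀, σ₀ | bio-ink viscosity, density, surface tension | 1 mPa·s, 1000 kg/m³, 0.072 N/m |
| C₀ | cushioning constant | 5 |
| C₁ | substrate stiffness constant | 5 |
| We_low | low-Weber plateau threshold | 5 |
| γ_cr, Δγ | critical expansion, ramp half-width | 1.5, 0.5 |

### Numerical choices

- The whole chain is vectorised over numpy arrays; `predict_single` and the
  array path share one implementation, tested to agree elementwise.
- The oblate-area formula uses a series expansion of artanh(e)/e for
  e < 10⁻⁷ so the sphere limit is smooth; it is verified against direct
  quadrature of the surface-of-revolution integral to ≤ 10⁻⁹ relative.
- A bare cell (D₀ = D_c) at V = 0 retains the low-We plateau deformation and
  lands at η ≈ 0.69, not 1. This is a genuine feature of the plateau (a
  small constant deformation independent of velocity), not an artifact; any
  droplet even slightly larger than the cell cushions it back to η ≈ 1 at
  low speed.
- Droplets smaller than the cell are outside the model. The ensemble layer
  either excludes them (default, reported as `excluded_fraction`) or floors
  them to a bare cell (`small_droplet_policy="bare_cell"`).

## 2. Ensemble layer (`cellspray.ensemble`)

Expected viability of a spray is the weight-averaged per-droplet survival
over a droplet spectrum {(D₀ᵢ, V₀ᵢ, wᵢ)}. The layer also provides viability
maps over a (diameter, velocity) grid, interpolated 50%-viability contours,
parameter sweeps (pressure, distance, viscosity, gelatin fraction) returned
as data frames, and a plain-text droplet-table format (CSV with
`diameter_um`, `velocity_m_s`, optional `weight`, and `# key: value`
metadata headers; malformed files report the offending line number).

## 3. Synthetic spray generator (`cellspray.synth`)

When no measured spectrum is available, spectra are drawn from a seeded
parametric model chosen for qualitative realism of pressure atomizers:

- **Sizes**: lognormal with σ_log = 0.45, median 30 µm at the reference
  pressure 0.4·10⁵ Pa, scaling as (P_ref/P)^{1/2} (higher pressure atomizes
  finer); clipped to [1, 100] µm, the detectable range of the imaging model.
- **Velocities**: mean 32 (P/10⁵ Pa)^{0.75} m/s, decaying as exp(−h/0.1 m)
  with nozzle distance h (air drag), with a mild positive size–velocity
  correlation (D/D_med)^{0.2} (small droplets decelerate fastest in flight)
  and 25% multiplicative Gaussian scatter, floored at 0.
- Presets cover pressures (0.2–1.0)·10⁵ Pa, distances 30–150 mm, and
  gelatin fractions 0–0.20.

These produce the expected qualitative trends — mean viability falls with
pressure and rises with flight distance — which the test suite verifies over
five seeds at n = 10⁴. The generator makes no claim to quantitative fidelity
for any particular nozzle.

## 4. Synthetic shadowgraphy (`cellspray.imaging`)

Double-pulse back-lit imaging is modelled on a 0.67 × 0.89 mm field of view
at 1 µm/pixel, pulse separation 1 µs, focal slab thickness δ_F = 0.1 mm,
background level 0.85, shadow contrast 0.9, additive Gaussian noise 0.02.
Droplets are stamped as anti-aliased dark discs and blurred with a Gaussian
of σ = 0.8 · (|z|/δ_F) · r_px to model defocus.

Detection: the image is smoothed (σ = 1 px), thresholded at 0.55 × the
background, and labelled. Candidate regions are rejected at the image border,
must reach ≥ 75% of the nominal shadow depth at their core (this "fullness"
gate is what rejects defocused droplets, and is size-uniform because the
blur scales with radius), and must pass a sharpness score (peak gradient ×
radius / shadow depth ≥ 0.7). Sizing uses the half-level area with a
+0.5 σ² correction for the smoothing-induced erosion, calibrated so median
size errors are below 1% in focus. Velocimetry matches the two frames by
minimum-cost assignment (displacement ≤ 60 µm, diameter mismatch ≤ 25%,
upward motion ≤ 3 µm) and reads V₀ from the centroid displacement over the
pulse separation.

The acceptance gates (fullness 0.75, sharpness 0.7) were calibrated once
against the blur model on scan grids of size and depth, before the recovery
studies were run, and then frozen. On 400 synthetic frame pairs the pipeline
recovers the ground-truth mean diameter and velocity within 10%; isolated
in-focus droplets are sized and tracked within 5%. The sharpness criterion
is a synthetic-data-calibrated stand-in for whatever focus criterion a real
rig would use.

## 5. Limitations

- The survival law and the cushioning exponent are phenomenological; the
  constants (C₀, C₁, γ_cr, Δγ) are fixed defaults, not fitted to data by
  this package.
- The spreading law is used outside its strict capillary-regime validity for
  viscous cells; this is flagged (once) but not prevented.
- The generator and imaging models are synthetic stand-ins: they support
  end-to-end testing with known ground truth, not instrument simulation.
- Oblique impacts, droplet–droplet interactions, evaporation in flight, and
  cell–cell crowding inside droplets are not modelled.
- Problem sizes used in the test suite (10⁴-droplet ensembles, 400 image
  pairs, five seeds) are this package's own choices, sized to give stable
  statistics at desk-scale runtimes.
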
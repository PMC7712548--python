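# Methods

`crownpore` analyzes cation permeation through an atomically thin,
crown-ether-functionalized pore as a rate process fed by bulk diffusion and
drift.  This note records the models, the numerical choices, and what the
synthetic data do and do not emulate.

## The site model

The pore is described by three effective sites along the transport axis: a
staging site on the association side (occupancy `P1`), the internal binding
site in the pore (`P2`), and an exit-side site (`P3`).  Transitions at the
internal site are one-way — at the working voltages (0.1–1 V) back-steps up
the potential gradient are rare — giving

```
dP1/dt = kb (1-P1) - kb' P1 - ka P1 (1-P2)
dP2/dt = ka P1 (1-P2) - kd P2 (1-P3)
dP3/dt = kd P2 (1-P3) - kexit_out P3 + kexit_in (1-P3)
```

with `kb` (`kb'`) the in (out) rate from bulk on the association side and a
generic fast exchange on the dissociation side.  Backward rates at the
internal site are accepted as optional parameters and default to zero.
Eliminating the boundary sites at steady state gives the closed-form
particle current

```
I/q = [ 1/kb + 1/(ktilde_a (1-P2)) ]^{-1},     ktilde_a = ka P1eq,
```

where `P1eq = kb/(kb+kb')` is the staging occupancy decoupled from the
pore.  The `(1-P2)` factor is the many-body blocking effect: a localized
ion shuts the pore until it dissociates.  Because the model takes the
*measured* `P2` as input, everything on the dissociation side drops out of
the fit.

The exit-site equation as written in one-way site chains of this type is
sign-ambiguous for the bulk exchange terms; we use the physically
consistent form above (filling by `kd P2` and `kexit_in`, draining by
`kexit_out`), under which the exit site is nearly empty whenever exit
exchange is fast — and the closed form above is independent of that choice.

**Mean-field character.**  These equations close pair products as
`<n1 (1-n2)> = P1 (1-P2)`.  For the single-channel `{0,1}^3` Markov chain
this is an approximation: `kinetics.stationary_distribution` solves the
8-state master equation exactly, and the factorized current deviates from
it by up to ~9% when a boundary site exchanges with its reservoir more
slowly than with the pore (e.g. `kb' = 0`, `ka >> kb`).  With reservoir
exchange 10–30× faster than pore transfer the error is below 1%.  The
stochastic consistency tests therefore sample that validity domain; the
exact solver is available for any rate set, and `gillespie_chain` (an exact
event-driven simulation of the same chain) agrees with it to Monte-Carlo
precision everywhere.

## Rate-constant estimators

All are closed forms in the module `rates`, returning audit records:

- diffusive capture `kb0 = Θ D c ap` with `Θ = 4` (absorbing disc) by
  default; `2π` and `4π` as named alternatives.  Defaults give ≈0.5 ns⁻¹
  at 1 mol/L.
- drift feeding `κb = π ap² / (q γp hp)` with `γp = 2 γb` by default (only
  the cation conducts in the pore); equivalently the access drop
  `Vb = π ap γb V/(4 γp hp)` delivered through `Ra = γb/(4 ap)`.
- dissociation `kd = μ e^{-Ud} (V/hp) / Δp` — drift velocity across the
  internal site with an Arrhenius factor; ≈76 ns⁻¹ (Δp = hp = 1 nm) to
  ≈190 ns⁻¹ (Δp = 0.4 nm) at 1 V.
- Hille-type resistance `R = γ (1/2ap + hp/π ap²)`, continuum conductance
  `Gp = q cp μp Ap/hp` and permeability `Pp = Dp/hp`.

The diffusion-limited regime requires `kb ≪ ktilde_a ≪ kd` and a bulk drop
below thermal, `qVb ≪ kBT`, bounding the voltage to
`Θ kBT c ap hp²/q ≪ qV ≪ Θ kBT hp/(π ap q)` — about 6 mV to 300 mV for the
default geometry.  "Much less than" is a configurable factor (default 3×).
`conductance_linearity` classifies G(V) per strain by the sign of a
weighted-least-squares slope; the slope uncertainty uses the propagated
measurement error (the per-point SEs are replica-derived and hence known),
not the line's residuals, because four-point voltage series are curved and
residual-based intervals would label every series ohmic.

## Landscape analysis

Free-energy profiles `F(z)` (kBT, z in nm) are modelled as geometric
dehydration plus screened Coulomb terms: the hydration-shell exclusion
fraction is the spherical-zone formula for a thin shell against a slab
(half-thickness = carbon van der Waals radius) pierced by the geometric
pore opening, verified against a rejection-sampling volume oracle; the
Coulomb term uses a distance-dependent permittivity interpolating linearly
from ≈4 at contact to the bulk value beyond the second hydration shell
(only the endpoints are physically constrained; the switching function is
configurable).  Hydration-shell energies default to order-of-magnitude
values (6 and 2 kBT at 0.33 and 0.55 nm) and should be overridden when
known; they scale the dehydration term only.

Applied bias is a linear ramp over |z| < 0.5 nm (configurable), i.e. about
10 kBT/nm of ideal field at 0.25 V.  Discrete-gradient analysis pairs each
local minimum with the next maximum toward +z after a 3-point moving
average, discarding extrema below 0.5 kBT prominence (sampled profiles
carry that order of noise); features whose gradient survives the ideal
field unchanged are labelled *irrelevant* — they are not rate limiting, so
no self-consistent potential drop develops across them.  Entropic
penalties for cylinder confinement, crossing-region squeeze and well
localization are the corresponding log state-ratio formulas.

## Brownian walkers

`simulate_walkers` integrates overdamped Langevin dynamics
(Euler–Maruyama) on the profile with absorbing planes, enforcing
`sqrt(2 D dt)` ≤ half the grid spacing.  The default force is the
piecewise-constant gradient of the linear interpolant of `F`; this makes
the potential the walker integrates *identical* to the profile the
splitting-probability and double-integral MFPT oracles integrate, leaving
only the O(√dt) absorbing-boundary bias (≈2% at the default step).
Central-difference and cubic-spline forces are available but soften sharp
barriers by a few percent relative to the quadrature oracles.  The one-way
incoming rate `Jin(z)` is measured from a Poisson-fed, source-reflecting
run as the rate of first forward plane crossings inside the observation
window; it is non-increasing toward the pore and its plateau equals the
net translocation rate.  Direct walker validation is performed at barriers
of a few kBT; a 10 kBT barrier (escape time ~ e^10 × the diffusion time)
is checked through the quadrature oracle's Arrhenius scaling instead.

## Fitting

`fit_bulk_model` fits the closed-form current with `kb(V) = kb0 + κb V`
(drift-fed), `kb0 e^{βV}` (activated; β in kBT per volt) or `κb V`
(drift-only), using the measured `P2` per row.  Rates are fitted in log
space (positivity); parameter SEs come from the covariance scaled by the
reduced chi-square.  Two weighting choices:

- *moderated* (default): per-point variance estimates from ~5 replicas are
  ~50% uncertain, and raw inverse-variance weighting is known to
  under-cover.  Variances are pooled through the physically expected laws
  — currents are event counts (var ∝ mean), occupancies are time-averaged
  binary signals (var ∝ P2(1−P2)) — with one fitted scale each.
- *pointwise*: the raw per-point SEs.

In both, the occupancy's uncertainty is propagated into the weights
(effective-variance method) because it enters the model as a regressor.
With moderated weights, 2-SE coverage of the generator truth is 94–97% per
parameter over 200 synthetic campaigns.

`extract_kd` reads `kd = (I/q)/P2` per point (plateau balance), fits
`A e^{c s}` per voltage and the combined law `B V e^{b qV/kBT + c s}` by
weighted log-linear least squares with errors propagated from both
observables.  `compare_models` ranks fits of identical data by adjusted R²
plus the weighted residual scale at the lowest voltage, where the feed
laws differ most.

## Synthetic data

The generator stands in for molecular-dynamics observables: per design
point it computes the model current and occupancy from the site chain and
then simulates `n_runs = 5` replicas of `run_length = 100 ns` (a 500 ns
campaign, the scale of the production runs the analysis is designed for)
of an event-driven two-state pore process — occupied→empty at `I/P2`
(each emptying is one counted translocation), empty→occupied at
`I/(1−P2)` — whose stationary occupancy and event rate equal the model
values exactly.  Currents are therefore genuine event counts with
correlated current/occupancy noise and `SE = sqrt(var/n_runs)`.  The exact
3-site chain is *not* used as the noise engine because its stationary
averages differ from the factorized model the fit assumes (see above);
using it would inject a model-mismatch bias larger than the reported SEs.
Gaussian and noise-free modes are provided for fast or exact pipelines.

Default truth: `kb0 = 0.5 ns⁻¹`, `κb = 2.2 (V ns)⁻¹`, `ktilde_a = 12 ns⁻¹`
and the plateau dissociation law `kd = 3.2 V e^{0.043 qV/kBT + 0.22 s}` ns⁻¹
multiplied by a residual exit-well factor `e^{-Uw}` with
`Uw = 4 kBT · max(0, 1−s/4) · max(0, 1−V/0.6)`.  The well term restores the
blocked-pore corner the plateau law cannot represent (occupancy ≈ 1 and an
effective open-pore rate of ~0.012 ns⁻¹ at 0 % strain and 0.1 V, ~0.25 ns⁻¹
at 0.25 V) and vanishes on the plateau; `well_depth = 0` gives the bare
plateau law.

Synthetic profiles are sums of Gaussians: a central feature whose
amplitude moves from an electrostatically stabilized well (strong rim
charge) toward a dehydration barrier as strain grows, satellite barriers
near ±0.35 nm, seeded per-point noise at the quoted SE, and optional
voltage tilt.  What the generator does **not** emulate: explicit water and
finite-size electrostatics, strain-dependent association barriers (the
weakly charged pore regime), chloride dynamics, concentration dependence,
and 2-D density maps.  Passing tests therefore demonstrate correctness of
the analysis chain under the model's own assumptions, not fidelity of
those assumptions to any particular experiment.

## Numerical conventions

Internal units: nm, ns, kBT, volts, ions/nm³; rates ns⁻¹ (reported also as
ions/s).  Default temperature 298 K (kBT/e ≈ 25.7 mV).  Default geometry:
nominal radius 0.29 nm + 7.5 pm per % strain, oxygen vdW 0.152 nm,
effective radius 0.1 nm, effective length 1 nm, internal site 0.4 nm,
staging/crossing spreads 0.1/0.02 nm, sampling-cylinder radius 0.28 nm.
Steady states solve a bracketed scalar root (residual < 1e-10 of the rate
scale); transients use LSODA at rtol 1e-10; the event-driven simulator is
seeded and bit-reproducible; every stochastic entry point takes an explicit
seed.  Problem sizes in the test suite (walker counts of order 10³, windows
of tens of ns, 20-campaign recovery studies) were chosen as the smallest
that leave the Monte-Carlo error clearly below each check's tolerance.

## Known limitations

- The one-way chain cannot describe the approach to equilibrium as V → 0.
- The factorized equations are quantitative only in the fast-exchange
  domain; use `stationary_distribution` outside it.
- Estimators treat the pore as a homogeneous continuum with effective
  radius/length; no self-consistent Poisson–Nernst–Planck solution.
- The lower edge of the diffusion-limited voltage window is a prediction;
  within this package nothing tests it below ~0.1 V.
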
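# crownpore

Kinetic and energetic analysis of ion transport through atomically thin,
crown-ether-functionalized pores — for modellers of sub-nanometre channels
(graphene nanopores, biomimetic pores, narrow biological channels) who want
to go from free-energy profiles and current/occupancy measurements to rate
constants, transport regimes and fitted feed/dissociation laws.

A pore in a 2-D membrane that holds at most one cation is modelled as a
three-site one-way chain — staging site, internal binding site (occupancy
P₂), exit site — fed from bulk at `kb` and drained at `kd`.  Eliminating
the boundary sites gives the closed-form particle current

```
I/q = [ 1/kb + 1/(k̃a (1−P₂)) ]⁻¹ ,    kb(V) = kb0 + κb V ,
```

where `k̃a` is the effective association rate and `(1−P₂)` carries the
many-body blocking of an occupied pore.  Around this core the package
provides:

- **`core`** — conditions, ion species (Einstein-linked mobility and
  diffusion), pore geometry with linear strain response, rim charge sets,
  YAML/JSON configuration.
- **`landscape`** — 1-D free-energy profiles: dehydration + screened-Coulomb
  model, voltage tilting, discrete min→max gradient analysis with
  relevance labels, entropic confinement penalties.
- **`walker`** — overdamped Brownian dynamics on a profile, splitting
  probability and mean-first-passage oracles, one-way incoming-rate curves
  Jin(z).
- **`kinetics`** — single-site and three-site models: closed forms,
  steady-state and transient solvers, an exact 8-state master-equation
  solver, and a seeded Gillespie simulator.
- **`rates`** — analytic estimators: diffusive capture Θ·D·c·a_p, drift
  feeding π·a_p²/(qγ_p·h_p), field-driven dissociation μ·E_p/Δ_p,
  pore+access resistance, continuum conductance and permeability.
- **`regimes`** — diffusion-limited window Θ·kBT·c·a_p·h_p²/q ≪ qV ≪
  Θ·kBT·h_p/(π·a_p), chain-inequality margins, drift-vs-diffusion balance,
  conductance linearity.
- **`fitting`** — weighted fits of the chain current (drift-fed, activated
  and drift-only feed laws), dissociation-rate extraction kd·P₂ = I/q with
  exponential-in-strain and combined laws, model comparison.
- **`synthetic`** — generator for measurement tables with event-counting
  noise and for parameterized free-energy profiles.

## Worked example

Analytic estimates for the default pore (K⁺ in 1 mol/L KCl, effective
radius 0.1 nm, effective length 1 nm), via the CLI:

```
$ crownpore estimates
capture_rate                             0.4714 ns^-1
drift_feed_coefficient                    1.381 ions/(V*ns)
drift_feed_coefficient                    2.762 ions/(V*ns)
dissociation_rate                          76.2 ns^-1
dissociation_rate                         190.5 ns^-1
pore_plus_access_resistance           2.615e+09 ohm
access_resistance_one_sided           1.775e+08 ohm
continuum_pore_conductance             2.31e-10 S
continuum_permeability                    1.957 nm/ns
bulk_voltage_drop_kBT                     1.529 kBT
diffusion_window                   (6.19 mV, 327 mV)
```

Reading: ions diffuse to the pore mouth at ≈0.5 ns⁻¹; drift adds
≈1.4×10⁹ ions/(V·s) (2.8×10⁹ with the full-salt resistivity); a
barrierless ion is driven out at 76–190 ns⁻¹ at 1 V; the one-sided access
drop is ≈1.5 kBT at 1 V; diffusion-limited currents are possible between
roughly 6 mV and 300 mV.

End-to-end, in Python — generate a synthetic measurement campaign (24
(strain, voltage) points, five 100 ns counting replicas each) and refit
the feed parameters:

```python
from crownpore import GeneratorSpec, generate_measurements, fit_bulk_model

table = generate_measurements(GeneratorSpec(), seed=1)
fit = fit_bulk_model(table, "drift_fed")
print(fit.params, fit.r_squared_adj)
```

prints (seed 1)

```
kb0      = 0.505 ± 0.016 ns⁻¹      (truth 0.5)
kappa_b  = 2.196 ± 0.060 (V ns)⁻¹  (truth 2.2)
ktilde_a = 12.31 ± 0.98  ns⁻¹      (truth 12)
adjusted R² = 0.998
```

i.e. the three feed parameters are recovered within one standard error and
the fit explains essentially all of the variance, as expected when the
blocked-pore corner (P₂ ≈ 1 at 0 % strain, 0.1 V) and the plateau are both
sampled.  `crownpore report --seed 1 --out report/` runs the same chain
from the shell and adds regime labels and the estimate table.

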
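# otofmr

Otolith stable-isotope reconstruction of **experienced temperature** and
**field metabolic rate (FMR)** for temperate wrasse, with ontogenetic and
spatial models — built for ecophysiologists and fisheries scientists who
want retrospective, individual-level thermal and energetic data from
otolith edge chemistry.

## The science

Otoliths precipitate aragonite in near isotopic equilibrium with ambient
water, and blood bicarbonate is a mixture of seawater DIC and respired
dietary carbon with widely separated δ¹³C end-members. Two per-fish
proxies follow:

- **Thermometry** — T(°C) = (a − (δ¹⁸O_oto − δ¹⁸O_sw)) / b with the
  saltwater-fish fractionation coefficients a = 3.465 ‰ and
  b = 0.209 ‰ °C⁻¹ (slope as a positive magnitude: warmer water, lighter
  otolith).
- **Respiration proxy** —
  C_resp = (δ¹³C_oto − δ¹³C_DIC) / (δ¹³C_diet − δ¹³C_DIC) + ε, converted
  to mass-specific oxygen consumption by the linear calibration
  FMR = (C_resp − 0.041) / 0.000971 (mgO₂ kg⁻¹ hr⁻¹).

Three models sit on top of the derived table:

1. **Ontogenetic thermal niche** (per location):
   OLS of T on log₁₀(mass) × species, with Tukey-adjusted pairwise
   species contrasts at a common mass and an experienced-temperature
   overlap summary across the conservation-reference-size (CRS) band.
2. **Anchored metabolic scaling** (per species):
   FMR = B₀ (M/M_a)^α exp[E(1/kT − 1/kT_a)], with B₀ fixed at the
   observed FMR of the median-mass individual (M_a, T_a); (α, E) by
   nonlinear least squares, compared against strict metabolic theory
   (α = −0.25, E = −0.65 eV on the 1/kT slope scale).
3. **Standardized location model** (large individuals only):
   ln FMR ~ z(ln M) + z(1/kT) + Species + Location, additive vs
   species×location structures ranked by AICc (likelihood backend) or
   DIC (MCMC backend), with coefficients back-transformed to natural
   units (exponents, eV, mgO₂ kg⁻¹ hr⁻¹).

A seeded synthetic-cohort generator inverts the proxy equations exactly,
so the whole pipeline is verifiable by parameter recovery without any
field data.

## Worked example

```python
import otofmr as o

species, locations = o.default_params()
cfg = o.simulation_config(locations, species)
samples, _ = o.simulate_cohort(species, locations, seed=1, n_per_cell=60)
derived, report = o.derive_all(samples, cfg)

fit = o.MetabolicScalingModel(derived, species="L. bergylta", config=cfg).fit()
print(fit.summary())

res = o.FMRLocationModel(derived, variant="additive", config=cfg).fit()
print(res.summary())
```

prints

```
Metabolic scaling fit: L. bergylta (n = 120)
  anchor: B0 = 160.1 mgO2/kg/hr at 142.7 g, 16.28 degC
  alpha = -0.471 +/- 0.138  (theory -0.25; exceeds: False)
  E     = -2.247 +/- 0.247 eV  (theory -0.65; exceeds: True)
  SSR = 84703.08; near-singular: False

Standardized FMR model (additive, backend=mle)
  n = 118 large individuals; AICc = 83.10; residual sd (ln FMR) = 0.328
  reference: species 'C. exoletus', location 'Dorset'
  term                          mean     2.5%    97.5%  rescaled
  Intercept                      1.929    1.337    2.521      6.88
  z_ln_mass                     -0.678   -0.985   -0.370     -0.62
  z_inv_temp                    -0.435   -0.583   -0.288     -1.45
  ...
  location[Skye]                -0.142   -0.427    0.144      0.87
```

Read: for this simulated ballan-wrasse cohort the allometric exponent is
−0.47 ± 0.14 (steeper than the canonical −0.25 but not significantly so
here) and thermal sensitivity −2.2 ± 0.2 eV (significantly steeper than
−0.65 eV — energy use falls with the ontogenetic shift into cooler water
faster than thermodynamics alone predicts). In the standardized model the
rescaled column gives the common mass exponent (−0.62), the common
thermal sensitivity (−1.45 eV) and each species' FMR level in
mgO₂ kg⁻¹ hr⁻¹; the Skye coefficient's interval spans zero — no
detectable location effect after accounting for mass, temperature and
species, matching the generative truth of this scenario.

The same stages are scriptable:

```sh
otofmr all --seed 1 --out runs/full           # simulate + derive + all fits
otofmr derive --input samples.csv --config config.yaml --out derived.csv
otofmr config-template --out config.yaml      # documented calibration defaults
```

To analyse real data, supply a CSV with columns `sample_id, species,
location, total_length_cm, body_mass_g, d18O_oto, d13C_oto, d13C_diet`
(missing cells empty) plus a config giving per-location seawater δ¹⁸O and
per-species length–weight coefficients, and run `otofmr all --input ...`.
This is also the route for the authors' deposited field dataset; it is an
offline workflow, not part of the test suite.

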
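# Methods notes

## Proxy equations and their orientation

Experienced temperature comes from the linear aragonite–water oxygen
fractionation relationship for saltwater fish,
T = (a − (δ¹⁸O_oto − δ¹⁸O_sw)) / b, with a = 3.465 ‰ and b stored as the
positive magnitude 0.209 ‰ °C⁻¹. The relationship is implemented in its
physically oriented form — otolith δ¹⁸O *decreases* as temperature
increases — which is the orientation required for warm-site cohorts to
reconstruct warmer temperatures (e.g. δ¹⁸O_oto ≈ 1.02 ‰ with
δ¹⁸O_sw = 0.5 ‰ gives 14.1 °C). Published statements of this equation
sometimes carry the slope's sign inside the coefficient and a negated
denominator; composing those two signs naively yields the unphysical
orientation, so the package fixes the orientation and keeps the slope
positive.

The respired-carbon fraction is the two-end-member mass balance
C_resp = (δ¹³C_oto − δ¹³C_DIC)/(δ¹³C_diet − δ¹³C_DIC) + ε, with ε added
outside the ratio and default 0. C_resp values outside [0, 1] are
retained and flagged, never clipped: negative or >1 values are
informative quality diagnostics, and the FMR calibration
FMR = (C_resp − 0.041)/0.000971 is affine, so clipping would bias
downstream fits. The calibration is the Atlantic-cod statistical
calibration; cross-taxon transfer is an assumption of the method.

Diet δ¹³C missing for an individual is imputed by the arithmetic mean of
its (species, location) group when available, falling back to the
species-wide mean (a flat species mean can be selected in config). A
species needing imputation with no measured diet value anywhere is a
data error.

Every forward conversion has an exact algebraic inverse (used by the
simulator), and the inversions round-trip to < 1e−9.

## Thermal ontogeny model

Within one location, T ~ log₁₀(M) × species by OLS, reference species
alphabetically first. Pairwise species contrasts at a common mass use
the studentized-range (Tukey–Kramer) adjustment with k = number of
species and the OLS residual degrees of freedom; for a family of one
pair this reduces to the unadjusted two-sided t test. The default
contrast mass for each pair is the geometric mean of the overlapping
observed mass range; a pair without overlap uses the combined range and
is flagged extrapolated. The CRS-band summary converts the minimum and
maximum conservation reference lengths to masses with the species
length–weight curve and reports the experienced-temperature ranges of
the below-minimum and above-maximum groups and their overlap width
(≥ 0 °C; undefined with counts when a group is empty).

## Anchored metabolic scaling

Because the ontogenetic descent into cooler water makes mass and
temperature collinear, B₀ in FMR = B₀ M^α e^(−Ea/kT) is not estimated but
anchored at data: B₀ is the observed FMR of the individual whose mass is
the sample median (even n: the lower-middle individual; exact mass ties:
geometric mean of the tied FMRs, mean of the tied temperatures), and the
model is reparameterized around the anchor's mass and temperature so B₀
is dimensionally coherent. A "smoothed" anchor (log–log regression
evaluated at the median mass) is available as a config switch. E is
defined as the slope on 1/(kT) (eV), so normal Arrhenius kinetics give
E < 0 and the strict-theory comparison values are α = −0.25,
E = −0.65 eV; a coefficient "exceeds theory" iff
|estimate − theory| > 1.96 SE.

(α, E) are estimated by nonlinear least squares on the natural FMR scale
(trust-region reflective, analytic Jacobian, tolerances 1e−10), starting
from (−0.25, −0.65) with documented restarts at (0, 0) and (−1, −3); a
log-scale linear fit of the same anchored model is provided as an
independent cross-check. Constant temperature across fish leaves E
unidentified: the Jacobian column vanishes, the fit is flagged
near-singular and SE(E) is reported as infinite.

**Standard errors.** FMR noise is multiplicative, so the natural-scale
residuals are strongly heteroskedastic, and the anchor's *own*
measurement noise enters every prediction through B₀. The reported
covariance is therefore (i) a leverage-corrected (HC3) sandwich of the
linearized least-squares problem plus (ii) a delta-method term for the
plug-in anchor, G σ̂²_ln G′ with G = −(J′J)⁺J′·pred (the sensitivity of
(α, E) to ln B₀) and σ̂²_ln the ln-scale residual variance. Simulation
shows plain curvature standard errors undercover badly in this anchored
design (≈45% at nominal 95%), while the combined estimator restores
92–99% coverage across a wide (α, E) range; the plain curvature
covariance is kept on the results object as `cov_curvature` for
diagnostics.

## Standardized location model

Large individuals — body mass at or above the per-species floors
(20/30/300/150/75 g for rock cook, goldsinny, ballan, cuckoo, corkwing) —
are modelled as ln FMR ~ z(ln M) + z(1/kT) + Species + Location, with
1/(kT_Kelvin) in eV⁻¹ so the rescaled temperature slope is directly an
activation energy. z-scoring (sample sd, ddof = 1) is computed on the
modelling subset, not the full data set: the standardization should
describe the population actually modelled; the full-data alternative
would only rescale the coefficients. Records with non-positive FMR are
dropped (counted) since the response is a logarithm.

Back-transformation: intercept-like terms exponentiate to
mgO₂ kg⁻¹ hr⁻¹ (species offsets add the intercept first), slopes divide
by the raw predictor's sd, and the location term exponentiates to an FMR
ratio between locations; by construction the two locations' predictions
differ by exactly that factor in the additive model.

Inference is a pluggable contract. The default backend is exact maximum
likelihood (OLS) with t intervals, ranked by AICc (with the +1 residual
sd parameter in k); it is used wherever many replicate fits are needed.
The Bayesian backend runs an emcee ensemble sampler with weakly
informative priors — Normal(0, 5²) on standardized coefficients,
half-Normal(0, 2.5) on the residual sd — reports percentile credible
intervals and the deviance-based DIC, and is reproducible under an
explicit seed (default 20191001). Candidate structures (additive vs
species×location interaction) are compared on the same subset and
criterion; ties break toward fewer parameters.

## Synthetic cohorts

The generator encodes the structure the analysis assumes and emits
raw-looking isotope tables by exact inversion of the proxy equations, so
derived values with all noise terms at zero reproduce the latent truth
to 1e−6. Per species: mass is log-uniform within bounds (emulating
size-balanced sampling); temperature follows a thermal-niche line
declining with log₁₀(mass) plus a location offset and Gaussian noise
(sd 0.8 °C); FMR follows the anchored scaling law at the species
reference mass with multiplicative lognormal noise (default ln-sd 0.2);
diet δ¹³C is Normal per species (means near −19 ‰, a documented marine
white-muscle convention, not a measured value) with a 15% missing
fraction.

Default scenario: the five two-location species with mass ranges
2–25 / 3–40 / 20–1000 / 10–400 / 5–150 g, niche lines giving emergent
median temperatures near 14 °C (Dorset) and 3.6 °C cooler (Skye),
species α between −0.37 and −0.84, and a zero location effect on ln FMR.
Thermal sensitivities are kept moderate (−0.6 to −3 eV) so that ≥99% of
generated C_resp lies in [0, 1]; a scenario pushing >10% of draws
outside [−0.5, 1.5] triggers an "unphysical" warning. The generator
exposes two transforms used by the model-level test scenarios:
`scenario_null_location` (zero location effect) and
`scenario_common_scaling` (a single (α, E) = (−0.53, −1.66 eV), ln-sd
0.3 across species), the latter because the common-slope location model
is only correctly specified — and frequentist coverage statements only
meaningful — when the generative slopes are in fact common.

What the simulator does *not* emulate: isotope measurement error (the
mass-spectrometric precision is an order of magnitude below the
ecological signal), seasonal integration of the otolith edge, uneven or
size-biased sampling, δ¹³C_DIC spatial variation, and species-specific
ε. Passing recovery tests therefore demonstrates the statistical
machinery is correct under the stated generative assumptions, not that
those assumptions hold in any particular sea.

## Problem sizes and determinism

The bundled checks use desk-scale sizes chosen to make Monte Carlo
noise small relative to the asserted margins: recovery of (α, E) over a
3×3 truth grid at n = 100 with 50 replicates per cell (coverage
aggregated per parameter across the grid; median relative bias pooled
across cells), location-effect coverage over 200 replicates of ~250
large individuals, and structure recovery over 50 replicates of ~300.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical cohorts,
CSVs and (for the MCMC backend) chains.

## Known limitations

- The anchored NLS conditions on the anchor individual's observed FMR;
  the SE correction propagates its noise but the point estimate still
  shifts with the anchor draw. The smoothed anchor reduces this at the
  cost of departing from the plain "observed individual" definition.
- With species-specific (α, E), any common-slope location model is an
  approximation; its slopes are then variance-weighted compromises and
  the structure comparison tends to prefer the interaction variant.
- DIC and AICc are not comparable across backends; model comparison
  refuses to mix them.
- The length–weight, CRS and threshold defaults bundled here are either
  synthetic (length–weight a = 0.01, b = 3) or the published per-species
  values; real analyses should supply their own config.
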
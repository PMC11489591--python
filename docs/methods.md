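# Methods

## The proxy model

Measured Mg/Ca of *N. pachyderma* (and its uncrusted sister species
*N. incompta*) is modelled as a separable product of a thermal and a
carbonate-chemistry control,

    Mg/Ca_meas = a·exp(b·T) · S([CO3^2-]),        S = p·[CO3^2-]^q,

with T the calcification temperature (°C) and [CO3^2-] in µmol kg⁻¹.
The correction chain estimates S by normalizing measured ratios against a
fixed temperature-only law (Mg/Ca_pred = 0.4·exp(0.09·T), the *N. incompta*
sensitivity assumed shared between the sister species), fits the power law
to normalized ratios vs. [CO3^2-], divides it out, and refits the corrected
ratios exponentially in temperature.  Central coefficients:
a = 0.372 mmol/mol, b = 0.0936 °C⁻¹, p = 3227.95, q = −1.53.  The
sensitivity is near unity above ~200 µmol kg⁻¹ and dominates below
~100 µmol kg⁻¹, which is exactly the glacial polar regime; inputs above
250 µmol kg⁻¹ are outside the calibrated range.

**Identifiability.**  The product form only constrains b, q and the product
a·p; the split between a and p is set by the anchor law used for
normalization.  Anchoring at a law whose temperature coefficient differs
from the data's true one leaks exp((b−b₀)T) scatter into the power-law fit
and shifts the recovered a by several percent while leaving a·p, b and q
intact.  Parameter-recovery experiments on synthetic data therefore anchor
at the generator's own temperature-only law (`fit_full_chain(...,
prediction_law=cfg.true_exp_law)`), the synthetic analogue of the field
assumption that the *N. incompta* law is the correct thermal sensitivity.

## The δ¹⁸O carbonate-ion proxy

Shell δ¹⁸O_c decreases linearly with [CO3^2-] at −0.0279 ‰ per µmol kg⁻¹,
with one intercept per crust state (crust calcite ~2 ‰ heavier than
ontogenetic calcite).  The fit is a shared-slope, two-intercept least
squares (ANCOVA form, via statsmodels OLS).  The intercepts are free
parameters of the method — they are fitted from calibration data or
supplied in configuration; the synthetic defaults (4.0 ‰ ontogenetic,
6.0 ‰ crusted) are chosen to give realistic polar δ¹⁸O_c values and are
not published constants.  Inverting the line turns a (sea-level-corrected)
fossil δ¹⁸O_c into the [CO3^2-] estimate used for the Mg/Ca correction;
estimates outside (0, 350) µmol kg⁻¹ are flagged out-of-calibration but
still computed, since glacial samples legitimately probe the low end.

## Fixed pre-processing offsets

* Tow (uncrusted, ontogenetic) material: Mg/Ca ×(1 − 0.15), δ¹⁸O_c +2.0 ‰,
  bringing live-collected shells onto the crusted fossil scale.
* Reductive cleaning: Mg/Ca ×(1 + 0.15) by default; 0.10 is available per
  record since published protocols span 10–15 % and per-dataset assignments
  are rarely documented.
* Ice volume: δ¹⁸O_c + rsl/10·0.11 ‰ with rsl the relative sea level (m,
  negative at glacials), removing the whole-ocean δ¹⁸O_sw enrichment
  (−120 m → −1.32 ‰) before δ¹⁸O_c is read as a [CO3^2-] proxy.

Each offset is applied exactly once; sample-state guards refuse
re-application rather than silently compounding.  Tow adjustments are
applied before any fitting.

## Carbonate-system solver

[CO3^2-], total-scale pH and Ω_calcite are computed from total alkalinity
and DIC with the de-facto default constant set of CO2SYS-family tools:
K1/K2 Lueker et al. (2000), KB Dickson (1990), total boron Uppström (1974),
KW Millero (1995, converted seawater→total scale), KS Dickson (1990),
KF Perez & Fraga (1987), calcite solubility Mucci (1983), Millero (1995)
pressure corrections.  The solver is a Brent root search on pH in [6, 9.5]
of the alkalinity residual (tolerance 10⁻¹⁰ pH units); nutrient alkalinity
is omitted (negligible for the waters targeted).  A non-bracketed residual
(pathological ALK/DIC) raises naming the inputs.  The constant set is a
deliberate, documented choice; the solver seam accepts pre-computed
[CO3^2-] columns wherever profiles already carry them.  Tests verify
agreement within 1 % in [CO3^2-] against an independently formulated
speciation solver (constants re-typed, dense-grid + bisection solution)
over ALK 2200–2400, DIC 1900–2250, S 30–35, T −1–20 °C.

## Equilibrium δ¹⁸O and calcification depth

Equilibrium calcite δ¹⁸O uses the classic quadratic paleotemperature form
T = 16.9 − 4.38·Δ + 0.10·Δ², Δ = δ¹⁸O_c − (δ¹⁸O_sw − 0.27), inverted via
the smaller (physical) root; the −0.27 ‰ converts water-scale (VSMOW)
values to the carbonate (VPDB) scale.  Alternative coefficient refits of
the same fractionation lineage can be registered by name; no vital-effect
offset is applied by default, with a configurable per-dataset offset for
records where one was characterised.  δ¹⁸O_sw comes from the profile where
measured, otherwise from a site-specific linear δ¹⁸O_sw–salinity mixing
line.  Calcification depth is the depth where the piecewise-linear
equilibrium profile crosses the measured δ¹⁸O_c, searched over 0–400 m; on
non-monotone profiles the shallowest crossing is returned (consistent with
the species' near-surface ecology) with the number of crossings reported,
never an average.  Depths beyond 300 m are flagged as ecologically suspect.
No crossing returns `matched=False` rather than raising, because fossil
values routinely fall outside modern profiles.

## Error model and Monte Carlo propagation

Stated input uncertainties (all 2σ): δ¹⁸O_c 0.2 ‰, [CO3^2-] 20 µmol kg⁻¹,
corrected-scale Mg/Ca 0.2 mmol/mol (absolute; a relative mode exists
because the published unit is ambiguous), calcification temperature 2.8 °C
(1.6 °C fallback where no depth-based estimate exists).  Perturbations are
independent Gaussians with σ = 2σ/2 by default; a uniform-on-±2σ option
exists since the underlying distribution is not documented.

The coefficient ensemble (n = 1000 draws by default) is a forward
simulation: the chain is point-fitted, then each draw re-simulates the
calibration set from that fit — environmental values drawn within their 2σ
around the tabulated ones, corrected-scale Mg/Ca noise added, negative
draws resampled (truncation counts logged) — and re-runs the full fit
chain against the tabulated values, anchored at the point fit.  This keeps
the ensemble median at the point estimate while the draws carry the full
empirical covariance of (p, q, a, b).  The obvious alternative, perturbing
the observed values and refitting, double-counts error the observations
already contain and systematically flattens the slope ensemble (median b
drops ~20 % in our experiments), which would contradict using the ensemble
median as the central calibration.  With all 2σ → 0 every draw equals the
point fit exactly.

Reconstructed-temperature uncertainty for one sample combines, per draw:
δ¹⁸O_c noise mapped through the oxygen–carbonate line into [CO3^2-], the
draw's (p, q) sensitivity, optional corrected-Mg/Ca noise, and the draw's
(a, b) inversion.  Intervals are empirical percentiles (16–84 and
2.5–97.5 %); "2σ half-width" is half the 2.5–97.5 span.  A 95 % prediction
interval can widen the coefficient-spread interval by a supplied residual
σ in quadrature.

The headline half-width computation (true 0 °C and 15 °C samples) uses the
composition the published figures describe: calibration-coefficient
uncertainty plus δ¹⁸O-derived [CO3^2-] uncertainty, without the Mg/Ca
measurement term.  The ensemble for it is generated under the noise
actually present in the synthetic calibration data, which reproduces the
published coefficient 2σ magnitudes (a ±0.010–0.015, b ±0.0035); building
it from the conservative environmental inputs instead (T ±2.8 °C) inflates
the coefficient spread ~60 % beyond those published magnitudes.
Representative modern surface [CO3^2-] at the two anchor temperatures is
taken as 100 µmol kg⁻¹ at 0 °C and 200 µmol kg⁻¹ at 15 °C (linear in
between), typical polar and temperate surface values.  At the study
conditions this yields ≈1.2–1.3 °C at 0 °C and ≈0.65–0.73 °C at 15 °C
(2σ): the 0 °C width matches the published ±1.2 °C, the 15 °C width sits
~0.2 °C below the published ±0.9 °C because the synthetic calibration is
slightly tighter than the field dataset.

## The synthetic forward model

`synth` generates the study conditions: 235 samples, temperature uniform
on −2–16 °C, [CO3^2-] uniform on 50–220 µmol kg⁻¹ (uniform, not Gaussian,
to mimic the design spread of a field calibration transect), a 50/50
tow/core-top split with the crust offsets applied in the forward
direction, and the stated 2σ noise on the proxies.  Noise enters on the
proxies only — corrected-scale Mg/Ca (absolute, truncated positive) and
δ¹⁸O_c — while the environmental values are exact: the environmental 2σ
describe assignment uncertainty and belong to the propagation stage, not
the generator's truth.  Water-column simulation produces smooth 0–400 m
profiles (exponential thermocline, optional mid-depth warm intrusion for
non-monotone cases) with carbonate chemistry solved from ALK/DIC and a
planted calcification depth; downcore simulation forward-models paired
proxies from an (age, SST, sea-level) history, with [CO3^2-] covarying
with SST through the representative-surface-water line and the ice-volume
δ¹⁸O term included.

What passing synthetic tests do **not** show about real data: the
generator has no seasonality or flux weighting, no depth-habitat change
through time, no dissolution, no inter-laboratory offsets beyond the
cleaning term, exact separability of the thermal and carbonate controls,
and a δ¹⁸O–[CO3^2-] relation with spatially constant intercepts.  Field
application inherits all of those caveats.

## Numerical choices

* Nonlinear fits on the natural scale via `scipy.optimize.curve_fit`,
  initialized from log-space OLS.  The power-law fit is iteratively
  reweighted with σᵢ ∝ the current model prediction, because the scatter
  of normalized Mg/Ca is multiplicative (it scales with the sensitivity,
  which spans nearly a decade over the calibrated range); unweighted
  natural-scale NLS is visibly biased steep in q.  The exponential fit is
  unweighted, matching its absolute error model.  r² is reported on the
  natural scale; quoted coefficient uncertainties are 2σ (Wald, from the
  fit covariance; the covariance is retained for propagation).
* Coverage behaviour at the study conditions (measured over repeated
  synthetic datasets): 95 % CIs for b, q and the oxy-slope cover their
  generating values at the nominal rate; the CI for a is conservative
  (the sensitivity-fit stage absorbs part of the shared Mg/Ca noise).
* Profile interpolation is linear and refuses extrapolation; no silent
  clamping.
* All randomness flows from a single `numpy.random.default_rng(seed)` per
  run; fixed seeds give bitwise-identical ensembles and CSVs (tables are
  written with `%.17g`, read back with round-trip float parsing).
* Degenerate inputs raise typed errors: identical salinities (mixing
  line), identical [CO3^2-] (power fit), temperature span ≤ 2 °C
  (exponential fit), even smoothing windows, empty age windows (named in
  the error).

## Problem sizes

Default experiment sizes are the study conditions themselves: 235-sample
calibration sets, 1000-draw ensembles, 300–500-repetition coverage
checks — all of which run in seconds on one CPU, so nothing is scaled
down.

## Known limitations

* The a/p split depends on the normalization anchor (see Identifiability);
  comparing pre-exponentials across studies requires the same anchor.
* The solver omits nutrient alkalinity; brackish or upwelling-influenced
  profiles with high phosphate/silicate would need a full-featured
  carbonate package behind the same seam.
* The δ¹⁸O–[CO3^2-] inversion assumes the crust state is known; mixed or
  partially crusted assemblages violate the two-intercept model.
* Window statistics combine row-level Monte-Carlo spreads in quadrature,
  treating rows as independent; shared calibration error makes window
  means slightly more correlated than that.
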
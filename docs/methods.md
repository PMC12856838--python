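# Methods

## Measurement model

A gas-saturation (DVME) run flows helium at ~50 sccm through a heated vial
until a known total standard volume has passed, trapping the analyte vapor
in a cooled capillary. The analysis treats the stream as saturated and
ideal, so Dalton's law gives

p_sat = p_saturator · y₂ / x₂, with p_saturator = p_ambient +
p_overpressure, y₂ = (m₂/M₂)/(m₁/M₁ + m₂/M₂), and x₂ = 1 − x₁ −
x_impurities.

Assumptions worth stating explicitly:

* **Saturation and no breakthrough.** The carrier leaves the vial at
  equilibrium and the trap captures everything; neither is modelled.
* **Helium solubility x₁ = 0.** Helium dissolves negligibly in large
  organic liquids; the field is settable for other carrier gases.
* **Area percent ≈ mole fraction.** GC-FID area-percent purity is mapped
  directly onto the condensed-phase mole-fraction impurity (equal response
  factors and similar impurity molar masses). For 96–99 % pure materials
  the error this introduces in x₂ is far below the purity uncertainty
  itself.
* **scc convention.** Standard cubic centimeters are referenced to
  273.15 K and 101 325 Pa by default; mass-flow vendors differ, so both
  are arguments. Gas metering uses the CODATA gas constant; the
  correlation and partitioning modules use R = 8.314 exactly, the value
  conventionally quoted with them.
* **Internal-standard quantitation** is a general line (mass ratio =
  slope · area ratio + intercept). An intercept can push a tiny peak to a
  negative mass; it is clipped to zero with a logged warning rather than
  raising, because a censored-at-zero mass is a physical outcome of
  calibration scatter while an exception would drop the run.

## Correlation and fit

The Clarke–Glew form truncated at the heat-capacity term (see README for
the equation) is used with θ = 307.15 K and p₀ = 0.1 MPa. Δ_vap C_p° is
held fixed during fitting — estimated from the ideal-gas heat capacity via
the Chickos correlation (−14.30 − 0.35 C_p°(g), expanded uncertainty
0.2·|Δ_vap C_p°|) and treated as temperature independent. With the
curvature fixed, the model is linear in (Δ_vap G°(θ), Δ_vap H°(θ)) and is
solved by ordinary least squares in R·ln(p/p₀) space in closed form
(`numpy.linalg.lstsq` on a two-column design). Choices:

* **Residual space.** "Unweighted least squares" is implemented in
  R ln(p/p₀) space — the space in which the equation is written and in
  which the model is linear. Multiplicative pressure noise becomes
  approximately additive homoskedastic noise there, which is also what
  makes the estimated standard errors meaningful.
* **Exclusion filter.** Only points with p_sat > 0.1 Pa (strict) enter
  the fit, applied once before fitting, never iteratively. At the bottom
  of the measurable range trapped masses are tiny and relative errors far
  exceed their nominal uncertainty estimates; the threshold is an
  argument.
* **Pooled replicates.** All replicate series are fitted together rather
  than averaged per temperature; with an unweighted linear model the two
  differ only when series are unbalanced, and pooling keeps the residual
  degrees of freedom honest.
* **Δ_vap C_p° precision in the pipeline.** The orchestrated pipeline
  rounds the Chickos estimate to the nearest integer before fixing it —
  the precision at which correlation parameter tables are distributed —
  so fits are exactly reproducible from a published parameter set. The
  underlying function returns full precision.
* **Covariance.** The 2×2 parameter covariance comes from s²(XᵀX)⁻¹ with
  s² = RSS/(n−2), transformed to (Δ_vap G°, Δ_vap H°) units; for n = 2
  (exact interpolation) it is defined as zero. The Δ_vap C_p° uncertainty
  is not folded into the fit; it propagates post hoc to Δ_vap H(T) through
  the linear Kirchhoff relation Δ_vap H(T) = Δ_vap H(θ) + Δ_vap C_p·(T−θ).

Enthalpies of vaporization at any temperature follow from that Kirchhoff
relation; d ln p/dT = Δ_vap H(T)/(R T²) supplies the temperature
sensitivity used by the uncertainty budget. Extrapolations outside the
fitted temperature span are flagged as such in every output table. Below
the melting point the correlation describes the supercooled liquid — the
convention aerosol partitioning models require, and the physically
relevant state in lung-lining fluid.

## Uncertainty budgets

Supplemental calibration detail for any specific apparatus is outside the
package, so the module implements the two generic propagation routes and
ships illustrative input profiles:

* **First order (GUM):** u_c² = Σ (∂p/∂v)² u(v)² with analytic partials of
  the measurement equation for v ∈ {m₁, m₂, p_ambient, p_overpressure,
  x₂}. Temperature does not appear in the measurement equation; its
  contribution enters through the correlation slope as
  (p · dlnp/dT · u_T)², reflecting the physical mechanism (incomplete
  thermal equilibration shifts the true sample temperature, and the
  pressure responds exponentially).
* **Monte Carlo:** every input drawn as an independent Gaussian, p_sat
  recomputed per draw, temperature applied as the multiplicative factor
  exp(dlnp/dT·δT); u_c is the sample standard deviation. Unphysical draws
  (m₁ ≤ 0, m₂ < 0, x₂ ∉ (0,1], non-positive vial pressure) are rejected
  and counted, with a warning above 1 %. Per-variable contributions come
  from one-at-a-time re-runs on independent substreams; a fixed seed
  reproduces the whole budget.

Inputs are treated as uncorrelated (correlation support deferred), and
u(T) is interpreted as a standard deviation. For relative inputs ≲5 % the
two routes agree to a few percent; for large inputs the Monte-Carlo total
exceeds first order because the multiplicative terms are log-normally
skewed — both behaviours are asserted in the tests. The shipped profiles
("standard", "short-equilibration") were chosen once so that total
relative u_c on a typical synthetic campaign falls in the 3–10 % range
characteristic of gas-saturation work at these pressures; they are
illustrative defaults, not calibration results, and real work should
supply a profile from its own instrument records.

## Synthetic campaigns

The generator defines the study conditions the tests run under: seven
nominal temperatures 364–424 K in 10 K steps, six replicate series, total
helium flows of 3000 scc (364–394 K), 2000 scc (404/414 K) and 1200 scc
(424 K) at 50 sccm (6000 scc at 364 K for CBN, where the smallest trapped
masses need longer collection), ambient pressure 83 kPa (a high-altitude
laboratory), and overpressure rising linearly from 400 Pa at 364 K by
8 Pa/K (viscous flow through the trap capillary grows with temperature; the
table is fully overridable where measured values exist).

For each run the generator perturbs the temperature (Gaussian sd 0.25 K
plus optional bias), evaluates the true correlation there, and inverts the
measurement equations to the trapped mass (y₂ = p·x₂/p_saturator,
m₂ = M₂·(y₂/(1−y₂))·(m₁/M₁)), then applies multiplicative Gaussian noise
(sd 3 %) to m₂. The record keeps the *nominal* temperature — the
incomplete-equilibration mechanism, in which the thermometer and the
sample briefly disagree — rather than noising the recorded value. Noise
levels were fixed once so that the first-order budget lands in the 3–10 %
relative band above.

What passing tests on this generator do show: the conversion chain and its
inverse are exact mutual inverses; the fit recovers generating parameters
exactly without noise and with correct standard-error coverage under
multiplicative noise; the exclusion filter counts behave as the analytic
pressure curve predicts. What they cannot show: correctness under real
instrument pathologies the generator omits — trap breakthrough, sample
degradation over a series, drifting calibration, correlated errors between
runs of a day, non-Gaussian GC integration error. Purity is constant per
campaign and chromatographic peak shapes are not simulated.

## Partitioning

C* and F_OA are computed with activity coefficient ζ = 1 by default (the
standard assumption when mixture data are absent) and equilibrium is
assumed — partitioning kinetics are out of scope. Volatility classes use
half-open, lower-edge-inclusive bands on the conventional decade grid
(ELVOC < 3·10⁻⁴ ≤ LVOC < 0.3 ≤ SVOC < 300 ≤ IVOC < 3·10⁶ ≤ VOC, in
µg·m⁻³); the source ranges are quoted without edge conventions, so the
inclusive-lower-edge rule is documented here and every edge sits in
configuration. Scenario presets: `breath-clean` (C_OA = 1.7 µg·m⁻³,
307.15 K) and `breath-ambient` (C_OA = 17 µg·m⁻³, 307.15 K).

One numerical note: evaluating the shipped CBN correlation at 307.15 K
gives 2.249e-5 Pa, which rounds to 2.2e-5 at two significant figures while
the value circulated with these parameters is 2.3e-5 — a rounding artifact
in that source; the full-precision number is the one that reproduces the
published C* = 2.7 µg·m⁻³, and the package always carries full precision
into the partitioning chain.

## Degenerate inputs and tie-breaks

m₂ = 0 is a valid record yielding p_sat = 0 (and is excluded from any
fit by the pressure floor). Fits require ≥2 usable points with distinct
temperatures and fail loudly otherwise; in the orchestrated pipeline a
per-compound fit failure is recorded in the report without aborting other
compounds, while an empty measurement table fails the whole run. Report
rounding follows the conventions of the field — pressures to two
significant figures, enthalpies to one decimal, fractions to two decimals,
heat-capacity changes to integers — with full precision always available
in the JSON output.

## Problem sizes

The default test campaign is 7 temperatures × 6 series = 42 runs per
compound; the noisy parameter-recovery study uses 500 seeded repeats of
that design, and the first-order/Monte-Carlo comparison uses 10⁵ draws.
These sizes give sampling errors comfortably below the tolerances being
asserted (e.g. ±0.2 % absolute on a 5 % relative uncertainty at 10⁵
draws).
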
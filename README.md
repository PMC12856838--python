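# cannavap

Cannabinoid vapor pressures from gas-saturation measurements, and what they
imply for breath-based drug detection.

Δ9-tetrahydrocannabinol (THC), cannabidiol (CBD) and cannabinol (CBN) are
routinely called "nonvolatile" and assumed to travel in exhaled breath only
inside aerosol droplets. Whether that is true is a vapor-pressure question:
the equilibrium split of a compound between breath vapor and breath aerosol
is set by its saturation pressure at ~307 K, which for these molecules is
so small (1e-5 to 1e-4 Pa) that it can only be measured at elevated
temperature and extrapolated down. `cannavap` implements the full analysis
chain for such measurements, for laboratory scientists working with
gas-saturation (transpiration / dynamic vapor microextraction, DVME)
apparatus and for anyone modelling vapor–aerosol partitioning of
semi-volatile drugs in breath.

## The model

A carrier-gas stream saturates with analyte in a heated vial; the analyte
mole fraction in the vapor gives the saturation pressure:

    p_sat = (p_ambient + p_overpressure) · y₂ / x₂,
    y₂ = (m₂/M₂) / (m₁/M₁ + m₂/M₂),   x₂ = 1 − x₁ − x_impurities

with m₁, m₂ the carrier and trapped analyte masses, M₁, M₂ their molar
masses, and x₂ the condensed-phase purity. Points above 0.1 Pa are fitted
with the Clarke–Glew equation truncated at the heat-capacity term,

    R ln(p/p₀) = −Δ_vap G°(θ)/θ + Δ_vap H°(θ)(1/θ − 1/T)
                 + Δ_vap C_p°(θ/T − 1 + ln(T/θ)),    p₀ = 0.1 MPa

with θ = 307.15 K (breath temperature) and Δ_vap C_p° fixed from the
Chickos correlation Δ_vap C_p° = −14.30 − 0.35 C_p°(g). That makes the fit
linear in (Δ_vap G°, Δ_vap H°) and exactly solvable. The fitted correlation
is extrapolated to breath (307.15 K) and body (310.15 K) temperature, and
converted into the volatility-basis-set quantities

    C* = M₂ · 10⁶ · ζ · p_corr / (R T)   [µg·m⁻³],
    F_OA = (1 + C*/C_OA)⁻¹

— the effective saturation concentration and the equilibrium aerosol-phase
mass fraction at an organic-aerosol loading C_OA. First-order (GUM) and
Monte-Carlo uncertainty budgets propagate the input-variable uncertainties
to u_c(p_sat), and a synthetic measurement generator inverts the whole
chain so every stage is testable without laboratory data.

The core fit is a scikit-learn style estimator
(`cannavap.ClarkeGlewRegressor`: temperatures in, pressures out, fitted
`dvap_g_`/`dvap_h_` with standard errors), so it composes with sklearn
tooling; `fit_clarke_glew` and friends are thin functional wrappers.

## Worked example

Simulate a realistic six-series DVME campaign for THC (seven temperatures,
364–424 K, 3 % trapped-mass noise, 0.25 K temperature scatter) and run the
full chain:

```
cannavap simulate --compound THC --seed 11 --out thc.csv
echo '{"measurements": "thc.csv"}' > config.json
cannavap run --config config.json --out demo
cat demo/report.txt
```

```
THC
---
  fit: n_used=36 n_excluded=6 <T>=399.0 K
  DvapG(theta) = 54.71 kJ/mol, DvapH(theta) = 118.81 kJ/mol, DvapCp = -157 J/(K mol)
  p_corr(307.15 K) = 5.0e-05 Pa (extrapolated)
  p_corr(310.15 K) = 7.8e-05 Pa (extrapolated)
  DvapH(298.15 K) = 120.2 kJ/mol
  DvapH(399.00 K) = 104.4 kJ/mol
  C_OA=1.7 ug/m3 @ 307.15 K: C*=6.1 ug/m3, F_OA=0.22, F_vapor=0.78, SVOC
  C_OA=17 ug/m3 @ 307.15 K: C*=6.1 ug/m3, F_OA=0.74, F_vapor=0.26, SVOC
```

Reading the report: the six 364 K runs fall below the 0.1 Pa floor and are
excluded (n_excluded=6); the fitted Gibbs energy and enthalpy of
vaporization at 307.15 K land within noise of the generating truth
(54.75, 119.00 kJ/mol); the correlation extrapolated to breath temperature
gives ~5e-5 Pa, an effective saturation concentration C* ≈ 6 µg·m⁻³ —
squarely semi-volatile (SVOC band 0.3–300 µg·m⁻³). At a clean-breath
aerosol loading of 1.7 µg·m⁻³ only 22 % of THC resides in the aerosol
phase (most is vapor); breathing ambient air at 17 µg·m⁻³ flips the
majority into the aerosol. Full-precision numbers are in
`demo/report.json`, per-point pressures in `demo/vapor_pressures.csv`.

The same chain is available as a library:

```python
from cannavap import (design_for, generate_series, vapor_pressure,
                      get_compound, ClarkeGlewRegressor)
recs = generate_series(design_for("CBD", seed=1))
pts = [vapor_pressure(r, get_compound("CBD")) for r in recs]
reg = ClarkeGlewRegressor(cp_gas=422.3).fit(
    [p.temperature for p in pts], [p.p_sat for p in pts])
reg.predict([307.15])  # breath-temperature vapor pressure, Pa
```

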
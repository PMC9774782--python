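# Methods

## Model and assumptions

The package implements the two-region pseudophase kinetic model for
water-insoluble antioxidants in oil-in-water emulsions. Assumptions:

* The emulsion's oil, interfacial, and aqueous regions behave as
  homogeneous pseudophases in dynamic equilibrium: antioxidant transport
  between regions is much faster than the probe reaction, so the
  distribution is described by time-independent partition constants.
* The antioxidant is insoluble in water (true of tocopherols well below
  their pKa of 9–10), so only P_O^I enters the rate law and the aqueous
  region holds 0% of the antioxidant. Water-soluble antioxidants, which
  need a three-region treatment, are out of scope.
* The probe's reactive group resides exclusively in the interfacial
  region, and the reaction is run under pseudo-first-order conditions
  ([AO] ≫ [probe]), so probe decay is a single exponential with rate
  constant k_obs = k_I · (AO_I).
* Absorbance of the derivatized probe is linear in probe concentration
  (assay calibration is assumed, not modeled).
* The oil volume fraction is held at its nominal value (0.1 for a 1:9 v/v
  emulsion) as surfactant is added; a `per-observation` policy is available
  for volume-renormalized designs.

## Estimation choices

**Trace fitting** (`traces`). Default mode is the linearized fit of
ln((A_t − A_inf)/(A_0 − A_inf)) on t, the classical treatment of the
assay's traces. When A_inf is not supplied in linearized mode, the last
observed point serves as the plateau estimate and is excluded from the
regression (including it would inject a log(0) point). This default is
*biased high* when the trace stops short of the plateau — the recorded
tail value overestimates A_inf — so supplying a measured A_inf, or using
the nonlinear mode (A_inf free), is preferred for traces covering < 4
half-lives. Points whose normalized amplitude is ≤ 0 raise an error naming
the point rather than being dropped: they signal a wrong plateau. A trace
whose amplitude is within 10× the noise floor (estimated from second
differences) is rejected as degenerate. The coverage check flags fits
spanning fewer than 2 half-lives (inclusive threshold).

**Replicate screening** (`replicates`). Dixon's Q (r10 statistic,
Q = gap/range for the most extreme value) against the two-sided
Dean–Dixon/Rorabacher critical table, n = 3–10 at 90/95/99% confidence;
95% is the default, the conventional analytical-chemistry choice. The test
is applied exactly once — iterated rejection is statistically invalid —
and at most one value is removed. Reported sd is the sample standard
deviation (n−1); aggregates with CV > 9% carry a precision flag, the upper
edge of the assay's expected 7–9% replicate precision.

**PKM fitting** (`pkm`). The reciprocal fit is unweighted OLS of 1/k_obs
on Φ_I, as the linearization implies; then k_I = 1/(slope·[AO_T]) and
P_O^I = Φ_O·slope/intercept. Parameter standard errors are first-order
(delta-method) propagations of the OLS slope/intercept covariance. The
covariance itself is the HC3 heteroscedasticity-robust estimate: replicate
noise is multiplicative in k_obs, so in reciprocal space the residual
variance scales with (1/k_obs)² and the homoscedastic formula understates
the uncertainty of the large-1/k end (measured ~10% understatement of
se(P_O^I) at 8% noise; HC3 is calibrated slightly conservative). A fitted
slope or intercept ≤ 0 is a model misfit, not a result: the rate law
requires positive intercepts. The nonlinear refit minimizes squared error
on the untransformed k_obs, initialized from the reciprocal fit; it is the
better estimator when noise is additive or multiplicative in k_obs, and on
exact data the two agree to machine precision. k_I is expressed in M⁻¹ s⁻¹
with antioxidant concentration per liter of interfacial region and [AO_T]
per liter of total emulsion — the only unit convention consistent with the
rate law and the enrichment formula simultaneously.

**Distributions** (`distribution`). Percentages are carried on the 0–100
scale. The oil-region effective concentration uses the same moles/volume
logic as the interfacial one, (AO_O) = [AO_T](%AO_O/100)/Φ_O, and is
validated by the mass-balance invariant
conc_I·Φ_I + conc_O·Φ_O = [AO_T] (10⁻⁹ tolerance). The default grid spans
Φ_I = 0.005–0.04, the experimental surfactant range. The partition-triple
identity P_W^O = P_W^I/P_O^I is checked at relative 10⁻⁶ (exact algebra
with float headroom).

**Acidity analysis** (`ph_analysis`). log₁₀ k_I is regressed on pH (base
10 by pH convention); the mechanism verdict accepts slopes within ±0.25 of
the theoretical 1, bracketing the 0.8–0.92 typically observed for
phenolate-mediated couplings. The invariance screen compares every pair of
P_O^I estimates against z·√(se_i² + se_j²). Its default critical value is
the Šidák-corrected two-sided normal quantile for the number of pairs at a
5% family-wise rate (z ≈ 2.63 for four acidities): with a fixed per-pair
z = 2, the chance of falsely flagging a truly constant P grows with the
number of acidities (~26% for four), defeating the screen's purpose. An
explicit `z` argument restores the raw per-pair rule. When standard errors
are unavailable the screen falls back to a 20% relative-spread threshold,
with a warning.

## Synthetic studies

The generator (`synthetic`) emulates the reference experimental design: a
1:9 v/v emulsion, V_T = 10 mL, Tween 20 (density 1.11 g/mL) at 0.5–4% w/w
giving Φ_I ≈ 0.0045–0.036; [AO_T] = 0.004 M; eight geometrically spaced
surfactant levels spanning Φ_I = 0.005–0.04 (the mass series 0.5, 1, 2, 4%
is itself geometric); pH levels 3, 4, 5, 6; triplicate runs. Defaults for
the planted truth are P_O^I = 5 — the value implied by a 20% interfacial
fraction at Φ_I = 0.005 — and k_I = 1 M⁻¹ s⁻¹ at the reference pH 3,
scaling as 10^(pH−3) (the inverse-[H⁺] law anchored at the most acidic
condition studied).

Replicate noise is multiplicative lognormal with exact mean 1 and CV 0.08:
rate constants are positive and the assay's stated precision (±7–9%) reads
as relative error. Trace noise is additive Gaussian in absorbance. The w/w
→ volume conversion assumes an emulsion density of 1.00 g/mL (only the
surfactant density is specified by the design); this is an approximation
good to a few percent. Seeds are explicit arguments everywhere — there is
no global random state — and each pH level of a study draws from an
independent stream derived from (seed, pH).

What the generator does *not* emulate: droplet-size distributions and
their evolution (creaming, coalescence), probe depletion, instrument
drift, interfacial acidity differing from bulk pH, or any systematic
(non-random) error in Φ_I. Passing tests therefore demonstrate that the
estimators recover parameters from data that *follow the model* at
realistic noise; they do not validate the pseudophase assumptions
themselves against real emulsions.

## Problem sizes and tolerances

Simulation-based checks use sizes chosen to keep sampling error well below
the margins being tested: 200 series for parameter-recovery medians (at 8%
noise the median relative error is ~8% for P_O^I and ~5% for k_I), 200
studies for the invariance screen's null pass rate, 10,000 triplicates for
the Q-test's empirical size (~5% at the 95% level), 500 seeds for the mean
acidity slope, 100 seeds for trace-recovery rates. Exact-algebra
invariants (round trips, closure, mass balance) are asserted at 10⁻⁸–10⁻⁹
relative, leaving two orders of magnitude of float headroom. The whole
suite runs in a few seconds on one CPU.

## Known limitations

* The linearized trace fit with a defaulted plateau is biased high; see
  above. The bias is a property of the estimator, not a bug, and the
  nonlinear mode avoids it.
* The reciprocal PKM fit inherits the classical double-reciprocal
  pathology: the smallest k_obs values dominate the regression. The HC3
  errors account for this in the uncertainty, and the nonlinear refit
  avoids it in the point estimate.
* Standard errors are first-order approximations; for strongly curved
  designs (very few Φ_I levels, high noise) they can understate the true
  spread of the slope/intercept *ratio* that defines P_O^I.
* The invariance screen tests a necessary condition for medium/
  concentration separation, not a sufficient one: a compensating pair of
  biases in k_I and P_O^I would pass it.
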
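# Methods

## Scenario construction

Reef carbonate production is represented by areal net ecosystem
calcification (NEC, kgCaCO₃ m⁻² y⁻¹) anchored at three epochs per RCP:

| RCP    | 2005 | 2050  | 2100  |
|--------|------|-------|-------|
| RCP2.6 | 2.8  | 0.95  | 0.73  |
| RCP4.5 | 2.8  | −0.63 | −1.39 |
| RCP8.5 | 2.8  | −1.45 | −1.57 |

A three-parameter exponential decay NEC(t) = a + b·e^(−k(t−2005)) is the
minimal form that passes exactly through three anchors while producing the
plateau behaviour the meta-analytic projections show (most of the decline
before 2050, virtually none after 2150). Eliminating a and b reduces the
fit to one monotone equation in k, solved by bracketed Brent iteration; a
brute-force (a, k) grid scan in the test suite confirms the same optimum.
Anchors that are not strictly decreasing are refused (`unfittable
anchors`), and anchor triples whose late decline outpaces the early one
admit no positive decay rate (`no exponential fit`).

Because the areal values enter only as the ratio rel(t) = 1 −
NEC(t)/NEC(2005), no global reef area is needed: the relative anomaly
directly rescales an assumed historical global carbonate production G₀ ∈
{30, 150, 300} TgC y⁻¹ spanning observational uncertainty. Fluxes are

    F_DIC(t) = rel(t) · G₀·10¹² / 12.011 · 10⁻¹⁵   [Pmol y⁻¹]
    F_Alk(t) = 2 · F_DIC(t)

— the 2:1 molar signature of CaCO₃ production decline. rel(t) may exceed 1
once NEC is negative (net dissolution); this is physical and assumed
sustainable on multicentennial timescales by the accumulated reef CaCO₃
reservoir. Fluxes are zero before 2005, follow the fitted curve to 2100,
and are **held at their 2100 values to 2300**: the projections saturate by
2100 and the clamp keeps the post-2100 series exactly constant, whereas
following the fitted curve would add a further ~1% drift for RCP2.6.
Molar masses are 12.011 (C) and 100.0869 (CaCO₃) g mol⁻¹; printed rounded
figures (0.25/1.25/2.50 PgCaCO₃ y⁻¹, 0.004/0.002 Pmol y⁻¹, …) are obtained
by rounding final outputs only.

## Carbonate chemistry

The solver finds the total-scale hydrogen-ion concentration closing

    Alk = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]

with K1/K2 from Lueker et al. (2000), KB from Dickson (1990), KW from
Millero (1995), CO₂ solubility from Weiss (1974) and total boron from Lee
et al. (2010) — a single hard-wired dialect, surface pressure only.
Phosphate and silicate terms are omitted because the box model carries no
nutrient state; pCO₂ is reported without a fugacity correction. The public
solver brackets pH in [2, 12] (Brent, ~1e−15 tolerance); the box-model
inner loop warm-starts a safeguarded Newton iteration from the previous
step's root and falls back to the bracketed solve. Internal units are
mol kg⁻¹; mol m⁻³ interfaces convert with a fixed density of
1026.5 kg m⁻³. The inverse solve (DIC from pCO₂ at given Alk) fixes
[CO₂*] by Henry's law, leaving a monotone one-dimensional root problem.
The Revelle factor and the sensitivities ∂pCO₂/∂DIC, ∂pCO₂/∂Alk are
central finite differences with a relative step of 1e−4 (validated against
a 1e−6 step).

## Box ocean

Four well-mixed boxes: reef shelf (area 1e12 m², 50 m deep — ~0.3% of the
3.6e14 m² ocean surface), open tropical surface (2.21e14 m², 100 m),
high-latitude surface (1.38e14 m², 250 m) and deep (1.282e18 m³; total
volume 1.337e18 m³). Transport combines a 30 Sv overturning loop
(high-lat → deep → tropical → high-lat) with bidirectional mixing of
8 Sv (reef–tropical), 60 Sv (tropical–high-lat) and 70 Sv
(high-lat–deep). The reef box is flushed in ~0.2 y, far faster than its
~0.6 y gas-exchange equilibration, so most of the pCO₂ anomaly induced by
reef fluxes is exported and vented elsewhere — the two-region analog of
enhancement escaping reef regions. Gas exchange uses a constant piston
velocity of 4 m d⁻¹ (~17 cm h⁻¹, a global-mean magnitude) with
F = k_w·K₀·(pCO₂_atm − pCO₂_box)·A; air–sea exchange alters DIC only,
alkalinity is only advected and injected.

Transport and mixing magnitudes were set once so that the unperturbed
historical run takes up a plausible ~1.9 PgC y⁻¹ in the 1990s and peaks
near 3.6 PgC y⁻¹ under RCP4.5; the feedback diagnostics are differences
between runs sharing this circulation and are insensitive to modest
retuning.

The default preindustrial surface temperature is a uniform 18 °C (near
the observed global-mean SST), with the deep box at 3 °C. Uniformity is a
deliberate idealization: with distinct surface temperatures no state can
simultaneously put every box at gas-exchange equilibrium and be stationary
under volume-conserving transport (alkalinity stationarity forces uniform
Alk, and equilibrium DIC then differs with temperature). The uniform
choice makes the per-box equilibrium an exact fixed point, giving a
preindustrial control with drift at rounding level (<1e−9 PgC y⁻¹) at the
cost of omitting the temperature-driven solubility pump — which cancels in
every scenario-minus-reference diagnostic. Optional linear SST ramps per
RCP (0.6/1.4/3.0 °C per century over 2005–2100, then 0/0.1/1.5 to 2300,
plus 0.4 °C over 1850–2005) perturb the surface boxes; the control stays
unwarmed.

Integration is explicit Euler at dt = 0.05 y (stability: the fastest rate,
reef-box flushing, is ~5 y⁻¹, giving dt·λ = 0.25; cumulative uptake agrees
with dt = 0.01 within 0.5%). All forcings are held constant within a
calendar year, which keeps the 1850–2005 segment of a scenario run bitwise
identical to its reference. State increments use Kahan-compensated
summation: control-run air–sea increments are ~10 ulp of the box
concentrations and plain accumulation would leak them, breaking
carbon-budget closure. Budget diagnostics close to <1e−9 relative (scaled
by at least 1e−6 of the 2.6e18 mol DIC inventory, the resolution floor of
differencing the inventory in float64). Anthropogenic uptake is defined as
run minus preindustrial control; enhancement as scenario minus same-RCP
reference.

## Ensemble and diagnostics

`run_ensemble` integrates 1850–2300: one control, three references, nine
scenarios (~5 s on one CPU, all from a shared preindustrial state).
Enhancement ΔF(t) is the annual-mean global air–sea flux difference;
cumulative enhancement is its annual sum; the peak is taken over
2005–2300 with ties broken by earliest year; percent enhancement is
relative to cumulative reference uptake since 1850; the reef-box share is
reef-box ΔF over global ΔF where the latter exceeds 1e−6 PgC y⁻¹.
PgC → GtCO₂ conversion uses the molar-mass ratio 44.009/12.011 = 3.664.

Time-of-emergence: annual series trend·t + AR(1) noise (stationary s.d. σ,
lag-1 autocorrelation φ); for each Monte-Carlo realization the OLS trend
over a growing record is tested against twice its standard error inflated
by the effective-sample-size factor √((1+φ)/(1−φ)); emergence is the first
record length (≥5 y) at which the trend is significant. Zero trend returns
a no-emergence sentinel. Realizations share common random numbers across
parameter grids, which makes median emergence time monotone in σ/trend by
construction of the comparison (not of the answer).

## Synthetic inputs

CO₂ pathways are monotone piecewise-cubic (PCHIP) interpolations through
round-number anchors consistent with the published RCP and extended (ECP)
concentration trajectories: shared historical segment from 285.2 ppm in
1850; RCP2.6 peaking at 443 ppm around 2050 and declining to 361 ppm by
2300; RCP4.5 stabilizing at 543 ppm after 2150; RCP8.5 reaching 936 ppm in
2100 and 1962 ppm by 2250. They are tagged `parametric`: adequate for the
mechanism studied here (the feedback depends weakly on the exact
concentration path), not a substitute for the official tables in
forcing-sensitive applications.

Reef masks seed a chosen number of cells uniformly at random within
|lat| ≤ 30° on a regular cell-centered grid (spherical cell areas),
deterministically per seed. Real reef atlases are clustered along coasts
and shallow banks; the synthetic mask reproduces only the properties the
pipeline relies on (tropical location, positive total area, conservative
flux distribution — the gridded export reproduces global totals to machine
precision). AR(1) alkalinity noise emulates the high interannual
variability of reef waters; it does not represent seasonal or sub-annual
variability, spatial covariance, or measurement error, so emergence times
here characterize the annual-mean detection problem only.

## What passing tests do and do not show

The desk-scale quantities (scenario fluxes, conversions, chemistry,
conservation) are exact reproductions. The ensemble enhancement magnitudes
come from a four-box ocean, not a 3-D GCM: tests assert sign, ordering,
near-linearity in G₀, RCP4.5≈RCP8.5 saturation, and order-of-magnitude
agreement (factor-of-two windows around 0.02–0.44 PgC y⁻¹ peak range),
not GCM-exact values. Reef-region shares are asserted only qualitatively
(high at onset, declining to ~2040). Known limitations: no spatial
heterogeneity of reef decline, constant reef organic production, no
sediment or pelagic calcification response, prescribed (not emissions-
driven) atmospheric CO₂, and no wind-speed-dependent gas transfer.
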
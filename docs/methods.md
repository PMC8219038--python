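# Methods

This note documents the models behind `leafgas`, the choices made where
the design was genuinely open, what the synthetic-data generators do and
do not emulate, and the numerical details a user fitting real data
should know.

## The forward model

C3 leaf photosynthesis follows the Farquhar–von Caemmerer–Berry (FvCB)
scheme: net assimilation is the *hard minimum* of the Rubisco-limited
and RuBP-regeneration-limited carboxylation rates minus day respiration,

    Ac = Vcmax (cc − Γ*) / (cc + Km),   Aj = J (cc − Γ*) / (4 cc + 8 Γ*),
    A  = min(Ac, Aj) − Rd.

No triose-phosphate-use limitation and no hyperbolic smoothing of the
minimum are applied: the A–cc fit estimates only Vcmax and Jmax, and a
smoothed minimum would trade bias in those two for an extra nuisance
parameter. All kinetic constants are for 25 °C and no temperature
response functions are included — the package targets measurements made
at 25 °C, and acclimation modelling is out of scope.

Electron transport follows the non-rectangular hyperbola (NRH)
`θJ² − (φI + Jmax)J + φI·Jmax = 0` (smaller root), evaluated in the
`2c/(b + √disc)` form which is exact at I = 0 and stable for θ → 0.

**Parameters** (defaults chosen as field-typical for well-watered
*Arabidopsis* rosettes at 25 °C):

| symbol | meaning | unit | default |
|---|---|---|---|
| Vcmax | max. Rubisco carboxylation | µmol m⁻² s⁻¹ | 60 |
| Jmax | max. electron transport | µmol m⁻² s⁻¹ | 120 |
| Γ* | chloroplastic CO2 compensation point | µmol mol⁻¹ | 42.75 |
| Km | effective Michaelis constant Kc(1+O/Ko) | µmol mol⁻¹ | 620.3322 |
| Rd | day respiration | µmol m⁻² s⁻¹ | 0.914 (generator truth) |
| θ, φ | NRH curvature / initial yield of J | – | 0.7 / 0.3 |
| gs | stomatal conductance to H2O | mol m⁻² s⁻¹ | 0.3 |
| gm | mesophyll conductance to CO2 | mol m⁻² s⁻¹ | 0.2 |

The default Km = 620.3322 is shipped as a fixed constant for A–cc
fitting. Its exact provenance is ambiguous: evaluating Kc(1 + O/Ko)
with the widely used chloroplastic constants Kc = 272.38 µmol mol⁻¹,
Ko = 165.82 mmol mol⁻¹ and O = 210 mmol mol⁻¹ gives 617.33, about 0.5%
lower. The constant is configurable everywhere it is used;
`km_chloroplastic` computes the closed form when Kc/Ko/O are supplied.

**Steady state.** The operating point solves demand = supply,
`A_demand(cc) = (ca − cc)·g_tot` with `1/g_tot = 1.6/gs + 1/gm` (1.6 is
the H2O:CO2 diffusivity ratio; gs is reported for water vapour, gm for
CO2). The root is found with Brent's method *in A rather than cc*:
`h(A) = A_demand(ca − A/g_tot) − A` is strictly decreasing, its bracket
`[−Rd − 1, max(A_demand(ca), 0) + 1]` provably contains the unique root
whenever ca > Γ*, and the formulation stays well conditioned as
conductances grow without bound (a cc-space search hits the
floating-point floor there, since flux residuals scale with g_tot).
The residual at the solution is required to be < 1e-9 µmol m⁻² s⁻¹.
Darkness is handled by the same bracket: with J = 0 the solution is
A = −Rd with a reversed gradient (cc > ci > ca), which the ordering
invariant Γ* ≤ cc ≤ ci ≤ ca therefore asserts only for A ≥ 0.

## Laisk estimation of ci* and Rd

Sub-curves measured at low CO2 under several sub-saturating irradiances
are each fitted by unweighted OLS `A = a + b·ci` (no weighting scheme is
assumed for analyser noise), and the intercepts are regressed on the
slopes: `a = α + β·b`, `ci* = −β`, `Rd = −α`. The slope–intercept form
uses all lines symmetrically and reduces to the pairwise intersection
for two lines. Negative Rd estimates are reported with a flag, never
clamped. Campaign-level pooling (`pool_laisk`) is an n-weighted mean of
per-plant fits, each weighted by its number of lines; the weighting is
a package choice, as the pooling rule for such campaigns is commonly
left unstated.

**Known limitation — curvature bias.** On data generated from the full
FvCB model the low-CO2 response is convex, so fitted chords lie above
the curve when extrapolated to the intersection. The slope–intercept
estimate is then biased: with the default truth and the standard design
(PAR {300, 150, 100, 50} × CO2 {150, 125, 100, 75, 50} µmol mol⁻¹) the
bias is ≈ +3.3 µmol mol⁻¹ in ci* and ≈ −0.33 µmol m⁻² s⁻¹ in Rd, nearly
identical with and without measurement noise — it is a property of the
estimator on curved data, not of sampling. Corrections for this
(gm-based curvature adjustments of the Laisk estimate) exist in the
literature but are deliberately out of scope; users should read ci*/Rd
from this package as the *apparent* (operational) quantities the
slope–intercept method defines. The generators also provide an
`idealized` mode producing exact common-intersection lines, on which
the estimator is exact to 1e-9; this separates estimator correctness
from model curvature in the test suite.

**ci\* versus Γ\*.** The apparent compensation point sits below the
chloroplastic one by the mesophyll drawdown at the compensation state:
Γ* = ci* + Rd/gm. `make_truth` applies this identity so that
FvCB-generated Laisk families intersect at the declared (ci*, −Rd).
The variable-J equation uses ci* as printed; round-trip tests that
simulate at known Γ* pass ci* = Γ* accordingly.

## Variable-J mesophyll conductance

The RuBP-limited FvCB equation is inverted per record for gm (see
README for the expression); cc follows as ci − A/gm. Two routes supply
J: under non-photorespiratory conditions (1% O2) J = 4(A+Rd) exactly;
otherwise J = ΦPSII·PAR·α·β from concurrent fluorescence, with leaf
absorptance α = 0.84 and PSII partitioning β = 0.5 — the field's
conventional values, both configurable, since instruments rarely report
leaf-specific calibrations.

Reliability is screened with δCc/δA = 12 ci* J/[J − 4(A+Rd)]², the
sensitivity of inferred chloroplastic CO2 to assimilation error. The
acceptance window 10 < δCc/δA < 50 is strict at both ends; records
outside it — or with a singular denominator J = 4(A+Rd), or a
non-positive gm — are retained with a reason flag and excluded from
aggregation only. The filter is a pure per-record predicate, hence
idempotent and order-independent.

## Response-curve fits

**Light response.** The NRH net-assimilation model
`A(I) = [φI + Asat − √((φI+Asat)² − 4θφI·Asat)]/(2θ) − Rd` is fitted by
bounded least squares in the response direction; an orthogonal-distance
mode (`method="odr"`) is available for when irradiance carries
comparable error, but response-direction OLS is the default because it
is reproducible without an error-variance ratio that measurements do
not provide. Initialisation is data-driven (φ from the low-light
slope, Asat from the curve maximum, Rd from the darkest point) with a
multistart over θ ∈ {0.4, 0.7, 0.95}; θ converging to a bound is
flagged. Derived quantities use closed forms: the light compensation
point `LCP = Rd(Asat − θRd)/(φ(Asat − Rd))` and the irradiance at 75%
saturation `I75 = 3Asat(1 − 0.75θ)/φ`. Because "Asat" is used for both
gross and net saturated rates in the literature, both conventions are
reported (`Asat`/`asat_net`, `I75`/`I75_net`); the primary values are
gross.

**A–cc.** ci is converted to cc with a supplied (usually mean
QC-passing) gm, then Vcmax and Jmax are fitted with Rd, Γ* and Km held
fixed; Jmax enters through the NRH at the curve's constant PAR, so the
fitted Jmax is commensurate with the light-response convention. The
reported inflection is the cc where the branches cross,
`(J·Km − 8Γ*Vcmax)/(4Vcmax − J)`. If every point lies on one branch the
other parameter is unidentified and is flagged as a lower bound rather
than an estimate. Least-squares tolerances are 1e-12 here (not the
1e-15 used for smooth fits): the min-of-branches model has a gradient
kink where a point switches limitation, which stalls tighter trust
regions under noise; 1e-12 is far below the fit's own statistical
resolution. Misspecified gm propagates as expected — gm too high biases
Vcmax low — and supplying `gm=None`/∞ reproduces a fit on ci exactly.

**Stopped-flow decay.** `F(t) = amplitude·e^(−kt) + plateau` is fitted
over the first 8 ms (0.125 ms sampling), with a log-linear initial k
and a multistart over k scales. A non-decreasing or constant trace is
returned as k = 0 with a `no_decay` flag instead of a spurious rate.

## Water-side computations

`gmin` comes from the OLS mass-loss slope of the post-closure drying
curve: `gmin = (rate/M_w)/(area · VPD/Patm)`, reported in mmol m⁻² s⁻¹.
The area basis is the single-sided projected area averaged between the
initial and final photographs (leaves shrink while drying; the mean is
the package's documented choice). Saturation vapour pressure uses the
Arden Buck form `es(T) = 0.61121·exp[(18.678 − T/234.5)·T/(257.14+T)]`
kPa; any standard es(T) within 0.1% gives the same gmin to well inside
measurement error. A configurable `discard_s` drops an initial
settling interval for series that begin before full stomatal closure.
Slopes above −1e-15 g s⁻¹ are reported as "no loss" with gmin = 0,
since an exactly constant series produces a slope at the floating-point
floor.

The chamber leak coefficient k (mol s⁻¹) is the OLS slope of apparent
CO2 flux against the ambient-to-chamber mole-fraction gradient measured
on a darkened leaf, whose constant respiration becomes the regression
intercept. The correction subtracts k·ΔC/leaf-area from A and marks
the record's provenance.

RWC = 100(FW − DW)/(SW − DW). Note the ratio is invariant to both
shifting and scaling all three masses (offsets cancel in numerator and
denominator) — a useful sanity property, since common transcription
errors (dropped parentheses) break it.

Whole-plant transpiration closes the sealed-pot mass balance
`E = (ΣV + Wi − Wf − FW)/At` (1 ml ≡ 1 g; soil evaporation is zero by
the membrane seal). Because the plant grows during the experiment, the
cumulative leaf area At is computed by default as the trapezoidal
time-integral of the weekly area measurements (m²·d); a plain sum of
the weekly areas (m²) is available as `mode="sum"`, and an explicit At
overrides both. The reported unit convention — grams of water per unit
cumulative leaf area — is stated with each result because axis units
for E vary between studies. A negative numerator is returned with a
warning (condensation/bookkeeping anomaly), never silently clipped.

## The synthetic-data generators

Each generator simulates one instrument protocol from the forward model
with a declared `SyntheticTruth`, using a single seeded stream with
draws in record order, so a (truth, seed) pair fixes the dataset
byte-for-byte:

* A–ci: 17 CO2 steps beginning at the 400 µmol mol⁻¹ growth set point
  (then 450…2000, 400…50), PAR 1500;
* light response: 9 descending steps 2000 → 0 at ca = 400, with an
  optional NRH-truth mode for exact light-curve round trips;
* Laisk families: 4 irradiances × 5 low-CO2 steps, FvCB mode or
  idealized exact-lines mode;
* drying curves (8 weighings, 27 min apart), sealed-pot weights with
  watering events, darkened-leaf leak series, and stopped-flow traces.

Noise is multiplicative Gaussian on the fluxes A and gs only — never on
set points — with cv = 0.02 by default (a typical match-mode
repeatability for a well-calibrated open gas-exchange system; the
instruments publish no noise figure, so this is a package choice).
Balance noise defaults to 0.5 mg for leaf weighings and 0.5 g for pot
weighings. ci is recomputed from the noisy fluxes as the analyser
would (`ci = ca − 1.6 A/gs`). Simulated ΦPSII is inverted from the
stoichiometric electron flux `(A+Rd)(4cc+8Γ*)/(cc−Γ*)` at the
noise-free operating point — the quantity fluorescence actually
reports — which equals the NRH supply rate only under RuBP limitation
(under Rubisco limitation PSII down-regulates below it).

What the generators deliberately do **not** emulate: instrument drift,
match-valve artifacts, leaks beyond the additive k·ΔC model,
heteroscedastic or autocorrelated noise, boundary-layer and energy-
balance effects, stomatal patchiness, and alternative electron sinks
decoupling fluorescence J from carboxylation. Passing recovery tests
therefore demonstrate estimator correctness under the stated generative
model, not robustness to every artifact of real campaigns — with one
exception worth repeating: the Laisk curvature bias above is a real
property of the method that the FvCB-mode generator does reproduce.

## Problem sizes used in tests and the acceptance script

Recovery grids use 1000 records (40 gm × 25 ca points); stochastic
checks use 150–500 replicates per quantity (Laisk bias 500, Vcmax RMSE
150–200, gmin/E 200, decay 3 × 6); synthetic campaigns in the
acceptance script use field-realistic sample sizes (16 plants for
Laisk pooling, 12 for gm and E, 21 leaves for gmin). These sizes give
sub-percent Monte-Carlo error on every reported mean while keeping a
full run in tens of seconds.
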
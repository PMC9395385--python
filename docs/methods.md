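# Methods

## Design construction and coding

The supported design family is the three-factor central composite design:
8 factorial points (all ±1 combinations), 6 axial points and a replicated
centre block. Coded units are (actual − centre)/step, with step the
factorial half-range (3 MPa, 5 °C, 10 % v/v for the packaged study).
General k-factor CCDs, fractional factorials and Box–Behnken designs are
out of scope.

Axial levels are stored **verbatim** per factor rather than derived from a
single axial distance α. The packaged design quotes a nominal α of 1.32,
but its printed axial settings imply per-factor coded distances of 1.33
(pressure), 1.40 (temperature) and 1.30 (water): real designs round axial
settings to operable values. Since the regression is computed on coded
levels derived from the actual settings, using the verbatim levels is what
makes the fit statistics reproducible. `FactorSpec` keeps α as metadata and
warns when it disagrees with the implied distance by more than 0.05.

`build_ccd` emits factorial, then axial, then centre runs in a fixed,
documented order; the packaged dataset keeps its published run order.

## Response-surface fitting

Models (`linear`, `2fi`, `quadratic`) are fitted by OLS on the coded scale,
via statsmodels. Fitting on coded factors makes coefficient magnitudes
comparable across factors and matches the convention of DOE software, so
published coefficient tables are only reproducible on this scale. The
intercept is fitted but not part of any published comparison.

Statistics:

- R² and adjusted R² with the standard df correction;
- PRESS from leave-one-out residuals eᵢ/(1−hᵢᵢ) using the hat matrix, and
  predicted R² = 1 − PRESS/SS_total;
- per-term partial (type III) p-values — for OLS these are the coefficient
  t-tests — with significance declared at p < 0.05;
- lack-of-fit F-test splitting residual SS into pure error (from exactly
  replicated design rows — the centre block in a CCD) and lack of fit. With
  no replicates the test is reported explicitly as unavailable with a
  reason, never as a silent NaN.

Degenerate inputs: a constant response is flagged
(`degenerate_response_=True`) and R²-type statistics are NaN; a rank-
deficient model matrix raises an error naming the collinear terms.

On the packaged data the yield 2FI fit gives R² = 0.954, adjusted
R² = 0.932, predicted R² = 0.897, and lack of fit p = 0.46 (adequate);
the solubility quadratic gives R² = 0.873 with significant lack of fit
(p ≈ 0.006), consistent with the visibly noisy centre replicates.

## Optimisation over the design region

`optimize_response` maximises the fitted polynomial over a coded box —
defaulting to the axial box, with the factorial box [−1, 1]³ available —
using multi-start L-BFGS-B from a deterministic 4×4×4 grid of starts plus,
for quadratics, the analytic stationary point when it lies inside the box.
Because a quadratic in three variables over a box attains its optimum either
at the stationary point or on the boundary, the grid multistart with box
constraints is reliable here; a 51³ grid oracle backs this in the tests.
Convergence tolerances are 1e−12 (function) and 1e−10 (gradient); ties are
broken by first-found from the deterministic start order. For models without
curvature (linear, 2FI) the optimum necessarily lands on the boundary.

The published optimum comparison point (24 MPa, 68.8 °C, 29.8 %) sits on
the factorial-box boundary (coded A = 1), so the `compare` workflow
optimises over [−1, 1]³. The package checks the model *prediction* at the
printed comparison points rather than asserting the argmax coordinates,
because the upstream DOE software's optimisation target (yield, solubility
or both) is not recoverable from the printed results.

## Cost model

OC = 2.73·COL + 1.23·(CUT + CRM), RM/year. CRM annualises per-run sample,
CO₂ and ethanol consumption at the configured prices; CUT is
Σ device power × annual hours × tariff; COL is 12 × monthly salary ×
operators. Fixed capital and waste treatment are excluded by design.

Several duty-cycle quantities are not part of the published record and are
set once as package defaults, at values a lab-to-pilot practitioner would
recognise: continuous operation (8 760 h/year) with 8-hour runs
back-to-back (1 095 runs/year), 2.0 kg CO₂ and 0.06 l co-solvent per 3 g
charge, minor equipment between 0.4 and 0.9 kW alongside the 13.82 kW
chiller. The tariff is stored in sen/kWh (36.5, i.e. RM 0.365/kWh) and
divided by 100 at compute time. Under these defaults utilities dominate the
direct costs (≈58 %, chiller-driven), labour ≈23 % and raw materials ≈19 %
(CO₂ ≈80 % of CRM) — the tests assert only the orderings (CUT largest;
chiller the top utility item), not the percentages, which depend on the
unpublished duty-cycle choices.

Across operating conditions only the water fraction changes the cost
(water displaces purchased ethanol); per-run electrical energy is treated
as independent of pressure and temperature because no per-condition energy
data exist. This makes cost ranking a strict function of water level.

## Safety scoring

% v/v water-in-ethanol converts to mole fractions through 20 °C handbook
densities and molar masses (the high-pressure density table ships as data
but is not used for this conversion; the conversion temperature is
configurable). Mixture boiling point and Hansen parameter are mole-fraction
linear mixes.

The mixture flash point solves Le Chatelier's rule with Antoine vapour
pressures (log₁₀ mmHg/°C convention, fixed in the config schema) by Brent
root finding on a −50…200 °C bracket (tolerance 1e−8 °C; a 0.01 °C grid
scan backs the solver in the tests to ≤0.02 °C). Non-flammable components
contribute zero to the sum. The liquid-phase activity model is pluggable:
van Laar with standard ethanol–water constants (A₁₂ = 1.6798,
A₂₁ = 0.9227) by default, since ethanol–water is strongly non-ideal and
ideal γ overstates the dilution effect on flammability; `"ideal"` (γ = 1)
is available for transparency and custom objects with a `gammas(x1)` method
plug in directly.

Logistic scores use the overflow-safe `expit` form. Argument units are part
of the schema: °C (S_FL), ppm (S_TX), NFPA integer (S_R), vol % (S_EXP).
Composition policy: only S_FL varies with water content, through the
mixture flash point; S_TX, S_R and S_EXP take the flammable component's
values, because water has no TLV-STEL, NFPA instability or explosive range
to contribute. This reproduces the observed variance pattern (flammability
drives the CSTS differences between water levels; the other scores are
flat). CO₂'s asphyxiant hazard and the vessel BLEVE/overpressure scenarios
are qualitative equipment-level facts and ship as a static hazard register,
outside the CSTS arithmetic.

## Performance index

Rank indices assign n to the best condition and 1 to the worst, ties
sharing the mean of their positions, so every column sums to n(n+1)/2.
Orientation follows the stated aim — highest solubility, lowest cost,
safest environment — and the three indices are summed unweighted. Rank
indices are invariant to strictly monotone transforms of a criterion, so
the selection never depends on criterion units.

The index ranks *operating conditions*, not runs: replicated centre points
collapse to one condition with their mean solubility by default (cost and
CSTS are deterministic per condition). Ranking all 20 rows instead is
available behind a flag and selects the same best condition on the packaged
data. Measured solubility is the default criterion; model-predicted
solubility can be supplied through the `solubility_column` hook. Ties on
I_performance break by higher I_solubility, then lower cost. Weighted
multi-criteria schemes (AHP, TOPSIS) are out of scope.

## Synthetic data generator

`generate_response` evaluates a known coded-scale polynomial on any design
and adds homoscedastic Gaussian noise from a seeded generator
(`numpy.random.default_rng`), giving a ground truth for parameter-recovery
and error-rate tests. The default noise SD is the pooled SD of the packaged
centre replicates (≈0.99 for yield), so power studies run at the scatter
the real rig produced. What it emulates: a polynomial response surface with
iid noise. What it does not: the heteroscedasticity, drift and lack-of-fit
visible in the real solubility response (its significant lack-of-fit test
shows the quadratic is an approximation). Passing recovery tests therefore
demonstrate correctness of the estimator, not adequacy of a polynomial
model for any particular extraction.

Fixture tables are verified against frozen SHA-256 digests at load time,
so accidental edits fail loudly.

## Problem sizes in the test suite

Monte-Carlo checks use 100 replicates (null term-rejection rate, rank
invariances), 50 seeds per noise level for coefficient recovery, 200 draws
for the generator's residual-SD check, and a 51³ grid for the optimiser
oracle; the full suite runs in a few seconds.

## Known limitations

- Cost percentages depend on unpublished duty-cycle assumptions; only
  orderings are meaningful.
- The van Laar constants are composition-only (temperature-independent);
  adequate over the narrow flash-point range involved.
- The flash-point model treats the co-solvent as a binary liquid at
  ambient pressure; CO₂ partitioning into the liquid phase is ignored.
- The solubility quadratic has significant lack of fit, so its predictions
  carry model error beyond the reported R²; comparisons use generous
  absolute bands (±0.3 on the 10³-scaled solubility).
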
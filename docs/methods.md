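# Methods

This note records the models implemented in `antcut`, the assumptions
behind them, the defaults of the synthetic-data generators, and the
numerical choices made where the design was genuinely open.

## The force model

Cutting a thin sheet is fracture: new surface is created at an energy
cost G_c (J m⁻²) per unit area, so a virtual-work argument bounds the
cutting force from below by F_min = G_c·t for a sheet of thickness t,
independent of the tool. Tool geometry enters through additional
dissipation near the crack tip. With the tool reduced to a single
characteristic length R (the cutting-edge radius) and the material to a
characteristic strength σ_c (its ultimate tensile strength), dimensional
analysis gives

    F_f = G_c·t + C·σ_c·R·t,   C = 1 + μ,

with μ the tool–substrate friction coefficient; C = 1 + μ is the exact
result for a cylindrical wire and is exposed as an override
(`CuttingToolSpec.C_override`) for other idealisations. The sharpness
index S = G_c·t/F_f = 1/(1 + C·σ_c·R/G_c) separates the material-bound
and geometry-dependent parts of the force: S = 1 iff R = 0. The model is
quasi-static and rate-independent; speed effects are handled separately
as multiplicative amplification factors (√(v₂/v₁) for tearing-like
fracture, (v₂/v₁)^k with an empirical k for cutting).

Material presets: PDMS (G_c = 100 J m⁻², σ_c = 4 MPa, t = 200 μm),
median tropical leaf (400 N m⁻¹, 3 MPa, 200 μm) and laurel lamina
(leaf toughness/strength with t = 250 μm). σ_c is a supplied material
constant, not derived from the tension fit.

Radius inversion, R = (F_f − G_c·t)/(C·σ_c·t), is exact algebra; its
round-trip precision is limited only by floating-point cancellation when
the geometry term is a vanishing fraction (< ~10⁻³) of the total force,
which no physically relevant tool/material pairing approaches.

## Measurement chain

* **Calibration.** The bending-beam sensor reads a distance that is
  linear in force only for small deflections, so polynomial
  force→reading models of degree 1–3 are fitted and the degree chosen by
  AIC under a Gaussian likelihood with plugged-in variance
  (AIC = n·ln(RSS/n) + 2k, k = degree + 2). The RSS is floored at
  numerical precision so exact fits tie, and ties break toward the lower
  degree. The inverse map is evaluated on a dense (8192-point) monotone
  grid extended ~30 % below the fit range so that small negative forces
  during retraction remain invertible; the interpolation error is
  < 10⁻⁹ N for the default quadratic.
* **Drift correction.** A line through the mean calibrated force in two
  unloaded baseline windows (defaults: first and last 1.5 s) is
  subtracted. For linear drift this is exact; the recovered rate is
  stored on the trace.
* **Extraction.** The initiation peak is the global force maximum of the
  advance phase (samples up to the maximum motor position). The steady
  state starts at the first position after the peak where the force
  stays within ±15 % of its forward running median over 0.2 mm of
  travel; because the peak's decaying tail can satisfy this band
  slightly early, a settling distance of 0.1 mm (exposed as
  `settle_mm`) is added before the averaging window. F_c is the mean
  calibrated force over 2 mm of motor travel from that point; F_s is the
  spacing pass averaged over the identical motor positions;
  F_f = F_c − F_s holds exactly by construction. The window is defined
  in motor position, not time; converting motor travel to sheet
  displacement by removing beam deflection (a ~2 % effect) is available
  via `compliance_mm_per_N` but off by default.
* **Validity.** A measurement is valid iff the steady state is at least
  as long as the window, the force is within the calibration range
  (≤ 245 mN), and none of the observational failure modes
  (head-capsule contact, slip out of the cut, fixation failure, holder
  slip) was reported. Short plateaus and undetectable peaks yield
  measurements flagged invalid rather than exceptions.

## Wear index

Pristine tooth lengths are estimated by per-tooth OLS of log₁₀ length on
log₁₀ body mass fitted to callows only (the allometric form is an
assumption; it matches the package's general treatment of scaling).
Tooth losses are ΔT_i = predicted − observed, so wear is positive, and
W = (ΔT₂ + α·ΔT₁)/2 with α = mean(ΔT₂)/mean(ΔT₁) computed over foragers
only — callows would contribute ~0/0 noise to both means. W has
dimension length; W* = W / predicted pristine T₂ is the relative index.
Specimens with unmeasurable teeth are dropped with a logged count. The
wear–force regression is OLS on untransformed data because W can be
negative for noisy callow measurements.

## Scaling predictions

The isometric null model R = a·m^(1/3) is anchored by a reference pair
(R_ref, m_ref) — by default the 5 μm radius inferred for a pristine
40 mg worker from its measured cutting force. Predicted forces
F_f(m) on a mass grid are summarised by OLS of log₁₀F (mN) on log₁₀m
(mg). The grid is uniform in log₁₀ mass (n = 100, range 2.1–46.4 mg)
because that is the space in which the regression is performed; doubling
the grid changes elevation and slope by < 0.005, and observed specimen
masses can be supplied instead (`masses_mg`). The predicted slope is
bounded between 0 (geometry-independent regime, C·σ_c·R/G_c ≪ 1) and
1/3 (R-dominated regime).

CV equality uses the Feltz–Miller asymptotic statistic
D_AD = Σ mᵢ(cᵢ − c̄)² / (c̄²(0.5 + c̄²)), chi-square with k − 1 degrees of
freedom, with c̄ the df-weighted pooled CV.

## Foraging capacity

Required cutting force per leaf is G_c·t (the pristine, geometry-free
bound) plus a wear shift of 2.09 mN μm⁻¹·W, the wear sensitivity
measured on PDMS and assumed material-independent. An optional tool
argument adds the C·σ_c·R·t geometry term per species for sensitivity
analysis; the geometry-free default is the model's stated assumption.
A species is cuttable when its requirement does not exceed the worker's
peak bite force F_b = 800·(m/40)^0.90 mN; ties count as cuttable. The
lifetime cut length keeps every factor of the worked estimate (colony
forager count, annual leaf area, cut length per area, active months)
as explicit arguments.

## Synthetic-data generators

The generators define the test conditions for the pipeline:

* **Traces.** Default 65 mN cut / 5 mN spacing force (a medium worker),
  motor speed 0.3 mm s⁻¹ over 5 mm, 81.4 Hz sampling, drift
  0.01 mN s⁻¹, Gaussian noise of 0.5 mN, a triangular initiation peak of
  1.5× the plateau over 0.2 mm following a 0.3 mm loading ramp, and 2 s
  unloaded dwells at both ends for drift baselines. Drift and noise are
  added in force units and then passed through the *inverse* of a
  quadratic sensor response (reading = 1.5F − 0.9F²), so the calibration
  stage is exercised honestly rather than fed identity readings.
* **Populations.** 85 workers, masses log-uniform over 1.8–46.4 mg,
  ~46 % foragers. Pristine tooth/blade lengths follow L = A·m^(1/3)
  (A = 40, 30, 250 μm for T₁, T₂, blade — realistic magnitudes chosen
  once, giving ~12 % relative loss at the default wear). Forager wear is
  normal(8, 10) μm truncated at zero (the truncation is a modelling
  choice; the real wear distribution beyond its mean ± sd is unknown),
  split between the teeth so that ΔT₂/ΔT₁ equals a configurable ratio
  (default 1, the equal-average-loss case α = 1, since the per-tooth
  partition is not independently constrained). Measurement noise
  (2 μm sd) is added last; callows get wear exactly zero.
* **Leaves.** Lognormal marginals with medians G_c = 400 N m⁻¹,
  t = 200 μm, σ_c = 3 MPa and log-sds 0.6/0.3/0.4 — spreads typical of
  broad leaf-trait surveys, chosen once. The three traits are sampled
  independently; real leaf traits covary, so capacity fractions from
  synthetic tables are structural illustrations, not trait-survey
  reproductions.
* **Material curves.** The unnotched tearing curve is linear with
  stiffness set so the work to the critical displacement is exactly
  G_c·w·t, making the trapezoid-integrated toughness exact for the
  noiseless curve; tension curves have slope E through 10 % strain.

Every generator draws from one `numpy.random.Generator` seeded per call;
identical seeds are bit-identical. What passing tests show is that the
pipeline recovers known ground truth under these idealised conditions
(single dominant peak, stationary plateau, linear drift, Gaussian noise,
independent lognormal traits); real traces with multiple re-initiation
peaks, non-stationary drift, or correlated leaf traits are outside what
the generators emulate.

## Problem sizes and numerical tolerances

The recovery harnesses use 500 trace pairs for force-extraction bias
(budget: 3 standard errors of the window mean), 200 replicates for
confidence-interval coverage of the allometric exponent (n = 40 callows)
and the wear–force slope (n = 24 foragers, residual sd 23 mN chosen to
match an R² ≈ 0.33 regression), and 1000 replicates for the CV-test
type-I error (two lognormal groups, CV 0.25, n = 30). These sizes give
comfortable statistical resolution while keeping the suite fast.
Noiseless constructions are asserted to 10⁻⁹ N through the full
calibration/drift/extraction chain (the dense-grid calibration inversion
dominates that budget) and to machine precision where no interpolation
is involved.

## Known limitations

* The sharpness model collapses tool geometry to a single length R;
  tooth spacing, wedge angle and blade curvature are not modelled.
* Validity criteria tied to events the sensor cannot see (head contact,
  slip, fixation failure) are taken as supplied flags, not detected.
* The capacity estimator treats leaf species as independent rows and
  ignores within-species trait variation.
* No crack-dynamics or mandible-kinematics simulation: the generators
  produce phenomenological traces, not mechanistic ones.
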
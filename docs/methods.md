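# Methods

## Rate laws and units

Three bisubstrate initial-velocity laws are implemented in closed form, with
A the sugar-nucleotide donor (UDP-GlcNAc) and B the acceptor (LacNAc):

* rapid-equilibrium random-order sequential:
  `v = k_cat[E][A][B] / (αK_AK_B + αK_A[B] + αK_B[A] + [A][B])`
* rapid-equilibrium compulsory order, A first:
  `v = k_cat[E][A][B] / (K_AK_B + K_B[A] + [A][B])`
* ping-pong bi-bi:
  `v = k_cat[E][A][B] / (K_A[B] + K_B[A] + [A][B])`

The compulsory-order and ping-pong forms are the classical Segel forms,
chosen so that the two textbook double-reciprocal signatures hold exactly:
ping-pong families are parallel, compulsory-order families share the 1/v-axis
intercept, and the random-order family meets at
`(−1/K_B, (1−α)/(k_cat[E]))` (varying B; symmetrically for A). Those
closed-form lines and the intersection point serve as oracles for the fitted
diagnostics.

Internal units are μM (concentrations), minutes (time), nM (enzyme), hence
velocities in nM product·min⁻¹; unit conversion happens only at I/O
boundaries. This keeps the denominator products (up to ~10⁷ μM²) far from
under/overflow. Velocity is defined as exactly 0 when either substrate
concentration is 0, removing the 0/0 at the double-zero corner.

## Synthetic assays

The generators emulate the study's designs and are the only "data" the
analyses see; all are driven by explicit seeds (no global random state) and
reproduce their closed-form models exactly at zero noise.

* **Noise model.** Multiplicative Gaussian with coefficient of variation `cv`
  plus an optional additive Gaussian term. Luminescence error is dominated by
  signal-proportional components, hence the CV form; the additive term covers
  read noise. Defaults used in the simulation studies: 5% CV, 3 replicates
  per grid cell — a conventional plate-assay regime, not a measured property
  of the original experiment.
* **Velocity tables.** Full factorial over the printed grid (UDP-GlcNAc
  {1000, 500, 250, 125, 62} μM × LacNAc {25000, 12500, 6250, 3120, 1560} μM)
  at 1.25 nM enzyme.
* **Progress curves.** `dP/dt = v(a₀−P, b₀−P)` with both substrates depleting
  1:1 with product and no product inhibition (the fitted law carries no
  product terms). Integration is fixed-step classical Runge–Kutta with step
  ≤ 0.1 min subdividing the caller's sample intervals, plus a conservation
  clamp `P ≤ min(a₀, b₀)`; the dynamics are smooth and non-stiff at these
  magnitudes, so the fixed step is accurate to ~10⁻¹⁰ relative on the scales
  tested. Readout is `background + RLU/μM · P(t)` plus noise. Plate fixtures
  use one shared 0–120 min clock read every 5 min, the natural design for a
  "start wells at offsets, quench together" assay; at the study's
  concentrations this keeps conversion at 0.2–1.3%, so initial-rate bias from
  depletion stays well under 1%.
* **SPR sensorgrams.** 1:1 Langmuir binding `R(t) = Req(1−e^(−(k_on·C+k_off)t))`
  with `Req = Rmax·C/(K_D+C)`, exponential dissociation from the stop value,
  a square bulk-refractive-index pulse during the injection (both cells), a
  baseline drift whose slope differs between active and reference cell (so
  blank cycles are genuinely required for exact correction), and an optional
  active-cell-only "solvent mismatch" term keyed to the reference-cell bulk
  excess — the quantity solvent-correction calibrations map in practice.
  Defaults: the printed 5-point 1:3 series (200…2.47 μM), 60 s association,
  120 s dissociation, 10 Hz sampling.
* **SEC.** Elution volume inverted from a log-linear calibration
  `log10(MW kDa) = intercept + slope·V`; standards are thyroglobulin (670),
  γ-globulin (158), ovalbumin (44), myoglobin (17) and vitamin B12 (1.35 kDa).

What the generators do **not** model: product inhibition, enzyme inactivation
over long incubations, plate position effects, SPR mass-transport limitation,
heterogeneous ligand, or baseline jumps. Passing tests therefore demonstrate
correctness of the inferential machinery under the stated error model, not
robustness to every artifact of real instruments.

## Velocity extraction

The UDP standard curve is fitted by OLS (signal on concentration); traces are
converted by inverting that line (slightly negative concentrations near
background are kept, not clamped, to avoid biasing regressions). The linear
range of each progress curve is the longest prefix window satisfying both a
conversion cap — product ≤ 10% of the limiting substrate, bounding depletion
bias — and local linearity r² ≥ 0.99 with at least 4 points; flat traces
count as linear with slope 0. The initial velocity is the least-squares slope
over that window with its regression standard error, reported in nM/min
without normalizing by enzyme (k_cat emerges from the global fit, which
carries [E] explicitly). Negative fitted velocities are retained with a flag.

A note on the conversion cap: the 10% rule is a guard, not a target horizon.
On a window that actually consumes 10% of a sub-saturating limiting substrate
(e.g. the 62 μM donor cells, far below K_A = 216 μM) the OLS slope is biased
low by ~3.5%; an assay designed for initial rates keeps conversion well below
the cap, as the default plate fixtures do.

## Mechanism inference

* **Diagnostics.** Per-fixed-level OLS lines in (1/conc, 1/v) space
  (nonpositive velocities excluded with a warning), then extra-sum-of-squares
  F-tests: common slope vs free slopes ("parallel" ⇒ ping-pong) and common
  intercept vs free intercepts ("on the y axis" ⇒ compulsory order), at
  p = 0.05 by default. On numerically exact data the F statistic degenerates
  (RSS → 0); the implementation then decides directly from whether the
  constrained model also fits exactly. Families of identical lines are
  flagged degenerate. Reciprocal space is used **only** for diagnostics —
  its error structure is too distorted for estimation.
* **Global fits.** All observations fitted at once in velocity space,
  minimizing Σ(v_obs − v_model)² with unit weights by default (a weights
  hook exists; 1/v weighting is the efficient choice under pure CV noise).
  Parameters are fitted as logarithms, which enforces positivity without
  constraints. Multi-start is deterministic: k_cat from max(v)/[E] ×
  {0.5, 1, 2}; K_A, K_B from the geometric mid-range of each substrate's
  levels × {0.2, 1, 5}; α ∈ {0.1, 1, 10}; Levenberg–Marquardt from every
  start, best RSS wins, ties broken by lowest k_cat. Standard errors are
  asymptotic (Jacobian at the optimum, delta method back to natural scale);
  non-convergence is reported in the result object, never raised.
* **Model comparison.** AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) across the
  three candidate laws (k = 4 for random-order, 3 otherwise; [E] is fixed,
  never fitted); the minimum wins.
* **Bootstrap.** Case-resampling percentile intervals (2.5/97.5), refitting
  from the base estimates. Resampling is over the whole observation pool by
  default: resampling **within** grid cells keeps the design balanced but,
  with r replicates per cell, shrinks the resampling variance by (r−1)/r —
  at r = 3 that is a 18% understatement of the standard error, measured here
  as 95%-interval coverage of 85–87% instead of 93%. The within-cell scheme
  remains available (`stratify_by_cell=True`) for designs with many
  replicates per cell.

### Identifiability of α on this design

α is determined by how the apparent K of one substrate shifts across the
other's levels; with the printed grid topping out at ~0.74 saturation of K_B,
it is the weakest-determined parameter. Gauss–Newton asymptotics at the
published constants give se(log α) ≈ 0.20 for the unit-weight estimator and
≈ 0.156 for the efficient 1/v-weighted estimator at 5% CV with 3 replicates
— i.e. a best attainable median relative error of ~10.5%, against ~1.5%
(k_cat), ~7.7% (K_A) and ~9.3% (K_B) observed for the default estimator.
Tightening α on this design requires more replicates or a wider acceptor
range, not a different fitting algorithm.

## SPR processing and affinity fits

Double referencing computes `active − reference − (blank_active −
blank_reference)` on the active cycle's time base (linear interpolation when
grids differ but overlap), which removes the bulk pulse and both cells'
drift exactly under the generator's additive model; the reference cell's bulk
excess during the injection is recorded as the key for solvent correction,
which subtracts a monotone calibration map's interpolated value (zero map =
identity; out-of-domain keys warn and clamp to the edge). The equilibrium
response is the mean over the final 10% of the association phase, flagged
non-equilibrium if still rising > 5% across that window. The steady-state fit
is least squares of `Rmax·C/(K_D+C) + offset` with log-parameterized K_D and
Rmax, the offset seeded at 0; it reports the saturation fraction at the top
concentration and warns when that is below 0.5 (K_D then rests on the
curvature of a nearly linear isotherm — the study's weak-acceptor situation).
The kinetic 1:1 fit shares one (k_on, k_off, Rmax) across all cycles;
dissociation-only input recovers k_off from the log-linear decay and flags
k_on unidentifiable. Theoretical Rmax is the standard
`density · (MW_analyte/MW_ligand) · valency`.

## Problem sizes

The simulation studies use 100 seeded plates for mechanism-selection
reliability, 200 for parameter-error medians, and 100 × 500 bootstrap refits
for coverage — enough for ±3–5% Monte-Carlo error on the reported rates,
which is the precision the acceptance bands require.

## Known limitations

* Product inhibition by UDP is ignored throughout (no product terms in the
  fitted law); real progress curves bend earlier than the simulated ones.
* The diagnostic F-tests inherit reciprocal-space heteroskedasticity; they
  are decision aids, matching how such plots are used, not calibrated
  hypothesis tests under the velocity-space error model.
* The SPR kinetic fit assumes instantaneous mixing and no mass transport;
  with the fast off-rates simulated here the steady-state K_D is the robust
  quantity, mirroring why steady-state affinities are preferred for such
  binders.
* SEC mass estimation assumes globular standards and analyte; shape effects
  are not modelled.
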
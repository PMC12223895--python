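# Methods

## Models

**Kinetics.** Extraction is modelled on the extracted-fraction scale
f(t) = m_l/m_tl ∈ [0, 1], where m_tl is the total lipid basis of the kernel
(g per 100 g). The pseudo-first-order model 1 − exp(−k₁t) has a single rate
constant; the Brimberg model 1 − exp(−k₂tⁿ) adds an exponent n that makes
the instantaneous rate time-dependent, capturing the fast "washing" of
surface oil (n < 1) ahead of slower matrix diffusion. It reduces exactly to
the first-order model at n = 1, and n is deliberately not capped at 1: the
form is well defined for any n > 0. Time is minutes and rate constants
min⁻¹ in the kinetics modules; the diffusion module uses seconds and m²/s.
No unit conversion is ever implicit.

The normaliser m_tl is a *required* input wherever real data are loaded.
For this kernel two defensible bases exist — total lipids by exhaustive
extraction (64.19 g/100 g) and hexane-extractable lipids (55.68 g/100 g) —
and the choice changes every fitted constant, so the package refuses to
guess. The synthetic generator defaults to 64.19 because its ground truth
is self-consistent either way.

**Temperature dependence.** Rate constants are regressed on the linearised
Arrhenius form ln k = ln k₀ − Eₐ/(R·T) by ordinary least squares (this is
what an "Arrhenius plot" estimates; nonlinear fitting of k = k₀e^(−Eₐ/RT)
would weight the high-k points more). R is fixed at 8.314 J mol⁻¹ K⁻¹.
The pipeline feeds the *pseudo-first-order* constants into this regression:
for this system the fitted Brimberg k₂ decreases with temperature because
it is entangled with the simultaneously varying exponent n, which an
Arrhenius law cannot represent, while k₁ rises monotonically and yields
Eₐ ≈ 27.5 kJ/mol. The function itself accepts any positive rate series.

**Diffusion.** The spherical-Fick series
M_t/M_∞ = 1 − (6/π²) Σ_{n≥1} n⁻² exp(−n²π²D_e t/R²) assumes a homogeneous
sphere, constant surface concentration and constant D_e. Its long-time
one-term truncation 1 − A·exp(−Bt) is the fitted model; A is estimated
freely rather than pinned to the spherical value 6/π² ≈ 0.608, because
surface washing removes part of the oil non-diffusively and inflates the
apparent A (fitted values near 1 here). D_e is recovered from B = D_eπ²/R²
given a particle radius. Since the study system's particle radius is not
reported, the default radius 1.22700 mm is back-calculated from the
published 25 °C anchor pair (D_e = 1.8×10⁻¹¹ m²/s, B = 1.18×10⁻⁴ s⁻¹) by
the exact inversion R = π√(D_e/B); every report echoes the radius used.
With an anchored radius, D_e ratios across temperature equal B ratios
exactly.

## Numerical choices

- Least squares uses Levenberg–Marquardt (`scipy.optimize.least_squares`,
  `method="lm"`) on **log-parameters**, which enforces positivity without
  bounds; step/cost/gradient tolerances are 1e-10 with at most 10⁴
  evaluations. Estimates and delta-method standard errors are reported on
  the natural scale. Non-convergence flags the result but still reports the
  statistics at the returned point.
- Initialisation: k from the last observation via −ln(1 − f_last)/t_last
  (rescaled by t_last^(−n₀) for Brimberg), n₀ = 0.5 — inside the range seen
  for washing-dominated extractions. The diffusion fit starts from the
  log-linearisation ln(1 − f) = ln A − Bt.
- R² is computed as 1 − SSE/SStot. For constant observations (zero total
  sum of squares) R² is 1 for an exact fit and NaN otherwise; the degenerate
  flat-data case is documented rather than assigned a parameter value.
- Both RMSE conventions are always reported because published tables mix
  them: the kinetic reference table matches √(SSE/(N − p)) (e.g.
  √(0.1425/5) = 0.1688) while the diffusion reference table matches √SSE
  (√0.0113 ≈ 0.1062). Reports name the convention of each field.
- Observation counts behind the reference tables' adjusted R²: 6 kinetic
  points (the 15–240 min grid, no t = 0 anchor) and 9 diffusion points,
  each with p = 2; these are the only integer counts consistent with all
  printed (R², R²_adj) pairs. Two printed values are internally
  inconsistent (the kinetic 60 °C SSE of 0.528 against its own RMSE, and
  the kinetic 50 °C adjusted R² of 0.984) and are treated as typos — they
  are carried in the reference CSVs as printed but asserted nowhere.
- The full Fick series is truncated when the next term falls below 1e-12
  (or at 10⁴ terms); at t = 0 the value is exactly 0 by the Basel-sum
  normalisation. The long-time model's reported value is floored at 0,
  since a fitted A > 1 makes the raw expression negative at small t.
- The brute-force grid search over k ∈ (0, 1], n ∈ (0, 2] exists purely as
  a test oracle for the optimizer; the (k, n) SSE surface has a strong
  correlation ridge, so grid minima are compared to LM by SSE and only
  coarsely by parameter location.

## Synthetic data

The generator mirrors the bench design: 6 withdrawals at 15, 30, 60, 120,
180, 240 min; temperatures 25, 50, 60 °C; optional Arrhenius-consistent
rate constants; noise_sigma = 0.02 on the fraction scale for stochastic
checks (the scale of gravimetric replicate scatter); 9-point long-duration
grids (5 min–4 h) for diffusion curves. Noise is additive Gaussian on the
fraction, truncated to [0, 1] afterwards with truncation events counted in
the ground-truth record. One integer seed spawns independent per-dataset
substreams (`numpy.random.SeedSequence`), making outputs byte-identical
across runs.

What the generator does *not* emulate: heteroscedastic or multiplicative
measurement error, correlated residuals from cumulative sampling, particle
size distributions, or solvent-loss artefacts. Passing recovery tests
therefore certify the estimation machinery under idealised noise, not the
field accuracy of the models on real kernels.

Test problem sizes (200 replicates for stochastic recovery, 100 seeds for
the end-to-end activation-energy check, 20 random instances for the
optimizer/oracle comparison, 10⁶-term series oracle at a single point) were
chosen to make medians stable while keeping the default suite fast.

## Known limitations

- Only spherical geometry and constant D_e; no slab/cylinder, shrinking
  particles, or variable surface concentration.
- No weighted or replicate-level (mixed) regression and no AIC/BIC model
  comparison; ranking uses adjusted R² with an RMSE tie-break.
- FAME totals are plain sums of area percentages with no renormalisation
  to 100 %, matching how such tables are published.
- The one-term diffusion model is biased at short times (B·t ≲ 1); fitting
  it to curves rich in early points inflates A and B. The series/truncation
  gap is bounded by the first neglected term only for B·t > 5.
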
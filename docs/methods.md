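# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `nanopbpk`, and what the test suite does and does not
establish about real data.

## Model structure and assumptions

The model is a seven-state linear, time-invariant compartment system:
five concentrations (plasma, lungs, MPS = liver + spleen, kidneys, lumped
"others") and two cumulative excreted masses (urine, feces). Its
assumptions:

* **Perfusion-limited transport.** Organ uptake is governed by blood flow,
  not membrane permeability: influx into organ *i* is Q_i·C_p. All organs
  hang in parallel off the plasma pool; the lungs are treated like every
  other parallel compartment even though their blood flow is numerically
  close to cardiac output. (The mouse literature flows — Q_lu = 667 mL/h
  against Q_mps + Q_k + Q_o = 251 mL/h — are mutually inconsistent with a
  series pulmonary circulation, so the parallel reading is the only
  self-consistent one.)
* **Unbound-fraction gating.** Only the unbound fraction f_i of particles
  in an organ re-enters circulation (outflux Q_i·f_i·C_i). The bound pool
  (1 − f_i)·C_i is immobile except for elimination.
* **First-order excretion from two organs only.** The kidneys eliminate
  bound particles into urine at rate k_e,k (h⁻¹), the MPS into feces at
  k_e,mps. The excretion term enters the concentration equation as
  −(1 − f_i)·k_e,i·C_i and the matching mass flux into the excreta pool is
  scaled by V_i — the unique placement that closes the mass balance
  exactly (every column of the amount-space rate matrix sums to zero).
* **Linearity.** No saturable uptake, no protein-corona kinetics, no
  tumor compartment, no radiolabel decay. Doubling the dose doubles every
  trajectory.
* **Unit density.** Organ volumes equal organ weights at 1 g/mL, which
  also makes %ID/g and %ID/mL interchangeable.

Default simulation units are %ID (dose normalised to 100) so model output
is directly comparable to percent-injected-dose-per-gram data without
knowing the absolute dose; an absolute µg mode exists for NCA, where the
standard murine regimen (20 mg/kg × 0.02 kg = 400 µg) is the default dose.

## Parameters

Physiology (volumes, flows, body weight) is fixed per species from the
packaged tables; the lumped MPS and "others" volumes are sums of organ
weights (liver + spleen; heart + brain + GI + muscle + parotid + thyroid
in humans). The eight nanoparticle-specific parameters are

| parameter | units | meaning |
|---|---|---|
| f_lu, f_mps, f_k, f_o | – (∈[0,1]) | unbound fraction per organ |
| k_e,mps, k_e,k | h⁻¹ | excretion rate constants (feces, urine) |
| Q_mps, Q_o | mL/h | empirical organ blood flows |

Q_mps and Q_o are *fitted* even though literature values exist: fitted
nanoparticle-effective flows deviate substantially from the physiological
ones (e.g. mouse Q_mps ≈ 3 mL/h for mesoporous spheres versus 113 mL/h
physiologically), reflecting that access of particles to the organ is not
simply bulk plasma flow. For the packaged human C-dot set, the fitted
Q_mps (80,854 mL/h) supersedes the physiological 87,000 mL/h in
simulations. One packaged cell is flagged as a source-internal conflict:
the Meso renal excretion constant is 3.41 h⁻¹ in the parameter table but
3.357 h⁻¹ in the accompanying narrative; the table value is packaged.

## Numerics

* **Integration.** The system is stiff — the plasma turnover time is
  ~8 s in the mouse while organ retention spans days — so the default
  integrator is LSODA with rtol 1e-8, atol 1e-10 and an analytic Jacobian.
  Because the system is LTI, an exact propagator via eigendecomposition of
  the rate matrix (with a per-interval matrix-exponential fallback for
  near-defective matrices) is available as `method="expm"`; calibration
  and sensitivity analysis use it internally for speed and exactness. The
  two routes agree to ≤ ~2×10⁻⁷ relative on all packaged parameter sets;
  the suite checks them against an independently constructed matrix
  exponential.
* **Calibration.** Bounded nonlinear least squares (trust-region
  reflective) on replicate means over all observed compartments. Bounds:
  f ∈ [0,1], k_e ≤ 100 h⁻¹, fitted flows ≤ the species' lung blood flow
  (a cardiac-output proxy) to keep them physiologic. Starting values
  default to the packaged set of the matching nanoparticle, else the
  bound-box midpoint, with 8 additional Latin-hypercube starts against
  local minima. Residuals are plain (model − observed) in %ID units by
  default. A log-scale objective (`log_residuals=True`) is provided and
  is the statistically matched (Gaussian-MLE) choice when measurement
  error is multiplicative, as in the synthetic generator; on such data it
  also conditions the problem far better — the plain objective is
  dominated by the numerically large lung concentrations and leaves the
  renal parameters poorly determined at 5% noise, while the log objective
  recovers all eight parameters to a few percent. The recovery studies
  therefore use the log objective.
* **Uncertainty.** Parameter covariance is the linearised (Jacobian-based)
  estimate s²(JᵀJ)⁻¹; confidence intervals use Student-t quantiles on the
  residual degrees of freedom, and trajectory bands use the pointwise
  delta method with forward-difference gradients. These are
  approximations; no profile-likelihood or resampling intervals are
  computed.
* **NCA.** Linear trapezoidal AUC with interpolated interval boundaries
  (hence exactly additive); no back-extrapolation before the first
  observation. λz uses the standard best-fit rule — log-linear regression
  over the last k = 3…n positive points maximising adjusted R², requiring
  a negative slope. Accumulating profiles (no decaying terminal phase)
  propagate "unavailable" (NaN) into AUC₀–∞, CL, V_d,ss and T½, matching
  how accumulating MPS compartments must be reported. AUMC uses the
  trapezoid on t·C plus the exponential tail C_last·t_last/λz + C_last/λz².
  C_max ties break to the earliest time.
* **GSA.** Ten independent Latin-hypercube replicates of 100 samples
  (1,000 model evaluations), each parameter perturbed ±50% around its
  baseline; unbound fractions are clipped at 1 after perturbation (the
  affected upper strata collapse onto the bound — clipping, not truncated
  resampling, and it is logged by the stratification tests). Outputs are
  the trapezoidal AUC from 0–500 h per concentration compartment on a
  400-point log-dense grid (converged to <0.1% against 10× refinement)
  plus the final cumulative urine and feces masses. Sensitivity indices
  are standardized regression coefficients from a joint z-scored OLS —
  the conventional MLRA definition, invariant to parameter units; ranking
  uses |SI|, with one-way ANOVA and Tukey HSD across replicates at
  α = 0.05. Volumes and the fixed lung/kidney flows are excluded: they
  are physiological constants, not nanoparticle properties.
* **Scaling.** Rate constants scale as P_h = P_m·(BW_h/BW_m)^(−0.25)
  (≈ 0.13 for 0.02 kg → 70 kg); only k_e,k and k_e,mps are scaled.
  Unbound fractions carry over as species-portable initial guesses and
  the empirical flows are replaced by the target species' physiological
  values — the assembled set is explicitly a starting point for
  recalibration against clinical data, not a prediction. The human model
  keeps the feces pathway structurally even when only urine is observed.

## Synthetic data

The generator emulates the layout of a radiotracer biodistribution study:
tissue concentrations at 5 min (encoded 1/12 h), 30 min, 2 h, 24 h and
72 h with n = 5 replicates, and cumulative urine/feces at 2, 24, 48 and
72 h. Noise is multiplicative log-normal with a mean-preserving
parameterization (σ² = ln(1 + CV²), default CV = 5% — a stand-in, since
the source study reports no inter-animal variance figures) applied
independently per observation. It does **not** emulate gamma-counter
counting statistics, radiolabel decay, organ-harvest mass variability, or
correlated errors within an animal. Passing recovery tests therefore show
that the estimator is correct and well-conditioned under the assumed
error model at the study's sampling design — not that real in vivo data
of this design would determine the parameters equally well.

## Scope and limitations

* The packaged kinetic parameter tables are reference values, not refit
  here: the original in vivo and clinical concentration data exist only
  as published figures, so goodness-of-fit statistics against them
  (Pearson R ≈ 0.97–0.99) and human NCA absolute values are not
  reproducible from this package. A soft consistency check instead
  verifies that simulation under the packaged mesoporous-sphere
  parameters lands in the same order of magnitude as the data-derived
  plasma and lung exposures, with the characteristic lung ≫ plasma
  pattern.
* The human mass dose for C dots is not determinable (activity-based
  dosing of a 44–158 kDa-coated particle), so human NCA is limited to
  shape, not absolute clearance values.
* Several cells of the packaged mouse NCA reference table suffered
  run-together typesetting in the source; ambiguous entries carry a
  `parsed-with-caution` provenance flag and are excluded from
  quantitative checks.
* At the mesoporous-sphere baseline the global sensitivity of the kidney
  AUC to f_k is intrinsically small: raising f_k drains the kidney faster
  (lowering its AUC) but also raises total renal throughput (raising it),
  and the two effects nearly cancel (local elasticity ≈ −0.04). Rankings
  of near-zero sensitivities are correspondingly unstable between
  replicates; the stable findings are that f_k and k_e,k dominate the
  urine output and plasma-side exposure, and k_e,mps and f_mps the MPS
  side.
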
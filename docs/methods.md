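# Methods

This note records the models implemented in micellekit, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## CMC breakpoint estimation

Model: the response is continuous and piecewise linear in the transformed
concentration x,

    y(x) = a + b₁·min(x − x_b, 0) + b₂·max(x − x_b, 0),

so continuity at the breakpoint is structural, not a penalty.  For fixed
x_b this is linear least squares; x_b is found by scanning candidates at
the observed abscissae that leave at least three points on each side, then
refining inside the bracketing interval with bounded scalar minimization
(tolerance 10⁻¹⁰ of the abscissa span).  On noiseless piecewise-linear
input the planted kink is recovered to optimizer precision with RSS at
rounding level — provided the sampling leaves three points per branch; a
kink closer than three points to either end of the grid is treated as not
identifiable rather than extrapolated.

Abscissa transforms follow each technique's plotting convention: log₁₀ c
for surface tension and fluorescence, linear c for conductivity and the
UV/vis peak position; all overridable per call.  The optional
`constrain_post_slope_zero` flag forces a horizontal second segment
(surface-tension plateau convention).

Detection guard: a one-segment line is compared with the two-segment model
by an F-test counting the breakpoint as a parameter (k = 4, or 3 when the
post-slope is constrained) at α = 0.05.  Perfectly collinear data are
reported as "no breakpoint" before the test (both RSS at rounding level).

Uncertainty: residual-resampling bootstrap (default 1000 replicates,
explicit seed required).  Raw least-squares residuals underestimate the
noise because k parameters have been absorbed, so residuals are inflated by
√(n/(n−k)) before resampling — the standard variance correction, and on
n = 15 series it is what brings the empirical coverage of the percentile
interval to its nominal level.  Pairs resampling was rejected because the
design points (the dilution series) are fixed by the experiment.

Cross-technique consensus flags any pair of detected CMCs differing by more
than 10×, the signature of a probe-binding artifact rather than a genuine
micellization onset (anionic-probe assays can report apparent CMCs two
orders of magnitude below colligative-property techniques).

## Gibbs adsorption isotherm

Γ = −(1/RT)·dγ/d ln c with the Gibbs prefactor n = 1 (the slope is treated
as that of a single adsorbing species; an ionic 1:1 treatment would halve
Γ and is left to the caller via the slope itself).  The natural-log basis
is the default because quoted tensiometry slopes in mN m⁻¹ "per unit log c"
are commonly per ln c; a `log_base="log10"` option divides by ln 10 for
per-decade slopes.  Default temperature 293 K (20 °C).  A = 10²⁰/(N_A·Γ)
in Å², and p = round(4πR²/A) assumes the interfacial area per molecule
transfers unchanged to the micelle core surface — an upper-bound estimate,
since the curved, corona-bearing micelle surface accommodates fewer heads
than a flat air–water interface.

## Absolute-intensity association number

M_mic = I(0)·N_A/(c·r₀²·v_p²·Δρ²) with r₀ = 0.28179×10⁻¹² cm and Δρ in
e cm⁻³.  Assumptions, in decreasing order of importance:

* **Tail-only contrast.**  The scattering contrast is the alkyl tail vs
  water; the peptide corona is ignored.  ρ_l = 129 e / v_l(Tanford),
  v_l = 27.4 + 26.9n Å³ with n = 15 for a C16 tail.  An extension hook
  (`ContrastModel.with_`) accepts any ρ_l for a two-component treatment.
* **Quoting precision.**  Electron densities are rounded to 3 decimals
  (1 mₑ Å⁻³) by default — the precision at which they are tabulated and
  combined in this analysis tradition; `rho_decimals=None` disables it.
  With the C16/water pair the rounding moves Δρ from 0.0336 to 0.0340
  e Å⁻³ and M_mic by ~2%.
* **Dilute limit.**  I(0) is used as measured (no S(0) correction), and the
  micelle concentration is the total concentration (monomer fraction
  ignored); both make M_mic an estimate rather than a measurement when
  micelle–micelle interference or free monomers are present.
* **wt% → g cm⁻³** at solution density 1.00 g cm⁻³ (1 wt% = 0.01 g cm⁻³).
* Default v_p = 1.15 cm³ g⁻¹ (≈ 259.5 cm³ mol⁻¹ / 225 g mol⁻¹ for an
  alkyl tail).

The implementation is validated against an explicit step-by-step SI
conversion oracle to < 10⁻⁹ relative.

## SAXS micelle model

    I(q) = scale_mic · ⟨|F_cs(q)|²⟩_poly · S_PY(q) + f_mono · P_coil(q) + background

* **Core–shell sphere**: F(q) = V_o(ρ_s−ρ_w)f(qR_o) + V_i(ρ_c−ρ_s)f(qR_i),
  f(x) = 3(sin x − x cos x)/x³ with a Taylor branch below x = 0.05 for
  stability (error < 10⁻¹²).
* **Polydispersity** is Gaussian on the core radius R_i with the shell
  thickness R_o − R_i held fixed, truncated at ±3σ and renormalized,
  41-node Gauss–Legendre quadrature.  Placing the width on R_i keeps the
  shell a chemically meaningful, composition-determined quantity; the σ
  bound R_i/3 keeps the truncated weight negligible.
* **Percus–Yevick hard spheres**: the analytic direct-correlation-function
  solution with two parameters (R_hs, φ).  Below A = 2qR_hs = 0.1 a series
  expansion of G(A)/A (through A²) replaces the trigonometric form, which
  cancels catastrophically there; the series reproduces the compressibility
  limit S(0) = (1−φ)⁴/(1+2φ)² exactly.  φ is capped below random close
  packing (0.64).  The structure factor multiplies the polydispersity-
  averaged intensity (monodisperse approximation; no decoupling
  correction) — the minimal-parameter choice appropriate to weakly
  structured micellar solutions.
* **Generalized Gaussian coil** (monomer term): the excluded-volume chain
  form factor built from lower incomplete gamma functions with
  U = (2ν+1)(2ν+2)(qRg)²/6; at ν = ½ it reduces to the Debye function to
  < 10⁻⁶, and ν ∈ [0.3, 1.0].
* **Forward intensity** `forward_intensity` reports the micelle term's
  q → 0 limit *excluding* S(0), the coil term and the background: a dilute
  extrapolation suitable for the molar-mass analysis above.

Fitting: bounded trust-region least squares (scipy `least_squares`, `trf`,
numerical Jacobian, `x_scale="jac"`) on (I_obs − I_model)/σ.  Internally
R_o is parameterized as R_i + thickness so the bound thickness > 0
preserves ordering throughout optimization.  Missing σ columns are
synthesized as 2% of I with a floor of 10⁻⁴·max I.  Parameter
uncertainties come from (JᵀJ)⁻¹ scaled by reduced χ²; non-convergence is
flagged in the result, and an optional multi-start mode (seeded ±10%
jitter of the initial vector) adds robustness on rugged problems.

## Aggregation propensity

AP = mean(SASA over an initial window)/mean(SASA over a final window).
Windows default to the first 2% (widened if needed to hold five samples)
and the last 25% of the trace.  The initial value is window-averaged
rather than read at t = 0 for noise robustness; the cost is a downward
bias of order (1 − ⟨e^(−t/τ)⟩_window) in the numerator when the decay time
τ is comparable to the window — with the default tight window the bias is
~1%.  The propagated error combines the two windows' standard errors of
the mean in quadrature, treating frames as independent; correlated MD
frames make it a lower bound.  `plateau_check` declares equilibration when
the |least-squares slope|/mean over the final window is below 1%/ns.

## Synthetic generators

All generators require an explicit seed, are bit-reproducible under it,
and emit a JSON truth sidecar of the planted parameters.

* `gen_titration`: continuous two-segment response on the technique's
  conventional abscissa with additive Gaussian noise (instrument-limited
  detectors); geometric concentration grids for log-abscissa techniques.
  Defaults emulate the C16-lipopeptide study conditions: a surface-tension
  plateau at 51 mN m⁻¹ reached with a pre-CMC slope of ≈ −10.8 mN m⁻¹ per
  ln c (−24.9 per decade), conductivity and UV/vis slope changes at the
  CMC, saturating fluorescence wavelength shift.
* `gen_saxs`: the full intensity model re-implemented by direct formula
  transcription — scalar sphere amplitudes, adaptive Gauss–Kronrod
  quadrature (rel. tol. 10⁻¹¹) for the polydispersity average — with *no
  shared helpers* with `saxs_model`.  This dual implementation is the
  primary correctness oracle: the two routes agree to < 10⁻⁸ relative on
  noiseless curves (measured ~10⁻¹⁴).  Noise is multiplicative Gaussian
  (counting statistics scale with signal), default 2%, with the σ column
  emitted.  Default grid: 200 points, q = 0.005–0.48 Å⁻¹.
* `gen_sasa`: S(t) = S_∞ + (S₀−S_∞)e^(−t/τ) with multiplicative Gaussian
  noise (default 1%), emulating micelle-relaxation SASA traces that
  plateau within a few ns.

What the generators do **not** emulate: smooth (non-piecewise-linear)
pre-transition curvature in titrations, q-resolution smearing, inter-batch
background mismatch or low-q aggregate upturns in SAXS, and autocorrelated
noise in MD traces.  Passing recovery tests therefore demonstrates
estimator correctness under the stated noise models, not robustness to
every instrument artifact.

## Problem sizes and numerical defaults

The test and acceptance workloads run at the scale of the emulated study:
titration series of n = 15 points, bootstrap with 1000 replicates and a
50-seed coverage study at 2%-of-range noise; SAXS fits on 200-point curves
at 2% noise over 10 seeds; SASA traces of 2000–5000 frames.  Key numerical
constants: breakpoint refinement tolerance 10⁻¹⁰ of the abscissa span;
form-factor series switch at x = 0.05; PY series switch at A = 0.1;
41 polydispersity nodes; optimizer capped at 4000 function evaluations.

## Known limitations

* The Gibbs analysis offers no ionic prefactor option beyond rescaling the
  slope; counterion-binding corrections are out of scope.
* The two-segment model cannot represent gradual micellization (broad
  transitions) — a sigmoid-transition model would be the next step.
* The SAXS model has no instrument-resolution smearing and no decoupling
  correction for polydisperse structure factors.
* M_mic from I(0) inherits every contrast-model assumption listed above;
  for monomer-rich systems it is a lower-bound estimate.
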
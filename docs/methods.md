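# Methods

## Kinematic reduction

All quantities are engineering (nominal): strain `ε = (L − L₀)/L₀`,
stress `σₙ = F/A₀` (kPa; N/mm² inputs are converted), strain rate
`ε̇ = L̇/L₀`. The material is treated as incompressible, and uniaxial
extension with traction-free lateral faces is imposed by substitution:
`λ₁ = λ = 1 + ε`, `λ₂ = λ₃ = λ^(−1/2)`, so `det F = 1` exactly and the
pressure (Lagrange multiplier) of the general incompressible stress
relation is eliminated. The nominal stress then reduces to a plain
derivative, `σₙ = dW/dλ`, which every model implements analytically.

The fiber pseudo-invariant is the squared stretch along a unit fiber
vector at angle `θ` from the loading axis, the standard `A·C·A`
contraction: `I₄ = λ²cos²θ + λ⁻¹sin²θ`. At the two operating angles this
gives `I₄(0) = λ²` and `I₄(π/2) = 1/λ`. The transversely isotropic
families enter the fiber direction only through these two operating
points during fitting; for off-axis exploration a `loading_axis` mode
(`I₄ = λ²` regardless of `θ`) is selectable, since for a 1-D analytical
treatment either convention is defensible and they differ only off-axis.

## Constitutive families and their quirks

Neo-Hookean, Yeoh and Ogden are the standard isotropic forms (Ogden with
an arbitrary number of `(μₙ, αₙ)` terms, default one). Two points in the
anisotropic families were genuinely open and are resolved as follows:

* **GOH exponent variant.** The GOH anisotropic energy is implemented in
  its standard form, `E = κ(I₁−3) + (1−3κ)(I₄−1)`, which leaves the
  reference configuration stress-free — a physical requirement. A
  circulating variant with an extra `−1` inside the squared exponent is
  retained as `variant="as_printed"` for audit; it predicts nonzero
  stress at zero strain and is never the default.
* **Fiber-term residual stress.** The fiber-matrix energy
  `φ cosθ (E_f/2)(exp(k(I₄−1)) − 1)` has slope `φ cosθ E_f k` at `λ = 1`,
  so for `θ < π/2` the model predicts a small residual stress at zero
  strain. This is a property of the functional form, implemented as
  written and covered by a test; with the calibrated desk-scale constants
  the residual is ≈0.3 kPa against a 59 kPa signal.
* **Tension-only switch.** Whether the GOH fiber term should be disabled
  when fibers are compressed (`I₄ < 1`, e.g. circumferential loading of
  axial fibers) is a modelling choice; the default keeps the term active
  (the literal equations), with `tension_only=True` available. The
  default is also what keeps the energy smooth, which the
  finite-difference oracle tests rely on.
* **Units.** Stresses and moduli are kPa throughout. The collagen fiber
  modulus is conventionally quoted in MPa (literature value 230 MPa for
  type I collagen, with a 20% volume fraction);
  `FiberParams.with_modulus_mpa` converts on ingestion. Note that
  inserting the histological 230 MPa directly into the exponential fiber
  term produces MPa-scale stresses, three orders of magnitude above the
  kPa-scale response of whole tissue — the term lumps fiber recruitment,
  crimp and load transfer into an *effective* modulus, so calibrated
  values are desk-scale kPa numbers, and the literature constants are
  retained only as interface defaults for the frozen constants of the
  fiber stage.

Every analytic stress is verified against a central finite difference of
the energy (step `h = 1e−6` on the stretch) to better than `1e−6`
relative over `λ ∈ [1.01, 1.5]` at both operating angles, and each energy
equals the quadrature integral of its stress.

## Calibration

Curves within an orientation are linearly resampled onto a common strain
grid (51 points on [0, 0.5] by default — the conservative strain window
within which the cross-section change of a soft strip can be neglected)
and averaged; fits target this mean curve. The objective is the plain sum
of squared stress residuals in kPa².

Optimisation is bounded L-BFGS-B with numerical gradients and seeded
multi-start (default 8 starts: the supplied initial point plus uniform
draws within bounds), because the exponential stiffening terms create
local minima. Default boxes and initial values: `C₁ ∈ (0, 10³]` kPa init
1, `C₂, C₃ ∈ [−10³, 10³]` kPa init 1, `μ ∈ (0, 10³]` kPa init 5,
`α ∈ [1, 20]` init 8, `k₁ ∈ (0, 10⁴]` kPa init 100, `k₂ ∈ (0, 10²]` init
1, `κ ∈ [0, 1/3]` init 0.3, `k ∈ (0, 10²]` init 2. Tight internal
tolerances (`ftol = 1e−15`) push noise-free recoveries to the 1e−9 level;
when the line search stalls exactly at an optimum the winner is polished
with a standard-tolerance restart, and an objective at the numerical
floor of the data (residuals below 1e−8 of the data scale) is reported as
converged. A parameter landing within 1e−6 of a bound raises a
`boundary_hit` flag. All randomness flows from one integer seed, so a fit
is bitwise reproducible.

Two protocols:

* **Two-stage (fiber model).** Stage 1 fits the Yeoh matrix on the
  circumferential mean; its prediction is `(1−φ)·σ_yeoh`, the exact
  circumferential response of the full model (the axial fiber term
  vanishes at `θ = π/2`). With `φ = 0` (the default) it is a plain Yeoh
  fit. Stage 2 freezes the matrix, `E_f` and `φ`, and fits the stiffening
  exponent `k` on the longitudinal mean. If the fiber term cannot affect
  the objective (`φ = 0` or `θ = π/2`) the stage emits a
  `FlatObjectiveWarning` and returns the initial `k` untouched instead of
  a spurious estimate.
* **Single-set.** One vector fitted to both orientation means pooled;
  anisotropic families switch `θ` per orientation (0 longitudinal, π/2
  circumferential — `θ` is an operating condition, never a fitted
  constant), isotropic families predict one shared curve. This is the
  protocol of the model comparison, which ranks families by mean percent
  RMSE and isolates per-model failures.

Percent RMSE is `100 · RMS(pred − obs) / mean|obs|`. The normaliser is a
convention, not a law; `range` and `max` are selectable and every report
records which was used. All three are invariant under joint rescaling of
prediction and observation.

## Synthetic data

The generator evaluates a ground-truth model on a strain grid per
orientation and adds optional per-point Gaussian noise, additive (scaled
by `sigma_frac` × the orientation's peak stress) or multiplicative. A
seed is mandatory whenever noise is on; output is bitwise reproducible.

`calibrate_emulation` produces the default study conditions: a
fiber-model parameter set whose circumferential curve reaches 33.01 kPa
at 0.5 strain and whose longitudinal curve reaches 59.4 kPa, with
near-equal slopes below the ≈0.25-strain stiffening onset — the
anisotropic signature measured on distal porcine urethra. The matrix
shape template (C-ratios 3.54 : 38.21 : −14.6) encodes the gradual
circumferential stiffening past ≈0.2 strain and is scaled to the
circumferential anchor in closed form; the exponent `k` is then solved
(1-D least squares) for the longitudinal anchor with `φ = 0.20` and a
desk-scale effective `E_f = 0.5` kPa. Infeasible target sets raise an
explicit report naming each missed anchor. The default noise level,
`sigma_frac = 0.02`, keeps replicate scatter below the per-organ
standard-deviation maxima observed ex vivo (6.9% circumferential, 8.7%
longitudinal).

What the generator does **not** emulate: toe-region recruitment
nonlinearity beyond what the Yeoh template carries, viscoelastic rate
effects, specimen-geometry variability, clamping end effects, and any
microstructural fiber-network behaviour. Passing tests therefore
demonstrate that the calibration machinery recovers known ground truth
and ranks model families correctly on data with the right anisotropic
structure — not that any family is the true model of real tissue.

## Problem sizes

The validation suite and the acceptance script run on 51–101-point strain
grids, one to ten specimens per orientation, 8-start fits, and a 20-replicate
noise study — sizes at which every stage is exact or converged well below
the tolerances asserted, while the full suite completes in seconds.

## Known limitations

* Uniaxial, incompressible, quasi-static only: no shear or biaxial modes,
  no compressible formulation, no viscoelasticity or damage, no FE
  export.
* The fiber model's residual reference stress (above) means its energy is
  not polyconvex-normalised at `λ = 1`; for the calibrated constants the
  effect is negligible but it is reported, not corrected.
* Identifiability: `k` and `E_f` enter the fiber term nearly
  collinearly; only `k` is free by default. Exponential-family constants
  (`k`, `k₂`) are weakly identified in general and are recovered to 1e−2
  relative rather than 1e−3.
* Mean-curve fitting discards specimen-level variance; no uncertainty
  quantification of the parameters is attempted.
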
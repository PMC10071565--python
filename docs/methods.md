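# Methods

## Error model

Each pair of matching half-map Fourier terms is modelled as
F₁ = S + ε₁, F₂ = S + ε₂, where the common signal S and the independent
noise terms ε are zero-mean circular complex normals with variances Σ_S
and Σ_E.  The joint density is a bivariate complex normal with covariance
[[Σ_S+Σ_E, Σ_S], [Σ_S, Σ_S+Σ_E]]; rotating to (F₁±F₂)/√2 diagonalizes it
with variances 2Σ_S+Σ_E and Σ_E, which gives the analytic maximizers of
the summed log-likelihood over any set of terms:

    Σ̂_S = ⟨Re F₁F₂*⟩,     Σ̂_E = ⟨|F₁−F₂|²⟩ / 2.

Both Σ_S and Σ_E vary with direction as well as resolution (preferred
orientations), so these estimators are applied over a small sphere in hkl
index space around every term.  Assumptions worth keeping in mind: the two
half-sets must be independent random splits (the pipeline warns when the
half-map difference power collapses in any shell, the signature of
filtered or duplicated inputs), and the variances must be close to
constant over a neighbourhood.

### Trend-corrected local estimation

The neighbourhood mean is a poor estimator where the field varies steeply
across the sphere: at low resolution the power spectrum changes by orders
of magnitude over a few index steps, and the arithmetic mean is dominated
by the innermost terms.  All local averages are therefore pre-whitened by
an adaptive radial profile (equal-count shell means, width-capped at low
s, log-interpolated) and the trend is restored after averaging.  The
signal-bearing fields share the total-power trend; the difference field
uses its own.  Neighbourhood means for every term at once are circular
convolutions with a spherical kernel over the fftn grid, normalized by
the convolved validity mask.

* Neighbourhood: sphere holding ≈ 100 terms (index radius 3 by default;
  configurable).
* Σ_E floor: 10⁻¹⁰ × mean term power, keeping likelihoods finite.
* Raw Σ̂_S may be negative; it is kept for correlation purposes and floored
  at zero only where a physical power is required (D_obs, normalization).

### Parametric signal model and hybrid estimate

Local Σ_S estimates degrade where the signal is weak, so they are blended
with a parametric model

    Σ_S(h) = A₀² · exp(−½ sᵀ β_A s) · m_b(s) · BEST(s),

with overall scale A₀, anisotropic tensor β_A (Å², capturing overall
anisotropic displacements), and per-resolution-bin multipliers m_b
restrained to one against a reference spectrum.  Fitting details:

* Equal-count resolution bins (default 20); quadratic restraint on log m_b
  with weight rising linearly from 10 (lowest resolution) to 40 (highest):
  low-resolution terms reflect molecular shape and may stray further from
  the reference.  The weights are small compared with the per-bin
  likelihood information wherever the data carry signal, so the restraints
  barely move strong data but pin hopeless bins to the prior.
* Identifiability: the multiplier vector is projected orthogonal to
  span{1, s²} — the overall scale belongs to A₀ and any quadratic falloff
  to the tensor.  Without the projection the three trade off freely.
* Optimization: L-BFGS-B with analytic gradients; tensor entries fitted in
  units of 1/⟨s²⟩ for conditioning; multipliers initialized from binwise
  local estimates (with the projected-out slope seeding the tensor), which
  avoids a stall in the collapsed-signal valley; up to 40 000 terms are
  used (striding if more), tolerance 10⁻⁸ relative.
* Reference spectrum: the original experimental tabulation of the average
  macromolecular power spectrum is not redistributed.  The shipped
  stand-in was built the same way: the ensemble-average spectrum of the
  generator's own object class (coil-like Gaussian-atom clusters, twelve
  realizations, 1.2 Å reference atom width), tabulated and interpolated
  monotonically.  Any two-column (s, power) table can be supplied instead;
  for real data the genuine tabulation should be.  The prior is weak, so
  the choice mainly stabilizes weak bins.

The hybrid estimate is Σ_S = w·local + (1−w)·model with
w = logistic(9·(CC_sphere − 0.95)), where CC_sphere is the local (real
part) half-map correlation.  The defaults (steepness 9, pivot 0.95) mean
the smooth model dominates below CC ≈ 0.8 and still contributes ~38% even
at CC = 1.  The blend is floored at zero.

### Normalization and D_obs

Averaging the half-maps halves the noise variance, so the averaged
coefficient has power Σ_S + Σ_E/2 and

    D_obs = [Σ_S / (Σ_S + Σ_E/2)]^½,   E_mean = F_mean/(Σ_S + Σ_E/2)^½.

For the normalizer the pipeline uses the trend-corrected local mean of
|F_mean|², which is algebraically identical to the local ML estimate of
Σ_S + Σ_E/2 but guaranteed positive and empirically consistent (shell
means of |E_mean|² sit at one).  The hybrid Σ_S feeds D_obs, where the
model's stability in weak regions matters.  This distinction is
deliberate: the likelihood amplifies any per-term normalization mismatch
by 1/(1−x²), which is large exactly where the data are good.

## Likelihood targets

With normalized model coefficients E_C, model quality
σ_A = √f · exp(−2π²Δ²s²/3) (the characteristic function of an isotropic
3-D Gaussian coordinate error with rms radial error Δ; equivalently an
error B-factor 8π²Δ²/3) and x = D_obs σ_A, the conditional distribution of
E_mean given E_C is complex normal with mean x·E_C and variance 1−x².
The per-term log-likelihood gain over the uninformative model (σ_A = 0)
is

    LLG = −ln(1−x²) + [2x E_m E_c cos Δφ − x²(E_m² + E_c²)]/(1−x²),

whose sum splits exactly into a correlation term (linear in model phases),
an amplitude-only scale term and a constant offset; the implementation
computes both forms on every call and verifies agreement to 10⁻⁸.  All
totals are multiplied by the oversampling factor (particle volume / box
volume), which compensates for correlations among neighbouring Fourier
terms in the padded box.

Model coefficients are computed by Gaussian-atom synthesis on the data
grid followed by an FFT, then normalized to unit mean-square power with a
smooth interpolated log shell spectrum (adaptive bins, width-capped at
low s) — a staircase normalizer would be punished severely by the
1/(1−x²) amplification.  A wrong pose has expected total LLG of −Σx²
(its claimed correlation is contradicted), not zero; the zero-mean null
property holds for the correlation part, whose corrected variance is
about twice the corrected eLLG total.

### Rotation target

Orientations are scored before any translation is known, so only
amplitudes carry information: the target is the Rice-likelihood gain

    LLG_rot = −ln(1−x²) − x²(E_m²+E_c²)/(1−x²) + ln I₀(2x E_m E_c/(1−x²)),

evaluated directly for each orientation of a quasi-uniform SO(3) grid
(super-Fibonacci sampling; default step 2·asin(d_min/4R) for model radius
R).  A fast pre-ranking pass interpolates the rotated model amplitude
spectrum trilinearly (amplitudes are exactly the quantity the target
needs); the leading candidates are re-scored by exact synthesis.  No
FFT-based rotation approximation is used.  Ties are broken by grid order.

### Translation target and rigid-body refinement

Only the correlation part of the LLG changes under translation (the model
amplitude spectrum is shift-invariant), so the exact LLG for every grid
translation is a constant plus one inverse FFT of the weighted
data–model coefficient product.  The grid maximum agrees with direct
per-position evaluation to numerical precision.

Rigid-body refinement maximizes the LLG over three perturbation rotations
about the model centre of mass (sequentially about fixed x, y, z axes —
locally near-orthogonal parameters whose numeric Hessian shows small
rotation–translation cross terms), three translations, optionally the
σ_A error Δ (bounds 0.1–3.0 Å, initialized at 1.0 Å, the typical
refined range being ~0.8–1.2 Å) and a cell scale factor (bounds 0.9–1.1)
compensating voxel-size error.  L-BFGS-B with numeric gradients
(step 10⁻³ in degrees/Å/percent units); the best-evaluated point is
tracked explicitly and the reported path is monotone.

The full docking pipeline (orientation scan → FFT translation search for
the leading orientations → refinement at half then full resolution)
flags a solution significant when its translation peak exceeds the grid
spread by 6 standard deviations; the expected maximum of the ~2.6·10⁵
null scores on a 64³ grid is itself ≈ 4.5σ, hence the margin.

## Information measures

Closed forms, per term, with x = D_obs σ_A:

* eLLG_tra = −ln(1−x²): the expectation of the phased LLG over the
  conditional distribution of the model coefficient given the data (the
  cross term in E_m² has zero mean; squared-amplitude correlations are
  dropped, an approximation quantified by a Monte-Carlo test).
* eLLG_rot = −½ ln(1−x⁴): exact quartic small-x limit x⁴/2; the
  tra/rot ratio at x = 0.01 is ≈ 20 000, and total eLLG_rot is inversely
  proportional to the search volume while total eLLG_tra is insensitive
  to it in the weak-signal regime.
* D_KL = −ln(1−D_obs²) nats (bits = nats/ln 2): the expected LLG of a
  perfect model, capped at D_obs = 1−10⁻⁹.  Per shell,
  K·log₂[(1+FSC)/(1−FSC)] with the Rosenthal–Henderson substitution
  D_obs = [2FSC/(1+FSC)]^½ reproduces K·D_KL(bits) exactly; the effective
  independent count K is the raw term count times the oversampling
  factor.

Terms with information below 0.01 bit are discarded after the error
analysis; the threshold is applied to the oversampling-corrected per-term
information by default, with a flag to apply it before correction.

## Synthetic data generator

The generator emulates exactly the statistical structure the error model
assumes — which is its purpose: every estimator can be checked against
recorded ground truth.  Defaults (the study conditions of the test
suite):

* 64³ grid, 1.2 Å voxels; ~300 unit-weight Gaussian atoms (σ = 1.2 Å) in
  a 20 Å-radius sphere, placed as four independent random-walk chains of
  3.8 Å steps.  Several chains fill the sphere much more isotropically
  than one long walk, emulating a globular multi-domain particle; a
  single chain's realized gyration tensor is strongly elongated, which
  would confound tensor-recovery tests.
* Analysis band d_min = 2.5 × voxel (3.0 Å): comfortably inside Nyquist,
  as real band-limited reconstructions are.  Near Nyquist the rendered
  Gaussian-atom spectrum is dominated by grid aliasing, which no real
  reconstruction shows; atom rasterization uses 6σ support to suppress
  truncation-ripple tails for the same reason.
* Signal: either the blurred transform of the atom model ("atoms" mode) or
  a draw from a prescribed Σ_T(s) ("spectrum" mode).  In atoms mode the
  recorded per-term signal power is the trend-corrected local mean of the
  realized blurred power — the ensemble the local estimators actually
  target; the realized single molecule is itself anisotropic, so clean
  injected-tensor recovery tests use spectrum mode, where the injected
  tensor is the only anisotropy.
* Noise: independent Hermitian-symmetric complex-normal fields per
  half-map; the directional shape is 1 + Σ c_j (û·m̂_j)⁴ over unit modes
  (smooth, even, no symmetry required) times an optional resolution
  profile.  The default level is auto-calibrated so the shell-mean D_obs
  crosses 0.5 at half-Nyquist, spanning strong, mixed and weak regimes in
  one fixture.
* One seeded generator; the two half-map noise streams are split from the
  spec seed for independence.  Same seed ⇒ bit-identical output.

What the generator does **not** emulate: CTF effects, per-particle motion
and radiation damage, solvent and masking artefacts, map symmetry, or
model incompleteness physics (f is an input, not emergent).  Passing
recovery tests therefore validate the estimators and targets under the
model's own assumptions; they do not certify behaviour on real maps whose
errors violate them (e.g. band-pass-filtered or masked half-maps, which
the pipeline detects only in the crudest way).

## Problem sizes and tolerances

The test suite works at 48³ (unit tests) and 64³ (recovery and docking
tests, ~35 000 terms); docking searches use 1 500 orientations with the
top 8 carried to translation search.  Recovery comparisons use 8 shells
for noise power (≤5% shell error), 10 for D_obs (≤0.05), and evaluate the
anisotropic falloff ratio at the fixture's calibration resolution
(half-Nyquist).  These sizes give each shell enough terms that the
statistical floor of the comparison sits below the tolerance.  Numerical
guards: x and D_obs capped at 1−10⁻⁹; Σ_E floored as above; ln I₀
computed via the exponentially scaled Bessel function.

## Known limitations

* The sphere-extraction taper (cosine, 3 voxels) is a pragmatic choice;
  masking effects on subvolume statistics are acknowledged but not
  modelled.
* CC_sphere uses the real part of the complex correlation; the modulus
  would be a valid alternative with slightly different small-sample bias.
* The exact blend of the hybrid at CC → 1, the restraint-weight profile
  and the sigmoid's algebraic form are implementation choices around
  stated defaults (steepness 9, pivot 0.95).
* Bulk solvent is not modelled; completeness f is a single effective
  parameter.
* The six-dimensional brute-force subvolume search strategy, multi-copy
  docking, flexible fitting and per-atom B refinement are out of scope.
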
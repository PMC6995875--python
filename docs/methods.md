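# Methods

This note documents the model, the numerical choices, and what the test
suite does and does not establish.

## Transport model

We solve the time-independent radiative transport equation for a layered
half-space under normally incident, sinusoidally modulated collimated
illumination. With the transverse ansatz `L(x, z, ŝ) = ψ(z, ŝ) e^{ikx}`,
`k = 2π fx`, and an order-N real spherical-harmonic expansion of `ψ`, each
homogeneous layer obeys a constant-coefficient system of (N+1)² depth ODEs

    A_z dc/dz + (Σ + k Âx) c = q(z),

where

* `A_z` and `Âx` are the matrices of `cos θ` and `sin θ cos φ` on the
  basis (built once per order by spherical quadrature that is exact for
  the band-limited integrands);
* `Σ = diag(μt − μs g_l)` is the collision operator, `g_l` the Legendre
  moments of the single-scattering phase function (Henyey–Greenstein,
  `g_l = g^l`; any moment sequence can be substituted);
* `q(z) = μs p(ẑ·ŝ) E(z)` is the first-scatter source driven by the
  attenuated reduced intensity `E(z)` of the collimated beam, which only
  excites the m = 0 harmonics.

Two structural reductions, both verified in the test suite, keep the
working system small and real:

* **Azimuthal parity.** The sine-azimuth harmonics decouple and are never
  excited by a normally incident source, leaving the cosine sector of size
  (N+1)(N+2)/2 (55 for N = 9).
* **Realification.** Conjugating by `diag(i^|m|)` converts the complex
  `ik`-coupling into a real antisymmetric matrix, because `sin θ cos φ`
  couples only adjacent azimuthal orders. Eigenproblems are then real; the
  physical reflectance involves only m = 0 coefficients and is real.

### δ-M forward-peak scaling

For g = 0.8 the truncated moment `g^{N+1}` is not negligible at N = 9 and
the plain truncation converges non-monotonically in N at high spatial
frequency (N = 9 vs N = 11 differed by up to 3.6% at fx = 0.5 mm⁻¹). We
therefore apply δ-M scaling by default: the phase function is split into a
forward δ-contribution of weight `f = g^{N+1}` plus a remainder whose
first N moments are exact (`μs → μs(1−f)`, `g_l → (g_l − f)/(1 − f)`);
`μs′` is invariant. With δ-M, successive orders agree to ≤0.31% over the
phantom property range and the full frequency grid, and the N = 9 solver
matched an independent two-layer Monte Carlo to ~0.3% at every frequency
during development.

### Boundary and interface conditions

The per-layer general solution is a particular exponential (following the
beam) plus eigenmodes of the generalized pencil `ν A_z v = −(Σ + kÂx) v`.
The streaming matrix is structurally singular (one null direction per
odd-sized azimuthal block), so the pencil has exactly rank(A_z) finite
modes — 50 for N = 9 — of which half decay with depth. Finite layers keep
all finite modes, with each exponential anchored at its nearest interface
so magnitudes never exceed one (no overflow for optically thick layers);
the terminal semi-infinite layer keeps only decaying modes.

Mode weights are fixed by Marshak-type projections:

* **Top surface.** Half-range conditions over incoming directions with
  internal Fresnel reflection for the ambient/medium index step
  (unpolarized, with total internal reflection; the Fresnel-weighted
  integrals are split at the critical angle so each piece is smooth). Test
  functions are `Y_{l'}^{m}` with `l'−m` odd, `floor((N+1−m)/2)` per
  azimuthal order — 25 conditions for N = 9, matching the 25 decaying
  modes of a semi-infinite medium.
* **Interior interfaces.** Radiance continuity projected onto both
  half-range test sets (50 conditions), treating the interface as
  index-matched: both phantom layers share one refractive index. Media
  whose layers differ in index are rejected rather than approximated.

These are standard constructions; exact layer-collapse (two identical
layers ≡ homogeneous, to machine precision) and the vanishing-layer limit
are regression-tested.

Detection integrates the outgoing radiance over the exit hemisphere with
Fresnel transmission; azimuthal integration leaves only m = 0
coefficients. The reported `Rd` is absolute, specular-excluded diffuse
reflectance per unit incident AC irradiance — the quantity a calibrated
SFDS instrument reports. No instrument transfer function is modeled.

### Parameters and degenerate inputs

* `order` (default 9): accuracy/cost balance; the boundary system for two
  layers is 75×75.
* `mode_floor` (default 1e-9 mm⁻¹): absorption is clamped at this floor.
  A strictly conservative layer at fx = 0 has a zero eigenvalue (no
  exponential mode); the clamp removes the degeneracy at the cost of an
  O(√mode_floor) ≈ 1e-4 perturbation of Rd, visible in the
  energy-conservation test (`Rd(fx=0) = 1` within 1e-3 for μa = 0,
  index-matched).
* `g = 1` is rejected (the reduced problem is undefined); `fx < 0` is
  rejected; eigen-decomposition failures and mode-count mismatches raise
  a conditioning error naming the (λ, fx) cell.
* Refractive indices default to n = 1.4 (tissue/silicone) over n = 1.0
  ambient; both configurable.

## Sensitivities

`∂Rd/∂p` is computed by central differences with relative step 0.01
(absolute step 1e-4 mm⁻¹ when the base value is small, as for weak
absorption), on the instrument grid fx = 0:0.01:0.5 mm⁻¹; reported peak
locations are therefore grid-quantized to 0.01 mm⁻¹. Step-halving changes
the curves by <1%. The decade-decay feature (first grid frequency where
|∂Rd/∂p| falls to a tenth of its planar value) is invariant to curve
rescaling, so it does not depend on the (unnormalized) sensitivity
definition. The peak feature maximizes |∂Rd/∂p|, which treats the
negative-signed absorption sensitivities and positive scattering
sensitivities uniformly.

For the reference configuration (bottom μs′ = 1 mm⁻¹, μa = 0.1 mm⁻¹,
300 μm top layer with μa = 0.01 mm⁻¹, g = 0.8) the solver places the
bottom-scattering sensitivity peak at 0.06 mm⁻¹ for every scattering
contrast in {0.4, 0.7, 1.0, 1.3, 1.6}× and sweeps the top-scattering peak
monotonically across 0.06–0.16 mm⁻¹ as the top layer's scattering weight
grows; absorption sensitivities are maximal at fx = 0 and decay by a
decade at 0.17 (bottom) and 0.28 (top) mm⁻¹. An independent Monte Carlo
cross-check (exact pathlength-derivative estimators) reproduced all of
these features to within one grid step during development.

## Staged inversion

All stages are bounded trust-region least squares
(`scipy.optimize.least_squares`, `trf`) with unweighted Rd residuals,
analytic sparsity patterns for the finite-difference Jacobians, fixed
documented initial guesses (A = 1 mm⁻¹, b = 1, μa = 0.05 mm⁻¹, β = 1) and
tolerances 1e-8; there is no random initialization, so reruns are bitwise
identical. Bounds: μa ∈ [0, 1] mm⁻¹, μs′ ∈ [0.05, 5] mm⁻¹, b ∈ [0, 4],
β ∈ [0, 10].

Design choices where the procedure was genuinely open:

* Stage-1 absorption is parameterized freely per wavelength (not
  basis-constrained) since it is discarded; this keeps the homogeneous fit
  unbiased by chromophore assumptions.
* The stage-1 power law is enforced inside the optimization (A, b are the
  scattering unknowns), not by post-hoc regression of per-λ fits.
* Stage 2 fits its two frequencies jointly; its unknown vector has length
  n_wavelengths + n_chromophores (33 at full scale). One basis shape is
  exercised, matching the two-layer phantom setting; the architecture
  admits several.
* fx = 0 (planar illumination) is retained in the low band; it is a valid
  solver input.
* Per-wavelength failures in stages 3/4 fall back to the prior stage's
  value and are flagged, keeping the pipeline total.
* Finely sampled measurements are subsampled to the 32-wavelength analysis
  grid by nearest neighbor.

Recovery of top-layer absorption degrades when the true value falls below
~0.075 mm⁻¹ — an identifiability limit of the low-frequency data, not a
solver failure; stage 4 flags wavelengths driven to the zero bound.

## Synthetic data generator

The generator emulates calibrated SFDS measurements of two-layer
siloxane-like phantoms: power-law scattering `A(λ/750)^−b` per layer, a
smooth multi-peak (Gaussian-sum) top absorption with a 600–850 nm double
hump at 0.01–0.02 mm⁻¹ (the "default" preset; a "high" preset raises the
hump band above 0.075 mm⁻¹ for top-absorption recovery studies), and a
hemoglobin-like bottom basis — a synthetic parametric stand-in with
visible double-peak, NIR bump and water-like rise, not literature
extinction data. Default conditions: top A = 1.1 mm⁻¹, b = 1.3; bottom
A = 1.0 mm⁻¹, b = 1.2, β = 1; 300 μm top thickness; g = 0.8; n = 1.4;
32 wavelengths over 450–1000 nm; 51 frequencies over 0–0.5 mm⁻¹.

Noise is multiplicative Gaussian (σ = 0.005) plus additive (σ = 1e-4),
seeded, applied per (λ, fx) cell and clipped to [0, 1] — chosen so that
recovery errors are inversion-dominated. Three-phase demodulation
(0, 2π/3, 4π/3) is emulated exactly; the calibration step of a real
instrument (reference-phantom division) is not simulated — synthetic maps
are born calibrated. Not emulated: imaging geometry, speckle,
projector/camera transfer functions, spatial heterogeneity within layers,
instrument spectral response. Passing recovery tests therefore demonstrate
the internal consistency of the method (an inverse-crime design: data
generated by the same forward model), not robustness to model mismatch on
real instruments.

## Problem sizes

The full-scale synthetic experiments use 32 wavelengths × 51 frequencies
and complete in a few minutes each on one CPU; unit tests run the same
pipeline at 4–16 wavelengths. Per-layer eigendecompositions are memoized
across the optimizer's finite-difference evaluations, which is what makes
the staged fits cheap.

## Known limitations

* The solver covers what the layered machinery supports naturally:
  index-matched interior interfaces, semi-infinite terminal layer, no
  polarization, no phase of the reflected modulation, no time dependence.
* P_N-type expansions converge slowly exactly at grazing/boundary-layer
  angular structure; with δ-M the residual order-truncation error is
  ≲0.3% of Rd, which bounds the fidelity of very-low-noise inversions.
* The staged design propagates stage-1/2 biases into stages 3/4; on
  synthetic data the bottom-layer spectra are recovered to a few percent,
  while top-layer absorption is only recoverable above ~0.075 mm⁻¹.
* The diffusion-approximation oracle used in tests is itself approximate;
  agreement is asserted at 10% and only in the diffusive regime
  (μs′/μa ≥ 100, 2π fx below the transport attenuation).
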
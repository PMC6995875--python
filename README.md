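# sfdlayers

Deterministic radiative-transport modelling of **spatial frequency-domain
spectroscopy (SFDS)** for layered turbid media, and staged recovery of the
optical properties of both layers of a two-layer medium — the regime of thin
superficial layers (thickness down to a tenth of the transport mean free
path `l* = 1/(μa + μs′)`) where the standard diffusion approximation breaks
down. It is aimed at biomedical-optics researchers working with layered
tissue and tissue-simulating phantoms (skin, epithelia, burn wounds).

## What it computes

**Forward model.** The radiance in a laterally modulated slab,
`L(x, z, ŝ) = ψ(z, ŝ) e^{i 2π fx x}`, is expanded in real spherical
harmonics up to order N (default N = 9). The radiative transport equation
then reduces, per layer, to (N+1)² coupled depth ODEs

```
A_z dc/dz + (Σ + 2π fx Âx) c = q(z)
```

with `Σ = diag(μt − μs g_l)` for Legendre phase moments `g_l`
(Henyey–Greenstein, `g_l = g^l`, with δ-M forward-peak scaling), `A_z` the
streaming matrix, `Âx` the transverse coupling, and `q` the first-scatter
source fed by the Beer–Lambert-attenuated collimated beam. Each layer is
solved by generalized eigendecomposition into exponential depth modes;
Marshak half-range conditions with internal Fresnel reflection close the
system at the surface, half-range continuity at interior interfaces, and
only decaying modes survive in the semi-infinite bottom layer. The result
is the calibrated diffuse reflectance `Rd(λ, fx)`. A two-layer Monte Carlo
cross-check (development-time oracle) agrees with the N = 9 solver to ~0.3%
over the full frequency grid.

**Sensitivities.** `∂Rd/∂p` versus `fx` for each layer's `μa` and `μs′`
(central finite differences), plus peak-location and decade-decay feature
extraction. These show which spatial frequencies carry information about
which layer and motivate the inversion's frequency bands.

**Staged inversion.** Given `Rd(λ, fx)` at 32 wavelengths (450–1000 nm), a
known top-layer thickness, and a known spectral *shape* for bottom-layer
absorption, four bounded least-squares stages recover all four property
spectra:

1. homogeneous power-law fits `μs′ = A (λ/750 nm)^(−b)` on a low band
   (fx = 0–0.10 mm⁻¹ → bottom layer) and a high band (0.30–0.40 mm⁻¹ →
   top layer);
2. joint fit of the scalar β (bottom `μa = β ×` basis) and free top-layer
   `μa(λ)` at fx = 0.01, 0.02 mm⁻¹ (33 unknowns for 32 wavelengths);
3. per-wavelength refinement of bottom `μs′` at fx = 0.06, 0.15 mm⁻¹,
   dropping the power-law constraint;
4. per-wavelength refinement of top `μa(λ)` at fx = 0.01, 0.02 mm⁻¹.

**Synthetic phantoms.** A generator emulating calibrated two-layer
siloxane-phantom measurements (power-law scattering, smooth multi-peak
absorption, 90/300 μm top layers, three-phase demodulation, seeded noise)
so everything is testable without instrument data.

## Worked example

```python
import numpy as np
from sfdlayers import (
    PhantomSpec, NoiseModel, ChromophoreBasis, StagedInversion,
    build_media, simulate_measurement, hemoglobin_like_basis,
)
from sfdlayers.synthetic import default_wavelength_grid

wl = default_wavelength_grid(32)                 # 450-1000 nm
fx = np.round(np.arange(51) * 0.01, 10)          # 0-0.5 mm^-1
spec = PhantomSpec()                             # 300 um top layer defaults
media = build_media(spec, wl)
meas = simulate_measurement(media, wl, fx, NoiseModel(0.005, 1e-4, seed=1))

basis = ChromophoreBasis(wl, hemoglobin_like_basis(wl))
result = StagedInversion(meas, basis, spec.thickness_top).fit()
print(result.summary())
```

prints

```
Staged two-layer SFDS inversion
===============================================
wavelengths: 32 (450-1000 nm)

Stage 1  reduced scattering power laws
  bottom: A = 1.0274 mm^-1, b = 1.2381 (residual 2.960e-02)
  top:    A = 1.0853 mm^-1, b = 1.2440 (residual 4.913e-03)
Stage 2  absorption
  beta = 0.9813 (residual 1.199e-02)
  top mua: median 0.0208 mm^-1
Stage 3  bottom mus' refinement
  median 1.0563 mm^-1, 0 fallback(s)
Stage 4  top mua refinement
  median 0.0184 mm^-1, 0 wavelength(s) at the zero-absorption bound
```

The generator's truth here is bottom `A = 1.0, b = 1.2` with `β = 1`
(hemoglobin-like basis) and top `A = 1.1, b = 1.3`: stage 1 recovers both
power laws within a few percent, β is recovered within 2%, and the stage-3
bottom scattering spectrum has a median error below 2%. Recovery of the
top-layer absorption is reliable only where it exceeds ~0.075 mm⁻¹
(see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
sfdlayers simulate --config run.yaml --out sim/
sfdlayers invert --measurement sim/measurement.csv --basis sim/basis.csv \
    --thickness 0.3 --out inv/
sfdlayers sensitivity --config run.yaml --out sens/
sfdlayers forward --config run.yaml --out fwd/
```

All artifacts are plain text (long-format CSV, JSON, YAML) and every run
echoes its effective configuration for bitwise reproducibility.

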
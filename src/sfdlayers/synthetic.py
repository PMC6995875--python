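"""Synthetic two-layer phantom spectra and simulated SFDS measurements.

Emulates calibrated spatial frequency-domain spectroscopy of two-layer
siloxane-like tissue phantoms: a thin top layer (90 or 300 um) with
power-law scattering and a smooth multi-peak absorption spectrum (a
naphthol-green-like dye analogue), over a semi-infinite bottom layer with
power-law scattering and absorption given by a scalar coefficient beta
times a known hemoglobin-like basis spectrum. Property ranges target
mua in [0.01, 0.2] mm^-1 and mus' in [0.5, 1.3] mm^-1 across
lambda = 450 to 1000 nm.

The basis and top-layer spectra here are synthetic parametric stand-ins
(sums of Gaussian peaks over a baseline) for the chromophores used in real
phantoms; they reproduce ranges and qualitative shapes, not literature
extinction data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .media import LayerOpticalProperties, LayeredMedium, PowerLawScattering
from .shef import SHEFConfig, DEFAULT_CONFIG, ReflectanceMap, reflectance_map

__all__ = [
    "GaussianPeakAbsorption",
    "PhantomSpec",
    "NoiseModel",
    "hemoglobin_like_basis",
    "top_absorption_preset",
    "default_wavelength_grid",
    "build_media",
    "simulate_measurement",
    "apply_noise",
    "demodulate_three_phase",
    "three_phase_patterns",
]

WAVELENGTH_MIN = 450.0
WAVELENGTH_MAX = 1000.0

#: Phantom design ranges (used for warnings only).
MUA_RANGE = (0.01, 0.2)
MUSP_RANGE = (0.5, 1.3)


def default_wavelength_grid(n: int = 32) -> np.ndarray:
    """n evenly spaced wavelengths spanning 450 to 1000 nm (inclusive)."""
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, n)


@dataclass(frozen=True)
class GaussianPeakAbsorption:
    """Smooth absorption spectrum: baseline plus Gaussian peaks.

    ``peaks`` is a tuple of (center nm, width nm, height mm^-1) triples.
    """

    baseline: float
    peaks: tuple[tuple[float, float, float], ...]

    def __call__(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        mua = np.full_like(wl, self.baseline)
        for center, width, height in self.peaks:
            mua = mua + height * np.exp(-(((wl - center) / width) ** 2))
        return mua


def hemoglobin_like_basis(wavelengths_nm) -> np.ndarray:
    """Synthetic hemoglobin-like bottom-layer absorption basis, mm^-1.

    A smooth stand-in with the qualitative features of a hemoglobin
    phantom: strong visible absorption with a double peak near 540/576 nm,
    a weak near-infrared bump near 760 nm, and a water-like rise near
    970 nm. Values stay within the phantom design range [0.01, 0.2] mm^-1.
    """
    shape = GaussianPeakAbsorption(
        baseline=0.015,
        peaks=(
            (460.0, 45.0, 0.06),
            (542.0, 18.0, 0.12),
            (576.0, 12.0, 0.10),
            (760.0, 30.0, 0.02),
            (970.0, 45.0, 0.035),
        ),
    )
    return shape(wavelengths_nm)


def top_absorption_preset(kind: str = "default") -> GaussianPeakAbsorption:
    """Naphthol-green-like top-layer absorption presets.

    ``"default"`` mimics the reference phantom dye: a blue absorption peak
    and a double hump across 600-850 nm with values between 0.01 and
    0.02 mm^-1. ``"high"`` raises the spectrum so the 600-800 nm band
    stays above 0.075 mm^-1, the regime where top-layer absorption is
    recoverable.
    """
    if kind == "default":
        return GaussianPeakAbsorption(
            baseline=0.005,
            peaks=((440.0, 55.0, 0.10), (640.0, 55.0, 0.012), (780.0, 55.0, 0.014)),
        )
    if kind == "high":
        # default spectrum with the 600-850 nm double hump widened and raised
        # so the whole 600-800 nm band sits above 0.075 mm^-1
        return GaussianPeakAbsorption(
            baseline=0.005,
            peaks=((440.0, 55.0, 0.10), (640.0, 80.0, 0.09), (780.0, 80.0, 0.08)),
        )
    raise ValueError(f"unknown top absorption preset {kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a synthetic two-layer phantom.

    Defaults describe the reference experiment: a 300-um top layer with
    power-law scattering (A = 1.1 mm^-1, b = 1.3) and the default
    naphthol-green-like absorption preset over a semi-infinite bottom layer
    with A = 1.0 mm^-1, b = 1.2 and absorption beta = 1 times the
    hemoglobin-like basis.
    """

    top_scattering: PowerLawScattering = PowerLawScattering(1.1, 1.3)
    top_absorption: GaussianPeakAbsorption = field(
        default_factory=lambda: top_absorption_preset("default")
    )
    bottom_scattering: PowerLawScattering = PowerLawScattering(1.0, 1.2)
    beta: float = 1.0
    thickness_top: float = 0.3
    g: float = 0.8
    n: float = 1.4
    n_ambient: float = 1.0

    def bottom_absorption(self, wavelengths_nm) -> np.ndarray:
        return self.beta * hemoglobin_like_basis(wavelengths_nm)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise on Rd: rd * (1 + eps_mult) + eps_add, clipped to [0, 1].

    ``eps_mult ~ N(0, multiplicative_sigma^2)`` and ``eps_add ~ N(0,
    additive_sigma^2)`` independently per (wavelength, frequency) cell.
    Defaults are small enough that synthetic recovery errors are dominated
    by the inversion, not the noise.
    """

    multiplicative_sigma: float = 0.005
    additive_sigma: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0 or self.additive_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


def build_media(spec: PhantomSpec, wavelengths_nm) -> list[LayeredMedium]:
    """One two-layer :class:`LayeredMedium` per wavelength, deterministically.

    Warns (without failing) when a generated property leaves the phantom
    design ranges mua in [0.01, 0.2] or mus' in [0.5, 1.3] mm^-1.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if np.any(wl < WAVELENGTH_MIN) or np.any(wl > WAVELENGTH_MAX):
        raise ValueError(
            f"wavelength grid must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
        )
    mua_t = spec.top_absorption(wl)
    musp_t = spec.top_scattering(wl)
    mua_b = spec.bottom_absorption(wl)
    musp_b = spec.bottom_scattering(wl)

    for name, arr, rng in (
        ("top mua", mua_t, MUA_RANGE),
        ("bottom mua", mua_b, MUA_RANGE),
        ("top musp", musp_t, MUSP_RANGE),
        ("bottom musp", musp_b, MUSP_RANGE),
    ):
        if np.any(arr < rng[0]) or np.any(arr > rng[1]):
            warnings.warn(
                f"{name} leaves the phantom design range {rng} mm^-1 "
                f"(min {arr.min():.4g}, max {arr.max():.4g})",
                stacklevel=2,
            )

    media = []
    for i in range(wl.size):
        top = LayerOpticalProperties(mua=float(mua_t[i]), musp=float(musp_t[i]), g=spec.g, n=spec.n)
        bottom = LayerOpticalProperties(mua=float(mua_b[i]), musp=float(musp_b[i]), g=spec.g, n=spec.n)
        media.append(
            LayeredMedium.two_layer(top, bottom, spec.thickness_top, n_ambient=spec.n_ambient)
        )
    return media


def apply_noise(measurement: ReflectanceMap, noise: NoiseModel) -> ReflectanceMap:
    """Apply the multiplicative-plus-additive noise model, seeded."""
    rng = np.random.default_rng(noise.seed)
    rd = measurement.rd
    eps_m = rng.standard_normal(rd.shape) * noise.multiplicative_sigma
    eps_a = rng.standard_normal(rd.shape) * noise.additive_sigma
    noisy = np.clip(rd * (1.0 + eps_m) + eps_a, 0.0, 1.0)
    return ReflectanceMap(
        wavelengths=measurement.wavelengths,
        frequencies=measurement.frequencies,
        rd=noisy,
    )


def simulate_measurement(
    media,
    wavelengths_nm,
    frequencies,
    noise: NoiseModel | None = None,
    config: SHEFConfig = DEFAULT_CONFIG,
) -> ReflectanceMap:
    """Forward-simulate a calibrated SFDS measurement.

    With ``noise=None`` (or zero sigmas) this equals
    :func:`sfdlayers.shef.reflectance_map` exactly; otherwise seeded noise
    is applied per cell.
    """
    clean = reflectance_map(media, wavelengths_nm, frequencies, config)
    if noise is None or (noise.multiplicative_sigma == 0 and noise.additive_sigma == 0):
        return clean
    return apply_noise(clean, noise)


# ---------------------------------------------------------------------------
# three-phase demodulation

#: Projection phase shifts: 0, 2*pi/3, 4*pi/3.
PHASE_SHIFTS = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def demodulate_three_phase(i1, i2, i3) -> np.ndarray:
    """AC amplitude from intensities at phase shifts 0, 2pi/3, 4pi/3.

    For i_k = DC + a*cos(phi0 + phase_k) the identity
    (sqrt(2)/3) * sqrt((i1-i2)^2 + (i2-i3)^2 + (i3-i1)^2) returns a exactly,
    for any DC offset and starting phase phi0.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    i3 = np.asarray(i3, dtype=float)
    return (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )


def three_phase_patterns(amplitude, dc=1.0, phi0=0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic intensity triplet whose modulation depth is ``amplitude``.

    Demodulating the returned triplet recovers ``amplitude`` to round-off,
    which is how a measured reflectance map is emulated end to end.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    return tuple(dc + amplitude * np.cos(phi0 + p) for p in PHASE_SHIFTS)
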
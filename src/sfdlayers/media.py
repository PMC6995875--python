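"""Optical property containers for layered turbid media.

Units follow biomedical-optics convention: absorption and scattering
coefficients in mm^-1, lengths in mm, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel thickness marking a semi-infinite layer.
SEMI_INFINITE = float("inf")


class DegeneratePhaseFunctionError(ValueError):
    """Raised when g = 1: purely forward scattering has no finite mus."""


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Optical properties of a single homogeneous layer at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1 (>= 0).
    musp : float
        Reduced scattering coefficient mus * (1 - g), mm^-1 (> 0).
    g : float
        Single-scattering anisotropy, mean cosine of the scattering angle
        (0 <= g < 1).
    n : float
        Refractive index (>= 1). Defaults to 1.4, typical of soft tissue
        and silicone phantoms.
    """

    mua: float
    musp: float
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        if not np.isfinite(self.mua) or self.mua < 0:
            raise ValueError(f"mua must be finite and >= 0, got {self.mua}")
        if not np.isfinite(self.musp) or self.musp <= 0:
            raise ValueError(f"musp must be finite and > 0, got {self.musp}")
        if self.g == 1:
            raise DegeneratePhaseFunctionError(
                "g = 1 (purely forward scattering) leaves mus = musp/(1-g) undefined"
            )
        if not 0 <= self.g < 1:
            raise ValueError(f"g must satisfy 0 <= g < 1, got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class DerivedTransport:
    """Transport quantities derived from :class:`LayerOpticalProperties`.

    mus = musp / (1 - g); mut = mua + mus; lstar = 1/(mua + musp) is the
    transport mean free path; albedo = mus / mut.
    """

    mus: float
    mut: float
    lstar: float
    albedo: float


def derive_transport(layer: LayerOpticalProperties) -> DerivedTransport:
    """Compute scattering coefficient, total attenuation, transport mean
    free path and single-scattering albedo for a layer."""
    mus = layer.musp / (1.0 - layer.g)
    mut = layer.mua + mus
    lstar = 1.0 / (layer.mua + layer.musp)
    return DerivedTransport(mus=mus, mut=mut, lstar=lstar, albedo=mus / mut)


def phase_moments(g: float, order: int) -> np.ndarray:
    """Legendre moments of the Henyey-Greenstein phase function.

    The HG phase function has l'th Legendre moment g**l, so the returned
    sequence is [1, g, g^2, ..., g^order] (length order + 1). Moments for an
    alternative phase function may be substituted wherever these are
    consumed; the solver only ever sees the moment sequence.
    """
    if not 0 <= g < 1:
        raise ValueError(f"g must satisfy 0 <= g < 1, got {g}")
    return g ** np.arange(order + 1, dtype=float)


@dataclass(frozen=True)
class LayeredMedium:
    """Stack of homogeneous layers, top first; the last layer is semi-infinite.

    Parameters
    ----------
    layers : tuple of LayerOpticalProperties
        Ordered top to bottom.
    thicknesses : tuple of float
        One per layer, mm; the last entry must be ``inf``
        (:data:`SEMI_INFINITE`), all others finite and positive.
    n_ambient : float
        Refractive index of the non-scattering half-space above the top
        surface (default 1.0, air).
    """

    layers: tuple[LayerOpticalProperties, ...]
    thicknesses: tuple[float, ...]
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        thicknesses = tuple(float(t) for t in self.thicknesses)
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "thicknesses", thicknesses)
        if len(layers) < 1:
            raise ValueError("at least one layer is required")
        if len(thicknesses) != len(layers):
            raise ValueError("one thickness per layer is required")
        if not np.isinf(thicknesses[-1]):
            raise ValueError("last layer must be semi-infinite (thickness inf)")
        for t in thicknesses[:-1]:
            if not (np.isfinite(t) and t > 0):
                raise ValueError(f"finite layer thicknesses must be > 0, got {t}")
        if self.n_ambient < 1:
            raise ValueError(f"n_ambient must be >= 1, got {self.n_ambient}")

    @classmethod
    def semi_infinite(cls, layer: LayerOpticalProperties, n_ambient: float = 1.0) -> "LayeredMedium":
        """Homogeneous semi-infinite medium."""
        return cls(layers=(layer,), thicknesses=(SEMI_INFINITE,), n_ambient=n_ambient)

    @classmethod
    def two_layer(
        cls,
        top: LayerOpticalProperties,
        bottom: LayerOpticalProperties,
        thickness_top: float,
        n_ambient: float = 1.0,
    ) -> "LayeredMedium":
        """Finite top layer over a semi-infinite bottom layer."""
        return cls(
            layers=(top, bottom),
            thicknesses=(thickness_top, SEMI_INFINITE),
            n_ambient=n_ambient,
        )


@dataclass(frozen=True)
class PowerLawScattering:
    """Inverse power-law scattering spectrum mus'(lambda) = A (lambda/lambda0)^-b.

    ``amplitude`` (A) is the reduced scattering coefficient at the reference
    wavelength ``lambda0`` (default 750 nm); ``exponent`` (b) is the
    dimensionless scattering power.
    """

    amplitude: float
    exponent: float
    lambda0: float = 750.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.lambda0 <= 0:
            raise ValueError(f"lambda0 must be > 0, got {self.lambda0}")

    def __call__(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return self.amplitude * (wl / self.lambda0) ** (-self.exponent)
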
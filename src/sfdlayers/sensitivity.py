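"""Spatial frequency-resolved reflectance sensitivities.

The reflectance sensitivity to a layer property p is the partial derivative
dRd/dp evaluated by central finite differences of the forward solver at each
spatial frequency. The frequency at which a sensitivity peaks, and the
frequency beyond which it has decayed by an order of magnitude from its
planar (fx = 0) value, quantify which spatial frequencies carry information
about which layer — the rationale behind the staged inversion's frequency
band choices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .media import LayeredMedium
from .shef import SHEFConfig, DEFAULT_CONFIG, solve_layered_reflectance

__all__ = [
    "SensitivityCurve",
    "sensitivity_curve",
    "peak_frequency",
    "decay_frequency",
    "BEYOND_GRID",
    "default_frequency_grid",
]

#: Sentinel returned by :func:`decay_frequency` when the threshold is never
#: crossed on the grid.
BEYOND_GRID = float("inf")

#: Properties of a layer that sensitivities can be taken with respect to.
_PROPERTIES = ("mua", "musp")


def default_frequency_grid() -> np.ndarray:
    """The instrument grid: 0 to 0.5 mm^-1 at 0.01 mm^-1 intervals."""
    return np.round(np.arange(0, 51) * 0.01, 10)


@dataclass(frozen=True)
class SensitivityCurve:
    """dRd/dp on a spatial frequency grid.

    ``parameter_id`` is ``"<property>_<layer index>"``, e.g. ``"musp_1"``
    for the reduced scattering coefficient of the bottom layer of a
    two-layer medium. Values carry units of mm (inverse of mm^-1).
    """

    frequencies: np.ndarray
    values: np.ndarray
    parameter_id: str

    def __post_init__(self) -> None:
        fx = np.asarray(self.frequencies, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if fx.size != vals.size:
            raise ValueError("frequency and value grids differ in length")
        if np.any(np.diff(fx) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("sensitivity values must be finite")
        object.__setattr__(self, "frequencies", fx)
        object.__setattr__(self, "values", vals)


def _perturbed(medium: LayeredMedium, layer_index: int, prop: str, value: float) -> LayeredMedium:
    layers = list(medium.layers)
    layers[layer_index] = _dc_replace(layers[layer_index], **{prop: value})
    return LayeredMedium(
        layers=tuple(layers),
        thicknesses=medium.thicknesses,
        n_ambient=medium.n_ambient,
    )


def sensitivity_curve(
    medium: LayeredMedium,
    layer_index: int,
    prop: str,
    frequencies=None,
    rel_step: float = 0.01,
    abs_step_floor: float = 1e-4,
    config: SHEFConfig = DEFAULT_CONFIG,
) -> SensitivityCurve:
    """Central finite-difference sensitivity dRd/dp over a frequency grid.

    Parameters
    ----------
    layer_index : int
        0 for the top layer, -1 or len-1 for the bottom layer.
    prop : {"mua", "musp"}
        Property differentiated with respect to.
    rel_step : float
        Relative perturbation of the base value, in (0, 0.1]. When the base
        value is below ``abs_step_floor / rel_step`` (relevant for small
        absorption), an absolute step of ``abs_step_floor`` is used instead
        so the difference stays well above solver noise.
    """
    if prop not in _PROPERTIES:
        raise ValueError(f"prop must be one of {_PROPERTIES}, got {prop!r}")
    if not 0 < rel_step <= 0.1:
        raise ValueError(f"rel_step must lie in (0, 0.1], got {rel_step}")
    if frequencies is None:
        frequencies = default_frequency_grid()
    frequencies = np.asarray(frequencies, dtype=float)
    layer_index = range(len(medium.layers))[layer_index]

    base = getattr(medium.layers[layer_index], prop)
    step = max(rel_step * base, abs_step_floor)
    lo = base - step
    if lo <= 0 and prop == "musp":
        lo = base / 2.0  # keep musp positive; one-sided shrink of the step
        step = base - lo
    med_plus = _perturbed(medium, layer_index, prop, base + step)
    med_minus = _perturbed(medium, layer_index, prop, lo)

    values = np.empty(frequencies.size)
    for j, fx in enumerate(frequencies):
        rp = solve_layered_reflectance(med_plus, float(fx), config)
        rm = solve_layered_reflectance(med_minus, float(fx), config)
        d = (rp - rm) / (2.0 * step)
        if not np.isfinite(d):
            raise ArithmeticError(
                f"non-finite sensitivity for {prop} of layer {layer_index} "
                f"at fx = {fx} mm^-1"
            )
        values[j] = d

    label = "_".join([prop, str(layer_index)])
    return SensitivityCurve(frequencies=frequencies, values=values, parameter_id=label)


def peak_frequency(curve: SensitivityCurve) -> float:
    """Grid frequency maximizing |dRd/dp|; ties break toward lower fx."""
    mags = np.abs(curve.values)
    if curve.values.size == 0:
        raise ValueError("empty sensitivity curve")
    if np.all(mags == 0):
        raise ValueError("all-zero sensitivity curve has no defined peak")
    return float(curve.frequencies[int(np.argmax(mags))])


def decay_frequency(curve: SensitivityCurve, factor: float = 10.0) -> float:
    """Smallest grid fx where |dRd/dp| has fallen to 1/factor of its fx=0 value.

    Returns :data:`BEYOND_GRID` if the threshold is never crossed. The
    result is invariant to uniform rescaling of the curve.
    """
    if factor <= 1:
        raise ValueError(f"factor must exceed 1, got {factor}")
    if not np.isclose(curve.frequencies[0], 0.0):
        raise ValueError("decay_frequency requires the curve to include fx = 0")
    mags = np.abs(curve.values)
    if mags[0] == 0:
        raise ValueError("zero sensitivity at fx = 0; decay is undefined")
    below = np.where(mags <= mags[0] / factor)[0]
    if below.size == 0:
        return BEYOND_GRID
    return float(curve.frequencies[below[0]])
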
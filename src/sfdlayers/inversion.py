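"""Four-stage recovery of two-layer optical property spectra from SFDS data.

Given a calibrated reflectance map Rd(lambda, fx), a known top-layer
thickness, and a known spectral shape for the bottom-layer absorption, the
inversion proceeds in four stages, each a bounded trust-region nonlinear
least squares against the spherical-harmonic forward solver:

1. Layer-specific reduced scattering. Homogeneous-medium fits on two
   frequency bands: the low band fx1 = [0, 0.02, ..., 0.10] mm^-1 senses
   mostly the bottom layer, the high band fx2 = [0.30, 0.32, ..., 0.40]
   mostly the top layer. Scattering is constrained to the inverse power law
   mus'(lambda) = A (lambda/750 nm)^-b; per-wavelength absorption is a free
   nuisance and is discarded.
2. Layer-specific absorption. With both scattering spectra fixed, a joint
   fit on fx = 0.01 and 0.02 mm^-1 of one scalar beta (multiplying the
   known bottom-layer basis) plus a free top-layer mua at every wavelength;
   the unknown vector has length n_wavelengths + n_chromophores.
3. Bottom scattering refinement. Dropping the power-law constraint, a
   per-wavelength scalar fit of bottom mus' on fx = 0.06 and 0.15 mm^-1
   (maximal / absorption-insensitive bottom-scattering sensitivity).
4. Top absorption refinement. A per-wavelength scalar fit of top mua on
   fx = 0.01 and 0.02 mm^-1, initialized at the stage-2 estimate, with all
   other spectra held at their best available values.

Every fit is deterministic: fixed initial guesses, no randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from .media import LayerOpticalProperties, LayeredMedium, PowerLawScattering
from .shef import SHEFConfig, DEFAULT_CONFIG, ReflectanceMap, solve_layered_reflectance

__all__ = [
    "StageConfig",
    "ChromophoreBasis",
    "BetaCoefficient",
    "StageDiagnostics",
    "Stage1Result",
    "Stage2Result",
    "Stage3Result",
    "Stage4Result",
    "InversionResult",
    "StagedInversion",
    "fit_homogeneous_band",
    "stage1",
    "stage2",
    "stage3",
    "stage4",
    "run_staged_inversion",
    "stage2_unknown_count",
]


@dataclass(frozen=True)
class StageConfig:
    """Frequency bands, bounds and tolerances of the staged inversion.

    Frequencies are in mm^-1. Defaults follow the reference protocol:
    six-frequency low and high bands for stage 1, fx = 0.01/0.02 for the
    absorption stages, fx = 0.06/0.15 for the bottom-scattering refinement,
    and 32 equispaced wavelengths spanning 450-1000 nm.
    """

    band1: tuple[float, ...] = (0.0, 0.02, 0.04, 0.06, 0.08, 0.10)
    band2: tuple[float, ...] = (0.30, 0.32, 0.34, 0.36, 0.38, 0.40)
    absorption_freqs: tuple[float, ...] = (0.01, 0.02)
    refine_freqs: tuple[float, ...] = (0.06, 0.15)
    n_wavelengths: int = 32
    lambda0: float = 750.0
    mua_bounds: tuple[float, float] = (0.0, 1.0)
    musp_bounds: tuple[float, float] = (0.05, 5.0)
    exponent_bounds: tuple[float, float] = (0.0, 4.0)
    beta_bounds: tuple[float, float] = (0.0, 10.0)
    init_amplitude: float = 1.0
    init_exponent: float = 1.0
    init_mua: float = 0.05
    init_beta: float = 1.0
    ftol: float = 1e-8
    xtol: float = 1e-8
    # medium assumptions used by the forward model during fitting
    g: float = 0.8
    n: float = 1.4
    n_ambient: float = 1.0


def stage2_unknown_count(n_wavelengths: int, n_chromophores: int = 1) -> int:
    """Dimension of the stage-2 unknown vector: one free top-layer mua per
    wavelength plus one concentration coefficient per chromophore."""
    return n_wavelengths + n_chromophores


@dataclass(frozen=True)
class ChromophoreBasis:
    """Known bottom-layer absorption spectrum shape, mm^-1 per unit beta."""

    wavelengths: np.ndarray
    shape: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        sh = np.asarray(self.shape, dtype=float)
        if wl.size != sh.size or wl.size < 2:
            raise ValueError("basis needs matching wavelength/shape arrays, >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("basis wavelengths must be strictly increasing")
        if np.any(sh < 0):
            raise ValueError("basis shape must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "shape", sh)

    def resample(self, wavelengths_nm) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.min() < self.wavelengths[0] - 1e-9 or wl.max() > self.wavelengths[-1] + 1e-9:
            raise ValueError(
                f"basis covers [{self.wavelengths[0]}, {self.wavelengths[-1]}] nm "
                f"but the analysis grid spans [{wl.min()}, {wl.max()}] nm"
            )
        return np.clip(PchipInterpolator(self.wavelengths, self.shape)(wl), 0.0, None)


@dataclass(frozen=True)
class BetaCoefficient:
    """Scalar multiplier of the bottom-layer basis; beta = 1 is perfect
    recovery when the basis equals the truth."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class StageDiagnostics:
    """Convergence record of one least-squares fit."""

    residual_norm: float
    n_forward_evaluations: int
    status: int
    message: str

    @property
    def converged(self) -> bool:
        return self.status > 0


@dataclass(frozen=True)
class Stage1Result:
    top_scattering: PowerLawScattering
    bottom_scattering: PowerLawScattering
    nuisance_mua_band1: np.ndarray
    nuisance_mua_band2: np.ndarray
    diagnostics_band1: StageDiagnostics
    diagnostics_band2: StageDiagnostics


@dataclass(frozen=True)
class Stage2Result:
    beta: BetaCoefficient
    top_absorption: np.ndarray
    diagnostics: StageDiagnostics


@dataclass(frozen=True)
class Stage3Result:
    bottom_scattering: np.ndarray
    fallback_flags: np.ndarray
    diagnostics: tuple[StageDiagnostics, ...]


@dataclass(frozen=True)
class Stage4Result:
    top_absorption: np.ndarray
    at_lower_bound: np.ndarray
    fallback_flags: np.ndarray
    diagnostics: tuple[StageDiagnostics, ...]


# ---------------------------------------------------------------------------
# measurement handling


def select_wavelengths(measurement: ReflectanceMap, config: StageConfig) -> np.ndarray:
    """Indices of the analysis wavelengths within the measurement grid.

    The analysis grid is ``n_wavelengths`` equispaced wavelengths over
    450-1000 nm; finely sampled measurements are subsampled by nearest
    neighbor. A measurement already on an n-wavelength grid is used as is.
    """
    wl = measurement.wavelengths
    if wl.size == config.n_wavelengths:
        return np.arange(wl.size)
    if wl.size < config.n_wavelengths:
        raise ValueError(
            f"measurement has {wl.size} wavelengths; the configuration "
            f"requires {config.n_wavelengths}"
        )
    target = np.linspace(450.0, 1000.0, config.n_wavelengths)
    idx = np.unique([int(np.argmin(np.abs(wl - t))) for t in target])
    if idx.size != config.n_wavelengths:
        raise ValueError("wavelength grid too coarse to supply distinct analysis points")
    return idx


def _require_frequencies(measurement: ReflectanceMap, freqs, stage: str) -> None:
    for fx in freqs:
        if not measurement.has_frequency(fx):
            raise ValueError(
                f"{stage} requires fx = {fx} mm^-1, absent from the measurement grid"
            )


def _ls_diag(res) -> StageDiagnostics:
    return StageDiagnostics(
        residual_norm=float(np.linalg.norm(res.fun)),
        n_forward_evaluations=int(res.nfev),
        status=int(res.status),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# forward-model helpers


def _homog_rd(mua, musp, fx_list, config: StageConfig, shef: SHEFConfig) -> np.ndarray:
    layer = LayerOpticalProperties(mua=float(max(mua, 0.0)), musp=float(musp), g=config.g, n=config.n)
    medium = LayeredMedium.semi_infinite(layer, n_ambient=config.n_ambient)
    return np.array([solve_layered_reflectance(medium, fx, shef) for fx in fx_list])


def _two_layer_rd(
    mua_t, musp_t, mua_b, musp_b, thickness, fx_list, config: StageConfig, shef: SHEFConfig
) -> np.ndarray:
    top = LayerOpticalProperties(mua=float(max(mua_t, 0.0)), musp=float(musp_t), g=config.g, n=config.n)
    bottom = LayerOpticalProperties(mua=float(max(mua_b, 0.0)), musp=float(musp_b), g=config.g, n=config.n)
    medium = LayeredMedium.two_layer(top, bottom, thickness, n_ambient=config.n_ambient)
    return np.array([solve_layered_reflectance(medium, fx, shef) for fx in fx_list])


# ---------------------------------------------------------------------------
# stage 1


def fit_homogeneous_band(
    measurement: ReflectanceMap,
    band,
    config: StageConfig,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> tuple[PowerLawScattering, np.ndarray, StageDiagnostics]:
    """Homogeneous-medium power-law fit of one spatial frequency band.

    Minimizes summed squared Rd residuals over (all analysis wavelengths,
    fx in band) with unknowns (A, b, mua(lambda) free per wavelength).
    Returns the fitted power law, the per-wavelength nuisance absorption
    (discardable by design), and convergence diagnostics.
    """
    _require_frequencies(measurement, band, "stage 1")
    idx = select_wavelengths(measurement, config)
    wl = measurement.wavelengths[idx]
    data = np.stack([measurement.column(fx)[idx] for fx in band], axis=1)
    n_wl, n_fx = data.shape

    def residuals(x):
        a, b = x[0], x[1]
        mua = x[2:]
        musp = a * (wl / config.lambda0) ** (-b)
        model = np.empty_like(data)
        for i in range(n_wl):
            model[i] = _homog_rd(mua[i], musp[i], band, config, shef)
        return (model - data).ravel()

    x0 = np.concatenate([[config.init_amplitude, config.init_exponent], np.full(n_wl, config.init_mua)])
    lower = np.concatenate([[config.musp_bounds[0], config.exponent_bounds[0]], np.full(n_wl, config.mua_bounds[0])])
    upper = np.concatenate([[config.musp_bounds[1], config.exponent_bounds[1]], np.full(n_wl, config.mua_bounds[1])])

    sparsity = lil_matrix((n_wl * n_fx, 2 + n_wl), dtype=int)
    sparsity[:, :2] = 1
    for i in range(n_wl):
        sparsity[i * n_fx : (i + 1) * n_fx, 2 + i] = 1

    res = least_squares(
        residuals, x0, bounds=(lower, upper), method="trf",
        ftol=config.ftol, xtol=config.xtol, jac_sparsity=sparsity,
    )
    if res.status <= 0:
        raise RuntimeError(
            f"stage-1 band fit did not converge (status {res.status}, "
            f"final residual {np.linalg.norm(res.fun):.3e})"
        )
    law = PowerLawScattering(float(res.x[0]), float(res.x[1]), config.lambda0)
    return law, res.x[2:].copy(), _ls_diag(res)


def stage1(
    measurement: ReflectanceMap,
    config: StageConfig,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> Stage1Result:
    """Recover layer-specific reduced scattering power laws.

    The low band (band1) estimate is assigned to the bottom layer, the high
    band (band2) estimate to the top layer; both stage-1 absorption
    estimates are nuisance values and are discarded downstream.
    """
    bottom, mua1, diag1 = fit_homogeneous_band(measurement, config.band1, config, shef)
    top, mua2, diag2 = fit_homogeneous_band(measurement, config.band2, config, shef)
    return Stage1Result(
        top_scattering=top,
        bottom_scattering=bottom,
        nuisance_mua_band1=mua1,
        nuisance_mua_band2=mua2,
        diagnostics_band1=diag1,
        diagnostics_band2=diag2,
    )


# ---------------------------------------------------------------------------
# stage 2


def stage2(
    measurement: ReflectanceMap,
    scattering: Stage1Result,
    basis: ChromophoreBasis,
    thickness: float,
    config: StageConfig,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> Stage2Result:
    """Joint recovery of beta (bottom absorption scale) and the top-layer
    absorption spectrum at the low frequencies fx = 0.01 and 0.02 mm^-1,
    holding both stage-1 scattering spectra fixed."""
    _require_frequencies(measurement, config.absorption_freqs, "stage 2")
    idx = select_wavelengths(measurement, config)
    wl = measurement.wavelengths[idx]
    freqs = config.absorption_freqs
    data = np.stack([measurement.column(fx)[idx] for fx in freqs], axis=1)
    n_wl, n_fx = data.shape

    musp_t = scattering.top_scattering(wl)
    musp_b = scattering.bottom_scattering(wl)
    shape = basis.resample(wl)

    def residuals(x):
        beta = x[0]
        mua_t = x[1:]
        model = np.empty_like(data)
        for i in range(n_wl):
            model[i] = _two_layer_rd(
                mua_t[i], musp_t[i], beta * shape[i], musp_b[i],
                thickness, freqs, config, shef,
            )
        return (model - data).ravel()

    x0 = np.concatenate([[config.init_beta], np.full(n_wl, config.init_mua)])
    lower = np.concatenate([[config.beta_bounds[0]], np.full(n_wl, config.mua_bounds[0])])
    upper = np.concatenate([[config.beta_bounds[1]], np.full(n_wl, config.mua_bounds[1])])

    sparsity = lil_matrix((n_wl * n_fx, stage2_unknown_count(n_wl)), dtype=int)
    sparsity[:, 0] = 1
    for i in range(n_wl):
        sparsity[i * n_fx : (i + 1) * n_fx, 1 + i] = 1

    res = least_squares(
        residuals, x0, bounds=(lower, upper), method="trf",
        ftol=config.ftol, xtol=config.xtol, jac_sparsity=sparsity,
    )
    if res.status <= 0:
        raise RuntimeError(
            f"stage-2 fit did not converge (status {res.status}, "
            f"final residual {np.linalg.norm(res.fun):.3e})"
        )
    return Stage2Result(
        beta=BetaCoefficient(float(res.x[0])),
        top_absorption=res.x[1:].copy(),
        diagnostics=_ls_diag(res),
    )


# ---------------------------------------------------------------------------
# stages 3 and 4 (per-wavelength scalar refinements)


def _scalar_fits(
    data: np.ndarray,
    freqs,
    model_for,
    x0: np.ndarray,
    bounds: tuple[float, float],
    config: StageConfig,
) -> tuple[np.ndarray, np.ndarray, list[StageDiagnostics]]:
    """Independent bounded scalar least-squares fits, one per wavelength.

    ``model_for(i, value)`` returns the model Rd vector at wavelength index
    i. On a per-wavelength failure the initial value is retained and
    flagged, keeping the pipeline total.
    """
    n_wl = data.shape[0]
    out = x0.copy()
    fallback = np.zeros(n_wl, dtype=bool)
    diags: list[StageDiagnostics] = []
    for i in range(n_wl):
        def residuals(x, i=i):
            return model_for(i, x[0]) - data[i]

        try:
            res = least_squares(
                residuals, [np.clip(x0[i], *bounds)], bounds=([bounds[0]], [bounds[1]]),
                method="trf", ftol=config.ftol, xtol=config.xtol,
            )
            ok = res.status > 0
        except Exception:
            ok = False
            res = None
        if ok:
            out[i] = res.x[0]
            diags.append(_ls_diag(res))
        else:
            fallback[i] = True
            diags.append(StageDiagnostics(np.nan, 0, -1, "fit failed; prior value kept"))
    return out, fallback, diags


def stage3(
    measurement: ReflectanceMap,
    prior_scattering: Stage1Result,
    prior_absorption: Stage2Result,
    basis: ChromophoreBasis,
    thickness: float,
    config: StageConfig,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> Stage3Result:
    """Per-wavelength refinement of bottom mus' at fx = 0.06 and 0.15 mm^-1,
    dropping the power-law constraint."""
    _require_frequencies(measurement, config.refine_freqs, "stage 3")
    idx = select_wavelengths(measurement, config)
    wl = measurement.wavelengths[idx]
    freqs = config.refine_freqs
    data = np.stack([measurement.column(fx)[idx] for fx in freqs], axis=1)

    musp_t = prior_scattering.top_scattering(wl)
    mua_b = prior_absorption.beta.beta * basis.resample(wl)
    mua_t = prior_absorption.top_absorption
    x0 = prior_scattering.bottom_scattering(wl)

    def model_for(i, musp_b_i):
        return _two_layer_rd(
            mua_t[i], musp_t[i], mua_b[i], musp_b_i, thickness, freqs, config, shef
        )

    out, fallback, diags = _scalar_fits(data, freqs, model_for, x0, config.musp_bounds, config)
    return Stage3Result(bottom_scattering=out, fallback_flags=fallback, diagnostics=tuple(diags))


def stage4(
    measurement: ReflectanceMap,
    prior_scattering: Stage1Result,
    prior_absorption: Stage2Result,
    prior_refined: Stage3Result,
    basis: ChromophoreBasis,
    thickness: float,
    config: StageConfig,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> Stage4Result:
    """Per-wavelength refinement of top mua at fx = 0.01 and 0.02 mm^-1,
    initialized at the stage-2 spectrum, with all other spectra fixed."""
    _require_frequencies(measurement, config.absorption_freqs, "stage 4")
    idx = select_wavelengths(measurement, config)
    wl = measurement.wavelengths[idx]
    freqs = config.absorption_freqs
    data = np.stack([measurement.column(fx)[idx] for fx in freqs], axis=1)

    musp_t = prior_scattering.top_scattering(wl)
    musp_b = prior_refined.bottom_scattering
    mua_b = prior_absorption.beta.beta * basis.resample(wl)
    x0 = prior_absorption.top_absorption.copy()

    def model_for(i, mua_t_i):
        return _two_layer_rd(
            mua_t_i, musp_t[i], mua_b[i], musp_b[i], thickness, freqs, config, shef
        )

    out, fallback, diags = _scalar_fits(data, freqs, model_for, x0, config.mua_bounds, config)
    at_lower = out <= config.mua_bounds[0] + 1e-6
    return Stage4Result(
        top_absorption=out, at_lower_bound=at_lower,
        fallback_flags=fallback, diagnostics=tuple(diags),
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class InversionResult:
    """Recovered spectra and per-stage provenance of a staged inversion.

    ``bottom_scattering`` and ``top_absorption`` are the final (stage 3/4)
    per-wavelength spectra; stage-wise snapshots are retained for
    diagnostics and error analysis.
    """

    wavelengths: np.ndarray
    top_scattering: PowerLawScattering
    bottom_scattering: np.ndarray
    beta: BetaCoefficient
    bottom_absorption: np.ndarray
    top_absorption: np.ndarray
    stage1: Stage1Result
    stage2: Stage2Result
    stage3: Stage3Result
    stage4: Stage4Result

    def top_scattering_spectrum(self) -> np.ndarray:
        return self.top_scattering(self.wavelengths)

    def summary(self) -> str:
        """Human-readable per-stage summary table."""
        s1, s2 = self.stage1, self.stage2
        lines = [
            "Staged two-layer SFDS inversion",
            "=" * 47,
            f"wavelengths: {self.wavelengths.size} "
            f"({self.wavelengths[0]:.0f}-{self.wavelengths[-1]:.0f} nm)",
            "",
            "Stage 1  reduced scattering power laws",
            f"  bottom: A = {s1.bottom_scattering.amplitude:.4f} mm^-1, "
            f"b = {s1.bottom_scattering.exponent:.4f} "
            f"(residual {s1.diagnostics_band1.residual_norm:.3e})",
            f"  top:    A = {s1.top_scattering.amplitude:.4f} mm^-1, "
            f"b = {s1.top_scattering.exponent:.4f} "
            f"(residual {s1.diagnostics_band2.residual_norm:.3e})",
            "Stage 2  absorption",
            f"  beta = {self.beta.beta:.4f} "
            f"(residual {s2.diagnostics.residual_norm:.3e})",
            f"  top mua: median {np.median(s2.top_absorption):.4f} mm^-1",
            "Stage 3  bottom mus' refinement",
            f"  median {np.median(self.bottom_scattering):.4f} mm^-1, "
            f"{int(self.stage3.fallback_flags.sum())} fallback(s)",
            "Stage 4  top mua refinement",
            f"  median {np.median(self.top_absorption):.4f} mm^-1, "
            f"{int(self.stage4.at_lower_bound.sum())} wavelength(s) at the "
            "zero-absorption bound",
        ]
        return "\n".join(lines)


def run_staged_inversion(
    measurement: ReflectanceMap,
    basis: ChromophoreBasis,
    thickness: float,
    config: StageConfig | None = None,
    shef: SHEFConfig = DEFAULT_CONFIG,
) -> InversionResult:
    """Execute stages 1 through 4 in order; deterministic given its inputs."""
    config = config or StageConfig()
    for freqs, name in (
        (config.band1, "stage 1 (band 1)"),
        (config.band2, "stage 1 (band 2)"),
        (config.absorption_freqs, "stage 2"),
        (config.refine_freqs, "stage 3"),
    ):
        _require_frequencies(measurement, freqs, name)

    idx = select_wavelengths(measurement, config)
    wl = measurement.wavelengths[idx]
    s1 = stage1(measurement, config, shef)
    s2 = stage2(measurement, s1, basis, thickness, config, shef)
    s3 = stage3(measurement, s1, s2, basis, thickness, config, shef)
    s4 = stage4(measurement, s1, s2, s3, basis, thickness, config, shef)
    return InversionResult(
        wavelengths=wl,
        top_scattering=s1.top_scattering,
        bottom_scattering=s3.bottom_scattering,
        beta=s2.beta,
        bottom_absorption=s2.beta.beta * basis.resample(wl),
        top_absorption=s4.top_absorption,
        stage1=s1,
        stage2=s2,
        stage3=s3,
        stage4=s4,
    )


class StagedInversion:
    """Model object binding a measurement to the staged inversion.

    Parameters
    ----------
    measurement : ReflectanceMap
        Calibrated SFDS reflectance.
    basis : ChromophoreBasis
        Known bottom-layer absorption spectral shape.
    thickness : float
        Known top-layer thickness, mm.
    config, shef : optional
        Stage and solver configuration.

    ``fit()`` returns an :class:`InversionResult`.
    """

    def __init__(
        self,
        measurement: ReflectanceMap,
        basis: ChromophoreBasis,
        thickness: float,
        config: StageConfig | None = None,
        shef: SHEFConfig = DEFAULT_CONFIG,
    ) -> None:
        if thickness <= 0 or not np.isfinite(thickness):
            raise ValueError(f"top-layer thickness must be finite and > 0, got {thickness}")
        self.measurement = measurement
        self.basis = basis
        self.thickness = float(thickness)
        self.config = config or StageConfig()
        self.shef = shef

    def fit(self) -> InversionResult:
        return run_staged_inversion(
            self.measurement, self.basis, self.thickness, self.config, self.shef
        )
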
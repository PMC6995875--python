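"""Readers and writers for spectra, reflectance maps and run configuration.

All on-disk formats are plain text: long-format delimited tables (CSV) for
grids, two-column tables for spectra, JSON for structured results, YAML for
configuration. Datasets are small (tens of wavelengths by tens of
frequencies), so inspectability wins over compactness.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inversion import ChromophoreBasis, InversionResult, StageConfig
from .media import PowerLawScattering
from .shef import ReflectanceMap, SHEFConfig
from .synthetic import NoiseModel, PhantomSpec, GaussianPeakAbsorption

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "read_reflectance_map",
    "write_reflectance_map",
    "reflectance_map_to_json",
    "reflectance_map_from_json",
    "write_inversion_result",
    "load_run_config",
]


class SpectrumParseError(ValueError):
    """Malformed spectrum table."""


def read_spectrum_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength_nm, value) delimited text file.

    A single header line is tolerated. Returns sorted, duplicate-free
    arrays; duplicate wavelengths with conflicting values are an error.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if not rows:
        raise SpectrumParseError(f"{path}: empty spectrum file")
    rows.sort(key=lambda r: r[0])
    wl = np.array([r[0] for r in rows])
    val = np.array([r[1] for r in rows])
    dup = np.where(np.diff(wl) == 0)[0]
    for i in dup:
        if val[i] != val[i + 1]:
            raise SpectrumParseError(
                f"{path}: duplicate wavelength {wl[i]} nm with conflicting values"
            )
    keep = np.concatenate([[True], np.diff(wl) > 0])
    return wl[keep], val[keep]


def write_spectrum_table(path, wavelengths, values, value_name: str = "value") -> None:
    """Write a two-column spectrum table (wavelength_nm, value)."""
    df = pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, dtype=float),
                       value_name: np.asarray(values, dtype=float)})
    df.to_csv(path, index=False, float_format="%.10g")


def write_reflectance_map(path, measurement: ReflectanceMap) -> None:
    """Long-format CSV with columns wavelength_nm, fx_per_mm, rd."""
    wl, fx = np.meshgrid(measurement.wavelengths, measurement.frequencies, indexing="ij")
    df = pd.DataFrame(
        {"wavelength_nm": wl.ravel(), "fx_per_mm": fx.ravel(), "rd": measurement.rd.ravel()}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_reflectance_map(path) -> ReflectanceMap:
    """Inverse of :func:`write_reflectance_map`; validates rd in [0, 1]."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavelength_nm", "fx_per_mm", "rd"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = df[(df.rd < 0) | (df.rd > 1)]
    if len(bad):
        cells = [(row.wavelength_nm, row.fx_per_mm) for row in bad.itertuples()][:5]
        raise ValueError(f"{path}: rd outside [0, 1] at cells {cells}")
    wl = np.sort(df.wavelength_nm.unique())
    fx = np.sort(df.fx_per_mm.unique())
    pivot = df.pivot(index="wavelength_nm", columns="fx_per_mm", values="rd")
    if pivot.isna().any().any():
        raise ValueError(f"{path}: incomplete (wavelength, fx) grid")
    return ReflectanceMap(wavelengths=wl, frequencies=fx, rd=pivot.loc[wl, fx].to_numpy())


def reflectance_map_to_json(measurement: ReflectanceMap) -> str:
    """Compact JSON form; round-trips exactly (floats serialized via repr)."""
    return json.dumps(
        {
            "wavelengths_nm": measurement.wavelengths.tolist(),
            "fx_per_mm": measurement.frequencies.tolist(),
            "rd": measurement.rd.tolist(),
        }
    )


def reflectance_map_from_json(text: str) -> ReflectanceMap:
    obj = json.loads(text)
    return ReflectanceMap(
        wavelengths=np.array(obj["wavelengths_nm"]),
        frequencies=np.array(obj["fx_per_mm"]),
        rd=np.array(obj["rd"]),
    )


def write_inversion_result(outdir, result: InversionResult) -> None:
    """Write an InversionResult as JSON plus per-stage delimited spectra."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wl = result.wavelengths
    payload = {
        "beta": result.beta.beta,
        "top_scattering_power_law": {
            "amplitude_per_mm": result.top_scattering.amplitude,
            "exponent": result.top_scattering.exponent,
            "lambda0_nm": result.top_scattering.lambda0,
        },
        "bottom_scattering_power_law_stage1": {
            "amplitude_per_mm": result.stage1.bottom_scattering.amplitude,
            "exponent": result.stage1.bottom_scattering.exponent,
            "lambda0_nm": result.stage1.bottom_scattering.lambda0,
        },
        "residual_norms": {
            "stage1_band1": result.stage1.diagnostics_band1.residual_norm,
            "stage1_band2": result.stage1.diagnostics_band2.residual_norm,
            "stage2": result.stage2.diagnostics.residual_norm,
        },
        "stage3_fallbacks": int(result.stage3.fallback_flags.sum()),
        "stage4_at_lower_bound": result.stage4.at_lower_bound.tolist(),
    }
    (outdir / "inversion_result.json").write_text(json.dumps(payload, indent=2))
    write_spectrum_table(outdir / "top_musp.csv", wl, result.top_scattering_spectrum(), "musp_per_mm")
    write_spectrum_table(outdir / "bottom_musp.csv", wl, result.bottom_scattering, "musp_per_mm")
    write_spectrum_table(outdir / "top_mua.csv", wl, result.top_absorption, "mua_per_mm")
    write_spectrum_table(outdir / "bottom_mua.csv", wl, result.bottom_absorption, "mua_per_mm")
    write_spectrum_table(outdir / "top_mua_stage2.csv", wl, result.stage2.top_absorption, "mua_per_mm")
    write_spectrum_table(
        outdir / "bottom_musp_stage1.csv", wl,
        result.stage1.bottom_scattering(wl), "musp_per_mm",
    )
    (outdir / "summary.txt").write_text(result.summary() + "\n")


# ---------------------------------------------------------------------------
# run configuration


def load_run_config_defaults() -> dict:
    """Default configuration objects (no file)."""
    return {
        "raw": {},
        "shef": SHEFConfig(),
        "stages": StageConfig(),
        "noise": NoiseModel(),
        "phantom": PhantomSpec(),
    }


def load_run_config(path) -> dict:
    """Parse a YAML run configuration into typed configuration objects.

    Recognized top-level keys: ``shef`` (order, mode_floor), ``stages``
    (StageConfig fields), ``noise`` (NoiseModel fields), ``phantom``
    (PhantomSpec fields with power laws as {amplitude, exponent} and
    absorption presets as {baseline, peaks}). Absent keys get defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    out: dict = {"raw": raw}
    out["shef"] = SHEFConfig(**raw.get("shef", {}))
    out["stages"] = StageConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("stages", {}).items()
    })
    out["noise"] = NoiseModel(**raw.get("noise", {}))

    ph = dict(raw.get("phantom", {}))
    kwargs = {}
    for side in ("top_scattering", "bottom_scattering"):
        if side in ph:
            kwargs[side] = PowerLawScattering(**ph.pop(side))
    if "top_absorption" in ph:
        spec = ph.pop("top_absorption")
        if isinstance(spec, str):
            from .synthetic import top_absorption_preset

            kwargs["top_absorption"] = top_absorption_preset(spec)
        else:
            kwargs["top_absorption"] = GaussianPeakAbsorption(
                baseline=spec["baseline"],
                peaks=tuple(tuple(p) for p in spec["peaks"]),
            )
    kwargs.update(ph)
    out["phantom"] = PhantomSpec(**kwargs)
    return out
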
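"""Physical constants, material optical properties and beam geometry.

All public interfaces accept the units in which they are conventionally
quoted (keV for photon energy, metres for propagation distances, µm for
sampling steps and apertures); everything is converted to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "HC_KEV_M",
    "R_E",
    "Material",
    "BeamGeometry",
    "wavenumber",
    "wavelength",
    "attenuation_coefficient",
    "electron_density_scale",
    "builtin_materials",
    "get_material",
]

#: Photon energy–wavelength product, keV·m (1.23984193 keV·nm).
HC_KEV_M = 1.23984193e-9

#: Classical electron radius, m.
R_E = 2.8179403e-15


def _require_positive(value: float, name: str) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class Material:
    """Optical properties of a homogeneous material at one photon energy.

    The complex refractive index is n = 1 − δ + iβ: ``delta`` drives the
    phase shift, ``beta`` the attenuation (μ = 2kβ).
    """

    name: str
    delta: float
    beta: float
    energy_keV: float

    def __post_init__(self) -> None:
        _require_positive(self.delta, "delta")
        _require_positive(self.beta, "beta")
        _require_positive(self.energy_keV, "energy_keV")
        if not math.isfinite(self.delta / self.beta):
            raise ValueError("delta/beta must be finite")

    @property
    def delta_over_beta(self) -> float:
        return self.delta / self.beta


@dataclass(frozen=True)
class BeamGeometry:
    """Setup geometry: energy, propagation distance and detector sampling.

    Parameters
    ----------
    energy_keV : photon energy (keV).
    z_od : object-to-detector distance (m).
    step_y_um : sampling step along y, the scan direction (µm).
    step_x_um : sampling step along x, parallel to the slits (µm).
    lsf_fwhm_x_um : FWHM of the system line spread function along x (µm).
        Along y the detector blur does not affect the edge-illumination
        signal, so no y blur is ever applied.
    """

    energy_keV: float
    z_od: float
    step_y_um: float
    step_x_um: float
    lsf_fwhm_x_um: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(self.energy_keV, "energy_keV")
        _require_positive(self.z_od, "z_od")
        _require_positive(self.step_y_um, "step_y_um")
        _require_positive(self.step_x_um, "step_x_um")
        if self.lsf_fwhm_x_um < 0:
            raise ValueError("lsf_fwhm_x_um must be >= 0")

    @property
    def step_y_m(self) -> float:
        return self.step_y_um * 1e-6

    @property
    def step_x_m(self) -> float:
        return self.step_x_um * 1e-6


def wavenumber(energy_keV: float) -> float:
    """X-ray wavenumber k = 2πE/(hc) in 1/m."""
    _require_positive(energy_keV, "energy_keV")
    return 2.0 * math.pi * energy_keV / HC_KEV_M


def wavelength(energy_keV: float) -> float:
    """X-ray wavelength λ = hc/E in m."""
    _require_positive(energy_keV, "energy_keV")
    return HC_KEV_M / energy_keV


def attenuation_coefficient(material: Material) -> float:
    """Linear attenuation coefficient μ = 2kβ in 1/m."""
    return 2.0 * wavenumber(material.energy_keV) * material.beta


def electron_density_scale(energy_keV: float) -> float:
    """Scale σ = r_e·λ²/(2π) (m³) linking δ to electron density.

    The line integral of δ along the beam equals σ·ρ_e,p where ρ_e,p is
    the projected electron density (electrons/m²); for a single-material
    object of thickness t, ρ_e,p = δ·t/σ.
    """
    lam = wavelength(energy_keV)
    return R_E * lam * lam / (2.0 * math.pi)


def builtin_materials() -> pd.DataFrame:
    """Table of bundled materials (name, energy_keV, delta, beta).

    δ and β are user-supplied tabulated values, not computed from chemical
    formulae; the bundled rows are the common test materials.
    """
    with resources.files("eiphase.data").joinpath("materials.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def get_material(name: str) -> Material:
    """Look up a bundled material by (case-insensitive) name."""
    table = builtin_materials()
    hit = table[table["name"].str.lower() == name.lower()]
    if hit.empty:
        known = ", ".join(table["name"])
        raise KeyError(f"unknown material {name!r}; bundled: {known}")
    row = hit.iloc[0]
    return Material(
        name=str(row["name"]),
        delta=float(row["delta"]),
        beta=float(row["beta"]),
        energy_keV=float(row["energy_keV"]),
    )
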
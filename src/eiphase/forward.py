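"""Forward model: simulate the normalized edge-illumination mixed image.

Along y (the scan direction, orthogonal to the slits) the object's refraction
angle shifts the beam across the detector aperture, modulating the counts
through the illumination curve; along x the signal is that of near-field
free-space propagation, expressed by the transport-of-intensity term. The
normalized signal of the linearized model is

    S_n = [ T + z·(C′/C0)·T·Δθ_y − (z/k)·∂x(T·∂xΦ) ] ⊛x LSF_x

with T = exp(−μt), Φ = −kδt and Δθ_y = (1/k)·∂yΦ = −δ·∂y t. The
``exact-curve`` mode replaces the Taylor-expanded refraction term with
T·C(y_e + z·Δθ_y)/C0, evaluating the illumination curve directly.

Source blur is already contained in the illumination curve and the detector
PSF does not affect the y signal, so the LSF blurs along x only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .materials import BeamGeometry, attenuation_coefficient, wavenumber
from .illumination import WorkingPoint, curve_fwhm
from .phantoms import MixedImage, ThicknessMap
from .retrieval import FWHM_TO_SIGMA, build_filter, pad_image

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMap",
    "RefractionMap",
    "transmission",
    "phase_shift",
    "refraction_angle_y",
    "simulate_mixed_image",
    "simulate_mixed_image_spectral",
    "taylor_validity_check",
]


@dataclass
class PhaseMap:
    """Phase shift Φ(x, y) in radians (Φ = −kδt, so ≤ 0 for matter)."""

    values: np.ndarray
    step_y_um: float
    step_x_um: float


@dataclass
class RefractionMap:
    """Refraction angle Δθ_y(x, y) in radians."""

    values: np.ndarray
    step_y_um: float
    step_x_um: float


def _require_material(t_map: ThicknessMap) -> None:
    if t_map.material is None:
        raise ValueError("thickness map needs an attached Material")


def transmission(t_map: ThicknessMap) -> np.ndarray:
    """Beam transmission T = exp(−μt), elementwise in (0, 1]."""
    _require_material(t_map)
    mu = attenuation_coefficient(t_map.material)
    return np.exp(-mu * t_map.values_m)


def phase_shift(t_map: ThicknessMap) -> PhaseMap:
    """Phase shift Φ = −kδt for a homogeneous object."""
    _require_material(t_map)
    k = wavenumber(t_map.material.energy_keV)
    return PhaseMap(
        -k * t_map.material.delta * t_map.values_m, t_map.step_y_um, t_map.step_x_um
    )


def refraction_angle_y(phase_map: PhaseMap, energy_keV: float) -> RefractionMap:
    """Refraction angle Δθ_y = (1/k)·∂Φ/∂y.

    Central differences in the interior, one-sided at the edges.
    """
    k = wavenumber(energy_keV)
    dphi_dy = np.gradient(phase_map.values, phase_map.step_y_um * 1e-6, axis=0)
    return RefractionMap(dphi_dy / k, phase_map.step_y_um, phase_map.step_x_um)


def _lsf_blur_x(values: np.ndarray, fwhm_um: float, step_x_um: float) -> np.ndarray:
    if fwhm_um <= 0:
        return values
    sigma_px = fwhm_um * FWHM_TO_SIGMA / step_x_um
    return gaussian_filter1d(values, sigma_px, axis=1, mode="mirror", truncate=6.0)


def simulate_mixed_image(
    t_map: ThicknessMap,
    geometry: BeamGeometry,
    curve,
    working_point: WorkingPoint,
    mode: str = "linearized",
    pad_fraction: float = 0.25,
) -> MixedImage:
    """Simulate the normalized mixed image S_n from a thickness map.

    ``mode='linearized'`` applies the first-order Taylor expansion of the
    illumination curve; ``'exact-curve'`` evaluates C(y_e + z·Δθ_y) without
    expansion. Derivatives are central differences on a padded grid (odd
    reflection, which continues ramps exactly; cropped back), the LSF is a
    unit-area Gaussian along x.
    """
    _require_material(t_map)
    if mode not in ("linearized", "exact-curve"):
        raise ValueError(f"mode must be 'linearized' or 'exact-curve', got {mode!r}")
    if mode == "linearized" and working_point.c1_per_um == 0.0:
        raise ValueError(
            "working point has zero slope: no refraction sensitivity in linearized mode"
        )
    mat = t_map.material
    k = wavenumber(mat.energy_keV)
    z = geometry.z_od
    dy, dx = t_map.step_y_um * 1e-6, t_map.step_x_um * 1e-6

    t_pad, crop = pad_image(t_map.values_m, pad_fraction, mode="odd")
    mu = attenuation_coefficient(mat)
    T = np.exp(-mu * t_pad)
    phi = -k * mat.delta * t_pad
    dtheta_y = np.gradient(phi, dy, axis=0) / k

    # transport-of-intensity term along x: −(z/k)·∂x(T·∂xΦ), discretized in
    # conservative (staggered flux) form so it reduces to the compact
    # three-point Laplacian when T varies slowly
    dphi_half = (np.roll(phi, -1, axis=1) - phi) / dx
    t_half = 0.5 * (T + np.roll(T, -1, axis=1))
    flux = t_half * dphi_half
    tie = -(z / k) * (flux - np.roll(flux, 1, axis=1)) / dx

    if mode == "linearized":
        refr = T * (1.0 + z * working_point.slope_ratio_per_m * dtheta_y)
    else:
        shift_um = z * dtheta_y * 1e6
        y_eval = working_point.y_e_um + shift_um
        lo, hi = curve.support_um
        if np.any(y_eval < lo) or np.any(y_eval > hi):
            raise ValueError(
                "refraction shift drives the working point outside the "
                "illumination curve's tabulated support"
            )
        refr = T * np.asarray(curve(y_eval)) / working_point.c0

    s = _lsf_blur_x(refr + tie, geometry.lsf_fwhm_x_um, t_map.step_x_um)[crop]
    meta = {
        "mode": mode,
        "z_od": z,
        "energy_keV": mat.energy_keV,
        "material": mat.name,
        "working_point": {
            "y_e_um": working_point.y_e_um,
            "c0": working_point.c0,
            "c1_per_um": working_point.c1_per_um,
            "branch": working_point.branch,
        },
        "lsf_fwhm_x_um": geometry.lsf_fwhm_x_um,
    }
    return MixedImage(s, t_map.step_y_um, t_map.step_x_um, meta)


def simulate_mixed_image_spectral(
    t_map: ThicknessMap,
    geometry: BeamGeometry,
    working_point: WorkingPoint,
    stencil: str = "difference",
    pad: bool = True,
    pad_fraction: float = 0.25,
) -> MixedImage:
    """Spectral evaluation of the compact single-material form.

    Regrouping the linearized model with T·∂t = −(1/μ)·∂exp(−μt) gives
    S_n = F⁻¹{ D · F{exp(−μt)} } with the same denominator D the retrieval
    divides by — an independent oracle for the spatial simulator and, with
    ``pad=False`` (periodic FFT on the given grid), the exact inverse pair
    of the retrieval operating on that same grid.
    """
    _require_material(t_map)
    mat = t_map.material
    mu = attenuation_coefficient(mat)
    amplitude = geometry.z_od * mat.delta / mu
    w = np.exp(-mu * t_map.values_m)
    if pad:
        w, crop = pad_image(w, pad_fraction, mode="odd")
    else:
        crop = (slice(None), slice(None))
    filt = build_filter(
        w.shape,
        t_map.step_y_um,
        t_map.step_x_um,
        amplitude,
        working_point.slope_ratio_per_m,
        geometry.lsf_fwhm_x_um,
        stencil=stencil,
    )
    s = np.fft.ifft2(np.fft.fft2(w) * filt.denominator).real[crop]
    meta = {"mode": f"spectral-{stencil}", "z_od": geometry.z_od, "material": mat.name}
    return MixedImage(s, t_map.step_y_um, t_map.step_x_um, meta)


def taylor_validity_check(
    t_map: ThicknessMap,
    geometry: BeamGeometry,
    curve,
    working_point: WorkingPoint,
    warn_ratio: float = 0.2,
) -> dict:
    """Check the linearization premise: refraction beam shifts must stay small
    compared with the illumination-curve width.

    Returns the maximum |z·Δθ_y| and its ratio to the curve FWHM; logs a
    warning above ``warn_ratio``.
    """
    _require_material(t_map)
    dtheta = refraction_angle_y(phase_shift(t_map), t_map.material.energy_keV)
    max_shift_m = float(np.max(np.abs(geometry.z_od * dtheta.values)))
    fwhm_um = curve_fwhm(curve)
    ratio = max_shift_m * 1e6 / fwhm_um
    if ratio > warn_ratio:
        logger.warning(
            "refraction shift reaches %.3g of the illumination-curve FWHM "
            "(max shift %.3g µm, FWHM %.3g µm): Taylor expansion may be inaccurate",
            ratio,
            max_shift_m * 1e6,
            fwhm_um,
        )
    return {
        "max_shift_um": max_shift_m * 1e6,
        "curve_fwhm_um": fwhm_um,
        "ratio": ratio,
        "within_linear_regime": ratio <= warn_ratio,
    }
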
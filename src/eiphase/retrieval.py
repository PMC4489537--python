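"""Single-image retrieval of thickness or projected electron density.

The normalized edge-illumination signal of a homogeneous object,

    S_n = [ W + A·(C′/C0)·∂y W − A·∂x² W ] ⊛x LSF_x,   W = exp(−μt),

with A = zδ/μ = (z/2k)(δ/β), becomes a single algebraic relation in Fourier
space (derivative theorem, forward kernel e^{−iξ·r}):

    F{S_n} = MTF_x(ξx) · [ 1 + A·ξx² + i·A·(C′/C0)·ξy ] · F{W} = D · F{W}.

The denominator D never vanishes — |D| ≥ MTF_x > 0 and D(0,0) = 1 — so the
retrieval  t = −ln( F⁻¹{ F{S_n}/D } )/μ  is stable at every frequency and
behaves as a low-pass filter: both attenuation and refraction information is
used, the attenuation signal anchoring the zero and low frequencies.

Under the weaker assumption of a constant δ/β ratio the same filter yields
the projected electron density ρ_e,p = −ln(·)/γ with γ = 2k(β/δ)·σ and
σ = r_e λ²/2π.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .materials import (
    BeamGeometry,
    Material,
    attenuation_coefficient,
    electron_density_scale,
    wavenumber,
)
from .illumination import WorkingPoint
from .phantoms import MixedImage, ThicknessMap

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalFilter",
    "ElectronDensityMap",
    "build_filter",
    "retrieve_thickness",
    "retrieve_electron_density",
    "pad_image",
    "FWHM_TO_SIGMA",
]

#: Gaussian FWHM → standard deviation conversion, 1/(2·sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class ElectronDensityMap:
    """Projected electron density ρ_e,p in electrons/µm²."""

    values: np.ndarray
    step_y_um: float
    step_x_um: float
    meta: dict | None = None


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def pad_image(values: np.ndarray, pad_fraction: float = 0.25, mode: str = "edge"):
    """Pad to the next power of two with at least ``pad_fraction`` margin per side.

    ``mode`` is 'edge' (replicate the border value — the correct continuation
    for a compactly supported object whose signal has flattened at the frame
    edge), 'odd' (point-reflection about the border value, which continues
    linear trends and is used for thickness maps in the forward model), or
    any other np.pad mode. Returns the padded array and the slices that crop
    back to the original.
    """
    ny, nx = values.shape
    out_shape, slices = [], []
    for n in (ny, nx):
        margin = int(math.ceil(pad_fraction * n))
        target = _next_pow2(n + 2 * margin)
        before = (target - n) // 2
        out_shape.append(target)
        slices.append(slice(before, before + n))
    pads = [(s.start, t - s.stop) for s, t in zip(slices, out_shape)]
    if mode == "odd":
        padded = np.pad(values, pads, mode="reflect", reflect_type="odd")
    else:
        padded = np.pad(values, pads, mode=mode)
    return padded, tuple(slices)


def sampled_gaussian_mtf(n: int, sigma_px: float) -> np.ndarray:
    """DFT of the discretely sampled, truncated, unit-sum Gaussian kernel.

    Matches circular convolution with the same kernel ``gaussian_filter1d``
    applies, which is what the difference-stencil filter must encode.
    """
    if sigma_px <= 0:
        return np.ones(n)
    impulse = np.zeros(n)
    impulse[0] = 1.0
    kernel = gaussian_filter1d(impulse, sigma_px, mode="wrap", truncate=6.0)
    return np.fft.fft(kernel).real


@dataclass
class RetrievalFilter:
    """Complex Fourier-domain denominator D(ξx, ξy) and its ingredients.

    ``amplitude_m2`` is A = zδ/μ (m²); ``slope_ratio_per_m`` is C′/C0 (1/m);
    ``mtf_x`` is MTF_x sampled on the grid's ξx frequencies. By construction
    |D| ≥ mtf_x > 0 everywhere and D(0, 0) = 1: the filter never diverges,
    in particular at the zeroth frequency.
    """

    denominator: np.ndarray  # complex, shape (ny, nx)
    amplitude_m2: float
    slope_ratio_per_m: float
    mtf_x: np.ndarray  # shape (nx,)
    step_y_um: float
    step_x_um: float
    stencil: str


def build_filter(
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    amplitude_m2: float,
    slope_ratio_per_m: float,
    lsf_fwhm_x_um: float = 0.0,
    stencil: str = "spectral",
) -> RetrievalFilter:
    """Build the retrieval denominator D on a discrete frequency grid.

    ``stencil='spectral'`` uses the continuous Fourier symbols (ξx², ξy) and
    the analytic Gaussian MTF — the filter as derived. ``'difference'`` uses
    the DFT symbols of the central-difference stencils and the sampled LSF
    kernel's DFT, the exact inverse of a discrete forward model built from
    those same stencils.
    """
    if amplitude_m2 < 0:
        raise ValueError("amplitude A must be >= 0")
    if stencil not in ("spectral", "difference"):
        raise ValueError(f"stencil must be 'spectral' or 'difference', got {stencil!r}")
    ny, nx = shape
    dy, dx = step_y_um * 1e-6, step_x_um * 1e-6
    xi_x = 2.0 * np.pi * np.fft.fftfreq(nx, d=dx)
    xi_y = 2.0 * np.pi * np.fft.fftfreq(ny, d=dy)
    sigma_m = lsf_fwhm_x_um * 1e-6 * FWHM_TO_SIGMA
    if stencil == "spectral":
        qx2 = xi_x**2
        sy = xi_y.copy()
        if ny % 2 == 0:
            # the Nyquist row is its own conjugate partner: an odd derivative
            # symbol there would break Hermitian symmetry and leak an
            # imaginary part into the real-valued image
            sy[ny // 2] = 0.0
        mtf = np.exp(-0.5 * (sigma_m * xi_x) ** 2)
    else:
        qx2 = (2.0 - 2.0 * np.cos(xi_x * dx)) / dx**2
        sy = np.sin(xi_y * dy) / dy
        mtf = sampled_gaussian_mtf(nx, sigma_m / dx)
    denom = mtf[None, :] * (
        1.0
        + amplitude_m2 * qx2[None, :]
        + 1j * amplitude_m2 * slope_ratio_per_m * sy[:, None]
    )
    return RetrievalFilter(
        denominator=denom,
        amplitude_m2=amplitude_m2,
        slope_ratio_per_m=slope_ratio_per_m,
        mtf_x=mtf,
        step_y_um=step_y_um,
        step_x_um=step_x_um,
        stencil=stencil,
    )


def _filtered_neglog(
    image: MixedImage,
    geometry: BeamGeometry,
    amplitude_m2: float,
    working_point: WorkingPoint,
    stencil: str,
    pad: bool,
    pad_fraction: float,
    eps: float,
    pad_mode: str = "edge",
):
    """Shared FFT core: divide by D, invert, clip and take −ln. Returns (−ln W, stats)."""
    if working_point.c1_per_um == 0.0:
        raise ValueError("working point has zero slope: no refraction sensitivity")
    values = image.values
    if pad:
        padded, crop = pad_image(values, pad_fraction, mode=pad_mode)
    else:
        padded, crop = values, (slice(None), slice(None))
    filt = build_filter(
        padded.shape,
        image.step_y_um,
        image.step_x_um,
        amplitude_m2,
        working_point.slope_ratio_per_m,
        geometry.lsf_fwhm_x_um,
        stencil=stencil,
    )
    w = np.fft.ifft2(np.fft.fft2(padded) / filt.denominator)
    real_rms = float(np.sqrt(np.mean(w.real**2)))
    imag_rms = float(np.sqrt(np.mean(w.imag**2)))
    w = w.real[crop]
    n_clipped = int(np.count_nonzero(w < eps))
    if n_clipped == w.size:
        raise ValueError(
            "every filtered pixel fell below the clipping floor: "
            "input is inconsistent with the forward model"
        )
    if n_clipped:
        logger.info("clipped %d/%d filtered pixels at eps=%g", n_clipped, w.size, eps)
    stats = {
        "clipped_pixels": n_clipped,
        "clipped_fraction": n_clipped / w.size,
        "imag_to_real_rms": imag_rms / real_rms if real_rms else 0.0,
        "stencil": stencil,
        "amplitude_m2": amplitude_m2,
        "slope_ratio_per_m": working_point.slope_ratio_per_m,
    }
    return -np.log(np.clip(w, eps, None)), stats


def retrieve_thickness(
    image: MixedImage,
    material: Material,
    geometry: BeamGeometry,
    working_point: WorkingPoint,
    stencil: str = "spectral",
    pad: bool = True,
    pad_fraction: float = 0.25,
    eps: float = 1e-8,
    pad_mode: str = "edge",
) -> ThicknessMap:
    """Recover the object thickness map from a single mixed image.

    t = −ln( F⁻¹{ F{S_n}/D } )/μ, evaluated on an edge-padded grid and
    cropped back; the argument of the logarithm is clipped below at ``eps``
    (clipped-pixel counts are logged and reported in the result's metadata).
    """
    mu = attenuation_coefficient(material)
    amplitude = geometry.z_od * material.delta / mu
    neglog, stats = _filtered_neglog(
        image, geometry, amplitude, working_point, stencil, pad, pad_fraction, eps, pad_mode
    )
    t_um = neglog / mu * 1e6
    # noise can ring slightly negative; clip for the thickness invariant and
    # keep the raw minimum in the metadata
    stats["raw_min_t_um"] = float(t_um.min())
    return ThicknessMap(
        np.clip(t_um, 0.0, None), image.step_y_um, image.step_x_um, material, stats
    )


def retrieve_electron_density(
    image: MixedImage,
    delta_over_beta: float,
    geometry: BeamGeometry,
    working_point: WorkingPoint,
    stencil: str = "spectral",
    pad: bool = True,
    pad_fraction: float = 0.25,
    eps: float = 1e-8,
    pad_mode: str = "edge",
) -> ElectronDensityMap:
    """Recover projected electron density assuming only a constant δ/β ratio.

    ρ_e,p = −ln( F⁻¹{ F{S_n}/D } )/γ with A = (z/2k)(δ/β) in D and
    γ = 2k·σ/(δ/β), σ = r_e λ²/2π. Reported in electrons/µm².
    """
    if not delta_over_beta > 0:
        raise ValueError(f"delta_over_beta must be > 0, got {delta_over_beta}")
    k = wavenumber(geometry.energy_keV)
    amplitude = geometry.z_od / (2.0 * k) * delta_over_beta
    gamma = 2.0 * k * electron_density_scale(geometry.energy_keV) / delta_over_beta
    neglog, stats = _filtered_neglog(
        image, geometry, amplitude, working_point, stencil, pad, pad_fraction, eps, pad_mode
    )
    rho_per_um2 = neglog / gamma * 1e-12  # e/m² → e/µm²
    return ElectronDensityMap(rho_per_um2, image.step_y_um, image.step_x_um, stats)
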
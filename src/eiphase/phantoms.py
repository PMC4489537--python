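"""Synthetic thickness maps with known ground truth, and Poisson noise injection.

All generators are pure functions of their arguments (plus an explicit
integer seed where randomness is involved); there is no global RNG state.
Grid convention: row index = y (scan direction), column index = x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .materials import Material

__all__ = [
    "ThicknessMap",
    "MixedImage",
    "cylinder_wire",
    "slab",
    "sphere",
    "wedge",
    "textured_phantom",
    "add_poisson_noise",
]


@dataclass
class ThicknessMap:
    """Projected object thickness t(x, y) in µm on a regular grid."""

    values: np.ndarray  # µm, shape (ny, nx)
    step_y_um: float
    step_x_um: float
    material: Material | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("thickness map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("thickness map must be finite")
        if np.any(self.values < 0):
            raise ValueError("thickness must be >= 0 everywhere")

    @property
    def values_m(self) -> np.ndarray:
        return self.values * 1e-6


@dataclass
class MixedImage:
    """Normalized edge-illumination signal S_n(x, y) (dimensionless)."""

    values: np.ndarray  # shape (ny, nx)
    step_y_um: float
    step_x_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("mixed image must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mixed image must be finite")


def _grid(shape, step_y_um, step_x_um):
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * step_y_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * step_x_um
    return y[:, None], x[None, :]


def cylinder_wire(
    diameter_um: float,
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    center_y_um: float = 0.0,
    material: Material | None = None,
    supersample: int = 1,
) -> ThicknessMap:
    """Perfectly cylindrical wire with its axis along x.

    The projected thickness is the chord t(y) = 2·sqrt((d/2)² − (y−yc)²)
    inside the wire and 0 outside, independent of x. ``supersample`` > 1
    area-averages each pixel over that many sub-samples along y to quantify
    discretisation error; by default pixels sample the chord at their centre.
    """
    if not diameter_um > 0:
        raise ValueError(f"diameter_um must be > 0, got {diameter_um}")
    if diameter_um < step_y_um:
        raise ValueError(
            f"wire diameter {diameter_um} µm is below one y step ({step_y_um} µm): unresolvable"
        )
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    ny, nx = shape
    y, _ = _grid(shape, step_y_um, step_x_um)
    r = diameter_um / 2.0

    def chord(yy):
        s2 = r * r - (yy - center_y_um) ** 2
        return 2.0 * np.sqrt(np.clip(s2, 0.0, None))

    if supersample == 1:
        t = chord(y)
    else:
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        t = np.mean([chord(y + o * step_y_um) for o in offs], axis=0)
    return ThicknessMap(np.broadcast_to(t, (ny, nx)).copy(), step_y_um, step_x_um, material)


def slab(
    thickness_um: float,
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    material: Material | None = None,
) -> ThicknessMap:
    """Uniform slab: constant thickness everywhere (analytic attenuation limit)."""
    if thickness_um < 0:
        raise ValueError("thickness_um must be >= 0")
    return ThicknessMap(np.full(shape, float(thickness_um)), step_y_um, step_x_um, material)


def sphere(
    diameter_um: float,
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    center_um: tuple[float, float] = (0.0, 0.0),
    material: Material | None = None,
) -> ThicknessMap:
    """Sphere: t = 2·sqrt(r² − ρ²) radially around ``center_um`` = (y, x)."""
    if not diameter_um > 0:
        raise ValueError(f"diameter_um must be > 0, got {diameter_um}")
    y, x = _grid(shape, step_y_um, step_x_um)
    r = diameter_um / 2.0
    rho2 = (y - center_um[0]) ** 2 + (x - center_um[1]) ** 2
    t = 2.0 * np.sqrt(np.clip(r * r - rho2, 0.0, None))
    return ThicknessMap(t, step_y_um, step_x_um, material)


def wedge(
    t_min_um: float,
    t_max_um: float,
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    axis: str = "y",
    material: Material | None = None,
) -> ThicknessMap:
    """Linear thickness ramp from t_min to t_max along ``axis`` ('y' or 'x')."""
    if t_min_um < 0 or t_max_um < 0:
        raise ValueError("wedge thicknesses must be >= 0")
    if axis not in ("y", "x"):
        raise ValueError("axis must be 'y' or 'x'")
    ny, nx = shape
    n = ny if axis == "y" else nx
    ramp = np.linspace(t_min_um, t_max_um, n)
    t = np.broadcast_to(ramp[:, None] if axis == "y" else ramp[None, :], (ny, nx))
    return ThicknessMap(t.copy(), step_y_um, step_x_um, material)


def textured_phantom(
    shape: tuple[int, int],
    step_y_um: float,
    step_x_um: float,
    seed: int,
    n_blobs: int = 12,
    blob_scale_um: float = 40.0,
    blob_thickness_um: float = 40.0,
    background_um: float = 10.0,
    smooth_um: float = 3.0,
    material: Material | None = None,
) -> ThicknessMap:
    """Petal-like textured phantom: smooth elliptical blobs on a soft background.

    Emulates a thin biological sample — pollen-grain-like smooth blobs of
    random size/orientation, plus a low-amplitude background membrane with
    embedded low-thickness circular spots (cell-like). Deterministic for a
    fixed seed; values are non-negative and bounded by
    ``blob_thickness_um + background_um``.

    The final map is softened with a Gaussian of width ``smooth_um`` so the
    phantom is slowly varying at the pixel scale — the regime in which the
    near-field transport-of-intensity description of the forward model is
    valid in the first place.
    """
    if blob_scale_um <= 0 or blob_thickness_um < 0 or background_um < 0:
        raise ValueError("blob scale must be > 0 and thicknesses >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    y, x = _grid(shape, step_y_um, step_x_um)
    ey, ex = (ny - 1) / 2.0 * step_y_um, (nx - 1) / 2.0 * step_x_um
    t = np.zeros(shape)

    # background membrane with gentle large-scale modulation
    if background_um > 0:
        ky = np.pi / max(ey, 1e-9) * rng.uniform(0.5, 1.5)
        kx = np.pi / max(ex, 1e-9) * rng.uniform(0.5, 1.5)
        phase_y, phase_x = rng.uniform(0, 2 * np.pi, 2)
        t += background_um * (0.75 + 0.25 * np.cos(ky * y + phase_y) * np.cos(kx * x + phase_x))
        # cell-like thin spots carved out of the membrane
        for _ in range(max(n_blobs // 2, 1) if n_blobs else 0):
            cy, cx = rng.uniform(-ey, ey), rng.uniform(-ex, ex)
            r = rng.uniform(0.3, 0.8) * blob_scale_um
            rho2 = ((y - cy) ** 2 + (x - cx) ** 2) / (r * r)
            t -= 0.5 * background_um * np.exp(-rho2)

    for _ in range(n_blobs):
        cy, cx = rng.uniform(-0.8 * ey, 0.8 * ey), rng.uniform(-0.8 * ex, 0.8 * ex)
        sy = rng.uniform(0.5, 1.5) * blob_scale_um
        sx = rng.uniform(0.5, 1.5) * blob_scale_um
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.4, 1.0) * blob_thickness_um
        yr = (y - cy) * np.cos(theta) + (x - cx) * np.sin(theta)
        xr = -(y - cy) * np.sin(theta) + (x - cx) * np.cos(theta)
        # compact smooth bump (C¹, exactly zero outside its ellipse)
        rho2 = (yr / sy) ** 2 + (xr / sx) ** 2
        t += amp * np.clip(1.0 - rho2, 0.0, None) ** 2

    t = np.clip(t, 0.0, background_um + blob_thickness_um)
    if smooth_um > 0:
        t = gaussian_filter(
            t, (smooth_um / step_y_um, smooth_um / step_x_um), mode="nearest"
        )
    return ThicknessMap(t, step_y_um, step_x_um, material)


def add_poisson_noise(image: MixedImage, photons_per_pixel: float, seed: int) -> MixedImage:
    """Add Poisson noise at the stated mean photon count per pixel.

    Each pixel value S is replaced by Poisson(n̄·S)/n̄ with n̄ =
    ``photons_per_pixel``, so the expectation is preserved pixel-wise and the
    relative standard deviation on a unit image is 1/sqrt(n̄).
    """
    if not photons_per_pixel > 0:
        raise ValueError(f"photons_per_pixel must be > 0, got {photons_per_pixel}")
    if np.any(image.values < 0):
        raise ValueError("cannot draw Poisson counts from negative pixel values")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(photons_per_pixel * image.values)
    meta = dict(image.meta)
    meta.update(noise="poisson", photons_per_pixel=photons_per_pixel, noise_seed=seed)
    return MixedImage(counts / photons_per_pixel, image.step_y_um, image.step_x_um, meta)
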
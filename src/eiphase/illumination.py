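"""Illumination curve C(y_e): fraction of the unperturbed beam reaching the detector.

Convention
----------
The abscissa ``y_e`` is the *beam-relative* offset in µm: the height of the
beam-profile centre above the lower edge of the detector aperture. With this
parametrisation an upward refraction shift Δy adds to y_e, so the recorded
fraction is C(y_e + z·Δθ_y), and on the default "lower" branch the slope
C′(y_e) is positive (an upward beam shift increases counts).

The analytic model folds the source blur into the curve (Gaussian convolution
of the beam profile); the detector point spread function is never applied to
the y signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = ["AnalyticCurve", "TabulatedCurve", "WorkingPoint", "working_point", "curve_fwhm"]


@dataclass(frozen=True)
class WorkingPoint:
    """Aperture offset and local curve values at which images are acquired.

    ``c1_per_um`` is the slope C′(y_e) in 1/µm; ``branch`` records which
    monotone edge of the curve the point sits on.
    """

    y_e_um: float
    c0: float
    c1_per_um: float
    branch: str

    def __post_init__(self) -> None:
        if not (0 < self.c0 <= 1):
            raise ValueError(f"C0 must be in (0, 1], got {self.c0}")

    @property
    def slope_ratio_per_m(self) -> float:
        """C′/C0 in 1/m, the refraction-sensitivity ratio."""
        return self.c1_per_um / self.c0 * 1e6


def _gauss_cdf(u: np.ndarray | float, sigma: float) -> np.ndarray | float:
    if sigma == 0.0:
        return np.heaviside(np.asarray(u, dtype=float), 0.5)
    return ndtr(np.asarray(u, dtype=float) / sigma)


def _gauss_pdf(u: np.ndarray | float, sigma: float) -> np.ndarray | float:
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))


class AnalyticCurve:
    """Illumination curve of a rect beam profile blurred by a Gaussian.

    The unit-mass beam profile is P = (1/a1)·rect_{a1} ⊛ N(0, sigma_src²),
    centred at 0; the detector aperture has width ``a2_um`` (``inf`` for a
    single edge). C(y_e) integrates P over the aperture when the beam centre
    sits ``y_e`` above the aperture's lower edge.
    """

    kind = "analytic"

    def __init__(self, a1_um: float, a2_um: float = math.inf, sigma_src_um: float = 0.0):
        if not a1_um > 0:
            raise ValueError(f"a1_um must be > 0, got {a1_um}")
        if not a2_um > 0:
            raise ValueError(f"a2_um must be > 0, got {a2_um}")
        if sigma_src_um < 0:
            raise ValueError(f"sigma_src_um must be >= 0, got {sigma_src_um}")
        self.a1_um = float(a1_um)
        self.a2_um = float(a2_um)
        self.sigma_src_um = float(sigma_src_um)

    # CDF of P: F(y) = (1/a1)·[H(y + a1/2) − H(y − a1/2)],
    # H(u) = u·Φσ(u) + σ²·φσ(u) is the antiderivative of the Gaussian CDF.
    def _profile_cdf(self, y):
        a, s = self.a1_um, self.sigma_src_um
        if s == 0.0:
            return np.clip((np.asarray(y, dtype=float) + a / 2) / a, 0.0, 1.0)

        def H(u):
            return u * _gauss_cdf(u, s) + s * s * _gauss_pdf(u, s)

        return (H(np.asarray(y, dtype=float) + a / 2) - H(np.asarray(y, dtype=float) - a / 2)) / a

    def profile(self, y):
        """Blurred unit-mass beam profile P(y) (1/µm)."""
        a, s = self.a1_um, self.sigma_src_um
        y = np.asarray(y, dtype=float)
        if s == 0.0:
            return np.where(np.abs(y) <= a / 2, 1.0 / a, 0.0)
        return (_gauss_cdf(y + a / 2, s) - _gauss_cdf(y - a / 2, s)) / a

    @property
    def support_um(self) -> tuple[float, float]:
        return (-math.inf, math.inf)

    def __call__(self, y_e):
        # beam centre y_e above the lower edge ⇒ aperture covers
        # profile coordinates [−y_e, −y_e + a2]
        lo = -np.asarray(y_e, dtype=float)
        if math.isinf(self.a2_um):
            c = 1.0 - self._profile_cdf(lo)
        else:
            c = self._profile_cdf(lo + self.a2_um) - self._profile_cdf(lo)
        return np.clip(c, 0.0, 1.0)

    def slope(self, y_e):
        """dC/dy_e in 1/µm."""
        lo = -np.asarray(y_e, dtype=float)
        upper = 0.0 if math.isinf(self.a2_um) else self.profile(lo + self.a2_um)
        return self.profile(lo) - upper

    def apex(self) -> float:
        """Offset of maximum illumination (beam centred in the aperture).

        For a single edge (infinite aperture) C saturates instead of peaking;
        the saturation offset is returned and only the lower branch exists.
        """
        if math.isinf(self.a2_um):
            return self.a1_um / 2 + 8.0 * self.sigma_src_um + 1.0
        return self.a2_um / 2.0

    def bracket_um(self) -> tuple[float, float]:
        """Offsets beyond which C is negligibly far from its asymptotes."""
        reach = self.a1_um / 2 + 8.0 * self.sigma_src_um
        a2 = 0.0 if math.isinf(self.a2_um) else self.a2_um
        return (-reach - 1.0, a2 + reach + 1.0)


class TabulatedCurve:
    """Measured illumination curve interpolated with a cubic spline.

    The curve is renormalised so its apex is exactly 1; a warning is logged
    when the raw apex differs from 1 by more than 5%. Evaluation outside the
    tabulated support is rejected (no extrapolation).
    """

    kind = "tabulated"

    def __init__(self, y_e_um: np.ndarray, c: np.ndarray):
        y_e_um = np.asarray(y_e_um, dtype=float)
        c = np.asarray(c, dtype=float)
        if y_e_um.ndim != 1 or y_e_um.size < 4:
            raise ValueError("tabulated curve needs a 1D grid of at least 4 points")
        if not np.all(np.diff(y_e_um) > 0):
            raise ValueError("tabulated y_e grid must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            raise ValueError("tabulated C values must be finite and >= 0")
        apex = c.max()
        if apex <= 0:
            raise ValueError("tabulated curve is identically zero")
        if abs(apex - 1.0) > 0.05:
            logger.warning("illumination curve apex %.4f renormalised to 1", apex)
        self.y_e_um = y_e_um
        self.c = c / apex
        self._spline = CubicSpline(self.y_e_um, self.c)

    @property
    def support_um(self) -> tuple[float, float]:
        return (float(self.y_e_um[0]), float(self.y_e_um[-1]))

    def _check_domain(self, y_e) -> np.ndarray:
        y_e = np.asarray(y_e, dtype=float)
        lo, hi = self.support_um
        if np.any(y_e < lo) or np.any(y_e > hi):
            raise ValueError(
                f"offset outside tabulated support [{lo}, {hi}] µm (no extrapolation)"
            )
        return y_e

    def __call__(self, y_e):
        return np.clip(self._spline(self._check_domain(y_e)), 0.0, 1.0)

    def slope(self, y_e):
        return self._spline(self._check_domain(y_e), 1)

    def apex(self) -> float:
        grid = np.linspace(*self.support_um, 4001)
        return float(grid[int(np.argmax(self._spline(grid)))])

    def bracket_um(self) -> tuple[float, float]:
        return self.support_um


def working_point(curve, fraction: float, branch: str = "lower") -> WorkingPoint:
    """Invert C on one monotone edge branch to the requested illumination fraction.

    ``branch='lower'`` selects the rising edge below the apex (C′ > 0),
    ``'upper'`` the falling edge above it. Bisection to 1e-9 relative.
    """
    if branch not in ("lower", "upper"):
        raise ValueError(f"branch must be 'lower' or 'upper', got {branch!r}")
    apex = curve.apex()
    c_max = float(curve(apex))
    if not (0 < fraction < c_max):
        raise ValueError(
            f"fraction must lie strictly inside (0, {c_max:.6g}) to sit on an edge "
            f"branch, got {fraction}"
        )
    lo, hi = curve.bracket_um()
    a, b = (lo, apex) if branch == "lower" else (apex, hi)

    def f(y):
        return float(curve(y)) - fraction

    # guard brackets where C has flattened to its asymptote
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise ValueError(f"fraction {fraction} unreachable on the {branch} branch")
    y_e = brentq(f, a, b, xtol=1e-12, rtol=1e-12)
    c0 = float(curve(y_e))
    c1 = float(curve.slope(y_e))
    if c1 == 0.0:
        raise ValueError("working point has zero slope (no refraction sensitivity)")
    return WorkingPoint(y_e_um=float(y_e), c0=c0, c1_per_um=c1, branch=branch)


def curve_fwhm(curve) -> float:
    """Full width of the region where C exceeds half its apex value (µm)."""
    apex = curve.apex()
    half = float(curve(apex)) / 2.0
    lo, hi = curve.bracket_um()

    def f(y):
        return float(curve(y)) - half

    left = brentq(f, lo, apex, xtol=1e-10)
    right = brentq(f, apex, hi, xtol=1e-10)
    return float(right - left)
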
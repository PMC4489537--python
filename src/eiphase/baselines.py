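"""Two-image retrieval baseline, 1D phase integration, and comparison metrics.

The classical edge-illumination retrieval separates transmission and
refraction from two images taken at symmetric working points on opposite
edges of the illumination curve; the phase (thickness) map then follows by
one-dimensional integration of the refraction image along y — a procedure
known to accumulate noise into streaks along the integration direction.
The metrics here quantify that: ``streak_index`` measures how much of the
residual variance lives in column-wise offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .illumination import WorkingPoint
from .phantoms import MixedImage, ThicknessMap

__all__ = [
    "ComparisonReport",
    "two_image_retrieval",
    "integrate_refraction",
    "streak_index",
    "rmse",
    "extract_profile",
    "compare_to_truth",
]


@dataclass
class ComparisonReport:
    """Quantitative comparison of a retrieved map against ground truth."""

    rmse: float
    streak_index: float
    clipped_fraction: float = 0.0
    profiles: dict = field(default_factory=dict)

    def as_flat_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "streak_index": self.streak_index,
            "clipped_fraction": self.clipped_fraction,
        }


def two_image_retrieval(
    s_plus: MixedImage,
    s_minus: MixedImage,
    wp_plus: WorkingPoint,
    wp_minus: WorkingPoint,
    z_od: float,
):
    """Separate transmission and refraction from two symmetric mixed images.

    Requires working points with equal illumination C0 and slopes of equal
    magnitude but opposite sign (opposite edges). Under the linearized model
    S± = T·(1 ± z·(C1/C0)·Δθ_y),

        T = (S⁺ + S⁻)/2,
        Δθ_y = C0·(S⁺ − S⁻) / (z·C1·(S⁺ + S⁻)),

    which is exact at the linearized-simulator level for objects with no
    free-space-propagation contrast along x.
    """
    if abs(wp_plus.c0 - wp_minus.c0) > 1e-6:
        raise ValueError("working points must have equal illumination fractions")
    if abs(wp_plus.c1_per_um + wp_minus.c1_per_um) > 1e-6 * abs(wp_plus.c1_per_um):
        raise ValueError("working points must have opposite slopes of equal magnitude")
    if s_plus.values.shape != s_minus.values.shape:
        raise ValueError("the two images must share a grid")
    total = s_plus.values + s_minus.values
    T = total / 2.0
    c1_per_m = wp_plus.c1_per_um * 1e6
    # photon-starved pixels can have zero counts in both images; |S⁺−S⁻| ≤ ΣS
    # so flooring the sum just maps those pixels to Δθ = 0
    safe_total = np.clip(total, 1e-6, None)
    dtheta = wp_plus.c0 * (s_plus.values - s_minus.values) / (z_od * c1_per_m * safe_total)
    return T, dtheta


def integrate_refraction(
    refraction: np.ndarray,
    delta: float,
    step_y_um: float,
    step_x_um: float,
    material=None,
) -> ThicknessMap:
    """Thickness by cumulative 1D integration of the refraction image along y.

    Δθ_y = −δ·∂y t, so t = −(1/δ)·Σ Δθ_y·Δy down each column, anchored at
    zero on the first row (the object is assumed absent at the frame edge —
    the boundary knowledge this baseline cannot do without).
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    t_m = -np.cumsum(refraction * step_y_um * 1e-6, axis=0) / delta
    return ThicknessMap(np.clip(t_m, 0.0, None) * 1e6, step_y_um, step_x_um, material)


def streak_index(residual: np.ndarray) -> float:
    """Fraction of residual variance explained by column-wise offsets.

    Var_x( mean_y(residual) ) / Var_{x,y}(residual): near 1 when the error is
    constant along each column (pure streaks), near 1/N_y for i.i.d. noise,
    and defined as 0 for a zero-variance residual.
    """
    residual = np.asarray(residual, dtype=float)
    total = residual.var()
    if total == 0.0:
        return 0.0
    return float(residual.mean(axis=0).var() / total)


def rmse(values: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square difference between two maps of identical shape."""
    values, truth = np.asarray(values, dtype=float), np.asarray(truth, dtype=float)
    if values.shape != truth.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((values - truth) ** 2)))


def extract_profile(values: np.ndarray, axis: str, index: int) -> np.ndarray:
    """1D profile through a map: axis 'y' gives column ``index`` (vertical
    profile), axis 'x' gives row ``index``."""
    values = np.asarray(values)
    if axis == "y":
        return values[:, index].copy()
    if axis == "x":
        return values[index, :].copy()
    raise ValueError("axis must be 'y' or 'x'")


def compare_to_truth(
    retrieved: ThicknessMap,
    truth: ThicknessMap,
    profile_index: int | None = None,
) -> ComparisonReport:
    """Bundle RMSE, streak index and (optionally) a vertical profile pair."""
    residual = retrieved.values - truth.values
    profiles = {}
    if profile_index is not None:
        profiles = {
            "retrieved": extract_profile(retrieved.values, "y", profile_index),
            "expected": extract_profile(truth.values, "y", profile_index),
        }
    clipped = 0.0
    meta = getattr(retrieved, "meta", None) or {}
    clipped = float(meta.get("clipped_fraction", 0.0))
    return ComparisonReport(
        rmse=rmse(retrieved.values, truth.values),
        streak_index=streak_index(residual),
        clipped_fraction=clipped,
        profiles=profiles,
    )
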
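"""Ellipse-based leaf-blade geometry.

Apple leaf blades are treated as ellipses with the blade length L on the
major axis and the blade width W on the minor axis.  Three quantities follow:

* blade area               A = pi * L * W / 4
* blade eccentricity       e = sqrt(L^2 - W^2) / L
* width/length ratio       k = W / L = sqrt(1 - e^2)

Within one shoot type and genotype, k is treated as a constant of the
genotype; it is estimated as the through-origin least-squares slope of W
against L (the ratio model W = k * L has no intercept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import FitError, InvalidMeasurementError, OrientationError, ParameterError
from .records import LeafRecord

__all__ = ["ShapeParams", "ellipse_area", "eccentricity", "k_from_e", "fit_k"]


@dataclass(frozen=True)
class ShapeParams:
    """Fitted blade-shape constants: width/length ratio k and eccentricity e."""

    k: float
    e: float
    fit_r2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.k <= 1.0:
            raise ParameterError(f"k must be in (0, 1], got {self.k}")
        if not 0.0 <= self.e < 1.0:
            raise ParameterError(f"e must be in [0, 1), got {self.e}")
        if abs(self.k - math.sqrt(1.0 - self.e**2)) > 1e-12:
            raise ParameterError(
                f"inconsistent shape parameters: k={self.k}, e={self.e}"
            )


def _check_axes(L: float, W: float) -> None:
    if L <= 0 or W <= 0:
        raise InvalidMeasurementError(
            f"blade length/width must be positive, got L={L}, W={W}"
        )
    if W > L:
        raise OrientationError(
            f"blade width {W} exceeds length {L}; assign the major axis to L"
        )


def ellipse_area(L: float, W: float) -> float:
    """Blade area (cm^2) of an elliptical leaf with length L and width W (cm)."""
    _check_axes(L, W)
    return math.pi * L * W / 4.0


def eccentricity(L: float, W: float) -> float:
    """Eccentricity of the elliptical blade, e = sqrt(L^2 - W^2) / L in [0, 1)."""
    _check_axes(L, W)
    return math.sqrt(L * L - W * W) / L


def k_from_e(e: float) -> float:
    """Width/length ratio k = sqrt(1 - e^2) for eccentricity e in [0, 1)."""
    if not 0.0 <= e < 1.0:
        raise ParameterError(f"eccentricity must be in [0, 1), got {e}")
    return math.sqrt(1.0 - e * e)


def fit_k(leaves: Iterable[LeafRecord]) -> ShapeParams:
    """Estimate the genotype ratio k from measured blades.

    Through-origin least squares of W on L: k = sum(L*W) / sum(L^2).  The
    reported r^2 is the squared Pearson correlation of W with k*L (1.0 when a
    single leaf pins the ratio exactly).
    """
    leaves = list(leaves)
    if not leaves:
        raise FitError("no leaves to fit k from")
    L = np.array([lf.blade_length for lf in leaves], dtype=float)
    W = np.array([lf.blade_width for lf in leaves], dtype=float)
    denom = float(np.sum(L * L))
    if denom <= 0:
        raise FitError("degenerate fit: all blade lengths are zero")
    k = float(np.sum(L * W) / denom)
    if not 0.0 < k <= 1.0:
        raise FitError(f"fitted k={k} outside (0, 1]; check blade orientation")
    resid = W - k * L
    sst = float(np.sum((W - W.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / sst)
    return ShapeParams(k=k, e=math.sqrt(max(0.0, 1.0 - k * k)), fit_r2=r2)
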
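"""Normalized leaf-area profile along a shoot: the Lorentz model and its
closed-form integral.

Within a shoot, individual leaf areas normalized by the biggest leaf area
follow a unimodal Lorentz (Cauchy-shaped) curve over the normalized rank x:

    f(x) = 1 / (1 + (x - x0)^2 / s^2)

where x0 is the normalized rank of the biggest leaf and s sets the width of
the size peak.  Normalized rank is R/nl for rosettes and vegetative shoots;
for bourse shoots, where the biggest leaf sits overwhelmingly at rank 2, it
is (R - 2)/nl so that the peak aligns at zero across shoots.

Summing the profile over ranks and dividing by nl approximates the integral
of f over the normalized-rank interval, which ties the profile to the total
leaf area allometry TLA = beta * nl * Amax.  The integral has the arctan
closed form

    integral_a^b f = s * [atan((x - x0)/s)]_a^b ,

strictly increasing in s and bounded by the interval width b - a, so for any
slope parameter beta in (0, b - a) there is exactly one s solving

    s * (atan((b - x0)/s) - atan((a - x0)/s)) = beta .

That inversion (``solve_s``) is the package's core computation: it turns the
robustly estimable slope beta into the profile width s without ever fitting
the noisy normalized scatter directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import DataError, ParameterError, RankError
from .records import ShootRecord

__all__ = [
    "ProfileParams",
    "normalized_rank",
    "normalized_area",
    "lorentz",
    "beta_closed_form",
    "bs_bounds",
    "solve_s",
    "bs_s_table",
    "fit_beta",
    "estimate_x0",
    "fit_profile_x0",
]

#: Largest bourse-shoot leaf count for which s is tabulated at fit time.
NL_TABLE_MAX = 18


@dataclass(frozen=True)
class ProfileParams:
    """Lorentz profile parameters for one (shoot type, genotype group).

    ``s`` is a per-nl table for bourse shoots (the closed form depends on nl
    through the integration bounds) and a scalar for rosettes.  ``x0`` is the
    normalized rank of the biggest leaf (0 for bourse shoots by construction
    of the shifted rank).  The profile maximum M is 1 after normalization.
    """

    beta: float
    s: float | Mapping[int, float]
    x0: float = 0.0
    beta_r2: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ParameterError(
                f"beta must be in (0, 1) for the profile to integrate, got {self.beta}"
            )
        if isinstance(self.s, Mapping):
            bad = {nl: v for nl, v in self.s.items() if not (v > 0 and math.isfinite(v))}
            if bad:
                raise ParameterError(f"s table has non-positive entries: {bad}")
        elif not (self.s > 0 and math.isfinite(self.s)):
            raise ParameterError(f"s must be positive and finite, got {self.s}")

    def s_for(self, nl: int) -> float:
        """Scale parameter for a shoot with nl leaves (table lookup or scalar);
        leaf counts beyond the table are solved on demand."""
        if isinstance(self.s, Mapping):
            if nl in self.s:
                return float(self.s[nl])
            lo, up = bs_bounds(nl)
            return solve_s(self.beta, lower=lo, upper=up, x0=0.0)
        return float(self.s)


def normalized_rank(R: int, nl: int, shoot_type: str) -> float:
    """Normalized acropetal rank: R/nl (RO, VS) or (R - 2)/nl (BS)."""
    if not 1 <= R <= nl:
        raise RankError(f"rank {R} outside 1..{nl}")
    if shoot_type == "BS":
        return (R - 2) / nl
    if shoot_type in ("RO", "VS"):
        return R / nl
    raise DataError(f"unknown shoot type {shoot_type!r}")


def normalized_area(A_R: float, Amax: float) -> float:
    """Leaf area normalized by the biggest leaf area on the shoot, in [0, 1]."""
    if Amax <= 0:
        raise DataError("degenerate shoot: biggest leaf area is zero")
    if A_R < 0 or A_R > Amax * (1 + 1e-12):
        raise DataError(f"leaf area {A_R} outside [0, Amax={Amax}]")
    return min(A_R / Amax, 1.0)


def lorentz(x, x0: float, s: float):
    """Lorentz profile value 1 / (1 + (x - x0)^2 / s^2); vectorized in x."""
    if s <= 0:
        raise ParameterError(f"s must be positive, got {s}")
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + ((x - x0) / s) ** 2)
    return float(out) if out.ndim == 0 else out


def beta_closed_form(s: float, lower: float, upper: float, x0: float = 0.0) -> float:
    """Definite integral of the Lorentz profile over [lower, upper].

    Evaluates s * [atan((x - x0)/s)] between the bounds; strictly increasing
    in s with supremum (upper - lower).
    """
    if s <= 0:
        raise ParameterError(f"s must be positive, got {s}")
    if not lower < upper:
        raise ParameterError(f"need lower < upper, got [{lower}, {upper}]")
    return s * (math.atan((upper - x0) / s) - math.atan((lower - x0) / s))


def bs_bounds(nl: int) -> tuple[float, float]:
    """Integration bounds of the shifted bourse-shoot rank, [-2/nl, (nl-2)/nl].

    Valid for all nl >= 1, including nl in {1, 2} where the interval lies at
    or below zero; the closed form holds regardless.
    """
    if nl < 1:
        raise ParameterError(f"nl must be >= 1, got {nl}")
    return -2.0 / nl, (nl - 2.0) / nl


_S_BRACKET = (1e-6, 1e3)


def solve_s(
    beta: float,
    *,
    lower: float,
    upper: float,
    x0: float = 0.0,
) -> float:
    """Invert the closed form: the unique s with integral(s) = beta.

    The integral is monotone in s, so a bracketed Brent solve on
    s in [1e-6, 1e3] is robust; the root satisfies |delta beta| <= 1e-10.
    """
    width = upper - lower
    if beta <= 0:
        raise ParameterError(f"beta must be positive, got {beta}")
    if beta >= width:
        raise ParameterError(
            f"no solution: beta={beta} must be below the interval width {width}"
        )
    lo, hi = _S_BRACKET

    def g(s: float) -> float:
        return beta_closed_form(s, lower, upper, x0) - beta

    return float(brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16))


def solve_s_bs(beta: float, nl: int) -> float:
    """Bourse-shoot scale parameter for a given leaf count."""
    lo, up = bs_bounds(nl)
    return solve_s(beta, lower=lo, upper=up, x0=0.0)


def bs_s_table(beta: float, nl_max: int = NL_TABLE_MAX) -> dict[int, float]:
    """Tabulate the bourse-shoot scale parameter for nl = 1..nl_max."""
    return {nl: solve_s_bs(beta, nl) for nl in range(1, nl_max + 1)}


def fit_beta(shoots: Iterable[ShootRecord]) -> tuple[float, float]:
    """Slope of the total-leaf-area allometry TLA = beta * (nl * Amax).

    Through-origin least squares of TLA on nl*Amax (the allometry has no
    intercept).  Returns (beta, r2) with r2 the squared Pearson correlation
    between TLA and its fit.
    """
    shoots = list(shoots)
    if not shoots:
        raise DataError("no shoots to fit beta from")
    x = np.array([sh.nl * sh.Amax for sh in shoots], dtype=float)
    y = np.array([sh.TLA for sh in shoots], dtype=float)
    denom = float(np.sum(x * x))
    if denom <= 0:
        raise DataError("degenerate fit: nl*Amax is zero for every shoot")
    beta = float(np.sum(x * y) / denom)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum((y - beta * x) ** 2)) / sst)
    return beta, r2


def estimate_x0(rosettes: Iterable[ShootRecord]) -> float:
    """Mean normalized rank of the biggest leaf, mean(RAmax / nl), in (0, 1]."""
    rosettes = list(rosettes)
    if not rosettes:
        raise DataError("no rosettes to estimate x0 from")
    vals = [sh.RAmax / sh.nl for sh in rosettes]
    return float(np.mean(vals))


def fit_profile_x0(
    rosettes: Iterable[ShootRecord],
    x0_init: float | None = None,
) -> float:
    """Peak position x0 from a free-amplitude Lorentz fit to the pooled
    normalized (rank, area) scatter.

    Each shoot's biggest leaf is excluded: its normalized area is identically
    1 by construction (self-normalization) and carries no information about
    the curve.  Falls back to the mean-rank estimate when fewer than four
    informative points remain or the fit fails.
    """
    rosettes = list(rosettes)
    if not rosettes:
        raise DataError("no rosettes to fit x0 from")
    fallback = estimate_x0(rosettes)
    xs: list[float] = []
    ys: list[float] = []
    for sh in rosettes:
        for lf in sh.leaves:
            if lf.rank == sh.RAmax:
                continue
            xs.append(normalized_rank(lf.rank, sh.nl, "RO"))
            ys.append(normalized_area(lf.area, sh.Amax))
    if len(xs) < 4:
        return fallback
    x = np.array(xs)
    y = np.array(ys)

    def model(x, M, x0, s):
        return M / (1.0 + ((x - x0) / s) ** 2)

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(1.0, x0_init if x0_init is not None else fallback, 0.4),
            bounds=([0.2, 0.0, 1e-3], [5.0, 1.5, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return fallback
    return float(popt[1])
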
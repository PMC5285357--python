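"""Calibrated forward models: per-leaf and whole-shoot leaf area from two
easy inputs (leaf count nl, longest-leaf length Lmax), plus whole-spur
reconstruction.

Bourse shoots and rosettes use the calibrated Lorentz chain

    A_R = alpha * (pi/4) * k * Lmax^2 / (1 + (R - R_peak)^2 / (nl^2 * s^2))

with R_peak = 2 for bourse shoots and R_peak = nl * x0 for rosettes (the
non-integer peak is used as-is; the formula is continuous in the offset).
Vegetative shoots use the descriptive linear profile

    A_R = p * (R / nl) * (pi/4) * k * Lmax^2 .

alpha is the calibration slope between measured and model-calculated total
leaf area on the training set; it is applied per leaf, so it cancels
identically between per-leaf and total predictions.  The module ships the
published parameter sets for the three cultivars Ariane (AR), Fuji (FU) and
Rome Beauty (RB) as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParameterError, RankError
from .profile import ProfileParams
from . import internode as _internode

__all__ = [
    "CalibratedModel",
    "VegShootParams",
    "predict_leaf_area",
    "predict_vs_leaf_area",
    "predict_total_leaf_area",
    "calibrate_alpha",
    "reconstruct_spur",
    "default_models",
    "default_vs_params",
    "default_internode_params",
]


@dataclass(frozen=True)
class CalibratedModel:
    """Full parameter set for one shoot type and genotype."""

    shoot_type: str
    genotype_group: tuple[str, ...]
    params: ProfileParams
    k: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.shoot_type not in ("BS", "RO"):
            raise ConfigError(
                f"CalibratedModel covers BS/RO, got {self.shoot_type!r}"
            )
        if not 0.0 < self.k <= 1.0:
            raise ParameterError(f"k must be in (0, 1], got {self.k}")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")

    def peak_rank(self, nl: int) -> float:
        return 2.0 if self.shoot_type == "BS" else nl * self.params.x0


@dataclass(frozen=True)
class VegShootParams:
    """Vegetative-shoot linear profile: slope p and blade ratio k."""

    p: float
    k: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.05:  # fitted slope of a normalized quantity
            raise ParameterError(f"p must be in (0, 1.05], got {self.p}")
        if not 0.0 < self.k <= 1.0:
            raise ParameterError(f"k must be in (0, 1], got {self.k}")


def _check_inputs(R: int, nl: int, Lmax: float) -> None:
    if not 1 <= R <= nl:
        raise RankError(f"rank {R} outside 1..{nl}")
    if Lmax <= 0:
        raise ParameterError(f"Lmax must be positive, got {Lmax}")


def predict_leaf_area(R: int, nl: int, Lmax: float, model: CalibratedModel) -> float:
    """Predicted area (cm^2) of the leaf at rank R on a BS or RO shoot."""
    _check_inputs(R, nl, Lmax)
    s = model.params.s_for(nl)
    peak = model.peak_rank(nl)
    amax = model.alpha * (math.pi / 4.0) * model.k * Lmax**2
    return amax / (1.0 + (R - peak) ** 2 / (nl**2 * s**2))


def predict_vs_leaf_area(R: int, nl: int, Lmax: float, vs: VegShootParams) -> float:
    """Predicted area (cm^2) of the leaf at rank R on a vegetative shoot."""
    _check_inputs(R, nl, Lmax)
    return vs.p * (R / nl) * (math.pi / 4.0) * vs.k * Lmax**2


def predict_total_leaf_area(nl: int, Lmax: float, model: CalibratedModel) -> float:
    """Predicted total shoot leaf area: sum of per-rank predictions."""
    return float(
        sum(predict_leaf_area(R, nl, Lmax, model) for R in range(1, nl + 1))
    )


def calibrate_alpha(measured_TLA, calculated_TLA) -> float:
    """Calibration slope of measured on calculated total leaf area.

    Through-origin least squares; after applying alpha, the training-set
    regression of measured on calibrated-calculated TLA has slope 1 by
    construction.
    """
    m = np.asarray(measured_TLA, dtype=float)
    c = np.asarray(calculated_TLA, dtype=float)
    if m.size == 0 or c.size == 0:
        raise DataError("empty calibration lists")
    if m.shape != c.shape:
        raise DataError(f"length mismatch: {m.shape} vs {c.shape}")
    if np.any(c <= 0):
        raise DataError("calculated TLA must be positive")
    return float(np.sum(c * m) / np.sum(c * c))


# --- published default parameter sets -------------------------------------

#: Bourse-shoot scale-parameter table by leaf count, per genotype group
#: (solutions of the closed form at beta = 0.67 and 0.50, printed at 2 dp).
BS_S_TABLE: dict[str, dict[int, float]] = {
    "AR|FU": {
        1: 2.13, 2: 0.70, 3: 0.38, 4: 0.35, 5: 0.36, 6: 0.38, 7: 0.40,
        8: 0.42, 9: 0.44, 10: 0.46, 11: 0.48, 12: 0.49, 13: 0.51, 14: 0.52,
        15: 0.53, 16: 0.54, 17: 0.55, 18: 0.55,
    },
    "RB": {
        1: 1.48, 2: 0.43, 3: 0.23, 4: 0.22, 5: 0.22, 6: 0.23, 7: 0.24,
        8: 0.25, 9: 0.25, 10: 0.26, 11: 0.27, 12: 0.28, 13: 0.29, 14: 0.30,
        15: 0.31, 16: 0.31, 17: 0.32, 18: 0.32,
    },
}

_BS_BETA = {"AR": 0.67, "FU": 0.67, "RB": 0.50}
_BS_K = {"AR": 0.60, "FU": 0.64, "RB": 0.66}
_BS_ALPHA = {"AR": 1.2, "FU": 0.99, "RB": 1.87}
_RO_K = {"AR": 0.75, "FU": 0.74, "RB": 0.71}
_RO_ALPHA = {"AR": 0.86, "FU": 0.92, "RB": 0.92}
RO_BETA, RO_S, RO_X0 = 0.69, 0.38, 0.63
VS_P, VS_K = 0.95, 0.56
INTERNODE_QI, INTERNODE_SI = 0.62, 0.12


def default_models() -> dict[tuple[str, str], CalibratedModel]:
    """Shipped parameter sets for every (shoot type, genotype) pair."""
    models: dict[tuple[str, str], CalibratedModel] = {}
    for g in ("AR", "FU", "RB"):
        group = ("AR", "FU") if g in ("AR", "FU") else ("RB",)
        table = BS_S_TABLE["AR|FU" if g in ("AR", "FU") else "RB"]
        models[("BS", g)] = CalibratedModel(
            shoot_type="BS",
            genotype_group=group,
            params=ProfileParams(beta=_BS_BETA[g], s=dict(table), x0=0.0),
            k=_BS_K[g],
            alpha=_BS_ALPHA[g],
        )
        models[("RO", g)] = CalibratedModel(
            shoot_type="RO",
            genotype_group=("AR", "FU", "RB"),
            params=ProfileParams(beta=RO_BETA, s=RO_S, x0=RO_X0),
            k=_RO_K[g],
            alpha=_RO_ALPHA[g],
        )
    return models


def default_vs_params() -> VegShootParams:
    """Shipped vegetative-shoot parameters (AR and FU pooled)."""
    return VegShootParams(p=VS_P, k=VS_K)


def default_internode_params() -> "_internode.InternodeParams":
    """Shipped logistic internode parameters for the spur continuum."""
    return _internode.InternodeParams(qi=INTERNODE_QI, si=INTERNODE_SI)


def reconstruct_spur(
    nl_RO: int,
    Lmax_RO: float,
    nl_BS: int,
    Lmax_BS: float,
    BL: float,
    BSL: float,
    models: Mapping[tuple[str, str], CalibratedModel],
    internode_params: "_internode.InternodeParams",
    genotype: str,
) -> pd.DataFrame:
    """Reconstruct the leafy architecture of a bearing spur.

    Returns one row per leaf along the rosette -> bourse-shoot continuum:
    continuum rank, source shoot, local rank, predicted leaf area (cm^2) and
    predicted insertion distance from the bourse base (cm).  Distances are
    nondecreasing in continuum rank and bounded by BL + BSL.
    """
    if nl_RO < 1 or nl_BS < 0:
        raise DataError(
            f"need at least one rosette leaf and nl_BS >= 0, got "
            f"nl_RO={nl_RO}, nl_BS={nl_BS}"
        )
    if BL <= 0 or BSL < 0:
        raise DataError(f"invalid lengths BL={BL}, BSL={BSL}")
    for key in (("RO", genotype),) + ((("BS", genotype),) if nl_BS else ()):
        if key not in models:
            raise ConfigError(f"missing parameter set for {key}")
    nl_total = nl_RO + nl_BS
    rows = []
    for R_I in range(1, nl_total + 1):
        if R_I <= nl_RO:
            source, local = "RO", R_I
            area = predict_leaf_area(local, nl_RO, Lmax_RO, models[("RO", genotype)])
        else:
            source, local = "BS", R_I - nl_RO
            area = predict_leaf_area(local, nl_BS, Lmax_BS, models[("BS", genotype)])
        dist = _internode.predict_cumulative_length(
            R_I, nl_total, BL, BSL, internode_params
        )
        rows.append(
            {
                "rank_continuum": R_I,
                "shoot": source,
                "rank_local": local,
                "area_cm2": area,
                "distance_cm": dist,
            }
        )
    return pd.DataFrame(rows)
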
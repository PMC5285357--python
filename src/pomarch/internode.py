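"""Logistic model of cumulative shoot length along the bourse -> bourse-shoot
continuum.

Treating the bourse (rosette axis) and its sylleptic bourse shoot as one
morphogenetic unit, the distance D_I from the bourse base to the insertion
node of the leaf at continuum rank R_I, normalized by the total length
BL + BSL, follows a logistic curve in the normalized rank:

    N(D_I) = 1 / (1 + exp((qi - R_I/nl) / si))

qi is the midpoint (the normalized rank at half the total length) and si the
logistic scale.  The resulting internode profile has short basal internodes
(bourse), a steep median zone (base of the bourse shoot) and flattening near
the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, FitError, ParameterError, RankError
from .records import SpurInternodeRecord

__all__ = [
    "InternodeParams",
    "logistic_ndi",
    "fit_internode_model",
    "predict_cumulative_length",
    "InternodeModel",
    "InternodeResults",
]


@dataclass(frozen=True)
class InternodeParams:
    """Fitted logistic constants (qi: midpoint, si: scale) with fit metrics."""

    qi: float
    si: float
    fit_r2: float | None = None
    rmse: float | None = None

    def __post_init__(self) -> None:
        if self.si <= 0:
            raise ParameterError(f"si must be positive, got {self.si}")


def logistic_ndi(nri, params: InternodeParams):
    """Normalized cumulative length at normalized rank nri; vectorized."""
    if params.si <= 0:
        raise ParameterError(f"si must be positive, got {params.si}")
    nri = np.asarray(nri, dtype=float)
    out = 1.0 / (1.0 + np.exp((params.qi - nri) / params.si))
    return float(out) if out.ndim == 0 else out


def predict_cumulative_length(
    R_I: int, nl: int, BL: float, BSL: float, params: InternodeParams
) -> float:
    """Distance (cm) from the bourse base to the insertion node at rank R_I."""
    if not 1 <= R_I <= nl:
        raise RankError(f"continuum rank {R_I} outside 1..{nl}")
    total = BL + BSL
    if total <= 0:
        raise DataError(f"BL + BSL must be positive, got {total}")
    return float(logistic_ndi(R_I / nl, params)) * total


def _logistic(x, qi, si):
    return 1.0 / (1.0 + np.exp((qi - x) / si))


def fit_internode_model(
    records: Iterable[SpurInternodeRecord],
) -> InternodeParams:
    """Nonlinear least squares of the logistic curve on pooled normalized
    (rank, cumulative length) points from all spur continua.

    Initialization: qi0 = median normalized rank, si0 = 0.1 (robust for
    sigmoid data on the unit interval).  Reports R^2 (squared Pearson
    correlation between observed and fitted normalized lengths) and RMSE on
    the normalized scale.
    """
    records = list(records)
    if len(records) < 4:
        raise DataError("need at least 4 internode points to fit the logistic")
    x = np.array([r.rank / r.nl for r in records], dtype=float)
    y = np.array(
        [r.cum_length / (r.bourse_length + r.bourse_shoot_length) for r in records],
        dtype=float,
    )
    if np.ptp(y) <= 0:
        raise FitError("degenerate data: all cumulative lengths are equal")
    med = float(np.median(x))
    if not (y.min() < 0.5 < y.max()):
        raise DataError(
            "internode points must span both sides of the logistic midpoint"
        )
    try:
        popt, _ = curve_fit(
            _logistic,
            x,
            y,
            p0=(med, 0.1),
            bounds=([0.0, 1e-4], [1.5, 5.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    qi, si = float(popt[0]), float(popt[1])
    yhat = _logistic(x, qi, si)
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / sst)
    return InternodeParams(qi=qi, si=si, fit_r2=r2, rmse=rmse)


class InternodeModel:
    """Logistic internode-length model bound to a spur continuum dataset.

    Parameters
    ----------
    records
        Pooled :class:`SpurInternodeRecord` points from one or more spurs.

    ``fit()`` returns an :class:`InternodeResults` carrying the estimates,
    fit diagnostics, a ``summary()`` table and ``predict``/``plot`` helpers.
    """

    def __init__(self, records: Sequence[SpurInternodeRecord]):
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "InternodeModel":
        from .records import internode_records_from_frame

        return cls(internode_records_from_frame(df))

    def fit(self) -> "InternodeResults":
        params = fit_internode_model(self.records)
        return InternodeResults(model=self, params=params)


@dataclass
class InternodeResults:
    """Fit results of :class:`InternodeModel`."""

    model: InternodeModel
    params: InternodeParams

    @property
    def qi(self) -> float:
        return self.params.qi

    @property
    def si(self) -> float:
        return self.params.si

    def predict(self, R_I: int, nl: int, BL: float, BSL: float) -> float:
        return predict_cumulative_length(R_I, nl, BL, BSL, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Logistic internode model: N(D) = 1 / (1 + exp((qi - R/nl)/si))",
            f"  n points : {len(self.model.records)}",
            f"  qi       : {p.qi:.4f}   (midpoint, normalized rank)",
            f"  si       : {p.si:.4f}   (logistic scale)",
            f"  R^2      : {p.fit_r2:.3f}" if p.fit_r2 is not None else "",
            f"  RMSE     : {p.rmse:.3f} (normalized length)"
            if p.rmse is not None
            else "",
        ]
        return "\n".join(s for s in lines if s)

    def plot(self, ax=None):
        """Observed normalized points with the fitted logistic curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = [r.rank / r.nl for r in self.model.records]
        y = [
            r.cum_length / (r.bourse_length + r.bourse_shoot_length)
            for r in self.model.records
        ]
        ax.scatter(x, y, s=12, alpha=0.6, label="observed")
        grid = np.linspace(0, 1, 200)
        ax.plot(grid, logistic_ndi(grid, self.params), "k-", label="logistic fit")
        ax.set_xlabel("normalized continuum rank")
        ax.set_ylabel("normalized cumulative length")
        ax.legend()
        return ax
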
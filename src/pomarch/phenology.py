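"""Thermal-time accumulation and the full-development filter.

Shoot development is tracked in growing degree hours (GDH) above a base
temperature (default 7 deg C), summed over the 24 hourly readings of a day
with sub-base hours contributing zero, and converted to cumulative growing
degree days (GDD = sum of daily GDH / 24) from the date of full bloom (FB).

Bourse shoots are considered fully developed — and retained for model
building — once their sampling GDD reaches a genotype-specific threshold
(defaults: AR 345, FU 201, RB 275 GDD).  Rosettes are fully preformed at
full bloom; only rosettes collected before harvest are retained.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "DEFAULT_BASE_TEMP",
    "DEFAULT_BS_THRESHOLDS",
    "daily_gdh",
    "daily_gdh_series",
    "cumulative_gdd",
    "full_development_filter",
]

DEFAULT_BASE_TEMP = 7.0
DEFAULT_BS_THRESHOLDS: dict[str, float] = {"AR": 345.0, "FU": 201.0, "RB": 275.0}


def daily_gdh(day_temps, T_b: float = DEFAULT_BASE_TEMP) -> float:
    """Growing degree hours of one day: sum of max(HT_h - T_b, 0) over
    exactly 24 hourly readings.  Invariant to the order of hours."""
    temps = np.asarray(day_temps, dtype=float)
    if temps.shape != (24,):
        raise DataError(f"a day needs exactly 24 hourly readings, got {temps.size}")
    return float(np.sum(np.maximum(temps - T_b, 0.0)))


def daily_gdh_series(
    temps: pd.DataFrame, T_b: float = DEFAULT_BASE_TEMP
) -> pd.Series:
    """Per-day GDH from an hourly temperature table.

    ``temps`` needs columns ``timestamp_iso`` (hourly instants) and
    ``temp_C``.  Days with fewer or more than 24 readings are rejected
    rather than interpolated.
    """
    if not {"timestamp_iso", "temp_C"} <= set(temps.columns):
        raise DataError("temperature table needs columns timestamp_iso, temp_C")
    ts = pd.to_datetime(temps["timestamp_iso"])
    frame = pd.DataFrame({"date": ts.dt.date, "temp": temps["temp_C"].astype(float)})
    counts = frame.groupby("date")["temp"].count()
    bad = counts[counts != 24]
    if len(bad):
        raise DataError(
            f"days without exactly 24 hourly readings: {list(bad.index)[:5]}"
        )
    out = frame.groupby("date")["temp"].apply(
        lambda v: float(np.maximum(v.to_numpy() - T_b, 0.0).sum())
    )
    out.index = pd.to_datetime(out.index)
    return out


def cumulative_gdd(
    daily: pd.Series,
    FB: _dt.date | str,
    D: _dt.date | str,
) -> float:
    """Cumulative growing degree days over [FB, D]: sum of daily GDH / 24.

    ``daily`` is a per-day GDH series (as from :func:`daily_gdh_series`);
    the series must cover every calendar day of the window.
    """
    fb = pd.Timestamp(FB).normalize()
    d = pd.Timestamp(D).normalize()
    if fb > d:
        raise DataError(f"full bloom {fb.date()} is after sampling day {d.date()}")
    idx = pd.DatetimeIndex(pd.to_datetime(daily.index)).normalize()
    window = pd.date_range(fb, d, freq="D")
    missing = window.difference(idx)
    if len(missing):
        raise DataError(
            f"temperature record does not cover {[str(m.date()) for m in missing[:5]]}"
        )
    series = pd.Series(daily.to_numpy(float), index=idx)
    return float(series.loc[window].sum() / 24.0)


def full_development_filter(
    shoots: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Retain only fully developed shoots.

    ``shoots`` needs columns ``shoot_type``, ``genotype`` and ``gdd``
    (sampling GDD since full bloom); rosette rows additionally honour a
    boolean ``at_harvest`` column (rosettes sampled at harvest are dropped).
    Bourse shoots are retained iff gdd >= the genotype threshold; vegetative
    shoots pass through (collected once fully developed).
    """
    thresholds = dict(DEFAULT_BS_THRESHOLDS if thresholds is None else thresholds)
    needed = {"shoot_type", "genotype", "gdd"}
    if not needed <= set(shoots.columns):
        raise DataError(f"shoot table needs columns {sorted(needed)}")
    keep = pd.Series(True, index=shoots.index)
    bs = shoots["shoot_type"] == "BS"
    for geno in shoots.loc[bs, "genotype"].unique():
        if geno not in thresholds:
            raise ConfigError(f"no full-development GDD threshold for {geno!r}")
    thr = shoots.loc[bs, "genotype"].map(thresholds)
    keep.loc[bs] = shoots.loc[bs, "gdd"].astype(float) >= thr.astype(float)
    ro = shoots["shoot_type"] == "RO"
    if "at_harvest" in shoots.columns:
        keep.loc[ro] &= ~shoots.loc[ro, "at_harvest"].astype(bool)
    return shoots.loc[keep].copy()
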
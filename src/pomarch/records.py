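"""Domain records: single leaves, whole shoots, and spur internode points.

The package works on two in-memory representations that are kept in sync:
plain :class:`pandas.DataFrame` tables (the CSV dialects documented in
:mod:`pomarch.io`) and the typed records below, which carry the derived
shoot-level quantities every model consumes:

``nl``     leaf count of the shoot,
``Amax``   area of the biggest leaf (ties broken toward the lowest rank),
``Lmax``   blade length of that same biggest-area leaf,
``TLA``    total leaf area (sum over ranks),
``RAmax``  acropetal rank of the biggest leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InvalidMeasurementError, OrientationError, RankError

SHOOT_TYPES = ("BS", "RO", "VS")
GENOTYPES = ("AR", "FU", "RB")


@dataclass(frozen=True)
class LeafRecord:
    """One leaf blade: acropetal rank, length, width and area (cm / cm^2).

    If ``area`` is omitted it is derived from the ellipse model
    A = pi * L * W / 4.
    """

    rank: int
    blade_length: float
    blade_width: float
    area: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise RankError(f"leaf rank must be >= 1, got {self.rank}")
        if self.blade_length <= 0 or self.blade_width <= 0:
            raise InvalidMeasurementError(
                f"blade length/width must be positive, got "
                f"L={self.blade_length}, W={self.blade_width}"
            )
        if self.blade_width > self.blade_length * (1 + 1e-12):
            raise OrientationError(
                f"blade width {self.blade_width} exceeds length "
                f"{self.blade_length}; assign the major axis to the length"
            )
        if self.area is None:
            object.__setattr__(
                self, "area", math.pi * self.blade_length * self.blade_width / 4.0
            )
        elif self.area < 0:
            raise InvalidMeasurementError(f"negative leaf area {self.area}")


@dataclass
class ShootRecord:
    """One shoot with its ordered leaves and derived summary quantities."""

    shoot_id: str
    shoot_type: str
    genotype: str
    leaves: list[LeafRecord]
    nl: int = field(init=False)
    Amax: float = field(init=False)
    Lmax: float = field(init=False)
    TLA: float = field(init=False)
    RAmax: int = field(init=False)

    def __post_init__(self) -> None:
        if self.shoot_type not in SHOOT_TYPES:
            raise DataError(f"unknown shoot type {self.shoot_type!r}")
        if self.genotype not in GENOTYPES:
            raise DataError(f"unknown genotype {self.genotype!r}")
        if not self.leaves:
            raise DataError(f"shoot {self.shoot_id!r} has no leaves")
        self.leaves = sorted(self.leaves, key=lambda lf: lf.rank)
        ranks = [lf.rank for lf in self.leaves]
        self.nl = len(ranks)
        if ranks != list(range(1, self.nl + 1)):
            raise RankError(
                f"shoot {self.shoot_id!r}: ranks must be 1..{self.nl} without "
                f"gaps or duplicates, got {ranks}"
            )
        areas = np.array([lf.area for lf in self.leaves])
        # ties in the biggest area break toward the lowest rank (argmax does)
        i = int(np.argmax(areas))
        self.RAmax = self.leaves[i].rank
        self.Amax = float(areas[i])
        self.Lmax = float(self.leaves[i].blade_length)
        self.TLA = float(areas.sum())
        if self.Amax <= 0:
            raise DataError(f"shoot {self.shoot_id!r}: biggest leaf area is zero")


@dataclass(frozen=True)
class SpurInternodeRecord:
    """One leaf-insertion point on the bourse / bourse-shoot continuum.

    ``rank`` counts from the first rosette leaf (1); the first bourse-shoot
    internode takes the rank of its insertion node plus one.  ``cum_length``
    is the distance (cm) from the bourse base to the insertion point.
    """

    spur_id: str
    rank: int
    cum_length: float
    bourse_length: float
    bourse_shoot_length: float
    nl: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.nl:
            raise RankError(
                f"spur {self.spur_id!r}: continuum rank {self.rank} outside 1..{self.nl}"
            )
        total = self.bourse_length + self.bourse_shoot_length
        if total <= 0:
            raise InvalidMeasurementError(
                f"spur {self.spur_id!r}: BL + BSL must be positive"
            )
        if self.cum_length < 0 or self.cum_length > total * (1 + 1e-9):
            raise InvalidMeasurementError(
                f"spur {self.spur_id!r}: cumulative length {self.cum_length} "
                f"outside [0, BL+BSL={total}]"
            )


def shoots_from_frame(df: pd.DataFrame) -> list[ShootRecord]:
    """Build :class:`ShootRecord` objects from a validated leaf table.

    Expects the columns of the leaf CSV dialect (see :mod:`pomarch.io`);
    missing ``area_cm2`` values are derived from the ellipse model.
    """
    shoots: list[ShootRecord] = []
    for sid, grp in df.groupby("shoot_id", sort=True):
        stype = grp["shoot_type"].iloc[0]
        geno = grp["genotype"].iloc[0]
        leaves = []
        for _, row in grp.iterrows():
            area = row.get("area_cm2")
            if area is not None and (isinstance(area, float) and math.isnan(area)):
                area = None
            leaves.append(
                LeafRecord(
                    rank=int(row["rank"]),
                    blade_length=float(row["blade_length_cm"]),
                    blade_width=float(row["blade_width_cm"]),
                    area=None if area is None else float(area),
                )
            )
        shoots.append(ShootRecord(str(sid), stype, geno, leaves))
    return shoots


def internode_records_from_frame(df: pd.DataFrame) -> list[SpurInternodeRecord]:
    """Build continuum records from an internode table; checks monotonicity."""
    records: list[SpurInternodeRecord] = []
    for sid, grp in df.groupby("spur_id", sort=True):
        grp = grp.sort_values("rank_continuum")
        d = grp["cum_length_cm"].to_numpy(float)
        if np.any(np.diff(d) < -1e-9):
            raise DataError(
                f"spur {sid!r}: cumulative length must be nondecreasing in rank"
            )
        nl = int(grp["rank_continuum"].max())
        for _, row in grp.iterrows():
            records.append(
                SpurInternodeRecord(
                    spur_id=str(sid),
                    rank=int(row["rank_continuum"]),
                    cum_length=float(row["cum_length_cm"]),
                    bourse_length=float(row["bourse_length_cm"]),
                    bourse_shoot_length=float(row["bourse_shoot_length_cm"]),
                    nl=nl,
                )
            )
    return records
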
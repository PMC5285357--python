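"""Readers, writers and validation for the package's table and parameter
file dialects.

Formats (UTF-8, comma-separated, dot decimal):

* leaf CSV      — shoot_id, genotype {AR,FU,RB}, shoot_type {BS,RO,VS},
                  rank, blade_length_cm, blade_width_cm, area_cm2 (optional;
                  derived from the ellipse model when absent)
* internode CSV — spur_id, rank_continuum, cum_length_cm, bourse_length_cm,
                  bourse_shoot_length_cm
* temperature   — timestamp_iso, temp_C (hourly)
* parameters    — JSON with a schema-version field; one entry per
                  (shoot type, genotype) plus the vegetative-shoot and
                  internode blocks.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .internode import InternodeParams
from .prediction import CalibratedModel, VegShootParams
from .profile import ProfileParams
from .records import GENOTYPES, SHOOT_TYPES

__all__ = [
    "read_leaf_table",
    "read_internode_table",
    "read_temperature_table",
    "write_params",
    "read_params",
]

PARAMS_SCHEMA_VERSION = 1

LEAF_COLUMNS = (
    "shoot_id",
    "genotype",
    "shoot_type",
    "rank",
    "blade_length_cm",
    "blade_width_cm",
)
INTERNODE_COLUMNS = (
    "spur_id",
    "rank_continuum",
    "cum_length_cm",
    "bourse_length_cm",
    "bourse_shoot_length_cm",
)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{what}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        raise DataError(
            f"{what}: non-numeric value in column {col!r} at row(s) "
            f"{[int(i) + 2 for i in bad[:5]]} (1-based, incl. header)"
        )
    return out


def read_leaf_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a leaf CSV; derives missing areas from the ellipse
    model and checks per-shoot rank contiguity."""
    df = pd.read_csv(path)
    _require_columns(df, LEAF_COLUMNS, f"leaf table {path}")
    for col in ("rank", "blade_length_cm", "blade_width_cm"):
        df[col] = _numeric(df, col, f"leaf table {path}")
    if df["rank"].isna().any():
        rows = df.index[df["rank"].isna()]
        raise DataError(
            f"leaf table {path}: missing rank at row(s) {[int(i) + 2 for i in rows[:5]]}"
        )
    bad_geno = set(df["genotype"].unique()) - set(GENOTYPES)
    if bad_geno:
        raise DataError(f"leaf table {path}: unknown genotype(s) {sorted(bad_geno)}")
    bad_type = set(df["shoot_type"].unique()) - set(SHOOT_TYPES)
    if bad_type:
        raise DataError(f"leaf table {path}: unknown shoot type(s) {sorted(bad_type)}")
    dup = df.duplicated(subset=["shoot_id", "rank"])
    if dup.any():
        rows = df.index[dup]
        raise DataError(
            f"leaf table {path}: duplicate (shoot_id, rank) at row(s) "
            f"{[int(i) + 2 for i in rows[:5]]}"
        )
    if "area_cm2" in df.columns:
        df["area_cm2"] = _numeric(df, "area_cm2", f"leaf table {path}")
    else:
        df["area_cm2"] = np.nan
    derive = df["area_cm2"].isna()
    df.loc[derive, "area_cm2"] = (
        math.pi * df.loc[derive, "blade_length_cm"] * df.loc[derive, "blade_width_cm"] / 4.0
    )
    for sid, grp in df.groupby("shoot_id"):
        ranks = sorted(grp["rank"].astype(int))
        if ranks != list(range(1, len(ranks) + 1)):
            raise DataError(
                f"leaf table {path}: shoot {sid!r} ranks are not contiguous 1..nl"
            )
    df["rank"] = df["rank"].astype(int)
    return df


def read_internode_table(path: str | Path) -> pd.DataFrame:
    """Load and validate an internode CSV (monotonicity is checked when
    records are built)."""
    df = pd.read_csv(path)
    _require_columns(df, INTERNODE_COLUMNS, f"internode table {path}")
    for col in INTERNODE_COLUMNS[1:]:
        df[col] = _numeric(df, col, f"internode table {path}")
    df["rank_continuum"] = df["rank_continuum"].astype(int)
    return df


def read_temperature_table(path: str | Path) -> pd.DataFrame:
    """Load an hourly temperature CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ("timestamp_iso", "temp_C"), f"temperature table {path}")
    df["temp_C"] = _numeric(df, "temp_C", f"temperature table {path}")
    return df


def _params_to_json(m: CalibratedModel) -> dict:
    s = m.params.s
    return {
        "shoot_type": m.shoot_type,
        "genotype_group": list(m.genotype_group),
        "beta": m.params.beta,
        "s": {str(nl): v for nl, v in s.items()} if isinstance(s, Mapping) else s,
        "x0": m.params.x0,
        "k": m.k,
        "alpha": m.alpha,
    }


def write_params(
    path: str | Path,
    models: Mapping[tuple[str, str], CalibratedModel],
    vs: VegShootParams | None = None,
    internode: InternodeParams | None = None,
) -> None:
    """Write a parameter JSON file (schema-versioned; numeric payload
    round-trips bit for bit through :func:`read_params`)."""
    payload: dict = {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "models": {f"{stype}:{geno}": _params_to_json(m)
                   for (stype, geno), m in sorted(models.items())},
    }
    if vs is not None:
        payload["vegetative_shoot"] = {"p": vs.p, "k": vs.k}
    if internode is not None:
        payload["internode"] = {"qi": internode.qi, "si": internode.si}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_params(
    path: str | Path,
) -> tuple[
    dict[tuple[str, str], CalibratedModel],
    VegShootParams | None,
    InternodeParams | None,
]:
    """Read a parameter JSON file back into model objects."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"parameter file {path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ConfigError(f"parameter file {path}: missing schema_version")
    if payload["schema_version"] != PARAMS_SCHEMA_VERSION:
        raise ConfigError(
            f"parameter file {path}: schema version {payload['schema_version']} "
            f"not supported (expected {PARAMS_SCHEMA_VERSION})"
        )
    models: dict[tuple[str, str], CalibratedModel] = {}
    for key, m in payload.get("models", {}).items():
        stype, geno = key.split(":")
        if geno not in GENOTYPES:
            raise ConfigError(f"parameter file {path}: unknown genotype {geno!r}")
        s = m["s"]
        if isinstance(s, dict):
            s = {int(nl): float(v) for nl, v in s.items()}
        models[(stype, geno)] = CalibratedModel(
            shoot_type=stype,
            genotype_group=tuple(m["genotype_group"]),
            params=ProfileParams(beta=m["beta"], s=s, x0=m["x0"]),
            k=m["k"],
            alpha=m["alpha"],
        )
    vs = None
    if "vegetative_shoot" in payload:
        vs = VegShootParams(**payload["vegetative_shoot"])
    internode = None
    if "internode" in payload:
        internode = InternodeParams(**payload["internode"])
    return models, vs, internode
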
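"""Validated flat-file I/O for survey tables, geometry and reports.

Schemas (CSV, UTF-8, header row; coordinates in metres of a declared planar
CRS; distances m, transect lengths km, areas km²):

* observer points:  ``point_id, observer, x_m, y_m``
* sightings:        ``transect_id, stratum, perp_distance_m, group_size,
                      vis, light`` (optional ``seen_front, seen_rear``)
* transects:        ``transect_id, stratum, length_km``
* capture history:  ``individual_id, history``

Validation errors carry 1-based data row numbers so a malformed file can be
fixed without guesswork.  Reports are written both as human-readable text
and as flat ``key = value`` files that diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import LIGHT_LEVELS, VIS_LEVELS

__all__ = [
    "SchemaError",
    "read_observer_points",
    "write_observer_points",
    "read_sightings",
    "write_sightings",
    "read_transects",
    "write_transects",
    "write_capture_history",
    "write_report",
    "scene_to_geojson",
]


class SchemaError(ValueError):
    """A file failed schema validation; message names rows and columns."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_observer_points(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["point_id", "observer", "x_m", "y_m"], path)
    bad = df[~df["observer"].isin(["A", "B"])]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad.index[0] + 1}: observer must be 'A' or 'B', got {bad['observer'].iloc[0]!r}"
        )
    for col in ("x_m", "y_m"):
        nn = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(nn):
            raise SchemaError(f"{path}: row {nn.index[0] + 1}: non-numeric {col}")
    return df


def write_observer_points(df: pd.DataFrame, path: str | Path) -> None:
    df[["point_id", "observer", "x_m", "y_m"]].to_csv(path, index=False)


def read_sightings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["transect_id", "stratum", "perp_distance_m", "group_size", "vis", "light"], path
    )
    dist = pd.to_numeric(df["perp_distance_m"], errors="coerce")
    if dist.isna().any():
        raise SchemaError(f"{path}: row {int(dist.isna().idxmax()) + 1}: non-numeric perp_distance_m")
    neg = df[dist < 0]
    if len(neg):
        raise SchemaError(
            f"{path}: row {neg.index[0] + 1}: negative perpendicular distance "
            f"{neg['perp_distance_m'].iloc[0]}"
        )
    size = pd.to_numeric(df["group_size"], errors="coerce")
    if (size.isna() | (size < 1)).any():
        row = int((size.isna() | (size < 1)).idxmax())
        raise SchemaError(f"{path}: row {row + 1}: group_size must be an integer >= 1")
    bad_vis = df[~df["vis"].isin(VIS_LEVELS)]
    if len(bad_vis):
        raise SchemaError(
            f"{path}: row {bad_vis.index[0] + 1}: vis {bad_vis['vis'].iloc[0]!r} "
            f"not in allowed categories {VIS_LEVELS}"
        )
    bad_light = df[~df["light"].isin(LIGHT_LEVELS)]
    if len(bad_light):
        raise SchemaError(
            f"{path}: row {bad_light.index[0] + 1}: light {bad_light['light'].iloc[0]!r} "
            f"not in allowed categories {LIGHT_LEVELS}"
        )
    for col in ("seen_front", "seen_rear"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_sightings(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["transect_id", "stratum", "perp_distance_m", "group_size", "vis", "light"]
    cols += [c for c in ("seen_front", "seen_rear") if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_transects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["transect_id", "stratum", "length_km"], path)
    ln = pd.to_numeric(df["length_km"], errors="coerce")
    if (ln.isna() | (ln <= 0)).any():
        row = int((ln.isna() | (ln <= 0)).idxmax())
        raise SchemaError(f"{path}: row {row + 1}: length_km must be a positive number")
    if df["transect_id"].duplicated().any():
        dup = df.loc[df["transect_id"].duplicated(), "transect_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate transect_id {dup!r}")
    return df


def write_transects(df: pd.DataFrame, path: str | Path) -> None:
    df[["transect_id", "stratum", "length_km"]].to_csv(path, index=False)


def write_capture_history(history: pd.DataFrame, path: str | Path) -> None:
    history[["individual_id", "history"]].to_csv(path, index=False)


def write_report(report: dict, path_txt: str | Path, path_kv: str | Path | None = None) -> None:
    """Write a nested report dict as text and flat key=value files."""

    def flatten(d: dict, prefix: str = "") -> dict:
        out = {}
        for k, v in d.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            if isinstance(v, dict):
                out.update(flatten(v, key))
            else:
                out[key] = v
        return out

    flat = flatten(report)
    lines = [f"{k} = {v}" for k, v in flat.items()]
    Path(path_txt).write_text("\n".join(lines) + "\n")
    if path_kv is not None:
        Path(path_kv).write_text("\n".join(lines) + "\n")


def scene_to_geojson(scene, path: str | Path) -> None:
    """Write scene geometry (island, bears, rocks, transects) as GeoJSON."""
    features = [
        {
            "type": "Feature",
            "properties": {"role": "island", "area_km2": scene.config.island_area_km2},
            "geometry": scene.island.__geo_interface__,
        }
    ]
    for r in scene.bears.itertuples():
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "bear", "bear_id": int(r.bear_id), "group_size": int(r.group_size)},
                "geometry": {"type": "Point", "coordinates": [r.x_m, r.y_m]},
            }
        )
    for r in scene.rocks.itertuples():
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "rock", "rock_id": int(r.rock_id)},
                "geometry": {"type": "Point", "coordinates": [r.x_m, r.y_m]},
            }
        )
    for line in scene.transect_lines:
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "transect"},
                "geometry": line.__geo_interface__,
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
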
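"""Readers and writers for the pipeline's text formats.

Tracts travel as GeoJSON FeatureCollections, exposure surfaces as ESRI
ASCII grids (header: ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value; rows top-first on disk, converted to the internal
lower-left-first convention at this boundary), deaths and exposures as
long-format CSV, configs and CRF sets as YAML, and run manifests as
JSON.  All writers go through an atomic ``.partial`` -> rename step so a
crash never leaves a truncated file in place of a real one.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from .config import POP_COLUMNS, SES_CATEGORIES, ScenarioConfig
from .exposure import ExposureGrid
from .hia import CRF, CRFSet

NODATA_DEFAULT = -9999.0


def _atomic_write(path: Path, text: str) -> None:
    partial = path.with_name(path.name + ".partial")
    partial.write_text(text)
    os.replace(partial, path)


def sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --- tracts (GeoJSON) -------------------------------------------------------


def write_tracts(tracts: pd.DataFrame, path: str | Path) -> None:
    features = []
    for _, row in tracts.iterrows():
        poly: Polygon = row["geometry"]
        coords = [[list(pt) for pt in poly.exterior.coords]]
        props = {"tract_id": row["tract_id"],
                 "ses_category": row["ses_category"]}
        for col in POP_COLUMNS:
            props[col] = int(row[col])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": coords},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": features}
    _atomic_write(Path(path), json.dumps(doc))


def read_tracts(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    rows = []
    seen: set[str] = set()
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(
                f"{path}: feature {i} has non-Polygon geometry "
                f"{geom.get('type')!r}")
        props = feat.get("properties") or {}
        for key in ["tract_id", "ses_category", *POP_COLUMNS]:
            if key not in props:
                raise ValueError(f"{path}: feature {i} missing property {key!r}")
        tid = props["tract_id"]
        if tid in seen:
            raise ValueError(f"{path}: duplicate tract_id {tid!r}")
        seen.add(tid)
        if props["ses_category"] not in SES_CATEGORIES:
            raise ValueError(
                f"{path}: tract {tid!r} has unknown ses_category "
                f"{props['ses_category']!r}")
        rings = geom["coordinates"]
        if len(rings) != 1:
            raise ValueError(f"{path}: tract {tid!r} has holes (unsupported)")
        poly = Polygon(rings[0])
        if poly.area <= 0:
            raise ValueError(f"{path}: tract {tid!r} has zero area")
        row = {"tract_id": tid, "geometry": poly,
               "ses_category": props["ses_category"]}
        for col in POP_COLUMNS:
            v = props[col]
            if not isinstance(v, int) or v < 0:
                raise ValueError(
                    f"{path}: tract {tid!r} population {col} must be a "
                    f"non-negative integer, got {v!r}")
            row[col] = v
        rows.append(row)
    return pd.DataFrame(rows)


# --- exposure grid (ESRI ASCII) ---------------------------------------------


def write_grid(grid: ExposureGrid, path: str | Path,
               nodata: float = NODATA_DEFAULT, fmt: str = "%.10g") -> None:
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin[0]:.10g}",
        f"yllcorner {grid.origin[1]:.10g}",
        f"cellsize {grid.cell_size:.10g}",
        f"NODATA_value {nodata:.10g}",
    ]
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    for r in range(grid.n_rows - 1, -1, -1):  # top row first on disk
        lines.append(" ".join(fmt % v for v in vals[r]))
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_grid(path: str | Path, pollutant: str | None = None) -> ExposureGrid:
    tokens = Path(path).read_text().split()
    header: dict[str, float] = {}
    pos = 0
    required = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"]
    while pos + 1 < len(tokens) and tokens[pos].lower() in required:
        header[tokens[pos].lower()] = float(tokens[pos + 1])
        pos += 2
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header key(s) {missing}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    body = tokens[pos:]
    if len(body) != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} values, found {len(body)}")
    vals = np.array([float(t) for t in body]).reshape(n_rows, n_cols)
    vals = np.where(vals == header["nodata_value"], np.nan, vals)
    vals = vals[::-1]  # disk is top-first; internal is lower-left-first
    if pollutant is None:
        pollutant = Path(path).stem
    return ExposureGrid(pollutant=pollutant,
                        origin=(header["xllcorner"], header["yllcorner"]),
                        cell_size=header["cellsize"], values=vals)


# --- tabular CSV ------------------------------------------------------------


def write_deaths(deaths: pd.DataFrame, path: str | Path) -> None:
    """Long-format death counts; zero rows omitted to keep files small."""
    out = deaths[deaths["deaths"] > 0].sort_values(
        ["tract_id", "cause", "age_class", "sex"], kind="stable")
    _atomic_write(Path(path), out.to_csv(index=False))


def read_deaths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    required = {"tract_id", "cause", "age_class", "sex", "deaths"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["deaths"] < 0).any() or (df["deaths"] % 1 != 0).any():
        raise ValueError(f"{path}: deaths must be non-negative integers")
    df["deaths"] = df["deaths"].astype(int)
    return df


def write_exposures(exposures: pd.DataFrame, path: str | Path) -> None:
    out = exposures.sort_values(["pollutant", "tract_id"], kind="stable")
    _atomic_write(Path(path), out.to_csv(index=False, float_format="%.10g"))


def read_exposures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    required = {"tract_id", "pollutant", "mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_stratum(stratum: pd.DataFrame, path: str | Path) -> None:
    out = stratum.copy()
    out["harbour"] = out["harbour"].astype(int)
    _atomic_write(Path(path), out.to_csv(index=False, float_format="%.10g"))


def read_stratum(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    df["harbour"] = df["harbour"].astype(bool)
    return df


# --- YAML config and CRFs ---------------------------------------------------


def write_config(config: ScenarioConfig, path: str | Path) -> None:
    _atomic_write(Path(path),
                  yaml.safe_dump(config.model_dump(mode="json"),
                                 sort_keys=True))


def read_config(path: str | Path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioConfig.model_validate(data)


def write_crf_set(crf: CRFSet, path: str | Path) -> None:
    doc = {"units": "RR per increment ug/m3; AQG annual mean ug/m3",
           "entries": [vars(e).copy() for e in crf.entries]}
    _atomic_write(Path(path), yaml.safe_dump(doc, sort_keys=True))


def read_crf_set(path: str | Path) -> CRFSet:
    doc = yaml.safe_load(Path(path).read_text())
    return CRFSet([CRF(**e) for e in doc["entries"]])


# --- manifest ---------------------------------------------------------------


def write_manifest(manifest: dict, path: str | Path) -> None:
    _atomic_write(Path(path), json.dumps(manifest, indent=2, sort_keys=True))
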
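"""File I/O: flux-record CSVs with schema validation, single-band rasters
(TIFF + JSON georeferencing sidecar), PCM-style polygon GeoJSON, and the
budget report writer."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .constants import Constants
from .upscale import combine_emissions, net_emission, to_co2e

__all__ = [
    "read_flux_csv", "write_flux_csv", "save_raster", "load_raster",
    "write_pcm_geojson", "read_pcm_geojson", "budget_matrix",
    "write_budget_report",
]

FLUX_COLUMNS = [
    "study_id", "ecozone", "peatland_class", "microform", "method",
    "basis", "nee_value", "ch4_value", "gs_days", "year",
]
_VALID_BASIS = {"daily", "seasonal", "annual"}
_VALID_METHOD = {"chamber", "eddy_covariance"}
_VALID_CLASS = {"bog", "poor_fen", "rich_fen", "fen", "unknown"}


def read_flux_csv(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a flux-record CSV; returns (accepted records, rejects with reasons).

    Rows failing validation are collected, never silently dropped. A header
    missing required columns raises.
    """
    df = pd.read_csv(path)
    required = {"study_id", "ecozone", "peatland_class", "basis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flux CSV header missing columns: {sorted(missing)}")

    reasons = pd.Series("", index=df.index)
    bad_basis = ~df["basis"].isin(_VALID_BASIS)
    reasons[bad_basis] += "invalid basis;"
    if "method" in df.columns:
        bad_m = df["method"].notna() & ~df["method"].isin(_VALID_METHOD)
        reasons[bad_m] += "invalid method;"
    bad_cls = ~df["peatland_class"].isin(_VALID_CLASS)
    reasons[bad_cls] += "invalid peatland_class;"
    if {"nee_value", "ch4_value"} & set(df.columns):
        no_val = True
        for c in ("nee_value", "ch4_value"):
            if c in df.columns:
                no_val &= df[c].isna()
        reasons[no_val] += "no flux value;"
    if "lat" in df.columns:
        bad_ll = df["lat"].notna() & ~df["lat"].between(41, 84)
        reasons[bad_ll] += "lat outside Canada;"
    if "lon" in df.columns:
        bad_ll = df["lon"].notna() & ~df["lon"].between(-141, -52)
        reasons[bad_ll] += "lon outside Canada;"

    ok = reasons == ""
    rejects = df[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    return df[ok].reset_index(drop=True), rejects.reset_index(drop=True)


def write_flux_csv(records: pd.DataFrame, path) -> None:
    cols = [c for c in FLUX_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols + [c for c in records.columns if c not in cols])


def save_raster(
    path, array: np.ndarray, transform=(0.0, 250.0, 0.0, 0.0, 0.0, -250.0),
    crs: str = "unknown-equal-area", nodata=None,
) -> None:
    """Write a single-band raster as TIFF with a JSON georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, array)
    meta = {"transform": list(transform), "crs": crs, "nodata": nodata,
            "dtype": str(array.dtype), "shape": list(array.shape)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_raster(path) -> Tuple[np.ndarray, dict]:
    path = Path(path)
    array = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return array, meta


def write_pcm_geojson(polygons: pd.DataFrame, path) -> None:
    """Write PCM-style polygons (bounding boxes + class percentages) as GeoJSON.

    ``polygons`` carries ecozone, area_km2, pct_* columns and bounding-box
    columns xmin/ymin/xmax/ymax in projected coordinates.
    """
    feats = []
    for _, row in polygons.iterrows():
        x0, y0, x1, y1 = row["xmin"], row["ymin"], row["xmax"], row["ymax"]
        props = {k: row[k] for k in polygons.columns
                 if k not in ("xmin", "ymin", "xmax", "ymax")}
        props = {k: (v.item() if hasattr(v, "item") else v) for k, v in props.items()}
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "Polygon", "coordinates": [[
                [x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_pcm_geojson(path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = []
    for feat in gj["features"]:
        props = dict(feat["properties"])
        xs = [p[0] for p in feat["geometry"]["coordinates"][0]]
        ys = [p[1] for p in feat["geometry"]["coordinates"][0]]
        props.update(xmin=min(xs), ymin=min(ys), xmax=max(xs), ymax=max(ys))
        rows.append(props)
    return pd.DataFrame(rows)


def budget_matrix(
    components: Mapping[str, Mapping[str, tuple]],
    gwp: float = 25.0,
    se_rule: str = "linear",
) -> pd.DataFrame:
    """Assemble the seasonal budget report matrix from per-class components.

    ``components`` maps gas ("NEE", "CH4") to {class: (mass, se)} in Mt.
    Rows NEE, CH4, CH4_CO2e and net; columns (class|combined) x (mean|se).
    CH4-as-CO2e and net rows are derived; combined columns are the configured
    combination (linear by default) of the class columns.
    """
    classes = list(components["NEE"].keys())
    rows = {}
    rows["NEE"] = dict(components["NEE"])
    rows["CH4"] = dict(components["CH4"])
    rows["CH4_CO2e"] = {c: to_co2e(*components["CH4"][c], gwp=gwp) for c in classes}
    rows["net"] = {c: net_emission(rows["NEE"][c], rows["CH4_CO2e"][c], rule=se_rule)
                   for c in classes}
    for name in rows:
        rows[name]["combined"] = combine_emissions(
            [rows[name][c] for c in classes], rule=se_rule
        )
    cols = ["combined"] + classes
    data = {}
    for col in cols:
        data[(col, "mean")] = [rows[r][col][0] for r in ("NEE", "CH4", "CH4_CO2e", "net")]
        data[(col, "se")] = [rows[r][col][1] for r in ("NEE", "CH4", "CH4_CO2e", "net")]
    out = pd.DataFrame(data, index=["NEE", "CH4", "CH4_CO2e", "net"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["class", "stat"])
    return out


def write_budget_report(
    matrix: pd.DataFrame, path, constants: Optional[Constants] = None,
    se_rule: str = "linear", precision: int = 1,
) -> None:
    """Write the budget matrix as CSV with a provenance footer recording the
    SE-combination rule and winter constants (the two reporting choices most
    likely to move the numbers)."""
    constants = constants or Constants()
    flat = matrix.round(precision).copy()
    flat.columns = [f"{c}_{s}" for c, s in flat.columns]
    with open(path, "w") as fh:
        flat.to_csv(fh, index_label="emission")
        fh.write(f"# se_rule={se_rule}\n")
        fh.write(f"# winter_co2_g_m2_day={constants.winter_co2}\n")
        fh.write(f"# winter_ch4_mg_m2_day={constants.winter_ch4}\n")
        fh.write(f"# gwp_ch4={constants.gwp_ch4}\n")
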
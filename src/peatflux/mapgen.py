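"""Rule-based synthesis of the nine-class peatland map and area tabulation.

A 250 m categorical map over {open, treed, forested} x {bog, poor fen,
rich fen} plus upland/water/nodata is built from a co-registered raster
stack: a treed/forested-peatland probability surface (thresholded at 0.5),
a landcover wetland layer supplying open-peatland evidence, a tamarack
biomass fraction separating the bog -> rich fen nutrient gradient, canopy
closure separating cover classes, and a water mask applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .constants import MapRules

__all__ = [
    "CLASS_CODES", "CODE_NAMES", "UPLAND", "WATER", "NODATA",
    "RasterStack", "classify_pixel", "classify_arrays", "majority_resample",
    "build_peatland_map", "tabulate_areas", "collapse_classes",
    "pcm_polygon_areas", "NINE_TO_THREE", "THREE_TO_TWO",
]

UPLAND = 0
WATER = 10
NODATA = 255

# cover-major ordering so the deterministic tie rule (lowest code) is stable
CLASS_CODES = {
    "forested_bog": 1, "forested_poor_fen": 2, "forested_rich_fen": 3,
    "treed_bog": 4, "treed_poor_fen": 5, "treed_rich_fen": 6,
    "open_bog": 7, "open_poor_fen": 8, "open_rich_fen": 9,
    "upland": UPLAND, "water": WATER, "nodata": NODATA,
}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}

NINE_TO_THREE = {code: name.split("_", 1)[1] for name, code in CLASS_CODES.items()
                 if code not in (UPLAND, WATER, NODATA)}
THREE_TO_TWO = {"bog": "bog", "poor_fen": "fen", "rich_fen": "fen"}


@dataclass
class RasterStack:
    """Co-registered single-grid layer stack (row-major numpy arrays).

    ``transform`` is a 6-tuple affine geotransform (GDAL order); the grid is
    assumed equal-area so cell areas are constant.
    """

    peat_prob: np.ndarray
    tamarack_frac: np.ndarray
    canopy_closure: np.ndarray
    landcover_code: np.ndarray
    water_mask: np.ndarray
    ecozone_id: np.ndarray
    transform: tuple = (0.0, 250.0, 0.0, 0.0, 0.0, -250.0)
    crs: str = "unknown-equal-area"
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        shapes = {
            name: getattr(self, name).shape
            for name in ("peat_prob", "tamarack_frac", "canopy_closure",
                         "landcover_code", "water_mask", "ecozone_id")
        }
        if len(set(shapes.values())) != 1:
            raise ValueError(f"layer grids differ: {shapes}")

    @property
    def shape(self) -> tuple:
        return self.peat_prob.shape


def _nutrient(tamarack: float, rules: MapRules) -> str:
    if tamarack < rules.tamarack_poor_min:
        return "bog"
    if tamarack <= rules.tamarack_rich_min:
        return "poor_fen"
    return "rich_fen"


def _cover(canopy: float, rules: MapRules) -> str:
    if canopy >= rules.canopy_forested_min:
        return "forested"
    if canopy >= rules.canopy_treed_min:
        return "treed"
    return "open"


def classify_pixel(
    peat_prob: float,
    landcover_code: int,
    tamarack_frac: float,
    canopy_closure: float,
    water: bool,
    rules: Optional[MapRules] = None,
) -> int:
    """Classify one pixel; reference scalar form of the mapping rules.

    Precedence: water mask, then the peatland-probability model, then
    open-wetland landcover evidence, else upland. NaN in a required layer
    yields nodata.
    """
    rules = rules or MapRules()
    if water:
        return WATER
    if np.isnan(peat_prob) or np.isnan(tamarack_frac) or np.isnan(canopy_closure):
        return NODATA
    if peat_prob >= rules.prob_threshold:
        return CLASS_CODES[f"{_cover(canopy_closure, rules)}_{_nutrient(tamarack_frac, rules)}"]
    if int(landcover_code) in rules.wetland_codes:
        return CLASS_CODES[f"open_{_nutrient(tamarack_frac, rules)}"]
    return UPLAND


def classify_arrays(
    peat_prob: np.ndarray,
    landcover_code: np.ndarray,
    tamarack_frac: np.ndarray,
    canopy_closure: np.ndarray,
    water_mask: np.ndarray,
    rules: Optional[MapRules] = None,
) -> np.ndarray:
    """Vectorized pixel classification over whole layers."""
    rules = rules or MapRules()
    out = np.full(peat_prob.shape, UPLAND, dtype=np.uint8)

    nutrient = np.full(peat_prob.shape, 0, dtype=np.uint8)  # 0 bog, 1 poor, 2 rich
    nutrient[tamarack_frac >= rules.tamarack_poor_min] = 1
    nutrient[tamarack_frac > rules.tamarack_rich_min] = 2

    cover = np.full(peat_prob.shape, 2, dtype=np.uint8)  # 0 forested, 1 treed, 2 open
    cover[canopy_closure >= rules.canopy_treed_min] = 1
    cover[canopy_closure >= rules.canopy_forested_min] = 0

    prob_peat = peat_prob >= rules.prob_threshold
    out[prob_peat] = (3 * cover + nutrient + 1).astype(np.uint8)[prob_peat]

    open_wet = ~prob_peat & np.isin(landcover_code, rules.wetland_codes)
    out[open_wet] = (6 + nutrient + 1).astype(np.uint8)[open_wet]

    bad = np.isnan(peat_prob) | np.isnan(tamarack_frac) | np.isnan(canopy_closure)
    out[bad] = NODATA
    out[water_mask.astype(bool)] = WATER
    return out


def majority_resample(fine: np.ndarray, factor: int, nodata: int = NODATA) -> np.ndarray:
    """Coarsen a categorical grid by block majority vote.

    Each ``factor x factor`` block takes its modal non-nodata class; ties go
    to the lowest class code; all-nodata blocks stay nodata. Grids not
    divisible by ``factor`` are padded with nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fine.copy()
    h, w = fine.shape
    H = -(-h // factor) * factor
    W = -(-w // factor) * factor
    padded = np.full((H, W), nodata, dtype=fine.dtype)
    padded[:h, :w] = fine

    blocks = padded.reshape(H // factor, factor, W // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(-1, factor * factor)

    ncodes = 256
    counts = np.zeros((blocks.shape[0], ncodes), dtype=np.int32)
    rows = np.repeat(np.arange(blocks.shape[0]), factor * factor)
    np.add.at(counts, (rows, blocks.ravel().astype(np.intp)), 1)
    counts[:, nodata] = 0  # never outvotes data

    best = counts.argmax(axis=1).astype(fine.dtype)  # argmax -> lowest code on ties
    empty = counts.sum(axis=1) == 0
    best[empty] = nodata
    return best.reshape(H // factor, W // factor)


def build_peatland_map(
    stack: RasterStack,
    rules: Optional[MapRules] = None,
    landcover_fine: Optional[np.ndarray] = None,
    fine_factor: int = 1,
) -> np.ndarray:
    """Apply the classification rules over a full raster stack.

    If the open-wetland landcover evidence is supplied at a finer grid
    (``landcover_fine`` with integer ``fine_factor``), it is first
    majority-resampled onto the stack's grid.
    """
    rules = rules or MapRules()
    landcover = stack.landcover_code
    if landcover_fine is not None:
        landcover = majority_resample(landcover_fine, fine_factor)
        if landcover.shape != stack.shape:
            raise ValueError(
                f"resampled landcover grid {landcover.shape} != stack grid {stack.shape}"
            )
    return classify_arrays(
        stack.peat_prob, landcover, stack.tamarack_frac,
        stack.canopy_closure, stack.water_mask, rules,
    )


def tabulate_areas(
    class_map: np.ndarray,
    ecozone_id: np.ndarray,
    cell_area_km2: float = 0.0625,
    ecozone_names: Optional[dict] = None,
) -> pd.DataFrame:
    """Count cells per (ecozone, class) and convert to km2."""
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if class_map.shape != ecozone_id.shape:
        raise ValueError("class map and ecozone grid differ in shape")
    pairs = pd.DataFrame({
        "ecozone": ecozone_id.ravel(),
        "class_code": class_map.ravel(),
    })
    counts = pairs.groupby(["ecozone", "class_code"]).size().reset_index(name="cells")
    counts["area_km2"] = counts["cells"] * cell_area_km2
    counts["class"] = counts["class_code"].map(CODE_NAMES)
    if ecozone_names:
        counts["ecozone"] = counts["ecozone"].map(ecozone_names)
    return counts[["ecozone", "class", "class_code", "cells", "area_km2"]]


def collapse_classes(table: pd.DataFrame, scheme: str = "nine_to_three") -> pd.DataFrame:
    """Merge area-table classes: nine cover x nutrient -> three nutrient
    classes, or three -> two (bog vs fen)."""
    if scheme == "nine_to_three":
        mapping = {CODE_NAMES[c]: n for c, n in NINE_TO_THREE.items()}
    elif scheme == "three_to_two":
        mapping = THREE_TO_TWO
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    df = table.copy()
    keep = df["class"].isin(mapping)
    df.loc[keep, "class"] = df.loc[keep, "class"].map(mapping)
    agg = {"area_km2": "sum"}
    if "cells" in df.columns:
        agg["cells"] = "sum"
    out = df.groupby(["ecozone", "class"], as_index=False).agg(agg)
    return out


def pcm_polygon_areas(polygons: pd.DataFrame, classes=("bog", "fen")) -> pd.DataFrame:
    """Peatland areas from soil-survey polygons carrying class percentages.

    ``polygons`` needs ``ecozone``, ``area_km2`` and ``pct_<class>`` columns;
    class area is the percentage-weighted polygon area summed per ecozone.
    Percentage sums above 100 within a polygon produce a warning column.
    """
    pct_cols = [f"pct_{c}" for c in classes]
    for col in pct_cols:
        vals = polygons[col]
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    oversum = polygons[pct_cols].sum(axis=1) > 100 + 1e-9
    if oversum.any():
        import warnings

        warnings.warn(f"{int(oversum.sum())} polygons with class percentages summing > 100")
    rows = []
    for cls, col in zip(classes, pct_cols):
        part = polygons["area_km2"] * polygons[col] / 100.0
        per_zone = part.groupby(polygons["ecozone"]).sum()
        rows.extend((z, cls, a) for z, a in per_zone.items())
    return pd.DataFrame(rows, columns=["ecozone", "class", "area_km2"])
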
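"""Stage runner tying the modules into a reproducible file-based pipeline.

Each stage reads named artifacts from a working directory and writes its own,
so stages can run independently or chained (``all``). A JSON run log records
the constants, seed and input digests behind every report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import assess, harmonize, io, mapgen, season, synth, upscale
from .config import PipelineConfig
from .constants import PRIMARY_ECOZONES
from .mapgen import CODE_NAMES, NODATA

__all__ = ["MissingInputError", "run_stage", "STAGES"]

STAGES = ("simulate", "harmonize", "season", "buildmap", "assess", "upscale", "all")

_ZONE_IDS = {i + 1: z for i, z in enumerate(PRIMARY_ECOZONES)}


class MissingInputError(FileNotFoundError):
    """An input artifact required by a stage does not exist."""


def _need(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing input artifact: {path}")
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log(out: Path, stage: str, cfg: PipelineConfig, inputs: list, outputs: list) -> None:
    entry = {
        "stage": stage,
        "seed": cfg.seed,
        "constants": vars(cfg.constants),
        "se_rule": cfg.se_rule,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    log_path = out / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else []
    log.append(entry)
    log_path.write_text(json.dumps(log, indent=1, default=str))


def _simulate(cfg: PipelineConfig, out: Path) -> list:
    scfg = synth.SynthConfig(seed=cfg.seed)
    records, truth = synth.gen_flux_records(scfg, constants=cfg.constants)
    io.write_flux_csv(records, out / "flux_records.csv")
    truth.to_csv(out / "truth_cells.csv", index=False)

    climate = []
    for i, zone in enumerate(PRIMARY_ECOZONES):
        series = synth.gen_climate_series(
            scfg.target_gs[zone], seed=cfg.seed * 1009 + i, noise_sd=0.5
        )
        series.insert(0, "ecozone", zone)
        climate.append(series)
    pd.concat(climate).to_csv(out / "climate_daily.csv", index=False)

    stack, oracle = synth.gen_landscape(scfg)
    io.save_raster(out / "peat_prob.tif", stack.peat_prob.astype(np.float32))
    io.save_raster(out / "tamarack_frac.tif", stack.tamarack_frac.astype(np.float32))
    io.save_raster(out / "canopy_closure.tif", stack.canopy_closure.astype(np.float32))
    io.save_raster(out / "landcover.tif", stack.landcover_code.astype(np.int16))
    io.save_raster(out / "water_mask.tif", stack.water_mask.astype(np.uint8))
    io.save_raster(out / "ecozone_id.tif", stack.ecozone_id.astype(np.int16))
    io.save_raster(out / "oracle_map.tif", oracle)

    points = synth.gen_validation_points(
        oracle, n=min(2000, oracle.size // 4), error_rate=scfg.validation_error_rate,
        seed=cfg.seed + 17,
    )
    points.to_csv(out / "validation_points.csv", index=False)

    # PCM-style polygons: coarse blocks with class percentages read off the
    # oracle map, standing in for the soil-survey polygon product
    polys = _polygonize(oracle, stack.ecozone_id, cfg, block=32)
    io.write_pcm_geojson(polys, out / "pcm_polygons.geojson")
    return [out / "flux_records.csv", out / "climate_daily.csv",
            out / "oracle_map.tif", out / "validation_points.csv",
            out / "pcm_polygons.geojson"]


def _polygonize(class_map, ecozone_id, cfg: PipelineConfig, block: int = 32) -> pd.DataFrame:
    cell = cfg.map_rules.cell_area_km2
    h, w = class_map.shape
    rows = []
    for r0 in range(0, h, block):
        for c0 in range(0, w, block):
            sub = class_map[r0 : r0 + block, c0 : c0 + block]
            zones = ecozone_id[r0 : r0 + block, c0 : c0 + block]
            usable = sub != NODATA
            if usable.sum() == 0:
                continue
            names = [CODE_NAMES[c] for c in sub[usable].ravel()]
            bog = np.mean([n.endswith("bog") for n in names]) * 100
            fen = np.mean([n.endswith("fen") for n in names]) * 100
            zone = _ZONE_IDS.get(int(np.bincount(zones.ravel()).argmax()), "other")
            rows.append({
                "ecozone": zone, "area_km2": usable.sum() * cell,
                "pct_bog": bog, "pct_fen": fen,
                "xmin": c0 * 250.0, "ymin": -(r0 + sub.shape[0]) * 250.0,
                "xmax": (c0 + sub.shape[1]) * 250.0, "ymax": -r0 * 250.0,
            })
    return pd.DataFrame(rows)


def _harmonize(cfg: PipelineConfig, out: Path) -> list:
    records, rejects = io.read_flux_csv(_need(out / "flux_records.csv"))
    rejects.to_csv(out / "flux_rejects.csv", index=False)
    gs_path = out / "growing_season.csv"
    gs_map = None
    if gs_path.exists():
        gs_df = pd.read_csv(gs_path)
        gs_map = dict(zip(gs_df["ecozone"], gs_df["gs_days"]))
    harm = harmonize.harmonize_records(records, gs_map, cfg.constants)
    harm.to_csv(out / "harmonized_fluxes.csv", index=False)
    table = harmonize.aggregate_emission_factors(harm)
    # every mappable ecozone x class x gas cell must end up with an emission
    # factor; cells with no study at all are borrowed outright
    from .refdata import EMISSION_FACTORS_SEPARATED as _cells

    required = list(
        _cells[["ecozone", "peatland_class", "gas"]].itertuples(index=False, name=None)
    )
    filled = harmonize.fill_missing_factors(table, cfg.similarity_map, required)
    filled.to_csv(out / "emission_factors.csv", index=False)
    return [out / "harmonized_fluxes.csv", out / "emission_factors.csv",
            out / "flux_rejects.csv"]


def _season(cfg: PipelineConfig, out: Path) -> list:
    climate = pd.read_csv(_need(out / "climate_daily.csv"))
    rows = []
    for zone, grp in climate.groupby("ecozone"):
        gs = season.growing_season(grp)
        rows.append((zone, gs.start_day, gs.end_day, gs.length))
    df = pd.DataFrame(rows, columns=["ecozone", "start_day", "end_day", "gs_days"])
    df.to_csv(out / "growing_season.csv", index=False)
    return [out / "growing_season.csv"]


def _buildmap(cfg: PipelineConfig, out: Path) -> list:
    layers = {}
    for name in ("peat_prob", "tamarack_frac", "canopy_closure",
                 "landcover", "water_mask", "ecozone_id"):
        arr, _ = io.load_raster(_need(out / f"{name}.tif"))
        layers[name] = arr
    stack = mapgen.RasterStack(
        peat_prob=layers["peat_prob"], tamarack_frac=layers["tamarack_frac"],
        canopy_closure=layers["canopy_closure"], landcover_code=layers["landcover"],
        water_mask=layers["water_mask"], ecozone_id=layers["ecozone_id"],
    )
    class_map = mapgen.build_peatland_map(stack, cfg.map_rules)
    io.save_raster(out / "class_map.tif", class_map, nodata=NODATA)
    areas = mapgen.tabulate_areas(
        class_map, stack.ecozone_id, cfg.map_rules.cell_area_km2, ecozone_names=_ZONE_IDS
    )
    areas.to_csv(out / "area_table.csv", index=False)
    mapgen.collapse_classes(areas, "nine_to_three").to_csv(
        out / "area_table_3class.csv", index=False
    )
    return [out / "class_map.tif", out / "area_table.csv", out / "area_table_3class.csv"]


def _assess(cfg: PipelineConfig, out: Path) -> list:
    class_map, _ = io.load_raster(_need(out / "class_map.tif"))
    points = pd.read_csv(_need(out / "validation_points.csv"))

    def collapse(code):
        name = CODE_NAMES[code]
        return name if code in (0, 10, 255) else name.split("_", 1)[1]

    collapsed = np.vectorize(collapse)(class_map)
    pred = collapsed[points["row"], points["col"]]
    keep = pred != "nodata"
    cm = assess.confusion_matrix(
        points.loc[keep, "true_class"], pred[keep],
        classes=["bog", "poor_fen", "rich_fen", "upland", "water"],
    )
    cm.to_csv(out / "confusion_matrix.csv")
    stats = assess.accuracy_stats(cm)

    def _safe(v):
        if isinstance(v, dict):
            return {k: _safe(x) for k, x in v.items()}
        if isinstance(v, float) and v != v:
            return None
        return float(v) if isinstance(v, (int, float)) else v

    (out / "accuracy.json").write_text(json.dumps(_safe(stats), indent=1))

    polys = io.read_pcm_geojson(_need(out / "pcm_polygons.geojson"))
    built_polys = _polygonize(class_map, io.load_raster(out / "ecozone_id.tif")[0],
                              cfg, block=32)
    n = min(len(polys), len(built_polys))
    comp = assess.polygon_bin_comparison(
        polys["pct_bog"].to_numpy()[:n], built_polys["pct_bog"].to_numpy()[:n]
    )
    comp["matrix"].to_csv(out / "polygon_bins_bog.csv")
    (out / "polygon_agreement.json").write_text(json.dumps(
        {"within_one_pct": comp["within_one_pct"], "n_polygons": comp["n_polygons"]}
    ))
    return [out / "confusion_matrix.csv", out / "accuracy.json",
            out / "polygon_bins_bog.csv", out / "polygon_agreement.json"]


def _upscale(cfg: PipelineConfig, out: Path) -> list:
    ef = pd.read_csv(_need(out / "emission_factors.csv"))
    areas = pd.read_csv(_need(out / "area_table_3class.csv"))
    gs_df = pd.read_csv(_need(out / "growing_season.csv"))
    gs_map = dict(zip(gs_df["ecozone"], gs_df["gs_days"]))
    areas = areas[areas["class"].isin(("bog", "poor_fen", "rich_fen"))]

    budget = upscale.national_budget(ef, areas, gs_map, cfg.constants, cfg.se_rule)
    budget.to_csv(out / "budget_cells.csv", index=False)

    comp = {"NEE": {}, "CH4": {}}
    cls_rows = budget[budget["level"] == "class"]
    for _, r in cls_rows.iterrows():
        comp[r["gas"]][r["peatland_class"]] = (r["mass_mt"], r["se_mt"])
    for gas in comp:
        for cls in ("bog", "poor_fen", "rich_fen"):
            comp[gas].setdefault(cls, (0.0, 0.0))
    matrix = io.budget_matrix(comp, gwp=cfg.constants.gwp_ch4, se_rule=cfg.se_rule)
    io.write_budget_report(matrix, out / "budget_report.csv", cfg.constants,
                           cfg.se_rule, cfg.report_precision)

    area_by_zone = areas.groupby("ecozone")["area_km2"].sum().to_dict()
    seasonal_nee = matrix.loc["NEE", ("combined", "mean")]
    seasonal_ch4 = matrix.loc["CH4", ("combined", "mean")]
    annual_nee = upscale.annualize_total(
        seasonal_nee, cfg.constants.winter_co2, "NEE", area_by_zone, gs_map)
    annual_ch4 = upscale.annualize_total(
        seasonal_ch4, cfg.constants.winter_ch4, "CH4", area_by_zone, gs_map)
    scen_nee = upscale.gs_scenario(seasonal_nee, matrix.loc["NEE", ("combined", "se")], 1.1)
    summary = {
        "seasonal_nee_mt": seasonal_nee,
        "seasonal_ch4_mt": seasonal_ch4,
        "net_seasonal_co2e_mt": matrix.loc["net", ("combined", "mean")],
        "annual_nee_mt": annual_nee,
        "annual_ch4_mt": annual_ch4,
        "annual_net_co2e_mt": annual_nee + annual_ch4 * cfg.constants.gwp_ch4,
        "gs_plus10pct_nee_mt": scen_nee[0],
    }
    (out / "budget_summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return [out / "budget_report.csv", out / "budget_summary.json",
            out / "budget_cells.csv"]


def run_stage(stage: str, cfg: PipelineConfig, out_dir) -> list:
    """Run one pipeline stage (or ``all``); returns the artifacts written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = ("simulate", "season", "harmonize", "buildmap", "assess", "upscale") \
        if stage == "all" else (stage,)
    runners = {
        "simulate": _simulate, "harmonize": _harmonize, "season": _season,
        "buildmap": _buildmap, "assess": _assess, "upscale": _upscale,
    }
    written = []
    for st in order:
        artifacts = runners[st](cfg, out)
        inputs = [] if st == "simulate" else [p for p in artifacts if Path(p).exists()]
        _log(out, st, cfg, inputs=[], outputs=artifacts)
        written.extend(artifacts)
    return written
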
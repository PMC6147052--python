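"""Synthetic inputs with the statistical and spatial structure the
analysis assumes: flux-study record tables in mixed reporting bases, daily
temperature series with a prescribed growing-season length, co-registered
raster landscapes with a rule-oracle class map, and noisy validation points.

Defaults emulate the compiled national study set: cell means/SEs per
ecozone x class x gas come from the published separated-fen emission-factor
table, NEE is Gaussian (signed), CH4 log-normal (positive, right-skewed),
and the record mix spans daily/seasonal/annual reporting so harmonization
has real work to undo. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import refdata
from .constants import Constants, PRIMARY_ECOZONES
from .mapgen import NODATA, UPLAND, WATER, CODE_NAMES, RasterStack
from .season import growing_season

__all__ = [
    "SynthConfig", "default_cell_params", "gen_flux_records",
    "gen_climate_series", "gen_landscape", "gen_validation_points",
    "oracle_classify",
]

MICROFORMS = ("hummock", "hollow", "lawn", "site")


@dataclass
class SynthConfig:
    """Knobs of the synthetic study conditions."""

    seed: int = 0
    records_per_cell: Optional[int] = None  # None -> published per-cell n
    basis_mix: tuple = (0.4, 0.4, 0.2)  # daily, seasonal, annual shares
    year_noise_frac: float = 0.1  # interannual sd as fraction of cell sd
    target_gs: dict = field(default_factory=lambda: {z: 165 for z in PRIMARY_ECOZONES})
    landscape_size: tuple = (256, 256)
    correlation_length: float = 8.0  # cells
    peat_prevalence: float = 0.25  # fraction of land above the probability threshold
    open_wetland_frac: float = 0.08
    water_frac: float = 0.02
    nodata_frac: float = 0.002
    class_mix: tuple = (0.7, 0.2, 0.1)  # bog, poor fen, rich fen within peatland
    validation_error_rate: float = 0.2


def default_cell_params() -> pd.DataFrame:
    """Observed (non-borrowed) cell parameters from the published synthesis.

    Returns one row per ecozone x class x gas with the published mean, the
    implied between-entry sd (SE x sqrt(n)) and n.
    """
    tbl = refdata.EMISSION_FACTORS_SEPARATED
    obs = tbl[(~tbl["borrowed"]) | (tbl["n"] == 1)].copy()
    obs = obs[obs["n"] >= 1]
    obs["sd"] = np.where(obs["n"] > 1, obs["se"] * np.sqrt(obs["n"]), 0.0)
    return obs[["ecozone", "peatland_class", "gas", "n", "mean", "sd"]].reset_index(drop=True)


def _lognormal_matched(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Log-normal draws with the requested arithmetic mean and sd."""
    if mean <= 0:
        raise ValueError("log-normal cell mean must be positive")
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def gen_flux_records(
    cfg: Optional[SynthConfig] = None,
    seed: Optional[int] = None,
    cell_params: Optional[pd.DataFrame] = None,
    constants: Optional[Constants] = None,
):
    """Generate a flux-record table plus the truth table that produced it.

    Entry-level true daily rates are drawn per cell (Gaussian for NEE,
    matched log-normal for CH4); each entry becomes 1-3 yearly records with
    small interannual jitter, reported on a randomly drawn basis with the
    corresponding inverse conversion applied, so the harmonization pipeline
    must undo it.
    """
    cfg = cfg or SynthConfig()
    seed = cfg.seed if seed is None else seed
    constants = constants or Constants()
    params = default_cell_params() if cell_params is None else cell_params
    rng = np.random.default_rng(seed)

    bases = ("daily", "seasonal", "annual")
    recs = []
    truth = []
    for _, cell in params.iterrows():
        zone, cls, gas = cell["ecozone"], cell["peatland_class"], cell["gas"]
        n_entries = int(cfg.records_per_cell or cell["n"])
        if n_entries < 1:
            continue
        mu, sd = float(cell["mean"]), float(cell["sd"])
        if gas == "CH4":
            entry_vals = _lognormal_matched(rng, mu, sd, n_entries)
        else:
            entry_vals = rng.normal(mu, sd, n_entries)
        truth.append((zone, cls, gas, mu, sd, n_entries))
        gs = float(cfg.target_gs.get(zone, constants.default_gs_days))

        for j, val in enumerate(entry_vals):
            study = f"{zone[:3]}-{cls}-{gas}-{j:03d}".replace(" ", "")
            microform = MICROFORMS[int(rng.integers(len(MICROFORMS)))]
            basis = bases[int(rng.choice(3, p=cfg.basis_mix))]
            n_years = int(rng.integers(1, 4))
            year_noise = rng.normal(0.0, cfg.year_noise_frac * sd, n_years)
            for y, eps in zip(range(2000, 2000 + n_years), year_noise):
                daily = val + eps
                nee = ch4 = np.nan
                if gas == "NEE":
                    reported = daily
                    if basis in ("seasonal", "annual"):
                        reported = daily * gs / constants.scaling_factor
                    if basis == "annual":
                        reported = reported + constants.winter_co2 * (365 - gs)
                    nee = reported
                else:
                    reported = daily
                    if basis in ("seasonal", "annual"):
                        reported = daily * gs / 1000.0
                    if basis == "annual":
                        reported = reported + constants.winter_ch4 / 1000.0 * (365 - gs)
                    ch4 = reported
                recs.append((study, zone, cls, microform, "chamber", basis,
                             nee, ch4, gs, y))

    records = pd.DataFrame(
        recs,
        columns=["study_id", "ecozone", "peatland_class", "microform", "method",
                 "basis", "nee_value", "ch4_value", "gs_days", "year"],
    )
    truth_table = pd.DataFrame(
        truth, columns=["ecozone", "peatland_class", "gas", "true_mean",
                        "true_sd", "n_entries"]
    )
    return records, truth_table


def gen_climate_series(
    target_gs: int, seed: int = 0, noise_sd: float = 0.0, amplitude: float = 15.0
) -> pd.DataFrame:
    """Sinusoidal daily temperature series whose detected growing season has
    approximately the requested length.

    The annual mean-temperature cycle peaks on day 200 with the given
    amplitude; the offset is solved so the 5 degC crossings sit target_gs
    days apart, and a constant 7 degC mean-to-minimum gap places the first
    autumn frost (tmin < -2 degC) at the warm-season exit.
    """
    if not 60 <= target_gs <= 250:
        raise ValueError("target growing-season length must lie in [60, 250]")
    rng = np.random.default_rng(seed)
    days = np.arange(1, 366)
    offset = 5.0 - amplitude * np.cos(np.pi * target_gs / 365.0)
    tmean = offset + amplitude * np.cos(2 * np.pi * (days - 200) / 365.0)
    if noise_sd > 0:
        tmean = tmean + rng.normal(0.0, noise_sd, tmean.size)
    tmin = tmean - 7.0
    series = pd.DataFrame({"day": days, "tmean_c": tmean, "tmin_c": tmin})
    # guard: the construction must actually admit a season
    growing_season(series)
    return series


def _smooth_uniform(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially correlated field with an exactly uniform [0,1] marginal."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    ranks = smooth.ravel().argsort().argsort()
    return ((ranks + 0.5) / ranks.size).reshape(shape)


def _piecewise_to_prob(u: np.ndarray, prevalence: float) -> np.ndarray:
    """Monotone map of a uniform field to [0,1] with P(x >= 0.5) = prevalence."""
    q = 1.0 - prevalence
    out = np.where(u < q, 0.5 * u / q, 0.5 + 0.5 * (u - q) / (1.0 - q))
    return out


def oracle_classify(
    peat_prob, landcover, tamarack, canopy, water, wetland_codes=(80, 81, 82, 83)
) -> int:
    """Plain nested-conditional statement of the mapping rules, kept
    independent of the vectorized map builder for cross-checking."""
    if water:
        return WATER
    if np.isnan(peat_prob) or np.isnan(tamarack) or np.isnan(canopy):
        return NODATA
    if tamarack < 0.10:
        nutrient = 0  # bog
    elif tamarack <= 0.25:
        nutrient = 1  # poor fen
    else:
        nutrient = 2  # rich fen
    if peat_prob >= 0.5:
        if canopy >= 50:
            return 1 + nutrient  # forested
        if canopy >= 10:
            return 4 + nutrient  # treed
        return 7 + nutrient  # open
    if int(landcover) in wetland_codes:
        return 7 + nutrient
    return UPLAND


def gen_landscape(cfg: Optional[SynthConfig] = None, seed: Optional[int] = None):
    """Synthesize a co-registered raster stack and its rule-oracle class map.

    Smoothed random fields drive the peatland-probability, tamarack and
    canopy layers; ecozones are Voronoi blocks of random centres; open
    wetland landcover evidence and water bodies come from further smooth
    fields. The oracle map applies the classification rules pixel by pixel.
    """
    cfg = cfg or SynthConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.landscape_size)
    if shape[0] * shape[1] > 1_000_000:
        raise ValueError("landscape larger than 1000 x 1000 cells")
    sig = cfg.correlation_length

    peat_prob = _piecewise_to_prob(_smooth_uniform(rng, shape, sig), cfg.peat_prevalence)

    u_tam = _smooth_uniform(rng, shape, sig)
    b, p, r = cfg.class_mix
    tamarack = np.interp(u_tam, [0.0, b, b + p, 1.0], [0.0, 0.10, 0.25, 1.0])

    canopy = _smooth_uniform(rng, shape, sig) * 100.0

    landcover = np.where(
        _smooth_uniform(rng, shape, sig) >= 1.0 - cfg.open_wetland_frac, 81, 210
    ).astype(np.int16)
    water = _smooth_uniform(rng, shape, sig / 2) >= 1.0 - cfg.water_frac

    k = len(PRIMARY_ECOZONES)
    centers = rng.uniform(0, 1, (k, 2)) * np.array(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr[None] - centers[:, 0, None, None]) ** 2 + (cc[None] - centers[:, 1, None, None]) ** 2
    ecozone_id = d2.argmin(axis=0).astype(np.int16) + 1

    if cfg.nodata_frac > 0:
        holes = rng.random(shape) < cfg.nodata_frac
        peat_prob = peat_prob.copy()
        peat_prob[holes] = np.nan

    stack = RasterStack(
        peat_prob=peat_prob,
        tamarack_frac=tamarack,
        canopy_closure=canopy,
        landcover_code=landcover,
        water_mask=water,
        ecozone_id=ecozone_id,
    )

    oracle = np.empty(shape, dtype=np.uint8)
    for i in range(shape[0]):
        for j in range(shape[1]):
            oracle[i, j] = oracle_classify(
                peat_prob[i, j], landcover[i, j], tamarack[i, j],
                canopy[i, j], water[i, j],
            )
    return stack, oracle


def gen_validation_points(
    class_map: np.ndarray,
    n: int,
    error_rate: float,
    seed: int = 0,
    include_water: bool = False,
) -> pd.DataFrame:
    """Sample labeled points on the map and corrupt a share of the labels.

    Labels use the three nutrient classes plus upland (and water when
    included); with probability ``error_rate`` a point's true label is
    flipped to a uniformly chosen different class, emulating ground-truth /
    map disagreement.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    valid = class_map != NODATA
    if not include_water:
        valid &= class_map != WATER
    rows, cols = np.nonzero(valid)
    if n > rows.size:
        raise ValueError(f"requested {n} points but only {rows.size} usable cells")
    pick = rng.choice(rows.size, size=n, replace=False)
    rr, cc = rows[pick], cols[pick]

    def collapse(code):
        name = CODE_NAMES[code]
        if code in (UPLAND, WATER):
            return name
        return name.split("_", 1)[1]

    labels = np.array([collapse(c) for c in class_map[rr, cc]], dtype=object)
    vocab = ["bog", "poor_fen", "rich_fen", "upland"] + (["water"] if include_water else [])
    flip = rng.random(n) < error_rate
    for i in np.nonzero(flip)[0]:
        others = [c for c in vocab if c != labels[i]]
        labels[i] = others[int(rng.integers(len(others)))]
    return pd.DataFrame({"row": rr, "col": cc, "true_class": labels})
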
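"""Harmonize heterogeneous peatland flux reports to a common daily basis.

Literature NEE and CH4 observations arrive on daily, growing-season
("seasonal") or annual bases. Everything is converted to mean daily
growing-season rates — the base unit of comparison — then pooled into
ecozone x peatland-class emission factors with standard errors, with data
gaps filled from the most similar ecozone.

Conventions: NEE in g CO2 m-2 day-1 with negative = net uptake; CH4 in
mg CH4 m-2 day-1 on the daily basis and g CH4 m-2 on seasonal/annual bases.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .constants import Constants, DEFAULT_REGION_MAP, PRIMARY_ECOZONES

__all__ = [
    "ClassificationError",
    "classify_peatland",
    "seasonal_to_daily_nee",
    "seasonal_to_daily_ch4",
    "daily_to_seasonal",
    "annual_to_seasonal",
    "winter_rate_reference",
    "harmonize_records",
    "aggregate_emission_factors",
    "fill_missing_factors",
    "regional_summary",
    "DEFAULT_SIMILARITY_MAP",
]


class ClassificationError(ValueError):
    """Raised when no informative evidence is available to classify a site."""


_PEAT_MOSS_TOKENS = ("sphagnum", "peat moss", "peat-moss")
_TRUE_MOSS_TOKENS = ("brown moss", "true moss", "amblystegiaceae", "drepanocladus")


def classify_peatland(
    ph: Optional[float],
    water_source: str = "unknown",
    pft_notes: str = "",
) -> str:
    """Assign bog / poor_fen / rich_fen from pH, hydrology and vegetation.

    Bogs are ombrotrophic (rain-fed) and Sphagnum-dominated; fens receive
    geogenous (mineral-influenced) water, with poor fens at pH < 5.5 and
    peat-moss dominance and rich-intermediate fens at pH >= 5.5 with true
    (brown) mosses.
    """
    notes = (pft_notes or "").lower()
    has_ph = ph is not None and not (isinstance(ph, float) and math.isnan(ph))
    if not has_ph and water_source in (None, "", "unknown") and not notes:
        raise ClassificationError("no pH, water-source or vegetation evidence given")

    peat_moss = any(tok in notes for tok in _PEAT_MOSS_TOKENS)
    true_moss = any(tok in notes for tok in _TRUE_MOSS_TOKENS)

    if water_source == "ombrotrophic" or (peat_moss and water_source != "geogenous"):
        return "bog"
    if water_source == "geogenous":
        if has_ph:
            return "rich_fen" if ph >= 5.5 else "poor_fen"
        if peat_moss:
            return "poor_fen"
        if true_moss:
            return "rich_fen"
    return "unknown"


def _check_gs(gs_days: float) -> None:
    if gs_days <= 0:
        raise ValueError(f"growing-season length must be positive, got {gs_days}")


def seasonal_to_daily_nee(seasonal_nee: float, gs_days: float, k: float = 5.0) -> float:
    """Seasonal NEE (g CO2 m-2 season-1) -> daily rate, scaled by ``k``."""
    _check_gs(gs_days)
    return seasonal_nee / gs_days * k


def seasonal_to_daily_ch4(seasonal_ch4: float, gs_days: float) -> float:
    """Seasonal CH4 (g CH4 m-2 season-1) -> daily rate in mg CH4 m-2 day-1."""
    _check_gs(gs_days)
    return seasonal_ch4 / gs_days * 1000.0


def daily_to_seasonal(daily_value: float, gs_days: float, gas: str, k: float = 5.0) -> float:
    """Exact inverse of the daily conversions; returns a seasonal total."""
    _check_gs(gs_days)
    if gas == "NEE":
        return daily_value * gs_days / k
    if gas == "CH4":
        return daily_value * gs_days / 1000.0
    raise ValueError(f"unknown gas {gas!r}")


def annual_to_seasonal(
    annual_value: float, gs_days: float, winter_rate: float, gas: str
) -> float:
    """Strip an assumed constant non-growing-season emission from an annual total.

    ``winter_rate`` is in g CO2 m-2 day-1 for NEE and mg CH4 m-2 day-1 for
    CH4 (converted to g internally, matching the seasonal CH4 unit).
    """
    if not 0 < gs_days < 365:
        raise ValueError("gs_days must lie in (0, 365)")
    if gas == "NEE":
        rate = winter_rate
    elif gas == "CH4":
        rate = winter_rate / 1000.0
    else:
        raise ValueError(f"unknown gas {gas!r}")
    return annual_value - rate * (365 - gs_days)


def winter_rate_reference(values, grouping: str = "simple") -> float:
    """Mean non-growing-season rate from literature reports.

    ``values`` is a sequence of rates or of (study, rate) pairs. ``simple``
    averages all rows; ``by_study`` averages per-study means first.
    """
    values = list(values)
    if not values:
        raise ValueError("empty list of winter rates")
    if isinstance(values[0], (tuple, list)):
        df = pd.DataFrame(values, columns=["study", "rate"])
        # study label before any parenthesised microform qualifier
        df["study"] = df["study"].str.split("(").str[0].str.strip()
        if grouping == "by_study":
            return float(df.groupby("study")["rate"].mean().mean())
        return float(df["rate"].mean())
    if grouping == "by_study":
        raise ValueError("by_study grouping requires (study, rate) pairs")
    return float(np.mean(values))


# --- record-level harmonization ---------------------------------------------


def harmonize_records(
    records: pd.DataFrame,
    gs_by_ecozone: Optional[Mapping[str, float]] = None,
    constants: Optional[Constants] = None,
) -> pd.DataFrame:
    """Convert every flux record to the common daily growing-season basis.

    ``records`` needs columns ``basis`` (daily/seasonal/annual), ``nee_value``
    and/or ``ch4_value``, plus either a ``gs_days`` column or an ``ecozone``
    resolvable through ``gs_by_ecozone``. Returns the input frame with
    ``daily_nee``, ``daily_ch4``, ``gs_days`` and a ``conversion_path``
    audit column added.
    """
    constants = constants or Constants()
    out = records.copy()

    if "gs_days" in out.columns:
        gs = out["gs_days"].astype(float)
    else:
        gs = pd.Series(np.nan, index=out.index)
    if gs_by_ecozone is not None and "ecozone" in out.columns:
        gs = gs.fillna(out["ecozone"].map(gs_by_ecozone))
    gs = gs.fillna(float(constants.default_gs_days))
    out["gs_days"] = gs

    bad = ~out["basis"].isin(["daily", "seasonal", "annual"])
    if bad.any():
        raise ValueError(f"unknown basis values: {sorted(out.loc[bad, 'basis'].unique())}")

    daily_nee, daily_ch4, paths = [], [], []
    for _, row in out.iterrows():
        basis = row["basis"]
        g = row["gs_days"]
        nee = row.get("nee_value", np.nan)
        ch4 = row.get("ch4_value", np.nan)
        path = []
        if basis == "annual":
            if not np.isnan(nee):
                nee = annual_to_seasonal(nee, g, constants.winter_co2, "NEE")
            if not np.isnan(ch4):
                ch4 = annual_to_seasonal(ch4, g, constants.winter_ch4, "CH4")
            path.append("annual->seasonal")
            basis = "seasonal"
        if basis == "seasonal":
            if not np.isnan(nee):
                nee = seasonal_to_daily_nee(nee, g, constants.scaling_factor)
            if not np.isnan(ch4):
                ch4 = seasonal_to_daily_ch4(ch4, g)
            path.append("seasonal->daily")
        daily_nee.append(nee)
        daily_ch4.append(ch4)
        paths.append("|".join(path) if path else "none")

    out["daily_nee"] = daily_nee
    out["daily_ch4"] = daily_ch4
    out["conversion_path"] = paths
    return out


def aggregate_emission_factors(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Pool harmonized records into an ecozone x class emission-factor table.

    Years are averaged first within each (study, microform) site entry;
    microforms stay separate entries to retain within-peatland variability.
    Then per (ecozone, class, gas): mean, SE = sample sd / sqrt(n), n.
    Cells with n = 1 get SE = NaN, to be gap-filled later.
    """
    entry_keys = [k for k in ("study_id", "microform") if k in harmonized.columns]
    group_keys = ["ecozone", "peatland_class"] + entry_keys

    rows = []
    for gas, col in (("NEE", "daily_nee"), ("CH4", "daily_ch4")):
        if col not in harmonized.columns:
            continue
        sub = harmonized.dropna(subset=[col])
        if sub.empty:
            continue
        entries = sub.groupby(group_keys, sort=True)[col].mean().reset_index()
        for (zone, cls), grp in entries.groupby(["ecozone", "peatland_class"], sort=True):
            vals = grp[col].to_numpy(dtype=float)
            n = len(vals)
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append((zone, cls, gas, n, float(np.mean(vals)), se, False, None))
    return pd.DataFrame(
        rows,
        columns=["ecozone", "peatland_class", "gas", "n", "mean", "se",
                 "borrowed", "borrowed_from"],
    )


#: Donor ecozone per (ecozone, class, gas) cell lacking a mean or SE; follows
#: the italic entries of the published synthesis tables. Chains (a donor that
#: is itself gap-filled) resolve over repeated passes.
DEFAULT_SIMILARITY_MAP = {
    ("Atlantic Maritime", "poor_fen", "NEE"): "Mixedwood Plains",
    ("Atlantic Maritime", "rich_fen", "NEE"): "Hudson Plains",
    ("Atlantic Maritime", "poor_fen", "CH4"): "Mixedwood Plains",
    ("Atlantic Maritime", "rich_fen", "CH4"): "Hudson Plains",
    ("Atlantic Maritime", "fen", "NEE"): "Mixedwood Plains",
    ("Atlantic Maritime", "fen", "CH4"): "Mixedwood Plains",
    ("Boreal Plains", "poor_fen", "NEE"): "Boreal Shield",
    ("Boreal Plains", "poor_fen", "CH4"): "Boreal Shield",
    ("Boreal Shield", "poor_fen", "NEE"): "Taiga Shield",
    ("Hudson Plains", "poor_fen", "NEE"): "Mixedwood Plains",
    ("Hudson Plains", "poor_fen", "CH4"): "Boreal Shield",
    ("Taiga Plains", "bog", "NEE"): "Boreal Plains",
    ("Taiga Plains", "poor_fen", "NEE"): "Taiga Shield",
    ("Taiga Plains", "poor_fen", "CH4"): "Taiga Shield",
    ("Taiga Shield", "bog", "NEE"): "Taiga Plains",
    ("Taiga Shield", "rich_fen", "NEE"): "Taiga Plains",
    ("Taiga Shield", "bog", "CH4"): "Taiga Plains",
}


def fill_missing_factors(
    table: pd.DataFrame,
    similarity_map: Optional[Mapping] = None,
    required_cells: Optional[list] = None,
) -> pd.DataFrame:
    """Fill absent emission-factor cells from the most similar ecozone.

    ``similarity_map`` maps (ecozone, peatland_class, gas) — or
    (ecozone, peatland_class) as a gas-independent fallback — to a donor
    ecozone. Missing means and/or SEs are copied from the donor's row for the
    same class and gas; the row is flagged ``borrowed`` with its donor.
    ``required_cells`` optionally lists (ecozone, class, gas) cells that must
    exist; absent ones are created and filled entirely from the donor.
    """
    similarity_map = DEFAULT_SIMILARITY_MAP if similarity_map is None else similarity_map
    table = table.copy()

    if required_cells:
        have = set(zip(table["ecozone"], table["peatland_class"], table["gas"]))
        for cell in required_cells:
            if cell not in have:
                table.loc[len(table)] = [cell[0], cell[1], cell[2], 0,
                                         np.nan, np.nan, False, None]

    def donor_for(zone, cls, gas):
        return similarity_map.get((zone, cls, gas)) or similarity_map.get((zone, cls))

    def missing_rows():
        return table.index[table["mean"].isna() | table["se"].isna()]

    # donors may themselves be borrowed; iterate until stable
    for _ in range(len(table) + 1):
        todo = missing_rows()
        if len(todo) == 0:
            break
        progressed = False
        for i in todo:
            zone, cls, gas = table.loc[i, ["ecozone", "peatland_class", "gas"]]
            donor = donor_for(zone, cls, gas)
            if donor is None:
                continue
            src = table[
                (table["ecozone"] == donor)
                & (table["peatland_class"] == cls)
                & (table["gas"] == gas)
            ]
            if src.empty:
                continue
            src = src.iloc[0]
            changed = False
            if pd.isna(table.at[i, "mean"]) and not pd.isna(src["mean"]):
                table.at[i, "mean"] = src["mean"]
                changed = True
            if pd.isna(table.at[i, "se"]) and not pd.isna(src["se"]):
                table.at[i, "se"] = src["se"]
                changed = True
            if changed:
                table.at[i, "borrowed"] = True
                table.at[i, "borrowed_from"] = donor
                progressed = True
        if not progressed:
            break

    left = missing_rows()
    if len(left) > 0:
        cells = table.loc[left, ["ecozone", "peatland_class", "gas"]].to_records(index=False)
        raise ValueError(f"no donor resolves cells: {list(map(tuple, cells))}")
    return table


def regional_summary(
    harmonized: pd.DataFrame,
    region_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Pool harmonized records into broad-region x class means and SEs.

    The default map groups the seven primary ecozones into temperate, boreal
    and subarctic regions.
    """
    region_map = DEFAULT_REGION_MAP if region_map is None else region_map
    unmapped = set(harmonized["ecozone"].unique()) - set(region_map)
    if unmapped:
        raise ValueError(f"ecozones missing from region map: {sorted(unmapped)}")
    regional = harmonized.copy()
    regional["ecozone"] = regional["ecozone"].map(region_map)
    out = aggregate_emission_factors(regional)
    return out.rename(columns={"ecozone": "region"})
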
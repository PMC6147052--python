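"""Growing-season detection from daily temperature series.

The growing season runs from the first day, at or after March 1st (Julian day
60 on a 365-day calendar), of a five-consecutive-day run with mean daily
temperature >= 5 degC, to the first day at or after August 1st (day 213) with
minimum daily temperature < -2 degC. Length is end - start (end-exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["GrowingSeason", "NoSeasonError", "growing_season", "ecozone_gs",
           "MAR1", "AUG1"]

MAR1 = 60
AUG1 = 213
_START_T = 5.0
_END_T = -2.0
_RUN = 5


class NoSeasonError(ValueError):
    """No qualifying growing-season start or end exists in the series."""


@dataclass(frozen=True)
class GrowingSeason:
    start_day: int
    end_day: int

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


def growing_season(series: pd.DataFrame) -> GrowingSeason:
    """Scan a complete daily series (columns day, tmean_c, tmin_c).

    Raises :class:`NoSeasonError` if no 5-day warm run begins before August
    1st or no killing frost occurs by December 31st.
    """
    df = series.sort_values("day")
    days = df["day"].to_numpy()
    if len(days) != 365 or days[0] != 1 or days[-1] != 365:
        raise ValueError("series must cover days 1..365 without gaps")
    tmean = df["tmean_c"].to_numpy(dtype=float)
    tmin = df["tmin_c"].to_numpy(dtype=float)

    warm = tmean >= _START_T
    start = None
    for d in range(MAR1, AUG1):  # run must begin before Aug 1
        i = d - 1
        if i + _RUN <= 365 and warm[i : i + _RUN].all():
            start = d
            break
    if start is None:
        raise NoSeasonError("no 5-day run of tmean >= 5 degC before August 1st")

    cold = tmin < _END_T
    end_candidates = np.nonzero(cold[AUG1 - 1 :])[0]
    if len(end_candidates) == 0:
        raise NoSeasonError("no day with tmin < -2 degC from August 1st onward")
    end = AUG1 + int(end_candidates[0])
    return GrowingSeason(start_day=start, end_day=end)


def ecozone_gs(
    gs_table: pd.DataFrame, ecozone_of: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Mean growing-season length per ecozone.

    ``gs_table`` has columns ``location`` and ``length`` plus either an
    ``ecozone`` column or a ``location -> ecozone`` mapping in ``ecozone_of``.
    """
    df = gs_table.copy()
    if "ecozone" not in df.columns:
        if ecozone_of is None:
            raise ValueError("need an ecozone column or a location->ecozone map")
        df["ecozone"] = df["location"].map(ecozone_of)
        if df["ecozone"].isna().any():
            missing = df.loc[df["ecozone"].isna(), "location"].tolist()
            raise ValueError(f"locations without ecozone assignment: {missing}")
    if df.empty:
        raise ValueError("no growing-season values supplied")
    return df.groupby("ecozone")["length"].mean().to_dict()
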
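"""CSV ingestion and emission for phenotype and weather tables.

Dialects:

* phenotypes — one row per plot: ``genotype,location,year,block,ME,<traits>``
  (``ME`` optional on input; assigned by delineation otherwise);
* weather — one row per location-day:
  ``location,lat,lon,elev,date,T2M,T2M_MAX,T2M_MIN,T2MDEW,RH2M,PRECTOT,WS2M,SIHS,DTIRF``
  with ISO dates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from enviromets.envirotyping import RAW_VARIABLES, WeatherSeries
from enviromets.varcomp import REQUIRED_COLUMNS

log = logging.getLogger(__name__)

PHENOTYPE_KEY = ("genotype", "location", "year", "block")
WEATHER_META = ("location", "lat", "lon", "elev", "date")


def read_phenotypes(path: str, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Read and validate a plot-level phenotype CSV.

    Requires ``genotype, location, year, block`` plus at least one trait
    column; reports non-numeric trait cells with their row numbers and
    duplicated plot keys.
    """
    df = pd.read_csv(path, dtype={"genotype": str, "location": str, "block": str})
    for col in PHENOTYPE_KEY:
        if col not in df.columns:
            raise ValueError(f"phenotype file {path}: missing required column {col!r}")
    trait_cols = traits or [c for c in df.columns
                            if c not in PHENOTYPE_KEY and c != "ME"]
    if not trait_cols:
        raise ValueError(f"phenotype file {path}: no trait columns found")
    for t in trait_cols:
        if t not in df.columns:
            raise ValueError(f"phenotype file {path}: missing trait column {t!r}")
        parsed = pd.to_numeric(df[t], errors="coerce")
        bad = parsed.isna() & df[t].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
            raise ValueError(
                f"phenotype file {path}: non-numeric values in {t!r} at "
                f"file row(s) {rows}")
        df[t] = parsed
    dup = df.duplicated(subset=list(PHENOTYPE_KEY), keep=False)
    if dup.any():
        keys = df.loc[dup, list(PHENOTYPE_KEY)].drop_duplicates().head(5)
        raise ValueError(
            f"phenotype file {path}: duplicated plot key(s): "
            f"{keys.to_dict('records')}")
    df["year"] = df["year"].astype(int)
    return df


def write_phenotypes(data: pd.DataFrame, path: str) -> None:
    cols = [c for c in (*PHENOTYPE_KEY, "ME") if c in data.columns]
    cols += [c for c in data.columns if c not in cols]
    data[cols].to_csv(path, index=False)


def read_weather(path: str) -> dict[str, WeatherSeries]:
    """Read a weather CSV into per-location series, validating invariants.

    Row-level failures (Tmin > Tmax, RH out of [0, 100], unparsable dates)
    raise with the offending file row; within-year date gaps are reported per
    location in the log.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*WEATHER_META, *RAW_VARIABLES) if c not in df.columns]
    if missing:
        raise ValueError(f"weather file {path}: missing column(s) {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(df.index[dates.isna()][0]) + 2
        raise ValueError(
            f"weather file {path}: unparsable date {df['date'].iloc[row - 2]!r} "
            f"at file row {row}")
    df["date"] = dates
    bad = df["T2M_MIN"] > df["T2M_MAX"]
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ValueError(f"weather file {path}: Tmin > Tmax at file row {row}")
    rh_bad = (df["RH2M"] < 0) | (df["RH2M"] > 100)
    if rh_bad.any():
        row = int(df.index[rh_bad][0]) + 2
        raise ValueError(
            f"weather file {path}: RH2M outside [0, 100] at file row {row}")
    out: dict[str, WeatherSeries] = {}
    for loc, sub in df.groupby("location", sort=True):
        sub = sub.sort_values("date").reset_index(drop=True)
        series = WeatherSeries(
            location=str(loc),
            latitude=float(sub["lat"].iloc[0]),
            longitude=float(sub["lon"].iloc[0]),
            elevation=float(sub["elev"].iloc[0]),
            data=sub[["date", *RAW_VARIABLES]].copy(),
        )
        series.validate()
        gaps = series.year_gaps()
        for year, days in gaps.items():
            log.warning("weather %s/%d: %d missing day(s), first %s",
                        loc, year, len(days), days[0].date())
        out[str(loc)] = series
    return out


def write_weather(collection: Mapping[str, WeatherSeries], path: str) -> None:
    frames = []
    for loc in sorted(collection):
        s = collection[loc]
        d = s.data.copy()
        d.insert(0, "location", s.location)
        d.insert(1, "lat", s.latitude)
        d.insert(2, "lon", s.longitude)
        d.insert(3, "elev", s.elevation)
        frames.append(d)
    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6g")
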
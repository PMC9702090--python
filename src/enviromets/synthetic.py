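"""Synthetic weather archives and trial phenotypes with planted structure.

The weather generator produces daily growing-season records per location and
year: a seasonal sinusoid (peaking mid July) plus AR(1) noise for
temperature, with archetype-level offsets for humidity, rainfall, wind and
radiation. Locations sharing an archetype have identical expected series, so
the between-archetype separation (and hence the recoverability of the
planted mega-environment partition) is controlled by the archetype offsets
relative to the daily noise.

The trial generator draws phenotypes from the crossed random-effects model

    y_ijkn = mu + G_i + M_j + Y_k + GM_ij + GY_ik + MY_jk + GMY_ijk
             + REP_n(jk) + e_ijkn

with independent zero-mean normal effects per term and user-specified
variances; the replicate effect is indexed by location x block within
mega-environment x year. All randomness is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from enviromets.config import SimulationConfig, VARIANCE_TERMS, WeatherArchetype
from enviromets.envirotyping import (
    WeatherSeries,
    saturation_vapor_pressure,
    solar_geometry,
)


def _season_dates(year: int, months: tuple[int, int]) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=year, month=months[0], day=1)
    end = (pd.Timestamp(year=year, month=months[1], day=1)
           + pd.offsets.MonthEnd(0))
    return pd.date_range(start, end, freq="D")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    z = rng.standard_normal(n)
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = z[0]
    c = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + c * z[t]
    return e * sd


def _location_year_weather(arch: WeatherArchetype, dates: pd.DatetimeIndex,
                           rng: np.random.Generator) -> pd.DataFrame:
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    season = arch.tmean_base + arch.tmean_amplitude * np.cos(
        2.0 * np.pi * (doy - 196) / 365.0)
    tmean = season + _ar1(rng, n, arch.ar1_rho, arch.noise_sd)
    trange = np.clip(
        arch.trange + _ar1(rng, n, arch.ar1_rho, 0.25 * arch.noise_sd), 0.5, None)
    tmax = tmean + 0.5 * trange
    tmin = tmean - 0.5 * trange
    depression = np.clip(
        arch.tdew_depression + _ar1(rng, n, arch.ar1_rho, 0.4 * arch.noise_sd),
        0.0, None)
    tdew = tmean - depression
    rh = 100.0 * (saturation_vapor_pressure(tdew)
                  / saturation_vapor_pressure(tmean))
    rh = np.clip(rh, 0.0, 100.0)
    if arch.noise_sd > 0:
        wet = rng.random(n) < arch.precip_wet_prob
        scale = arch.precip_mean / max(arch.precip_wet_prob, 1e-9)
        precip = np.where(wet, rng.exponential(scale, n), 0.0)
    else:
        precip = np.full(n, arch.precip_mean)
    wind = np.clip(
        arch.wind_mean + _ar1(rng, n, arch.ar1_rho, 0.15 * arch.noise_sd),
        0.05, None)
    rta, _ = solar_geometry(arch.latitude, doy)
    clearness = np.clip(
        arch.clearness + _ar1(rng, n, arch.ar1_rho, 0.04 * arch.noise_sd),
        0.05, 0.75)
    sihs = clearness * rta
    dtirf = (arch.dtirf_base + 0.25 * (tmean - 20.0)
             + _ar1(rng, n, arch.ar1_rho, 0.2 * arch.noise_sd))
    return pd.DataFrame({
        "date": dates,
        "T2M": tmean,
        "T2M_MAX": tmax,
        "T2M_MIN": tmin,
        "T2MDEW": tdew,
        "RH2M": rh,
        "PRECTOT": precip,
        "WS2M": wind,
        "SIHS": sihs,
        "DTIRF": dtirf,
    })


def simulate_weather(config: SimulationConfig,
                     years: list[int] | None = None) -> dict[str, WeatherSeries]:
    """Generate daily growing-season weather for every configured location.

    ``years`` defaults to the historical archive span
    (``weather_first_year .. +n_weather_years``); pass ``config.years`` for
    trial-period weather. Determinism: each (location, year) stream is seeded
    independently from ``rng_seed``, so output does not depend on iteration
    order.
    """
    if years is None:
        years = [config.weather_first_year + i for i in range(config.n_weather_years)]
    if not years:
        raise ValueError("at least one year required")
    out: dict[str, WeatherSeries] = {}
    for li, loc in enumerate(config.locations):
        arch = config.archetypes[config.me_archetypes[loc]]
        frames = []
        for year in years:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.rng_seed, 7, li, year]))
            frames.append(_location_year_weather(arch, _season_dates(year, config.season_months), rng))
        data = pd.concat(frames, ignore_index=True)
        series = WeatherSeries(location=loc, latitude=arch.latitude,
                               longitude=arch.longitude + 0.1 * li,
                               elevation=arch.elevation, data=data)
        series.validate()
        out[loc] = series
    return out


def _draw_effects(rng: np.random.Generator, levels: pd.Index | list,
                  variance: float) -> dict:
    vals = rng.standard_normal(len(levels)) * np.sqrt(variance)
    return dict(zip(levels, vals))


def simulate_trial(config: SimulationConfig,
                   me_labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Simulate plot-level phenotypes for the configured trial design.

    One record per genotype x location x year x block; each trait is the
    grand mean plus independent normal draws for each model term at its
    factor level. ``me_labels`` overrides the mega-environment labeling
    (default: the archetype mapping, i.e. the planted truth).

    Returns a tidy frame with columns ``genotype, location, year, block, ME``
    plus one column per trait.
    """
    config.validate()
    labels = dict(me_labels) if me_labels is not None else dict(config.me_archetypes)
    genotypes = [f"G{i + 1:02d}" for i in range(config.n_genotypes)]
    locations = config.locations
    years = config.years
    blocks = [f"B{b + 1}" for b in range(config.n_blocks)]

    idx = pd.MultiIndex.from_product(
        [genotypes, locations, years, blocks],
        names=["genotype", "location", "year", "block"])
    frame = idx.to_frame(index=False)
    frame["ME"] = frame["location"].map(labels)
    mes = sorted(set(labels.values()))

    for ti, trait in enumerate(config.traits):
        comps = {term: float(config.variance_components.get(trait, {}).get(term, 0.0))
                 for term in VARIANCE_TERMS}
        for term, var in comps.items():
            if var < 0:
                raise ValueError(f"negative variance for term {term!r}")
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, 11, ti]))
        g = _draw_effects(rng, genotypes, comps["G"])
        m = _draw_effects(rng, mes, comps["M"])
        y = _draw_effects(rng, years, comps["Y"])
        gm = _draw_effects(rng, pd.MultiIndex.from_product([genotypes, mes]), comps["GM"])
        gy = _draw_effects(rng, pd.MultiIndex.from_product([genotypes, years]), comps["GY"])
        my = _draw_effects(rng, pd.MultiIndex.from_product([mes, years]), comps["MY"])
        gmy = _draw_effects(rng, pd.MultiIndex.from_product([genotypes, mes, years]),
                            comps["GMY"])
        # replicate = location x block within ME x year
        rep = _draw_effects(rng, pd.MultiIndex.from_product([locations, blocks, years]),
                            comps["REP"])
        eps = rng.standard_normal(len(frame)) * np.sqrt(comps["residual"])

        mu = float(config.grand_means[trait])
        gv = frame["genotype"].map(g).to_numpy()
        mv = frame["ME"].map(m).to_numpy()
        yv = frame["year"].map(y).to_numpy()
        gmv = pd.MultiIndex.from_frame(frame[["genotype", "ME"]]).map(gm).to_numpy()
        gyv = pd.MultiIndex.from_frame(frame[["genotype", "year"]]).map(gy).to_numpy()
        myv = pd.MultiIndex.from_frame(frame[["ME", "year"]]).map(my).to_numpy()
        gmyv = pd.MultiIndex.from_frame(frame[["genotype", "ME", "year"]]).map(gmy).to_numpy()
        repv = pd.MultiIndex.from_frame(frame[["location", "block", "year"]]).map(rep).to_numpy()
        frame[trait] = (mu + gv + mv + yv + gmv + gyv + myv + gmyv + repv + eps)
    return frame
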
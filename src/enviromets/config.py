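"""Configuration containers for simulation and analysis runs.

Defaults emulate a summer-maize multi-environment trial: 26 hybrids grown at
10 locations over 2 seasons in randomized complete blocks with 3 replicates,
with 9 agronomic traits, and locations drawn from 4 climate archetypes that
the delineation stage should recover as mega-environments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Order of the random-effect variance terms in the trial model
#: y = mu + G + M + Y + GM + GY + MY + GMY + REP(M:Y) + error.
VARIANCE_TERMS = ("G", "M", "Y", "GM", "GY", "MY", "GMY", "REP", "residual")

#: Desired direction of selection per default trait: for moisture content,
#: plant/ear height and bare tip length smaller is better; for yield and the
#: ear/kernel traits larger is better.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "GY": "increase",
    "EL": "increase",
    "ER": "increase",
    "GWE": "increase",
    "HSW": "increase",
    "GMC": "decrease",
    "PH": "decrease",
    "EH": "decrease",
    "BTL": "decrease",
}

#: Default grand means for the nine traits (units: GY Mg ha-1, GMC %,
#: PH/EH/EL/BTL cm, ER rows, GWE g, HSW g). Values are field-realistic for
#: modern temperate hybrids.
DEFAULT_GRAND_MEANS: dict[str, float] = {
    "BTL": 1.2,
    "EH": 105.0,
    "EL": 17.5,
    "ER": 15.0,
    "GMC": 25.0,
    "GWE": 180.0,
    "GY": 11.0,
    "HSW": 32.0,
    "PH": 260.0,
}

#: Default variance components per trait for the random-effects generator,
#: keyed trait -> {term -> variance}. These are typical magnitudes for a
#: maize MET with a dominant replicate(location x block) and residual
#: variance and a non-trivial three-way interaction.
DEFAULT_VARIANCE_COMPONENTS: dict[str, dict[str, float]] = {
    "BTL": {"G": 0.050, "M": 0.000, "Y": 0.000, "GM": 0.048, "GY": 0.000,
            "MY": 0.000, "GMY": 0.353, "REP": 0.135, "residual": 0.472},
    "EH": {"G": 50.028, "M": 0.000, "Y": 27.351, "GM": 0.000, "GY": 4.622,
           "MY": 30.248, "GMY": 59.987, "REP": 98.436, "residual": 126.749},
    "EL": {"G": 0.211, "M": 0.053, "Y": 0.083, "GM": 0.219, "GY": 0.000,
           "MY": 0.000, "GMY": 0.311, "REP": 0.657, "residual": 1.337},
    "ER": {"G": 0.859, "M": 0.000, "Y": 0.016, "GM": 0.078, "GY": 0.000,
           "MY": 0.000, "GMY": 0.484, "REP": 0.138, "residual": 1.194},
    "GMC": {"G": 1.357, "M": 0.000, "Y": 9.488, "GM": 0.000, "GY": 0.000,
            "MY": 2.738, "GMY": 1.011, "REP": 4.033, "residual": 9.136},
    "GWE": {"G": 39.221, "M": 104.484, "Y": 55.866, "GM": 26.481,
            "GY": 10.899, "MY": 0.000, "GMY": 77.715, "REP": 300.744,
            "residual": 464.349},
    "GY": {"G": 0.038, "M": 0.000, "Y": 0.000, "GM": 0.059, "GY": 0.000,
           "MY": 0.453, "GMY": 0.355, "REP": 1.521, "residual": 1.185},
    "HSW": {"G": 1.770, "M": 0.000, "Y": 0.000, "GM": 0.250, "GY": 0.000,
            "MY": 0.000, "GMY": 0.852, "REP": 12.844, "residual": 9.817},
    "PH": {"G": 199.780, "M": 96.522, "Y": 31.061, "GM": 0.000, "GY": 4.833,
           "MY": 11.210, "GMY": 128.617, "REP": 108.140, "residual": 274.329},
}


@dataclass
class WeatherArchetype:
    """Seasonal climate parameters shared by all locations of one archetype.

    The daily generator draws, for each location-year, a seasonal sinusoid
    (peaking mid July) plus AR(1) noise for temperature, and archetype-level
    parameters for humidity, rainfall, wind and radiation. Offsets between
    archetypes are constant in expectation, so locations sharing an archetype
    are closer in descriptor space than locations in different archetypes.
    """

    latitude: float = 36.0
    longitude: float = 115.0
    elevation: float = 50.0
    tmean_base: float = 20.0        # deg C, annual mean level of Tmean
    tmean_amplitude: float = 8.0    # deg C, seasonal half-range
    trange: float = 9.0             # deg C, mean diurnal Tmax - Tmin
    tdew_depression: float = 4.0    # deg C, mean Tmean - Tdew (>= 0)
    precip_mean: float = 3.5        # mm day-1 long-run mean
    precip_wet_prob: float = 0.35   # fraction of wet days
    wind_mean: float = 2.0          # m s-1
    clearness: float = 0.55         # SIHS / extraterrestrial radiation
    dtirf_base: float = 28.0        # MJ m-2 day-1 longwave at Tmean = 20
    noise_sd: float = 1.5           # deg C daily AR(1) noise on temperature
    ar1_rho: float = 0.6            # daily autocorrelation of the noise


def default_archetypes() -> dict[str, WeatherArchetype]:
    """Four contrasting archetypes: wet-warm, hot, dry-continental, cool."""
    return {
        "A": WeatherArchetype(latitude=31.5, tmean_base=23.0, tmean_amplitude=7.0,
                              trange=8.0, tdew_depression=2.5, precip_mean=5.5,
                              precip_wet_prob=0.45, clearness=0.45),
        "B": WeatherArchetype(latitude=33.5, tmean_base=22.0, tmean_amplitude=8.0,
                              trange=9.0, tdew_depression=3.5, precip_mean=4.0,
                              dtirf_base=30.0),
        "C": WeatherArchetype(latitude=37.0, tmean_base=20.0, tmean_amplitude=9.0,
                              trange=11.5, tdew_depression=6.5, precip_mean=2.5,
                              precip_wet_prob=0.28, clearness=0.62),
        "D": WeatherArchetype(latitude=37.5, elevation=120.0, tmean_base=17.5,
                              tmean_amplitude=9.0, trange=9.5,
                              tdew_depression=4.5, precip_mean=3.0),
    }


def default_location_archetypes(n_locations: int = 10) -> dict[str, str]:
    """Map generic location ids to the four default archetypes (1/3/4/2)."""
    pattern = ["A"] + ["B"] * 3 + ["C"] * 4 + ["D"] * 2
    ids = [f"L{i + 1:02d}" for i in range(n_locations)]
    return {loc: pattern[i % len(pattern)] for i, loc in enumerate(ids)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic weather archive and trial generator."""

    n_genotypes: int = 26
    n_locations: int = 10
    n_years: int = 2
    n_blocks: int = 3
    first_year: int = 2019
    me_archetypes: dict[str, str] = field(default_factory=default_location_archetypes)
    archetypes: dict[str, WeatherArchetype] = field(default_factory=default_archetypes)
    variance_components: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_VARIANCE_COMPONENTS.items()}
    )
    grand_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GRAND_MEANS))
    rng_seed: int = 42
    #: historical span (years) of the weather archive used for delineation
    n_weather_years: int = 20
    weather_first_year: int = 2001
    #: May 1 .. Oct 31 growing-season window (month numbers)
    season_months: tuple[int, int] = (5, 10)
    sowing_month_day: tuple[int, int] = (6, 1)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def traits(self) -> list[str]:
        return sorted(self.grand_means)

    @property
    def locations(self) -> list[str]:
        return sorted(self.me_archetypes)

    @property
    def years(self) -> list[int]:
        return [self.first_year + i for i in range(self.n_years)]

    def validate(self) -> None:
        if self.n_locations <= 0:
            raise ValueError("n_locations must be positive")
        if self.n_genotypes <= 0:
            raise ValueError("n_genotypes must be positive")
        if self.n_years <= 0:
            raise ValueError("n_years must be positive")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2 (replication required)")
        if not self.grand_means:
            raise ValueError("trait list (grand_means) must be non-empty")
        if len(self.me_archetypes) != self.n_locations:
            raise ValueError(
                f"me_archetypes maps {len(self.me_archetypes)} locations, "
                f"expected n_locations={self.n_locations}"
            )
        for loc, arch in self.me_archetypes.items():
            if arch not in self.archetypes:
                raise ValueError(f"location {loc!r} maps to unknown archetype {arch!r}")
        for trait, comps in self.variance_components.items():
            for term, var in comps.items():
                if term not in VARIANCE_TERMS:
                    raise ValueError(f"unknown variance term {term!r} for trait {trait!r}")
                if var < 0:
                    raise ValueError(
                        f"negative variance for term {term!r} of trait {trait!r}: {var}"
                    )


@dataclass
class AnalysisConfig:
    """Knobs of the analysis chain (delineation through selection)."""

    k_clusters: int = 4
    quantiles: tuple[float, ...] = (0.01, 0.25, 0.50, 0.75, 0.975, 0.99)
    #: crop stages as DAS (days-after-sowing) windows, inclusive bounds
    stages: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "initial": (0, 14),
        "leaf_expansion_1": (15, 35),
        "leaf_expansion_2": (36, 65),
        "flowering": (66, 90),
        "grain_filling": (91, 120),
    })
    theta_y: float = 70.0
    theta_s: float = 30.0
    intensity: float = 0.23
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    etp_method: str = "priestley_taylor"
    cardinal_temps: tuple[float, float, float, float] = (9.0, 26.0, 32.0, 45.0)
    tbase: float = 8.0
    qc_sd: float = 3.0
    lrt_distribution: str = "chi2"      # or "mixture" (50:50 chi2_0 : chi2_1)
    run_lrt: bool = True


@dataclass
class RunConfig:
    """Top-level run configuration (YAML-serializable)."""

    outdir: str = "enviromets_out"
    weather_path: str | None = None
    phenotype_path: str | None = None
    simulate: bool = True
    seed: int = 42
    log_level: str = "INFO"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.analysis.intensity <= 1:
            raise ValueError("selection intensity must be in (0, 1]")
        if self.analysis.theta_y + self.analysis.theta_s <= 0:
            raise ValueError("theta_y + theta_s must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        ana = raw.pop("analysis", {})
        sim = raw.pop("simulation", {})
        if "stages" in ana:
            ana["stages"] = {k: tuple(v) for k, v in ana["stages"].items()}
        if "cardinal_temps" in ana:
            ana["cardinal_temps"] = tuple(ana["cardinal_temps"])
        if "quantiles" in ana:
            ana["quantiles"] = tuple(ana["quantiles"])
        if "archetypes" in sim:
            sim["archetypes"] = {
                k: WeatherArchetype(**v) for k, v in sim["archetypes"].items()
            }
        for key in ("season_months", "sowing_month_day"):
            if key in sim:
                sim[key] = tuple(sim[key])
        return cls(
            analysis=AnalysisConfig(**ana),
            simulation=SimulationConfig(**sim),
            **raw,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
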
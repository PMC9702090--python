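"""Environmental covariables, envirotype matrix, enviromic kernel and
mega-environment delineation.

A raw daily weather series (9 measured variables) is expanded into 19
environmental covariables: the raw variables plus thermal, water-demand and
solar-geometry descriptors (temperature range, reference evapotranspiration,
precipitation deficit, vapor pressure deficit, slope of the saturation
vapor-pressure curve, a cardinal-temperature radiation-use-efficiency factor,
growing degree-days, actual/potential sunshine hours and extraterrestrial
radiation). Per environment, covariables are aggregated into monthly windows
of the growing season over a span of years, forming the envirotype matrix W
(environments x descriptors). The enviromic kernel

    K_E = W W' / (trace(W W') / n_environments)

is a normalized similarity among environments (trace(K_E) equals the number
of environments), and mega-environments are groups obtained by average-
linkage (UPGMA) clustering of the kernel-induced distance
d(i, j) = sqrt(K_ii + K_jj - 2 K_ij).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

RAW_VARIABLES = (
    "T2M", "T2M_MAX", "T2M_MIN", "T2MDEW", "RH2M",
    "PRECTOT", "WS2M", "SIHS", "DTIRF",
)

DERIVED_VARIABLES = (
    "TRANGE", "ETP", "PETP", "VPD", "SVP", "FRUE", "GDD", "n", "N", "RTA",
)

COVARIABLES = RAW_VARIABLES + DERIVED_VARIABLES

#: flux / accumulation covariables aggregated by window sums; the remaining
#: (state) covariables are aggregated by window means
SUM_VARIABLES = frozenset({"PRECTOT", "ETP", "PETP", "GDD", "n", "N", "RTA"})

SOLAR_CONSTANT = 0.0820          # MJ m-2 min-1
LATENT_HEAT = 2.45               # MJ kg-1, vaporization of water
STEFAN_BOLTZMANN = 4.903e-9      # MJ K-4 m-2 day-1
ALBEDO = 0.23                    # reference grass surface


@dataclass
class WeatherSeries:
    """Daily raw meteorological records for one location.

    ``data`` holds one row per day with the columns of :data:`RAW_VARIABLES`
    plus a ``date`` column (datetime64). Temperatures in deg C, RH in %,
    precipitation in mm day-1, wind at 2 m in m s-1, shortwave insolation and
    downward longwave flux in MJ m-2 day-1.
    """

    location: str
    latitude: float
    longitude: float
    elevation: float
    data: pd.DataFrame

    def validate(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        df = self.data
        missing = [c for c in ("date",) + RAW_VARIABLES if c not in df.columns]
        if missing:
            raise ValueError(f"weather series {self.location}: missing columns {missing}")
        bad = df["T2M_MIN"] > df["T2M_MAX"]
        if bad.any():
            raise ValueError(
                f"weather series {self.location}: Tmin > Tmax on "
                f"{df.loc[bad, 'date'].iloc[0].date()}"
            )
        rh = df["RH2M"]
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError(f"weather series {self.location}: RH2M outside [0, 100]")
        if (df["PRECTOT"] < 0).any():
            raise ValueError(f"weather series {self.location}: negative precipitation")

    def year_gaps(self) -> dict[int, list[pd.Timestamp]]:
        """Missing calendar days within each year's covered date span."""
        gaps: dict[int, list[pd.Timestamp]] = {}
        dates = pd.DatetimeIndex(self.data["date"])
        for year, idx in dates.groupby(dates.year).items():
            idx = pd.DatetimeIndex(sorted(idx))
            full = pd.date_range(idx[0], idx[-1], freq="D")
            miss = full.difference(idx)
            if len(miss):
                gaps[year] = list(miss)
        return gaps


@dataclass
class CovariableParams:
    """Parameters of the derived covariables.

    ``tbase`` (deg C) is the growing-degree-day base; ``cardinal_temps`` are
    (Tb, Topt1, Topt2, Tceil) of the piecewise-linear temperature effect on
    radiation-use efficiency; ``angstrom_a/b`` invert the Angstrom equation
    for actual sunshine hours; ``etp_method`` is ``"priestley_taylor"``
    (alpha = 1.26) or ``"penman_monteith"`` (FAO-56 reference crop).
    """

    tbase: float = 8.0
    cardinal_temps: tuple[float, float, float, float] = (9.0, 26.0, 32.0, 45.0)
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    etp_method: str = "priestley_taylor"
    priestley_taylor_alpha: float = 1.26


def saturation_vapor_pressure(t: np.ndarray | float) -> np.ndarray | float:
    """Tetens saturation vapor pressure e_s(T) in kPa for T in deg C."""
    t = np.asarray(t, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def svp_slope(t: np.ndarray | float) -> np.ndarray | float:
    """Slope of the saturation vapor-pressure curve (kPa per deg C)."""
    t = np.asarray(t, dtype=float)
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def solar_geometry(latitude: float, doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extraterrestrial radiation (MJ m-2 day-1) and daylight hours.

    Standard daily solar geometry: inverse relative Earth-Sun distance,
    solar declination, and sunset hour angle from latitude and day of year.
    """
    phi = np.deg2rad(latitude)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    rta = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    daylight = 24.0 / np.pi * ws
    return rta, daylight


def frue(tmean: np.ndarray, cardinal: tuple[float, float, float, float]) -> np.ndarray:
    """Piecewise-linear temperature effect on radiation-use efficiency.

    0 below Tb and above Tceil, 1 on the optimal plateau [Topt1, Topt2],
    linear in between.
    """
    tb, topt1, topt2, tceil = cardinal
    t = np.asarray(tmean, dtype=float)
    up = (t - tb) / (topt1 - tb)
    down = (tceil - t) / (tceil - topt2)
    return np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, 1.0)


def _net_radiation(series: WeatherSeries, rta: np.ndarray, ea: np.ndarray) -> np.ndarray:
    """Daily net radiation (MJ m-2 day-1) from shortwave balance and the
    FAO-56 net-outgoing-longwave estimate."""
    df = series.data
    rs = df["SIHS"].to_numpy(float)
    rso = (0.75 + 2e-5 * series.elevation) * rta
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, rs / rso, 1.0)
    rel = np.clip(rel, 0.3, 1.0)
    tmax_k4 = (df["T2M_MAX"].to_numpy(float) + 273.16) ** 4
    tmin_k4 = (df["T2M_MIN"].to_numpy(float) + 273.16) ** 4
    rnl = (STEFAN_BOLTZMANN * 0.5 * (tmax_k4 + tmin_k4)
           * (0.34 - 0.14 * np.sqrt(np.clip(ea, 0.0, None)))
           * (1.35 * rel - 0.35))
    return (1.0 - ALBEDO) * rs - rnl


def _psychrometric_constant(elevation: float) -> float:
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    return 0.665e-3 * pressure


def reference_et(series: WeatherSeries, params: CovariableParams,
                 rta: np.ndarray, ea: np.ndarray, es_mean: np.ndarray,
                 delta: np.ndarray) -> np.ndarray:
    """Daily reference evapotranspiration (mm day-1), floored at 0."""
    df = series.data
    gamma = _psychrometric_constant(series.elevation)
    rn = _net_radiation(series, rta, ea)
    if params.etp_method == "priestley_taylor":
        etp = params.priestley_taylor_alpha * delta / (delta + gamma) * rn / LATENT_HEAT
    elif params.etp_method == "penman_monteith":
        t = df["T2M"].to_numpy(float)
        u2 = df["WS2M"].to_numpy(float)
        etp = (0.408 * delta * rn
               + gamma * 900.0 / (t + 273.0) * u2 * (es_mean - ea)) / (
            delta + gamma * (1.0 + 0.34 * u2))
    else:
        raise ValueError(f"unknown etp_method {params.etp_method!r}")
    return np.clip(etp, 0.0, None)


def derive_covariables(series: WeatherSeries,
                       params: CovariableParams | None = None) -> pd.DataFrame:
    """Expand a raw weather series into the full 19-covariable daily table.

    Returns a DataFrame with ``date`` plus all :data:`COVARIABLES` columns.
    Raises if the series fails its physical invariants or has missing days
    within a year.
    """
    params = params or CovariableParams()
    series.validate()
    gaps = series.year_gaps()
    if gaps:
        year, days = next(iter(gaps.items()))
        raise ValueError(
            f"weather series {series.location}: missing day(s) in {year}, "
            f"first gap {days[0].date()}"
        )
    df = series.data.sort_values("date").reset_index(drop=True)
    out = df[["date", *RAW_VARIABLES]].copy()

    tmax = df["T2M_MAX"].to_numpy(float)
    tmin = df["T2M_MIN"].to_numpy(float)
    tmean = df["T2M"].to_numpy(float)
    tdew = df["T2MDEW"].to_numpy(float)
    doy = pd.DatetimeIndex(df["date"]).dayofyear.to_numpy()

    out["TRANGE"] = tmax - tmin
    ea = saturation_vapor_pressure(tdew)
    es_mean = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))
    out["VPD"] = np.clip(es_mean - ea, 0.0, None)
    delta = svp_slope(tmean)
    out["SVP"] = delta
    rta, daylight = solar_geometry(series.latitude, doy)
    out["RTA"] = rta
    out["N"] = daylight
    rs = df["SIHS"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(rta > 0, rs / rta, 0.0)
    out["n"] = np.clip((frac - params.angstrom_a) / params.angstrom_b, 0.0, 1.0) * daylight
    etp = reference_et(series, params, rta, ea, es_mean, delta)
    out["ETP"] = etp
    out["PETP"] = df["PRECTOT"].to_numpy(float) - etp
    out["GDD"] = np.clip(0.5 * (tmax + tmin) - params.tbase, 0.0, None)
    out["FRUE"] = frue(tmean, params.cardinal_temps)
    return out


@dataclass
class EnvirotypeMatrix:
    """Standardized environment x descriptor matrix W with QC metadata.

    ``values`` rows are environments; columns are keyed ``{year}_{cov}_{mm}``
    (year, covariable, month window). ``col_means``/``col_sds`` hold the
    pre-standardization parameters; ``dropped`` lists QC-removed columns.
    """

    values: pd.DataFrame
    col_means: pd.Series
    col_sds: pd.Series
    dropped: list[str] = field(default_factory=list)
    qc_sd: float = 3.0

    @property
    def environments(self) -> list[str]:
        return list(self.values.index)


def build_w_matrix(covariables: Mapping[str, pd.DataFrame],
                   years: Sequence[int] | None = None,
                   months: Sequence[int] = (5, 6, 7, 8, 9, 10),
                   qc_sd: float = 3.0,
                   variables: Sequence[str] = COVARIABLES) -> EnvirotypeMatrix:
    """Assemble the envirotype matrix W from per-environment covariable tables.

    Each column is one (year, covariable, month) window aggregate — mean for
    state variables, sum for flux/accumulation variables. Columns are
    standardized across environments (population SD); any column with a
    standardized cell beyond ``+-qc_sd`` is removed and logged.
    """
    if len(covariables) < 2:
        raise ValueError("at least 2 environments required to build W")
    rows = {}
    for env, df in covariables.items():
        dates = pd.DatetimeIndex(df["date"])
        sub = df.assign(_year=dates.year, _month=dates.month)
        sub = sub[sub["_month"].isin(list(months))]
        if years is not None:
            sub = sub[sub["_year"].isin(list(years))]
        agg = {c: ("sum" if c in SUM_VARIABLES else "mean") for c in variables}
        g = sub.groupby(["_year", "_month"]).agg(agg)
        rec = {}
        for (year, month), r in g.iterrows():
            for cov in variables:
                rec[f"{year}_{cov}_{month:02d}"] = r[cov]
        rows[env] = rec
    w = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    if years is not None:
        expect = len(list(years)) * len(list(variables)) * len(list(months))
        if w.shape[1] != expect or w.isna().any().any():
            raise ValueError(
                f"incomplete coverage: got {w.shape[1]} columns "
                f"({int(w.isna().any().sum())} with gaps), expected {expect}"
            )
    means = w.mean(axis=0)
    sds = w.std(axis=0, ddof=0)
    keep_scale = sds > 0
    z = (w - means) / sds.where(keep_scale, 1.0)
    z.loc[:, ~keep_scale] = 0.0
    outlier_cols = z.columns[(z.abs() > qc_sd).any(axis=0)]
    if len(outlier_cols):
        log.info("QC removed %d descriptor column(s) beyond +-%gSD: %s",
                 len(outlier_cols), qc_sd, list(outlier_cols[:10]))
    z = z.drop(columns=outlier_cols)
    return EnvirotypeMatrix(values=z, col_means=means.drop(index=outlier_cols),
                            col_sds=sds.drop(index=outlier_cols),
                            dropped=list(outlier_cols), qc_sd=qc_sd)


@dataclass
class EnviromicKernel:
    """Normalized environment-similarity kernel K_E."""

    values: pd.DataFrame
    normalization: float

    @property
    def environments(self) -> list[str]:
        return list(self.values.index)


def enviromic_kernel(w: EnvirotypeMatrix | pd.DataFrame) -> EnviromicKernel:
    """K_E = W W' / (trace(W W') / n_environments); trace(K_E) = n."""
    values = w.values if isinstance(w, EnvirotypeMatrix) else w
    mat = np.asarray(values, dtype=float)
    ww = mat @ mat.T
    tr = np.trace(ww)
    if tr <= 0:
        raise ValueError("W is all-zero: kernel normalization undefined")
    norm = tr / mat.shape[0]
    k = ww / norm
    k = 0.5 * (k + k.T)  # guard symmetry against rounding
    return EnviromicKernel(
        values=pd.DataFrame(k, index=values.index, columns=values.index),
        normalization=norm,
    )


@dataclass
class MEAssignment:
    """Partition of environments into mega-environments."""

    labels: dict[str, str]
    linkage: np.ndarray
    k: int

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for env, me in self.labels.items():
            out.setdefault(me, []).append(env)
        return {me: sorted(envs) for me, envs in sorted(out.items())}


def kernel_distance(kernel: EnviromicKernel) -> pd.DataFrame:
    """Kernel-induced Euclidean distance d(i,j) = sqrt(Kii + Kjj - 2Kij)."""
    k = kernel.values.to_numpy(float)
    diag = np.diag(k)
    d2 = np.clip(diag[:, None] + diag[None, :] - 2.0 * k, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    return pd.DataFrame(np.sqrt(d2), index=kernel.values.index,
                        columns=kernel.values.columns)


def delineate_mega_environments(kernel: EnviromicKernel, k: int = 4) -> MEAssignment:
    """Cut an average-linkage (UPGMA) tree of the kernel distance into k MEs.

    Labels are ``ME1..MEk``, numbered by the alphabetically first member of
    each cluster so that the labeling is invariant to input ordering.
    """
    n = len(kernel.environments)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    dist = kernel_distance(kernel)
    order = np.argsort(np.asarray(kernel.environments, dtype=object))
    envs = [kernel.environments[i] for i in order]
    dmat = dist.to_numpy(float)[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(dmat, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # relabel clusters ME1..MEk in order of each cluster's first (sorted) member
    first_member: dict[int, str] = {}
    for env, c in zip(envs, raw):
        first_member.setdefault(int(c), env)
    ordered = sorted(first_member, key=lambda c: first_member[c])
    rename = {c: f"ME{i + 1}" for i, c in enumerate(ordered)}
    labels = {env: rename[int(c)] for env, c in zip(envs, raw)}
    return MEAssignment(labels=labels, linkage=z, k=k)


def env_typing(covariables: Mapping[tuple[str, int], pd.DataFrame],
               assignment: MEAssignment | Mapping[str, str],
               stages: Mapping[str, tuple[int, int]],
               quantiles: Sequence[float] = (0.01, 0.25, 0.50, 0.75, 0.975, 0.99),
               variables: Sequence[str] = COVARIABLES) -> pd.DataFrame:
    """Quantile typology of trial weather per (ME, year, crop stage).

    ``covariables`` maps (location, year) trial keys to daily covariable
    tables carrying a ``das`` (days after sowing) column. Class breakpoints
    are the global quantiles of each covariable across all trial days; the
    output is a long table of relative day frequencies per
    (ME, year, stage, covariable, class), summing to 1 within each group.
    """
    labels = assignment.labels if isinstance(assignment, MEAssignment) else dict(assignment)
    frames = []
    for (loc, year), df in covariables.items():
        if "das" not in df.columns:
            raise ValueError(f"trial ({loc}, {year}): covariable table lacks 'das'")
        sub = df.copy()
        sub["ME"] = labels[loc]
        sub["year"] = year
        frames.append(sub)
    allday = pd.concat(frames, ignore_index=True)

    def stage_of(das: int) -> str | None:
        for name, (lo, hi) in stages.items():
            if lo <= das <= hi:
                return name
        return None

    allday["stage"] = allday["das"].map(stage_of)
    allday = allday[allday["stage"].notna()]

    qs = sorted(quantiles)
    records = []
    for cov in variables:
        vals = allday[cov].to_numpy(float)
        breaks = np.unique(np.quantile(vals, qs))
        edges = np.concatenate([[-np.inf], breaks, [np.inf]])
        classes = pd.cut(allday[cov], bins=edges, duplicates="drop")
        grouped = (allday.assign(_cls=classes)
                   .groupby(["ME", "year", "stage", "_cls"], observed=True)
                   .size())
        totals = grouped.groupby(["ME", "year", "stage"]).transform("sum")
        freq = grouped / totals
        for (me, year, stage, cls), f in freq.items():
            records.append({"ME": me, "year": year, "stage": stage,
                            "covariable": cov, "class": str(cls),
                            "frequency": float(f),
                            "n_days": int(grouped.loc[(me, year, stage, cls)])})
    typ = pd.DataFrame.from_records(records)
    empty = typ["frequency"].isna()
    if empty.any():
        log.info("typology: %d empty (ME, year, stage) cells omitted", int(empty.sum()))
        typ = typ[~empty]
    return typ.reset_index(drop=True)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    dropped: list[str]


def environment_pca(table: pd.DataFrame) -> PCAResult:
    """PCA of the environment x mean-covariable table on the correlation scale.

    Constant columns are dropped (logged); remaining columns are standardized
    and the correlation matrix eigendecomposed. Scores are environment
    coordinates, loadings are variable coordinates.
    """
    if table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 environments")
    sds = table.std(axis=0, ddof=1)
    dropped = list(table.columns[sds == 0])
    if dropped:
        log.info("PCA dropped constant column(s): %s", dropped)
    x = table.drop(columns=dropped)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = np.corrcoef(x.to_numpy(float), rowvar=False)
    r = np.atleast_2d(r)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    ncomp = min(x.shape[0] - 1, x.shape[1])
    evals = evals[:ncomp]
    evecs = evecs[:, :ncomp]
    # sign convention: largest-magnitude loading of each component positive
    signs = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(ncomp)])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    scores = z.to_numpy(float) @ evecs
    comp = [f"PC{i + 1}" for i in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        loadings=pd.DataFrame(evecs * np.sqrt(evals), index=x.columns, columns=comp),
        eigenvalues=evals,
        explained_variance_ratio=evals / np.trace(r),
        dropped=dropped,
    )
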
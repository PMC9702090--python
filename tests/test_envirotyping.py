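"""Covariable formulas, W matrix, enviromic kernel, delineation, typology
and PCA, each checked against independent oracles or closed forms."""

import math

import numpy as np
import pandas as pd
import pytest

from enviromets.config import SimulationConfig, WeatherArchetype
from enviromets.envirotyping import (
    COVARIABLES,
    CovariableParams,
    EnviromicKernel,
    WeatherSeries,
    build_w_matrix,
    delineate_mega_environments,
    derive_covariables,
    enviromic_kernel,
    env_typing,
    environment_pca,
    kernel_distance,
    svp_slope,
)
from enviromets.synthetic import simulate_weather

from conftest import small_archetypes


def make_series(n_days=30, latitude=35.0, seed=0, year=2019, **overrides):
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{year}-06-01", periods=n_days, freq="D")
    tmean = 22 + 4 * rng.standard_normal(n_days)
    trange = np.abs(6 + 2 * rng.standard_normal(n_days)) + 0.5
    data = pd.DataFrame({
        "date": dates,
        "T2M": tmean,
        "T2M_MAX": tmean + trange / 2,
        "T2M_MIN": tmean - trange / 2,
        "T2MDEW": tmean - np.abs(3 + rng.standard_normal(n_days)),
        "RH2M": np.clip(70 + 10 * rng.standard_normal(n_days), 0, 100),
        "PRECTOT": np.clip(rng.exponential(3, n_days) - 1, 0, None),
        "WS2M": np.abs(2 + rng.standard_normal(n_days)),
        "SIHS": np.clip(18 + 4 * rng.standard_normal(n_days), 1, None),
        "DTIRF": 28 + rng.standard_normal(n_days),
    })
    for col, val in overrides.items():
        data[col] = val
    return WeatherSeries(location="X", latitude=latitude, longitude=110.0,
                         elevation=50.0, data=data)


class TestCovariables:
    def test_gdd_zero_when_temps_at_base(self):
        s = make_series(T2M=8.0, T2M_MAX=8.0, T2M_MIN=8.0, T2MDEW=5.0)
        out = derive_covariables(s, CovariableParams(tbase=8.0))
        assert (out["GDD"] == 0).all()

    def test_vpd_zero_when_dew_equals_temperature(self):
        s = make_series(T2M=20.0, T2M_MAX=20.0, T2M_MIN=20.0, T2MDEW=20.0)
        out = derive_covariables(s)
        assert np.allclose(out["VPD"], 0.0, atol=1e-12)

    def test_svp_slope_at_20C(self):
        # independent evaluation of the closed form at Tmean = 20 C
        assert svp_slope(20.0) == pytest.approx(0.145, abs=5e-4)

    def test_equator_daylight_is_12h(self):
        out = derive_covariables(make_series(latitude=0.0))
        assert np.allclose(out["N"], 12.0, atol=0.05)

    def test_physical_invariants(self):
        out = derive_covariables(make_series(n_days=200, seed=3))
        assert (out["GDD"] >= 0).all()
        assert out["FRUE"].between(0, 1).all()
        assert out["N"].between(0, 24).all()
        assert (out["RTA"] >= 0).all()
        assert (out["ETP"] >= 0).all()
        assert (out["VPD"] >= 0).all()

    def test_missing_day_rejected_with_gap_named(self):
        s = make_series(n_days=10)
        s.data = s.data.drop(index=4)
        with pytest.raises(ValueError, match="2019-06-05"):
            derive_covariables(s)

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            derive_covariables(make_series(latitude=95.0))

    @pytest.mark.parametrize("etp_method", ["priestley_taylor", "penman_monteith"])
    def test_straight_line_oracle(self, etp_method):
        """Independent scalar re-evaluation of every covariable formula on
        100 random days (1e-9)."""
        s = make_series(n_days=100, seed=42, latitude=33.0)
        params = CovariableParams(etp_method=etp_method)
        out = derive_covariables(s, params)
        phi = math.radians(s.latitude)
        gamma = 0.665e-3 * 101.3 * ((293 - 0.0065 * s.elevation) / 293) ** 5.26

        def es(t):
            return 0.6108 * math.exp(17.27 * t / (t + 237.3))

        for i, row in s.data.iterrows():
            tmax, tmin, tmean, tdew = (row["T2M_MAX"], row["T2M_MIN"],
                                       row["T2M"], row["T2MDEW"])
            doy = row["date"].timetuple().tm_yday
            assert out.loc[i, "TRANGE"] == pytest.approx(tmax - tmin, abs=1e-9)
            ea = es(tdew)
            vpd = max((es(tmax) + es(tmin)) / 2 - ea, 0.0)
            assert out.loc[i, "VPD"] == pytest.approx(vpd, abs=1e-9)
            delta = 4098 * es(tmean) / (tmean + 237.3) ** 2
            assert out.loc[i, "SVP"] == pytest.approx(delta, abs=1e-9)
            dr = 1 + 0.033 * math.cos(2 * math.pi * doy / 365)
            dec = 0.409 * math.sin(2 * math.pi * doy / 365 - 1.39)
            ws = math.acos(max(-1, min(1, -math.tan(phi) * math.tan(dec))))
            rta = (24 * 60 / math.pi) * 0.0820 * dr * (
                ws * math.sin(phi) * math.sin(dec)
                + math.cos(phi) * math.cos(dec) * math.sin(ws))
            assert out.loc[i, "RTA"] == pytest.approx(rta, abs=1e-9)
            nn = 24 / math.pi * ws
            assert out.loc[i, "N"] == pytest.approx(nn, abs=1e-9)
            sun = min(max((row["SIHS"] / rta - 0.25) / 0.50, 0.0), 1.0) * nn
            assert out.loc[i, "n"] == pytest.approx(sun, abs=1e-9)
            gdd = max(0.0, (tmax + tmin) / 2 - params.tbase)
            assert out.loc[i, "GDD"] == pytest.approx(gdd, abs=1e-9)
            tb, t1, t2, tc = params.cardinal_temps
            fr = min(1.0, max(0.0, min((tmean - tb) / (t1 - tb),
                                       (tc - tmean) / (tc - t2))))
            assert out.loc[i, "FRUE"] == pytest.approx(fr, abs=1e-9)
            # net radiation + reference ET
            rso = (0.75 + 2e-5 * s.elevation) * rta
            rel = min(max(row["SIHS"] / rso, 0.3), 1.0)
            rnl = (4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
                   * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * rel - 0.35))
            rn = 0.77 * row["SIHS"] - rnl
            if etp_method == "priestley_taylor":
                etp = max(0.0, 1.26 * delta / (delta + gamma) * rn / 2.45)
            else:
                u2 = row["WS2M"]
                esm = (es(tmax) + es(tmin)) / 2
                etp = max(0.0, (0.408 * delta * rn + gamma * 900 / (tmean + 273)
                                * u2 * (esm - ea))
                          / (delta + gamma * (1 + 0.34 * u2)))
            assert out.loc[i, "ETP"] == pytest.approx(etp, abs=1e-9)
            assert out.loc[i, "PETP"] == pytest.approx(
                row["PRECTOT"] - etp, abs=1e-9)


class TestWMatrix:
    def test_full_archive_descriptor_count(self):
        """10 locations x 20 years x 19 covariables x 6 monthly windows ->
        2,280 descriptor columns before QC."""
        cfg = SimulationConfig(rng_seed=2)
        wx = simulate_weather(cfg)
        cov = {loc: derive_covariables(s) for loc, s in wx.items()}
        years = range(cfg.weather_first_year,
                      cfg.weather_first_year + cfg.n_weather_years)
        w = build_w_matrix(cov, years=years)
        assert w.values.shape == (10, 20 * 19 * 6 - len(w.dropped))
        assert len(w.dropped) + w.values.shape[1] == 2280

    def test_one_year_one_covariable_six_windows(self, small_config):
        wx = simulate_weather(small_config, years=[2019])
        cov = {loc: derive_covariables(s) for loc, s in wx.items()}
        w = build_w_matrix(cov, years=[2019], variables=["GDD"], qc_sd=99.0)
        assert w.values.shape[1] == 6

    def test_standardized_columns(self, small_config):
        wx = simulate_weather(small_config, years=[2019])
        cov = {loc: derive_covariables(s) for loc, s in wx.items()}
        w = build_w_matrix(cov, years=[2019])
        vals = w.values.to_numpy()
        assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(vals.std(axis=0), 1.0, atol=1e-12)

    def test_qc_removes_outlier_column(self):
        # 20 synthetic environments, one column with a single z=4 outlier
        rng = np.random.default_rng(1)
        n = 20
        frames = {}
        base = pd.date_range("2019-05-01", "2019-10-31", freq="D")
        for i in range(n):
            df = pd.DataFrame({"date": base})
            for cov in COVARIABLES:
                df[cov] = 10 + rng.standard_normal(len(base))
            frames[f"E{i:02d}"] = df
        clean = build_w_matrix(frames, years=[2019], qc_sd=3.0)
        assert "2019_T2M_07" not in clean.dropped
        # plant an outlier in a single (env, month) window of one covariable;
        # a 7-SD shift of one of 20 cells lands near z = 3.6 after the shift
        # itself inflates the column SD
        target = frames["E00"]
        month_mask = pd.DatetimeIndex(target["date"]).month == 7
        orig = pd.Series({e: f.loc[pd.DatetimeIndex(f["date"]).month == 7,
                                   "T2M"].mean() for e, f in frames.items()})
        osd = orig.std(ddof=0)
        target.loc[month_mask, "T2M"] += 7.0 * osd
        dirty = build_w_matrix(frames, years=[2019], qc_sd=3.0)
        assert dirty.values.shape[1] == clean.values.shape[1] - 1
        assert "2019_T2M_07" in dirty.dropped

    def test_single_environment_rejected(self):
        base = pd.date_range("2019-05-01", "2019-05-31", freq="D")
        df = pd.DataFrame({"date": base, **{c: 1.0 for c in COVARIABLES}})
        with pytest.raises(ValueError):
            build_w_matrix({"only": df})


class TestKernel:
    def test_identity_w_gives_identity_kernel(self):
        w = pd.DataFrame(np.eye(2), index=["E1", "E2"])
        k = enviromic_kernel(w)
        # WW' = I, trace 2, divisor 1 -> K = I
        assert np.allclose(k.values.to_numpy(), np.eye(2))

    def test_trace_symmetry_psd(self, rng):
        w = pd.DataFrame(rng.standard_normal((8, 30)),
                         index=[f"E{i}" for i in range(8)])
        k = enviromic_kernel(w)
        m = k.values.to_numpy()
        assert np.trace(m) == pytest.approx(8.0, abs=1e-9)
        assert np.abs(m - m.T).max() == 0.0
        assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_all_zero_rejected(self):
        w = pd.DataFrame(np.zeros((3, 5)), index=list("abc"))
        with pytest.raises(ValueError):
            enviromic_kernel(w)


class TestDelineation:
    def _kernel(self, mat, names):
        df = pd.DataFrame(mat, index=names, columns=names)
        return EnviromicKernel(values=df, normalization=1.0)

    def test_k1_single_label(self, rng):
        w = pd.DataFrame(rng.standard_normal((5, 10)),
                         index=[f"E{i}" for i in range(5)])
        a = delineate_mega_environments(enviromic_kernel(w), k=1)
        assert len(set(a.labels.values())) == 1

    def test_duplicate_environments_colabeled(self, rng):
        base = rng.standard_normal((4, 12))
        w = np.vstack([base, base[0]])  # E4 duplicates E0
        w = pd.DataFrame(w, index=["E0", "E1", "E2", "E3", "E4"])
        kern = enviromic_kernel(w)
        assert kernel_distance(kern).loc["E0", "E4"] == pytest.approx(0, abs=1e-9)
        for k in (2, 3, 4):
            a = delineate_mega_environments(kern, k=k)
            assert a.labels["E0"] == a.labels["E4"]

    def test_permutation_invariance(self, rng):
        w = pd.DataFrame(rng.standard_normal((7, 15)),
                         index=[f"E{i}" for i in range(7)])
        a = delineate_mega_environments(enviromic_kernel(w), k=3)
        perm = w.sample(frac=1.0, random_state=1)
        b = delineate_mega_environments(enviromic_kernel(perm), k=3)
        assert a.labels == b.labels

    def test_k_out_of_range(self, rng):
        w = pd.DataFrame(rng.standard_normal((4, 6)), index=list("abcd"))
        kern = enviromic_kernel(w)
        for k in (0, 5):
            with pytest.raises(ValueError):
                delineate_mega_environments(kern, k=k)

    def test_planted_archetypes_recovered(self):
        """4 archetypes with offsets >> noise -> adjusted Rand = 1 at k=4."""
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(rng_seed=9, n_weather_years=3,
                               weather_first_year=2017)
        wx = simulate_weather(cfg)
        cov = {loc: derive_covariables(s) for loc, s in wx.items()}
        kern = enviromic_kernel(build_w_matrix(cov))
        a = delineate_mega_environments(kern, k=4)
        locs = sorted(a.labels)
        ari = adjusted_rand_score([cfg.me_archetypes[l] for l in locs],
                                  [a.labels[l] for l in locs])
        assert ari == 1.0


class TestTypology:
    def _cov_tables(self, values_by_trial):
        out = {}
        for (loc, year), vals in values_by_trial.items():
            n = len(vals)
            df = pd.DataFrame({
                "date": pd.date_range(f"{year}-06-01", periods=n, freq="D"),
                "das": np.arange(n),
            })
            for cov in COVARIABLES:
                df[cov] = vals
            out[(loc, year)] = df
        return out

    STAGES = {"early": (0, 59), "late": (60, 120)}

    def test_frequencies_sum_to_one(self, rng):
        cov = self._cov_tables({("L1", 2019): rng.uniform(0, 1, 120),
                                ("L2", 2019): rng.uniform(0, 1, 120)})
        typ = env_typing(cov, {"L1": "ME1", "L2": "ME2"}, self.STAGES)
        sums = typ.groupby(["ME", "year", "stage", "covariable"])["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_constant_covariable_single_class(self):
        cov = self._cov_tables({("L1", 2019): np.full(120, 7.0)})
        typ = env_typing(cov, {"L1": "ME1"}, self.STAGES)
        assert (typ.groupby(["stage", "covariable"])["frequency"].max() == 1.0).all()

    def test_uniform_quantile_frequencies(self, rng):
        """10^4 uniform days: class frequencies match quantile spacings
        within binomial error (+-0.02)."""
        vals = rng.uniform(0, 1, 10_000)
        cov = self._cov_tables({("L1", 2019): vals})
        typ = env_typing(cov, {"L1": "ME1"}, {"all": (0, 10_000)},
                         variables=["GDD"])
        qs = [0.01, 0.25, 0.50, 0.75, 0.975, 0.99]
        expected = np.diff([0.0] + qs + [1.0])
        got = typ.sort_values("class")["frequency"].to_numpy()
        assert len(got) == len(expected)
        assert np.abs(np.sort(got) - np.sort(expected)).max() < 0.02


class TestPCA:
    def test_explained_variance_sums_to_one(self, rng):
        table = pd.DataFrame(rng.standard_normal((6, 4)))
        res = environment_pca(table)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_table(self, rng):
        u = rng.standard_normal(5)
        v = rng.standard_normal(3)
        table = pd.DataFrame(np.outer(u, v))
        res = environment_pca(table)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_variable_eigenvalues_closed_form(self, rng):
        rho = 0.6
        n = 20_000
        x = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        res = environment_pca(pd.DataFrame(x))
        assert res.eigenvalues[0] == pytest.approx(1 + rho, abs=0.02)
        assert res.eigenvalues[1] == pytest.approx(1 - rho, abs=0.02)

    def test_constant_column_dropped(self, rng):
        table = pd.DataFrame(rng.standard_normal((6, 3)))
        table["const"] = 5.0
        res = environment_pca(table)
        assert res.dropped == ["const"]
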
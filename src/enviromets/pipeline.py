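"""End-to-end orchestration: envirotyping -> delineation -> typology ->
variance components -> MPS -> MTMPS -> selection differentials.

Every stage writes its tables under the configured output directory; a
machine-readable ``summary.json`` (stable schema, byte-identical under a
fixed seed) and a run log close the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from enviromets import io as emio
from enviromets.config import RunConfig
from enviromets.envirotyping import (
    COVARIABLES,
    CovariableParams,
    build_w_matrix,
    delineate_mega_environments,
    derive_covariables,
    enviromic_kernel,
    env_typing,
    environment_pca,
)
from enviromets.mtmps import (
    cross_me_summary,
    factor_analysis,
    mtmps,
    select,
    selection_differentials,
)
from enviromets.stability import mean_stability_table, weight_scenarios
from enviromets.synthetic import simulate_trial, simulate_weather
from enviromets.varcomp import (
    fit_random_model,
    lrt_random_effects,
    validate_trial_frame,
    varcomp_table,
    variance_contributions,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and prior artifacts."""

    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


def adjusted_rand_index(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    from sklearn.metrics import adjusted_rand_score

    items = sorted(labels_a)
    return float(adjusted_rand_score([labels_a[i] for i in items],
                                     [labels_b[i] for i in items]))


def _covariable_params(cfg: RunConfig) -> CovariableParams:
    a = cfg.analysis
    return CovariableParams(tbase=a.tbase, cardinal_temps=a.cardinal_temps,
                            etp_method=a.etp_method)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summary_schema() -> dict:
    with resources.files("enviromets.data").joinpath("summary_schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: dict) -> None:
    """Structural check of the summary against the checked-in schema."""
    schema = summary_schema()
    _check_node(summary, schema, "summary")


def _check_node(value, schema, path):
    typ = schema["type"]
    pytypes = {"object": dict, "number": (int, float), "string": str,
               "integer": int, "boolean": bool, "array": list}
    if not isinstance(value, pytypes[typ]):
        raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
    if typ == "object":
        for key, sub in schema.get("properties", {}).items():
            if key in schema.get("required", []) and key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
            if key in value:
                _check_node(value[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            known = set(schema.get("properties", {}))
            for key, sub in value.items():
                if key not in known:
                    _check_node(sub, extra, f"{path}.{key}")
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(value):
            _check_node(item, schema["items"], f"{path}[{i}]")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the summary dict (also written to
    ``summary.json``). Raises :class:`StageError` on stage failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("enviromets")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    completed: list[str] = []
    sim = config.simulation
    ana = config.analysis
    params = _covariable_params(config)
    summary: dict = {"seed": int(config.seed), "stages": []}
    log.info("run config: %s", json.dumps(dataclasses.asdict(config),
                                          default=_json_default, sort_keys=True))

    def stage(name):
        def wrap(fn):
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, completed, exc) from exc
            completed.append(name)
            summary["stages"].append(name)
            return out
        return wrap

    @stage("weather")
    def weather():
        if config.simulate:
            sim.rng_seed = int(config.seed)
            archive = simulate_weather(sim)
            emio.write_weather(archive, str(outdir / "weather.csv"))
        else:
            archive = emio.read_weather(config.weather_path)
        return archive

    @stage("envirotype")
    def wmatrix():
        cov = {loc: derive_covariables(s, params) for loc, s in weather.items()}
        w = build_w_matrix(cov, qc_sd=ana.qc_sd)
        w.values.to_csv(outdir / "w_matrix.csv")
        kern = enviromic_kernel(w)
        kern.values.to_csv(outdir / "kernel.csv")
        mean_table = pd.DataFrame({
            loc: df[list(COVARIABLES)].mean(axis=0) for loc, df in cov.items()
        }).T
        pca = environment_pca(mean_table)
        pca.scores.to_csv(outdir / "pca_scores.csv")
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        return w, kern

    w, kern = wmatrix

    @stage("delineate")
    def assignment():
        assign = delineate_mega_environments(kern, k=ana.k_clusters)
        pd.Series(assign.labels, name="ME").rename_axis("location") \
            .sort_index().to_csv(outdir / "me_assignment.csv")
        return assign

    @stage("phenotypes")
    def trial():
        if config.simulate:
            data = simulate_trial(sim, me_labels=assignment.labels)
            emio.write_phenotypes(data, str(outdir / "phenotypes.csv"))
        else:
            data = emio.read_phenotypes(config.phenotype_path)
            if "ME" in data.columns:
                data = data.drop(columns="ME")
            data["ME"] = data["location"].map(assignment.labels)
            if data["ME"].isna().any():
                missing = sorted(data.loc[data["ME"].isna(), "location"].unique())
                raise ValueError(f"location(s) without weather/ME: {missing}")
        validate_trial_frame(data)
        return data

    traits = [c for c in trial.columns
              if c not in ("genotype", "location", "year", "block", "ME")]

    @stage("typology")
    def typology():
        trial_years = sorted(trial["year"].unique())
        if config.simulate:
            tw = simulate_weather(sim, years=trial_years)
        else:
            tw = weather
        sow_m, sow_d = sim.sowing_month_day
        cov = {}
        for loc, series in tw.items():
            df = derive_covariables(series, params)
            dates = pd.DatetimeIndex(df["date"])
            for year in trial_years:
                sowing = pd.Timestamp(year=year, month=sow_m, day=sow_d)
                sub = df[dates.year == year].copy()
                sub["das"] = (pd.DatetimeIndex(sub["date"]) - sowing).days
                cov[(loc, year)] = sub
        typ = env_typing(cov, assignment, ana.stages, ana.quantiles)
        typ.to_csv(outdir / "typology.csv", index=False)
        return typ

    @stage("varcomp")
    def varcomp():
        results = []
        for t in traits:
            res = fit_random_model(trial, t)
            if ana.run_lrt:
                res = lrt_random_effects(trial, t, full=res,
                                         distribution=ana.lrt_distribution)
            results.append(res)
        table = varcomp_table(results)
        table.to_csv(outdir / "varcomp.csv")
        parts = []
        for res in results:
            part = variance_contributions(res.variances, res.J, res.K,
                                          res.total_reps)
            part.insert(0, "trait", res.trait)
            parts.append(part)
        pd.concat(parts, ignore_index=True).to_csv(
            outdir / "variance_partitions.csv", index=False)
        return results

    @stage("selection")
    def selection():
        mes = sorted(set(assignment.labels.values()))
        per_me = {}
        for me in mes:
            rm_cols, mean_cols, wi_cols = {}, {}, {}
            for t in traits:
                direction = ana.directions.get(t, "increase")
                tab = mean_stability_table(trial, me, t,
                                           direction, ana.theta_y, ana.theta_s)
                tab.to_csv(outdir / f"stability_{me}_{t}.csv")
                scen = weight_scenarios(tab["rY"], tab["rW"])
                scen.insert(0, "trait", t)
                scen.insert(0, "ME", me)
                scen.to_csv(outdir / f"scenarios_{me}_{t}.csv", index=False)
                rm_cols[t] = tab["MPS"]
                mean_cols[t] = tab["mean"]
                wi_cols[t] = tab["Wi"]
            rm = pd.DataFrame(rm_cols)
            model = factor_analysis(rm)
            model.loadings.to_csv(outdir / f"fa_loadings_{me}.csv")
            model.scores.to_csv(outdir / f"fa_scores_{me}.csv")
            dist = mtmps(model)
            result = select(dist, intensity=ana.intensity)
            result.ranking.to_csv(outdir / f"mtmps_{me}.csv")
            ds_mean = selection_differentials(pd.DataFrame(mean_cols),
                                              result.selected, ana.directions)
            ds_wi = selection_differentials(pd.DataFrame(wi_cols),
                                            result.selected, ana.directions,
                                            stability=True)
            ds_mean.to_csv(outdir / f"differentials_mean_{me}.csv")
            ds_wi.to_csv(outdir / f"differentials_stability_{me}.csv")
            per_me[me] = {"model": model, "result": result,
                          "ds_mean": ds_mean, "ds_wi": ds_wi}
        if len(per_me) >= 2:
            membership = cross_me_summary({m: d["result"] for m, d in per_me.items()})
            membership.to_csv(outdir / "cross_me_membership.csv")
        else:
            membership = None
        return per_me, membership

    per_me, membership = selection

    summary["mega_environments"] = {
        me: members for me, members in assignment.members().items()
    }
    if config.simulate:
        summary["delineation_ari_vs_archetypes"] = adjusted_rand_index(
            sim.me_archetypes, assignment.labels)
    summary["traits"] = traits
    summary["varcomp"] = {}
    for res in varcomp:
        sp, h2, ac = res.heritability()
        summary["varcomp"][res.trait] = {
            "variances": {k: float(v) for k, v in sorted(res.variances.items())},
            "sigma2_P": float(sp), "H2": float(h2), "Ac": float(ac),
            "converged": bool(res.converged),
            "lrt_pvalues": {k: (None if np.isnan(v) else float(v))
                            for k, v in sorted(res.lrt_pvalues.items())},
        }
    summary["selection"] = {}
    for me, d in per_me.items():
        summary["selection"][me] = {
            "selected": d["result"].selected,
            "n_factors": int(d["model"].n_factors),
            "explained_variance_pct": float(100.0 * d["model"].explained_variance.sum()),
            "dS_pct_mean": {t: float(v) for t, v in
                            d["ds_mean"]["dS_pct"].round(6).items()},
            "dS_pct_stability": {t: float(v) for t, v in
                                 d["ds_wi"]["dS_pct"].round(6).items()},
        }
    if membership is not None:
        summary["cross_me_counts"] = {
            g: int(n) for g, n in membership["n_selected"].items()}

    validate_summary(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    root.removeHandler(handler)
    handler.close()
    return summary
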
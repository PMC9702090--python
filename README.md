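# enviromets

Envirotyping-based mega-environment delineation and multi-trait
mean-performance-and-stability selection for plant-breeding
multi-environment trials (METs).

## The problem

When candidate genotypes (e.g. maize hybrids) are evaluated across many
locations and years, genotype-by-environment interaction (GEI) makes
rankings environment-dependent. Instead of selecting one "ideal" genotype
for all sites, locations can be grouped into **mega-environments (MEs)** —
sets of sites sharing long-term weather patterns — and selection performed
within each ME for genotypes that are *stable across years*. `enviromets`
implements that full chain for breeders and quantitative geneticists:

1. **Envirotyping.** Daily weather per location is expanded into 19
   environmental covariables: the 9 raw variables (T2M, T2M_MAX, T2M_MIN,
   T2MDEW, RH2M, PRECTOT, WS2M, shortwave insolation SIHS, downward longwave
   DTIRF) plus TRANGE, reference evapotranspiration ETP, precipitation
   deficit PETP = P − ETP, vapor pressure deficit VPD, the slope Δ of the
   saturation vapor-pressure curve, a cardinal-temperature radiation-use
   factor FRUE, growing degree-days GDD, actual/potential sunshine hours
   n and N, and extraterrestrial radiation RTA.
2. **Enviromic kernel and delineation.** Monthly growing-season aggregates
   over a span of years form the envirotype matrix **W** (environments ×
   descriptors, standardized, ±3 SD quality control). The enviromic kernel

   K_E = W W′ / (trace(W W′)/n)

   is a normalized environment similarity (trace = n environments); MEs are
   cut from a UPGMA tree of the kernel-induced distance
   d(i,j) = √(K_ii + K_jj − 2K_ij).
3. **Variance components.** Per trait, the crossed random-effects model
   y = μ + G + M + Y + GM + GY + MY + GMY + REP(M:Y) + ε is fitted by
   REML (average-information updates on Henderson's mixed-model equations),
   with likelihood-ratio tests per term, and broad-sense heritability on a
   genotype-mean basis

   σ²_P = σ²_G + σ²_GY/K + σ²_GM/J + σ²_GMY/JK + σ²_ε/Σreps,
   H² = σ²_G/σ²_P, Ac = √H².
4. **Stability and MPS.** Within each ME, Wricke's ecovalence
   W_i = Σ_k (Ȳ_ik − Ȳ_i· − Ȳ_·k + Ȳ_··)² measures instability across
   years; trait means and W_i are rescaled to 0–100 (100 = desired end) and
   combined as MPS_i = (rY_i·θ_Y + rW_i·θ_s)/(θ_Y+θ_s), default θ_Y/θ_s =
   70/30, with a 21-scenario weight scan.
5. **MTMPS selection.** The genotype × trait MPS table is factor-analyzed
   (eigenvalue > 1 retention, varimax rotation, regression scores
   F = Z(A′R⁻¹)′); each genotype's **MTMPS** is its Euclidean distance in
   factor-score space to the all-100 ideotype. The lowest-MTMPS genotypes
   are selected (default intensity 23%) and selection differentials
   ΔS% = (X_s − X_o)/X_o·100 are reported for trait means and stability.

A synthetic-data module generates weather archives with planted climate
archetypes and trial phenotypes from the random-effects model, so the whole
chain is testable without any external data service.

## Worked example

Heritability from variance components (J = 4 MEs, K = 2 years, 60
location×block×year replicate combinations):

```python
>>> from enviromets import heritability
>>> vc = {"G": 0.038, "GM": 0.059, "GY": 0.0, "GMY": 0.355, "residual": 1.185}
>>> sigma_p, h2, ac = heritability(vc, J=4, K=2, total_reps=60)
>>> round(sigma_p, 3), round(h2, 3), round(ac, 3)
(0.117, 0.325, 0.57)
```

σ²_P = 0.117 is the variance of a genotype mean for grain yield; H² = 0.325
says about a third of that variance is genotypic, and Ac = 0.570 is the
corresponding selection accuracy.

A compact simulate-then-analyze run (4 locations planted in 2 climate
archetypes, 8 genotypes, 2 years):

```python
>>> from enviromets.config import RunConfig, AnalysisConfig, SimulationConfig
>>> from enviromets.pipeline import run_pipeline
>>> cfg = RunConfig(outdir="demo", seed=7,
...                 analysis=AnalysisConfig(k_clusters=2, run_lrt=False),
...                 simulation=SimulationConfig(
...                     n_genotypes=8, n_locations=4, n_years=2, n_blocks=2,
...                     me_archetypes={"L01": "A", "L02": "A",
...                                    "L03": "C", "L04": "C"}))
>>> summary = run_pipeline(cfg)
>>> summary["mega_environments"]
{'ME1': ['L01', 'L02'], 'ME2': ['L03', 'L04']}
>>> summary["delineation_ari_vs_archetypes"]
1.0
```

The delineation recovers the planted two-archetype partition exactly
(adjusted Rand index 1.0); `demo/` then contains the W matrix, kernel, ME
assignment, typology, per-trait variance components, per-ME
stability/MPS/MTMPS tables, selection differentials and a `summary.json`.

The same pipeline is scriptable from the shell:

```bash
enviromets simulate --seed 42 --outdir data/
enviromets delineate data/weather.csv -k 4 --out me.csv
enviromets run --outdir full_run --seed 42
```

## Layout

- `src/enviromets/synthetic.py` — weather + trial generators (planted structure)
- `src/enviromets/envirotyping.py` — covariables, W, K_E, delineation, typology, PCA
- `src/enviromets/varcomp.py` — REML variance components, LRT, H², partitions
- `src/enviromets/stability.py` — genotype-year means, ecovalence, MPS, weight scan
- `src/enviromets/mtmps.py` — factor analysis, ideotype distance, selection, ΔS%
- `src/enviromets/io.py`, `pipeline.py`, `cli.py` — CSV dialects, orchestration, CLI
- `docs/methods.md` — modeling assumptions, defaults and limitations
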
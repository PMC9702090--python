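"""Multi-trait mean-performance-and-stability (MTMPS) selection.

The per-trait MPS values form a genotype x trait table ``rM`` on a 0-100
scale in which 100 is always the desired end. An exploratory factor analysis
groups correlated traits: principal-component extraction from the
correlation matrix R, retention of factors with eigenvalue > 1, varimax
rotation (Kaiser row-normalized) of the retained loadings A, and regression
scores

    F = Z (A' R^-1)'

with Z the column-standardized rM. The ideotype — 100 for every trait — is
standardized with the genotype-sample column means/SDs and pushed through
the same scoring map; each genotype's MTMPS is its Euclidean distance to the
ideotype in factor-score space (lower = better). Selection takes the
``round(intensity * q)`` lowest-MTMPS genotypes, and selection differentials
report the percent change of the selected subset's mean relative to the
population mean for both trait means and ecovalences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 500) -> np.ndarray:
    """Varimax rotation of a p x f loading matrix.

    Maximizes the variance of squared loadings per factor; with Kaiser
    normalization rows are scaled to unit communality during rotation. For a
    single factor the loadings are returned unchanged.
    """
    l = np.asarray(loadings, dtype=float).copy()
    p, f = l.shape
    if f < 2:
        return l
    if kaiser:
        comm = np.sqrt((l ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        l = l / comm[:, None]
    rot = np.eye(f)
    d_old = 0.0
    for _ in range(max_iter):
        lr = l @ rot
        u, s, vt = np.linalg.svd(
            l.T @ (lr ** 3 - lr @ np.diag((lr ** 2).sum(axis=0)) / p))
        rot = u @ vt
        d_new = s.sum()
        if d_new <= d_old * (1.0 + tol):
            break
        d_old = d_new
    l = l @ rot
    if kaiser:
        l = l * comm[:, None]
    return l


@dataclass
class FactorModel:
    """Fitted factor-analysis of the genotype x trait MPS table."""

    rm: pd.DataFrame                     # input table after dropping constants
    correlation: pd.DataFrame            # R (p x p)
    eigenvalues: np.ndarray
    loadings_initial: pd.DataFrame       # unrotated, retained factors
    loadings: pd.DataFrame               # A, varimax-rotated
    communalities: pd.Series
    explained_variance: np.ndarray       # share of total variance per factor
    scores: pd.DataFrame                 # F (q x f)
    ideotype_scores: np.ndarray          # 1 x f
    col_means: pd.Series
    col_sds: pd.Series
    dropped: list[str] = field(default_factory=list)
    used_pinv: bool = False

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def factor_analysis(rm: pd.DataFrame, retention: float = 1.0,
                    ideotype_value: float = 100.0) -> FactorModel:
    """Exploratory factor analysis of the genotype x trait MPS table.

    Retains factors with eigenvalue > ``retention`` (at least one); constant
    columns are dropped with a warning (they carry no correlation
    structure). A singular correlation matrix falls back to the
    pseudo-inverse for the scoring map (flagged on the result).
    """
    if rm.shape[1] < 2:
        raise ValueError("factor analysis needs at least 2 trait columns")
    sds = rm.std(axis=0, ddof=1)
    dropped = list(rm.columns[(sds == 0) | sds.isna()])
    if dropped:
        warnings.warn(f"constant trait column(s) dropped from factor analysis: "
                      f"{dropped}", UserWarning)
    x = rm.drop(columns=dropped)
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant trait columns remain")
    p = x.shape[1]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mean) / sd
    r = np.corrcoef(x.to_numpy(float), rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    nf = int(np.sum(evals > retention))
    if nf == 0:
        warnings.warn("no eigenvalue above the retention threshold; "
                      "falling back to 1 factor", UserWarning)
        nf = 1
    init = evecs[:, :nf] * np.sqrt(np.clip(evals[:nf], 0.0, None))
    rotated = varimax(init)
    # orient each factor so its dominant loading is positive (sign-only;
    # distances to the ideotype are invariant to this choice)
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(nf)])
    signs[signs == 0] = 1.0
    rotated = rotated * signs

    try:
        rinv = np.linalg.inv(r)
        used_pinv = False
    except np.linalg.LinAlgError:
        rinv = np.linalg.pinv(r)
        used_pinv = True
        log.warning("singular correlation matrix: using pseudo-inverse for scores")
    beta = rinv @ rotated                        # p x f scoring coefficients
    scores = z.to_numpy(float) @ beta
    z_ideo = ((ideotype_value - mean) / sd).to_numpy(float)
    ideo = z_ideo @ beta

    factors = [f"FA{i + 1}" for i in range(nf)]
    return FactorModel(
        rm=x,
        correlation=pd.DataFrame(r, index=x.columns, columns=x.columns),
        eigenvalues=evals,
        loadings_initial=pd.DataFrame(init, index=x.columns, columns=factors),
        loadings=pd.DataFrame(rotated, index=x.columns, columns=factors),
        communalities=pd.Series((rotated ** 2).sum(axis=1), index=x.columns),
        explained_variance=np.clip(evals[:nf], 0.0, None) / p,
        scores=pd.DataFrame(scores, index=x.index, columns=factors),
        ideotype_scores=ideo,
        col_means=mean,
        col_sds=sd,
        dropped=dropped,
        used_pinv=used_pinv,
    )


def mtmps(model: FactorModel) -> pd.Series:
    """Euclidean distance of each genotype's factor scores to the ideotype."""
    diff = model.scores.to_numpy(float) - model.ideotype_scores[None, :]
    return pd.Series(np.sqrt((diff ** 2).sum(axis=1)),
                     index=model.scores.index, name="MTMPS")


@dataclass
class SelectionResult:
    """Ranking, selected set and intensity for one mega-environment."""

    ranking: pd.DataFrame        # genotype-indexed: MTMPS, rank, selected
    selected: list[str]
    intensity: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select(scores: pd.Series, intensity: float = 0.23) -> SelectionResult:
    """Select the ``round(intensity * q)`` genotypes closest to the ideotype.

    Ties in MTMPS are broken by genotype label for determinism.
    """
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be in (0, 1]")
    q = len(scores)
    n_sel = int(round(intensity * q))
    if n_sel == 0:
        raise ValueError(
            f"intensity {intensity} selects 0 of {q} genotypes")
    order = scores.reset_index()
    order.columns = ["genotype", "MTMPS"]
    order = order.sort_values(["MTMPS", "genotype"]).reset_index(drop=True)
    order["rank"] = np.arange(1, q + 1)
    order["selected"] = order["rank"] <= n_sel
    ranking = order.set_index("genotype")
    return SelectionResult(ranking=ranking,
                           selected=list(order.loc[order["selected"], "genotype"]),
                           intensity=intensity)


def selection_differentials(values: pd.DataFrame, selected: Sequence[str],
                            directions: Mapping[str, str],
                            stability: bool = False) -> pd.DataFrame:
    """Percent selection differentials per trait column of ``values``.

    ``values`` is genotype-indexed (trait means, or ecovalences when
    ``stability=True``). DeltaS% = (Xs - Xo) / Xo * 100 with Xs the selected
    subset's mean and Xo the population mean. ``desired`` flags whether the
    sign agrees with the trait's registered direction (for ecovalence the
    desired sign is always negative: selection should reduce instability).
    """
    unknown = [g for g in selected if g not in values.index]
    if unknown:
        raise ValueError(f"selected genotype(s) not in table: {unknown}")
    rows = []
    for trait in values.columns:
        xo = float(values[trait].mean())
        xs = float(values.loc[list(selected), trait].mean())
        if xo == 0:
            rows.append({"trait": trait, "Xo": xo, "Xs": xs,
                         "dS_pct": float("nan"), "desired": None})
            continue
        ds = (xs - xo) / xo * 100.0
        if stability:
            desired = ds <= 0
        else:
            want = directions.get(trait, "increase")
            desired = ds >= 0 if want == "increase" else ds <= 0
        rows.append({"trait": trait, "Xo": xo, "Xs": xs,
                     "dS_pct": ds, "desired": desired})
    return pd.DataFrame(rows).set_index("trait")


def cross_me_summary(results: Mapping[str, SelectionResult]) -> pd.DataFrame:
    """Per-genotype membership of the selected sets across mega-environments."""
    if len(results) < 2:
        raise ValueError("cross-ME summary needs >= 2 mega-environments")
    genotypes = sorted({g for r in results.values() for g in r.ranking.index})
    rows = []
    for g in genotypes:
        mes = sorted(me for me, r in results.items() if g in r.selected)
        rows.append({"genotype": g, "n_selected": len(mes),
                     "mega_environments": ",".join(mes)})
    return pd.DataFrame(rows).set_index("genotype")
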
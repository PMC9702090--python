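"""Genotype means, Wricke's ecovalence, and the MPS index per
mega-environment.

Within a mega-environment, the genotype x year mean table (pooled over the
ME's locations and blocks) feeds Wricke's ecovalence

    W_i = sum_k (Ybar_ik - Ybar_i. - Ybar_.k + Ybar_..)^2,

a genotype's contribution to the genotype x year interaction sum of squares
(lower = more stable across years). Trait means and ecovalences are linearly
rescaled to 0-100 so that 100 is always the desired end (direction-aware),
and combined into the mean-performance-and-stability index

    MPS_i = (rY_i * theta_Y + rW_i * theta_s) / (theta_Y + theta_s)

with default weights theta_Y = 70 (performance) and theta_s = 30
(stability). A weight scan over theta_Y/theta_s ratios shows how the
genotype ranking shifts between performance-only and stability-only.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd


def genotype_year_means(data: pd.DataFrame, me: str, trait: str) -> pd.DataFrame:
    """Genotype x year mean matrix within one mega-environment.

    Cell (i, k) is the mean over all locations and blocks of the ME in year
    k. Genotypes missing any year are excluded with a warning (their
    ecovalence across years is undefined).
    """
    sub = data[data["ME"] == me]
    if sub.empty:
        raise ValueError(f"no records for ME {me!r}")
    mat = sub.pivot_table(index="genotype", columns="year", values=trait,
                          aggfunc="mean")
    incomplete = mat.index[mat.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"ME {me}, trait {trait}: genotype(s) missing a year excluded: "
            f"{list(incomplete)}", UserWarning)
        mat = mat.drop(index=incomplete)
    return mat


def ecovalence(means: pd.DataFrame) -> pd.Series:
    """Wricke's ecovalence per genotype from a genotype x year mean matrix."""
    if means.shape[0] < 2 or means.shape[1] < 2:
        raise ValueError(
            f"ecovalence needs >=2 genotypes and >=2 years, got {means.shape}")
    m = means.to_numpy(float)
    resid = (m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True)
             + m.mean())
    return pd.Series((resid ** 2).sum(axis=1), index=means.index, name="Wi")


def rescale(values: pd.Series | np.ndarray, direction: str) -> pd.Series:
    """Direction-aware linear rescaling to 0-100.

    ``direction="increase"``: the largest original value maps to 100.
    ``direction="decrease"``: the smallest original value maps to 100.
    A constant vector carries no ranking information and maps to 50
    everywhere (with a warning).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be increase|decrease, got {direction!r}")
    s = pd.Series(values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("rescale requires finite values")
    oma, omi = float(s.max()), float(s.min())
    if oma == omi:
        warnings.warn("constant vector in rescale: all values set to 50",
                      UserWarning)
        return pd.Series(50.0, index=s.index)
    nma, nmi = (100.0, 0.0) if direction == "increase" else (0.0, 100.0)
    out = (nma - nmi) / (oma - omi) * (s - oma) + nma
    return out.clip(0.0, 100.0)  # guard rounding at the endpoints


def mps(ry: pd.Series, rw: pd.Series, theta_y: float = 70.0,
        theta_s: float = 30.0) -> pd.Series:
    """Weighted mean-performance-and-stability index in [0, 100]."""
    if theta_y + theta_s <= 0:
        raise ValueError("theta_y + theta_s must be positive")
    ry = pd.Series(ry, dtype=float)
    rw = pd.Series(rw, dtype=float)
    if len(ry) != len(rw) or not ry.index.equals(rw.index):
        raise ValueError("rY and rW must be aligned on the same genotypes")
    return (ry * theta_y + rw * theta_s) / (theta_y + theta_s)


def default_weight_grid() -> list[tuple[float, float]]:
    """The 21 theta_Y/theta_s pairs 100/0, 95/5, ..., 0/100."""
    return [(100.0 - 5.0 * i, 5.0 * i) for i in range(21)]


def weight_scenarios(ry: pd.Series, rw: pd.Series,
                     ratios: Sequence[tuple[float, float]] | None = None
                     ) -> pd.DataFrame:
    """Genotype rank (1 = highest MPS) per performance/stability weight pair.

    Ties get average ranks (deterministic). Returns a long frame
    (scenario, theta_y, theta_s, genotype, mps, rank).
    """
    if ratios is None:
        ratios = default_weight_grid()
    if not ratios:
        raise ValueError("ratios must be non-empty")
    frames = []
    for ty, ts in ratios:
        score = mps(ry, rw, ty, ts)
        rank = score.rank(ascending=False, method="average")
        frames.append(pd.DataFrame({
            "scenario": f"{ty:g}/{ts:g}",
            "theta_y": ty, "theta_s": ts,
            "genotype": score.index, "mps": score.values, "rank": rank.values,
        }))
    return pd.concat(frames, ignore_index=True)


def mean_stability_table(data: pd.DataFrame, me: str, trait: str,
                         direction: str, theta_y: float = 70.0,
                         theta_s: float = 30.0) -> pd.DataFrame:
    """Full per-(ME, trait) table: mean, W_i, rY, rW, MPS, rank.

    Ecovalence is always rescaled with ``direction="decrease"`` (lower W_i is
    better); the trait mean with the trait's registered direction.
    """
    mat = genotype_year_means(data, me, trait)
    wi = ecovalence(mat)
    ybar = mat.mean(axis=1)
    ry = rescale(ybar, direction)
    rw = rescale(wi, "decrease")
    score = mps(ry, rw, theta_y, theta_s)
    out = pd.DataFrame({
        "mean": ybar, "Wi": wi, "rY": ry, "rW": rw, "MPS": score,
        "rank": score.rank(ascending=False, method="average"),
    })
    out.index.name = "genotype"
    return out
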
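"""REML variance components, likelihood-ratio tests, heritability.

For each trait the crossed random-effects model

    y_ijkn = mu + G_i + M_j + Y_k + GM_ij + GY_ik + MY_jk + GMY_ijk
             + REP_n(jk) + e_ijkn

is fitted with the intercept as the only fixed effect and every other term
random with its own variance. Estimation is EM-REML on Henderson's
mixed-model equations (MME): per iteration the MME coefficient matrix

    C = W'W + diag(0, lambda_t I),   lambda_t = sigma_e^2 / sigma_t^2

is factorized once; solutions give the BLUP updates

    sigma_t^2 <- (u_t'u_t + sigma_e^2 tr(C^tt)) / q_t
    sigma_e^2 <- (y'y - s'W'y) / (n - p)

where C^tt is the t-th diagonal block of C^{-1}. EM guarantees non-negative
estimates; components shrinking below a floor are fixed at zero (boundary)
and dropped from the equations. The REML log-likelihood is evaluated from
the same factorization,

    -2 l_R = (n-p-q) log sigma_e^2 + sum_t q_t log sigma_t^2 + log|C|
             + y'Py + (n-p) log 2 pi,

which makes likelihood-ratio tests between nested variance structures cheap.

Broad-sense heritability on a genotype-mean basis:

    sigma_P^2 = sigma_G^2 + sigma_GY^2/K + sigma_GM^2/J + sigma_GMY^2/(JK)
                + sigma_e^2 / total_reps
    H^2 = sigma_G^2 / sigma_P^2,    Ac = sqrt(H^2)

with J mega-environments, K years and ``total_reps`` the total number of
location x block x year replicate combinations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

log = logging.getLogger(__name__)

#: model terms (besides the residual) and the factor columns that key them
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "G": ("genotype",),
    "M": ("ME",),
    "Y": ("year",),
    "GM": ("genotype", "ME"),
    "GY": ("genotype", "year"),
    "MY": ("ME", "year"),
    "GMY": ("genotype", "ME", "year"),
    "REP": ("location", "block", "year"),
}

REQUIRED_COLUMNS = ("genotype", "location", "year", "block", "ME")


def validate_trial_frame(data: pd.DataFrame, traits: Sequence[str] | None = None) -> None:
    """Check the plot-level frame: required factors present, replicate levels
    nest within ME x year, no duplicated plot keys."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial data missing required column(s): {missing}")
    key = ["genotype", "location", "year", "block"]
    dup = data.duplicated(subset=key)
    if dup.any():
        rows = data.loc[dup, key].head(5).to_dict("records")
        raise ValueError(f"duplicated plot keys, e.g. {rows}")
    me_per_loc = data.groupby("location")["ME"].nunique()
    bad = me_per_loc[me_per_loc > 1]
    if len(bad):
        raise ValueError(
            f"location(s) mapped to multiple MEs (nesting violated): {list(bad.index)}"
        )
    if traits:
        for t in traits:
            if t not in data.columns:
                raise ValueError(f"trait column {t!r} not in data")


@dataclass
class VarCompResult:
    """REML fit of the crossed random-effects model for one trait."""

    trait: str
    variances: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    boundary_terms: list[str] = field(default_factory=list)
    lrt_pvalues: dict[str, float] = field(default_factory=dict)
    lrt_stats: dict[str, float] = field(default_factory=dict)
    J: int = 0
    K: int = 0
    total_reps: int = 0

    def heritability(self) -> tuple[float, float, float]:
        return heritability(self.variances, self.J, self.K, self.total_reps)


def _design(data: pd.DataFrame, trait: str,
            terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Dense [X | Z_1 .. Z_T] design and response for the given random terms."""
    y = pd.to_numeric(data[trait], errors="raise").to_numpy(float)
    n = len(y)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    meta: list[tuple[str, int]] = []
    for term in terms:
        cols = MODEL_TERMS[term]
        key = data[list(cols)].astype(str).agg("|".join, axis=1)
        codes, levels = pd.factorize(key, sort=True)
        q = len(levels)
        if q < 2:
            raise ValueError(
                f"term {term!r} has {q} level(s); cannot estimate its variance"
            )
        z = np.zeros((n, q))
        z[np.arange(n), codes] = 1.0
        blocks.append(z)
        meta.append((term, q))
    return np.hstack(blocks), y, meta


class _MMESolver:
    """Factorized mixed-model equations for one set of active terms.

    Uses the absorption identity P = (I - W C^-1 W') / sigma_e^2 to expose
    BLUPs, the REML log-likelihood, score elements and average-information
    products without ever forming the n x n matrix V.
    """

    def __init__(self, w, wtw, wty, yty, y, meta, offsets, p, sig, sig_e):
        self.w, self.y = w, y
        self.meta, self.offsets, self.p = meta, offsets, p
        self.sig, self.sig_e = dict(sig), sig_e
        self.n = len(y)
        self.active = [term for term, _ in meta if sig[term] > 0]
        cols = list(range(p)) + [j for term, _ in meta if sig[term] > 0
                                 for j in range(*offsets[term])]
        self.cols = np.asarray(cols)
        self.wtw_a = wtw[np.ix_(self.cols, self.cols)]
        self.wty_a = wty[self.cols]
        self.yty = yty
        lam = np.zeros(len(cols))
        self.block = {}
        for term, q in meta:
            if sig[term] <= 0:
                continue
            lo, hi = offsets[term]
            mask = (self.cols >= lo) & (self.cols < hi)
            self.block[term] = mask
            lam[mask] = sig_e / sig[term]
        self.lam = lam
        c = self.wtw_a.copy()
        c[np.diag_indices_from(c)] += lam
        try:
            self.cf = linalg.cho_factor(c, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise RuntimeError("MME coefficient matrix singular; "
                               "confounded terms?") from exc
        self.sol = linalg.cho_solve(self.cf, self.wty_a, check_finite=False)
        self.cinv = linalg.cho_solve(self.cf, np.eye(len(cols)),
                                     check_finite=False)
        self.sse = yty - float(self.sol @ self.wty_a)
        self.e = y - w[:, self.cols] @ self.sol        # residuals y - Xb - Zu
        self.py = self.e / sig_e

    def loglik(self) -> float:
        q = sum(q for term, q in self.meta if self.sig[term] > 0)
        logdet_g = sum(q * np.log(self.sig[term])
                       for term, q in self.meta if self.sig[term] > 0)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(self.cf[0]))))
        ypy = self.sse / self.sig_e
        minus2l = ((self.n - self.p - q) * np.log(self.sig_e) + logdet_g
                   + logdet_c + ypy + (self.n - self.p) * np.log(2.0 * np.pi))
        return -0.5 * minus2l

    def em_update(self) -> tuple[dict, float]:
        sig_e = self.sse / (self.n - self.p)
        new = {}
        for term, q in self.meta:
            if self.sig[term] <= 0:
                new[term] = 0.0
                continue
            mask = self.block[term]
            u = self.sol[mask]
            tr = float(np.trace(self.cinv[np.ix_(mask, mask)]))
            new[term] = (float(u @ u) + sig_e * tr) / q
        return new, sig_e

    def _apply_p(self, v: np.ndarray) -> np.ndarray:
        wv = self.w[:, self.cols].T @ v
        return (v - self.w[:, self.cols] @ linalg.cho_solve(
            self.cf, wv, check_finite=False)) / self.sig_e

    def scores_and_ai(self, z_codes, wtw, wty) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """REML score vector and average-information matrix over ALL
        variance parameters (every model term + residual), including terms
        currently at the zero boundary — their positive score signals
        re-entry."""
        names = [term for term, _ in self.meta] + ["residual"]
        fs, trs = [], []
        for term, _ in self.meta:
            lo, hi = self.offsets[term]
            # sigma_e^2 tr(P Z Z') = tr(Z'Z) - tr(U' C^-1 U), U = W_active' Z
            u = wtw[np.ix_(self.cols, np.arange(lo, hi))]
            tr_zz = float(np.sum(np.diag(wtw)[lo:hi]))
            tr_abs = float(np.sum((self.cinv @ u) * u))
            trs.append((tr_zz - tr_abs) / self.sig_e)
            codes = z_codes[term]
            ztpy = np.bincount(codes, weights=self.py)
            fs.append(ztpy[codes])                     # Z Z' P y
        # residual: tr(P) = (n - p - q_active + tr(C^-1 D)) / sigma_e^2
        tr_p = (self.n - len(self.cols)
                + float(np.sum(np.diag(self.cinv) * self.lam))) / self.sig_e
        trs.append(tr_p)
        fs.append(self.py)
        score = np.empty(len(names))
        for i, f in enumerate(fs):
            score[i] = -0.5 * (trs[i] - float(f @ self.py))
        pf = [self._apply_p(f) for f in fs]
        ai = np.empty((len(names), len(names)))
        for i in range(len(names)):
            for j in range(i, len(names)):
                ai[i, j] = ai[j, i] = 0.5 * float(fs[i] @ pf[j])
        return score, ai, names


def fit_random_model(data: pd.DataFrame, trait: str,
                     terms: Sequence[str] | None = None,
                     max_iter: int = 200, tol: float = 1e-8,
                     n_em_start: int = 3,
                     zero_floor_frac: float = 1e-8) -> VarCompResult:
    """REML fit of the full (or reduced) random model for one trait.

    Estimation runs on Henderson's mixed-model equations: a short EM-REML
    warm-up followed by average-information (AI) Newton steps, with
    step-halving and EM fallback whenever a proposal leaves the parameter
    space or decreases the restricted likelihood. Variances are constrained
    non-negative; a component falling below ``zero_floor_frac * var(y)`` is
    fixed at the zero boundary and reported as 0 (it can re-enter only by
    never being dropped, so drops are taken conservatively from EM steps or
    at negative boundary scores).

    ``terms`` defaults to all eight random terms; pass a subset for reduced
    models (used by the likelihood-ratio test).
    """
    validate_trial_frame(data, [trait])
    if terms is None:
        terms = list(MODEL_TERMS)
    w, y, meta = _design(data, trait, terms)
    n = len(y)
    p = 1
    vary = float(np.var(y)) or 1.0
    floor = zero_floor_frac * vary

    wtw = w.T @ w
    wty = w.T @ y
    yty = float(y @ y)
    offsets = {}
    pos = p
    for term, q in meta:
        offsets[term] = (pos, pos + q)
        pos += q
    # per-term level codes for fast Z Z' v products
    z_codes = {}
    for term, _ in meta:
        key = data[list(MODEL_TERMS[term])].astype(str).agg("|".join, axis=1)
        z_codes[term], _ = pd.factorize(key, sort=True)

    sig = {term: vary / (len(meta) + 1) for term, _ in meta}
    sig_e = vary / (len(meta) + 1)

    def make_solver(s, se):
        return _MMESolver(w, wtw, wty, yty, y, meta, offsets, p, s, se)

    solver = make_solver(sig, sig_e)
    loglik = solver.loglik()
    converged = False
    stagnant = 0
    it = 0
    for it in range(1, max_iter + 1):
        if it <= n_em_start:
            new, new_e = solver.em_update()
            for term, _ in meta:
                if 0 < new[term] < floor:
                    new[term] = 0.0
            cand = make_solver(new, new_e)
            cand_ll = cand.loglik()
        else:
            score, ai, names = solver.scores_and_ai(z_codes, wtw, wty)
            theta = np.array([solver.sig[t] for t in names[:-1]] + [solver.sig_e])
            # KKT: parameters at 0 with negative score stay clamped at 0
            clamped = np.append((theta[:-1] <= 0.0) & (score[:-1] <= 0.0), False)
            free = ~clamped
            # ascent-guaranteed Newton step: project AI (free block) to PD
            ai_f = ai[np.ix_(free, free)]
            evals, evecs = np.linalg.eigh(0.5 * (ai_f + ai_f.T))
            # floor small/negative eigenvalues: keeps the step an ascent
            # direction and bounds its length along ill-determined axes
            evals = np.clip(evals, max(1e-6 * evals.max(), 1e-300), None)
            step = np.zeros_like(theta)
            step[free] = evecs @ ((evecs.T @ score[free]) / evals)
            clamped = clamped[:-1]
            cand, cand_ll = None, -np.inf
            frac = 1.0
            for _ in range(25):
                prop = theta + frac * step
                prop[:-1] = np.where(clamped, 0.0, np.clip(prop[:-1], 0.0, None))
                prop[:-1][prop[:-1] < floor] = 0.0
                prop[-1] = max(prop[-1], 1e-10 * vary)
                new = {t: float(v) for t, v in zip(names[:-1], prop[:-1])}
                try:
                    cand = make_solver(new, float(prop[-1]))
                except RuntimeError:
                    frac *= 0.5
                    continue
                cand_ll = cand.loglik()
                if cand_ll >= loglik - 1e-10:
                    break
                frac *= 0.5
            if cand is None or cand_ll < loglik - 1e-8:
                # AI failed to improve: take a plain EM step instead
                new, new_e = solver.em_update()
                for term, _ in meta:
                    if 0 < new[term] < floor:
                        new[term] = 0.0
                cand = make_solver(new, new_e)
                cand_ll = cand.loglik()
        delta = max(
            max(abs(cand.sig[t] - solver.sig[t]) for t, _ in meta),
            abs(cand.sig_e - solver.sig_e))
        improve = cand_ll - loglik
        solver, loglik = cand, cand_ll
        if it > n_em_start:
            if delta < tol * vary and abs(improve) < 1e-8:
                converged = True
                break
            # flat likelihood ridge: parameters trade off with no gain
            stagnant = stagnant + 1 if abs(improve) < 1e-9 else 0
            if stagnant >= 3:
                converged = True
                break

    if not converged:
        warnings.warn(
            f"AI-REML did not reach tol after {it} iterations for {trait!r} "
            f"(last estimates kept)", RuntimeWarning)

    j = int(data["ME"].nunique())
    k = int(data["year"].nunique())
    total_reps = int(data[["location", "block", "year"]].astype(str)
                     .agg("|".join, axis=1).nunique())
    variances = {term: float(solver.sig[term]) for term, _ in meta}
    variances["residual"] = float(solver.sig_e)
    boundary = [term for term, _ in meta if solver.sig[term] == 0.0]
    if boundary:
        log.info("trait %s: boundary (zero) variance for %s", trait, boundary)
    return VarCompResult(
        trait=trait, variances=variances, loglik=loglik, converged=converged,
        n_iter=it, n_obs=n, boundary_terms=boundary,
        J=j, K=k, total_reps=total_reps,
    )


def lrt_random_effects(data: pd.DataFrame, trait: str,
                       full: VarCompResult | None = None,
                       terms: Sequence[str] | None = None,
                       distribution: str = "chi2",
                       **fit_kwargs) -> VarCompResult:
    """Likelihood-ratio tests for each random term of the full model.

    Each term is dropped in turn, the reduced model refitted, and the
    statistic 2(l_full - l_reduced) (floored at 0) referred to chi2(1)
    (default, conservative at the boundary) or to the 50:50 mixture
    chi2(0):chi2(1) (``distribution="mixture"``). Returns the full-model
    result with ``lrt_stats`` / ``lrt_pvalues`` filled in.
    """
    if terms is None:
        terms = list(MODEL_TERMS)
    if full is None:
        full = fit_random_model(data, trait, terms=terms, **fit_kwargs)
    if not full.converged:
        raise RuntimeError(f"full model for {trait!r} did not converge; no LRT")
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        try:
            reduced = fit_random_model(data, trait, terms=reduced_terms, **fit_kwargs)
        except RuntimeError:
            full.lrt_stats[term] = float("nan")
            full.lrt_pvalues[term] = float("nan")
            log.warning("LRT for %s/%s: reduced fit failed, p unavailable", trait, term)
            continue
        stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        if distribution == "chi2":
            pval = float(chi2.sf(stat, df=1))
        elif distribution == "mixture":
            pval = float(0.5 * chi2.sf(stat, df=1)) if stat > 0 else 1.0
        else:
            raise ValueError(f"unknown LRT reference distribution {distribution!r}")
        full.lrt_stats[term] = stat
        full.lrt_pvalues[term] = pval
    return full


def heritability(vc: Mapping[str, float], J: int, K: int,
                 total_reps: int) -> tuple[float, float, float]:
    """(sigma_P^2, H^2, Ac) from a variance-component mapping.

    ``vc`` must carry G, GM, GY, GMY and residual entries (missing terms
    count as 0). ``total_reps`` is the total number of location x block x
    year combinations (e.g. 10 locations x 3 blocks x 2 years = 60).
    """
    if min(J, K, total_reps) < 1:
        raise ValueError("J, K and total_reps must be >= 1")
    g = float(vc.get("G", 0.0))
    gy = float(vc.get("GY", 0.0))
    gm = float(vc.get("GM", 0.0))
    gmy = float(vc.get("GMY", 0.0))
    err = float(vc.get("residual", 0.0))
    for name, v in (("G", g), ("GY", gy), ("GM", gm), ("GMY", gmy), ("residual", err)):
        if v < 0:
            raise ValueError(f"negative variance for {name}")
    sigma_p = g + gy / K + gm / J + gmy / (J * K) + err / total_reps
    if sigma_p == 0:
        warnings.warn("sigma_P^2 = 0; H^2 defined as 0", RuntimeWarning)
        return 0.0, 0.0, 0.0
    h2 = g / sigma_p
    return sigma_p, h2, float(np.sqrt(h2))


def variance_contributions(vc: Mapping[str, float], J: int, K: int,
                           total_reps: int) -> pd.DataFrame:
    """Two percentage partitions of the fitted variances.

    ``phenotypic``: each model term's share of the total phenotypic variance
    (sum of all nine components). ``genotype_mean``: each component of
    sigma_P^2 (G, GY/K, GM/J, GMY/JK, residual/total_reps) as a share of
    sigma_P^2. Both columns sum to 100.
    """
    terms = list(MODEL_TERMS) + ["residual"]
    total = sum(float(vc.get(t, 0.0)) for t in terms)
    pheno = {t: (100.0 * float(vc.get(t, 0.0)) / total if total > 0 else 0.0)
             for t in terms}
    comps = {
        "G": float(vc.get("G", 0.0)),
        "GY/K": float(vc.get("GY", 0.0)) / K,
        "GM/J": float(vc.get("GM", 0.0)) / J,
        "GMY/JK": float(vc.get("GMY", 0.0)) / (J * K),
        "residual/reps": float(vc.get("residual", 0.0)) / total_reps,
    }
    sp = sum(comps.values())
    gmean = {k: (100.0 * v / sp if sp > 0 else 0.0) for k, v in comps.items()}
    out = pd.DataFrame({
        "partition": (["phenotypic"] * len(pheno)) + (["genotype_mean"] * len(gmean)),
        "component": list(pheno) + list(gmean),
        "percent": list(pheno.values()) + list(gmean.values()),
    })
    return out


def varcomp_table(results: Sequence[VarCompResult]) -> pd.DataFrame:
    """Wide per-trait summary: variance components, sigma_P^2, H^2, Ac."""
    rows = {}
    for res in results:
        sp, h2, ac = res.heritability()
        col = {f"sigma2_{t}": res.variances.get(t, 0.0) for t in MODEL_TERMS}
        col["sigma2_residual"] = res.variances.get("residual", 0.0)
        col["sigma2_P"] = sp
        col["H2"] = h2
        col["Ac"] = ac
        for term, pv in res.lrt_pvalues.items():
            col[f"p_{term}"] = pv
        rows[res.trait] = col
    return pd.DataFrame(rows)
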
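"""Heritability and genetic correlation over engineered features.

Given a kinship matrix K, a feature y is modeled by the linear mixed model
y = Xb + g + e with g ~ N(0, sg^2 K) and e ~ N(0, se^2 I); heritability
(PVE) is sg^2 / (sg^2 + se^2), estimated by maximum likelihood over the
variance ratio using the spectral decomposition of K (EMMA-style: one
eigendecomposition, then a 1-D optimization).  Because a mouse contributes
many runs, a representative run is drawn at random per mouse, the feature is
quantile-normalized to a standard normal, and the fit is repeated over many
draws; the median and IQR over draws are reported.  Significance is a
likelihood-ratio test of sg^2 = 0 against the boundary mixture
(chi2_0 + chi2_1)/2, Bonferroni-corrected over features.

Pairwise genetic correlation uses a bivariate mixed model with genetic and
environmental covariance, fitted by ML in the eigenbasis of K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# kinship

def compute_kinship(genotypes: np.ndarray) -> np.ndarray:
    """Centered-scaled dosage cross-product divided by marker count
    (VanRaden-style), projected to PSD if needed."""
    G = np.asarray(genotypes, float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("need a mice x markers dosage matrix")
    freq = np.nanmean(G, axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * freq * (1 - freq), 1e-12))
    Z = (G - 2 * freq[None, :]) / sd[None, :]
    Z = np.nan_to_num(Z)
    K = Z @ Z.T / G.shape[1]
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        w2, V = np.linalg.eigh(K)
        K = (V * np.clip(w2, 0, None)) @ V.T
    return (K + K.T) / 2.0


def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Map ranks to standard-normal quantiles (Blom offsets)."""
    y = np.asarray(y, float)
    n = y.size
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


# ---------------------------------------------------------------------------
# EMMA spectral ML

def _profile_loglik(log_delta: float, xi: np.ndarray, eta: np.ndarray) -> float:
    """Profile restricted log-likelihood over delta = se2/sg2, in the
    eigenbasis of the fixed-effect-projected kinship (sg2 profiled out)."""
    delta = np.exp(log_delta)
    m = eta.size
    q = float((eta * eta / (xi + delta)).sum())
    if q <= 0:
        return -np.inf
    return 0.5 * (m * (np.log(m / (2 * np.pi)) - 1.0 - np.log(q))
                  - np.log(xi + delta).sum())


def _project_spectrum(y, K, X):
    """Eigen-structure of S K S (S projects out the fixed effects), with
    the q null directions dropped, and the rotated phenotype."""
    n = y.size
    q = X.shape[1]
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    xi, U = np.linalg.eigh((S @ K @ S + (S @ K @ S).T) / 2.0)
    keep = np.argsort(xi)[q:]          # drop the q smallest (≈ 0)
    xi = np.clip(xi[keep], 0.0, None)
    eta = U[:, keep].T @ y
    return xi, eta


def emma_ml(y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None,
            grid: int = 100) -> dict:
    """Variance components by spectral maximum likelihood in the
    fixed-effect-projected space (the EMMA construction): one
    eigendecomposition of S K S, then a 1-D search over log(delta) on
    [-10, 10] refined by bounded scalar optimization.

    The projected (restricted) likelihood is used because the dosage-based
    kinship is singular in the intercept direction, where an unprojected
    ML profile degenerates.  Returns PVE = sg2/(sg2+se2) with K normalized
    to mean diagonal 1, the maximized log-likelihood, and the sg2 = 0
    limit for the boundary likelihood-ratio test.
    """
    y = np.asarray(y, float)
    n = y.size
    K = np.asarray(K, float)
    K = K / np.mean(np.diag(K))
    if X is None:
        X = np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    xi, eta = _project_spectrum(y, K, X)
    grid_pts = np.linspace(-10, 10, grid)
    vals = np.array([_profile_loglik(g, xi, eta) for g in grid_pts])
    i = int(np.nanargmax(vals))
    lo = grid_pts[max(i - 1, 0)]
    hi = grid_pts[min(i + 1, grid - 1)]
    res = optimize.minimize_scalar(lambda g: -_profile_loglik(g, xi, eta),
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    ll = float(-res.fun)
    delta = float(np.exp(res.x))
    pve = 1.0 / (1.0 + delta)
    # null model: sg2 = 0 is the delta -> inf limit of the same likelihood
    m = eta.size
    ll0 = float(0.5 * m * (np.log(m / (2 * np.pi)) - 1.0
                           - np.log((eta * eta).sum())))
    if ll < ll0:
        ll, pve = ll0, 0.0
    return {"pve": float(pve), "loglik": ll, "loglik_null": ll0,
            "delta": delta}


@dataclass
class HeritabilityEstimate:
    feature: str
    pve_median: float
    pve_iqr: tuple[float, float]
    per_draw: list = field(default_factory=list)
    p_value: float = np.nan
    significant: bool = False


def estimate_pve(y_runs: pd.DataFrame, K: np.ndarray,
                 covariates: pd.DataFrame | None = None,
                 n_draws: int = 100, seed: int = 0,
                 feature: str = "feature") -> HeritabilityEstimate:
    """PVE of one feature: per draw, sample one run per mouse, quantile
    normalize, fit the LMM with fixed effects of age and cohort, record
    PVE; report median/IQR and a boundary-mixture LRT p-value (median over
    draws).

    ``y_runs`` columns: mouse_id, value (+ optional age_months, cohort).
    K rows must align with sorted unique mouse ids.
    """
    rng = np.random.default_rng(seed)
    mice = sorted(y_runs["mouse_id"].unique())
    if K.shape[0] != len(mice):
        raise ValueError("kinship not aligned to mice")
    groups = {m: g.index.to_numpy() for m, g in y_runs.groupby("mouse_id")}
    pves, lrts = [], []
    for _ in range(n_draws):
        idx = np.array([rng.choice(groups[m]) for m in mice])
        y = y_runs.loc[idx, "value"].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 10:
            continue
        yq = np.full(y.size, np.nan)
        yq[ok] = quantile_normalize(y[ok])
        cols = [np.ones(len(mice))]
        if "age_months" in y_runs.columns:
            cols.append(y_runs.loc[idx, "age_months"].to_numpy(float))
        if "cohort" in y_runs.columns:
            d = pd.get_dummies(y_runs.loc[idx, "cohort"], drop_first=True)
            for c in d.columns:
                cols.append(d[c].to_numpy(float))
        X = np.column_stack(cols)
        fit = emma_ml(yq[ok], K[np.ix_(ok, ok)], X[ok])
        pves.append(fit["pve"])
        lrts.append(max(2 * (fit["loglik"] - fit["loglik_null"]), 0.0))
    if not pves:
        return HeritabilityEstimate(feature, np.nan, (np.nan, np.nan))
    pves = np.array(pves)
    lrt = float(np.median(lrts))
    # 1/2 chi2_0 + 1/2 chi2_1 boundary mixture
    p = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
    return HeritabilityEstimate(
        feature, float(np.median(pves)),
        (float(np.quantile(pves, 0.25)), float(np.quantile(pves, 0.75))),
        pves.tolist(), float(p))


def heritability_table(features: pd.DataFrame, meta: pd.DataFrame,
                       K: np.ndarray, n_draws: int = 100, seed: int = 0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """PVE for every feature column with Bonferroni significance flags."""
    rows = []
    ests = []
    for j, name in enumerate(features.columns):
        df = pd.DataFrame({"mouse_id": meta["mouse_id"],
                           "value": features[name],
                           "age_months": meta["age_months"],
                           "cohort": meta["cohort"]})
        df = df[np.isfinite(df["value"])]
        if df.empty or df["mouse_id"].nunique() < 10:
            continue
        # restrict kinship to mice present
        mice_all = sorted(meta["mouse_id"].unique())
        mice = sorted(df["mouse_id"].unique())
        sel = [mice_all.index(m) for m in mice]
        est = estimate_pve(df.reset_index(drop=True), K[np.ix_(sel, sel)],
                           n_draws=n_draws, seed=seed + j, feature=name)
        ests.append(est)
    m = len(ests)
    for est in ests:
        est.significant = bool(est.p_value * m < alpha)
        rows.append({"feature": est.feature, "pve_median": est.pve_median,
                     "pve_q25": est.pve_iqr[0], "pve_q75": est.pve_iqr[1],
                     "p_value": est.p_value, "significant": est.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genetic correlation (bivariate LMM)

def _bivariate_nll(theta, lam, Y, X):
    """Negative log-likelihood of the bivariate LMM in the eigenbasis of K,
    with fixed effects profiled out by GLS.  2x2 covariances per eigenvalue
    are handled in closed form (vectorized).
    theta = (log sg1, log sg2, atanh rg, log se1, log se2, atanh re)."""
    sg1, sg2 = np.exp(theta[0]), np.exp(theta[1])
    rg = np.tanh(theta[2])
    se1, se2 = np.exp(theta[3]), np.exp(theta[4])
    re = np.tanh(theta[5])
    g12 = rg * np.sqrt(sg1 * sg2)
    e12 = re * np.sqrt(se1 * se2)
    s11 = lam * sg1 + se1
    s22 = lam * sg2 + se2
    s12 = lam * g12 + e12
    det = s11 * s22 - s12 * s12
    if np.any(det <= 1e-300):
        return 1e10
    i11, i22, i12 = s22 / det, s11 / det, -s12 / det
    p = X.shape[1]
    # profile fixed effects: stacked GLS normal equations
    XtX = X[:, :, None] * X[:, None, :]      # (n, p, p)
    A = np.zeros((2 * p, 2 * p))
    A[:p, :p] = (i11[:, None, None] * XtX).sum(0)
    A[p:, p:] = (i22[:, None, None] * XtX).sum(0)
    A[:p, p:] = (i12[:, None, None] * XtX).sum(0)
    A[p:, :p] = A[:p, p:].T
    b = np.concatenate([
        ((i11 * Y[:, 0] + i12 * Y[:, 1])[:, None] * X).sum(0),
        ((i12 * Y[:, 0] + i22 * Y[:, 1])[:, None] * X).sum(0)])
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e10
    mu1, mu2 = X @ beta[:p], X @ beta[p:]
    r1, r2 = Y[:, 0] - mu1, Y[:, 1] - mu2
    quad = i11 * r1 * r1 + 2 * i12 * r1 * r2 + i22 * r2 * r2
    n = lam.size
    return float(0.5 * (np.log(det).sum() + quad.sum()
                        + 2 * n * np.log(2 * np.pi)))


def genetic_correlation(y1: np.ndarray, y2: np.ndarray, K: np.ndarray,
                        X: np.ndarray | None = None) -> dict:
    """Genetic correlation rG (bivariate LMM, ML) and covariate-residualized
    phenotypic (partial) correlation rP for two features on shared mice."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = y1.size
    K = np.asarray(K, float)
    K = K / np.mean(np.diag(K))
    if X is None:
        X = np.ones((n, 1))
    lam, V = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    Y = np.column_stack([V.T @ y1, V.T @ y2])
    Xt = V.T @ X
    # rP: residualize on covariates in the original basis
    r1 = y1 - X @ np.linalg.lstsq(X, y1, rcond=None)[0]
    r2 = y2 - X @ np.linalg.lstsq(X, y2, rcond=None)[0]
    rp = float(np.corrcoef(r1, r2)[0, 1])
    v1, v2 = y1.var(), y2.var()
    rp_c = float(np.arctanh(np.clip(rp, -0.9, 0.9)))

    def start(gshare, rg0):
        return np.array([np.log(v1 * gshare + 1e-6), np.log(v2 * gshare + 1e-6),
                         rg0,
                         np.log(v1 * (1 - gshare) + 1e-6),
                         np.log(v2 * (1 - gshare) + 1e-6), rp_c])

    # the surface can have a genetic-light local optimum; multi-start NM
    starts = [start(0.5, rp_c), start(0.8, np.arctanh(np.clip(1.5 * rp, -0.95, 0.95))),
              start(0.2, rp_c)]
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x0 in starts:
            res = optimize.minimize(_bivariate_nll, x0, args=(lam, Y, Xt),
                                    method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-6,
                                             "fatol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        return {"rG": np.nan, "rP_partial": rp, "converged": False}
    rg = float(np.tanh(best.x[2]))
    return {"rG": rg, "rP_partial": rp, "converged": bool(best.success),
            "nll": float(best.fun)}
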
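"""Age-binned phenotype networks.

For each 3-month age bin we estimate a sparse Gaussian-copula graphical
model over the engineered features: a nonparanormal (rank-based) correlation
matrix, followed by a time-varying graphical lasso that fits one sparse
precision matrix per bin with an l1 sparsity penalty within bins and a
column-group ("perturbed node") smoothness penalty between adjacent bins.
Features are grouped by bootstrap consensus spectral clustering; network
summaries are the resilience statistic (1/2 log det of the correlation
matrix, i.e. the negative multivariate mutual information of the Gaussian
copula; 0 for independent features, increasingly negative with dependence)
and per-cluster connectivity (summed absolute partial correlation of edges
crossing the cluster boundary).

Sign convention: resilience <= 0 and *decreases* as dependence grows, so a
declining curve across age bins means a loss of resilience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# nonparanormal correlation

def nearest_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix
    (eigenvalue clipping + diagonal renormalization)."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() < eps:
        w = np.clip(w, eps, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def nonparanormal_corr(X: np.ndarray) -> np.ndarray:
    """Rank-based latent-Gaussian correlation: Spearman rho transformed by
    2 sin(pi rho / 6), projected to the nearest PD correlation matrix.
    Invariant to monotone transforms of the marginals.  Constant features
    get zero correlation to everything (with a warning).  NaNs are handled
    pairwise."""
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 runs and >= 2 features")
    const = np.array([np.nanstd(X[:, j]) == 0 or np.isfinite(X[:, j]).sum() < 2
                      for j in range(p)])
    if const.any():
        warnings.warn(f"{int(const.sum())} constant/empty features set to zero correlation")
    if np.isnan(X).any() or const.any():
        rho = pd.DataFrame(X).corr(method="spearman", min_periods=3).to_numpy()
        rho = np.where(np.isfinite(rho), rho, 0.0)
    else:
        rho = stats.spearmanr(X).statistic
        if np.ndim(rho) == 0:  # p == 2
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    R = 2.0 * np.sin(np.pi * rho / 6.0)
    R[const, :] = 0.0
    R[:, const] = 0.0
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    return nearest_correlation(R)


# ---------------------------------------------------------------------------
# time-varying graphical lasso (ADMM)

@dataclass
class PrecisionSet:
    """Per-age-bin sparse precision matrices with penalties and metadata."""
    bins: list                       # bin identifiers, ordered by age
    correlations: list[np.ndarray]
    precisions: list[np.ndarray]
    lambda_sparsity: float
    lambda_smooth: float
    n_runs: list[int] = field(default_factory=list)

    def partial_correlations(self) -> list[np.ndarray]:
        out = []
        for Th in self.precisions:
            d = np.sqrt(np.diag(Th))
            P = -Th / np.outer(d, d)
            np.fill_diagonal(P, 1.0)
            out.append(P)
        return out

    def edge_list(self, feature_names: list[str], threshold: float = 1e-8) -> pd.DataFrame:
        rows = []
        for b, P in zip(self.bins, self.partial_correlations()):
            iu = np.triu_indices_from(P, k=1)
            for i, j in zip(*iu):
                w = P[i, j]
                if abs(w) > threshold:
                    rows.append({"bin": b, "source": feature_names[i],
                                 "target": feature_names[j], "weight": float(w)})
        return pd.DataFrame(rows, columns=["bin", "source", "target", "weight"])


def _prox_logdet(S: np.ndarray, M: np.ndarray, eta: float) -> np.ndarray:
    """argmin <S,Th> - logdet Th + (eta/2)||Th - M||_F^2."""
    A = (M + M.T) / 2.0 - S / eta
    w, V = np.linalg.eigh(A)
    theta = (w + np.sqrt(w * w + 4.0 / eta)) / 2.0
    return (V * theta) @ V.T


def _soft_offdiag(A: np.ndarray, t: float) -> np.ndarray:
    Z = np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
    np.fill_diagonal(Z, np.diag(A))
    return (Z + Z.T) / 2.0


def _group_col_shrink(D: np.ndarray, t: float) -> np.ndarray:
    """Column-group soft threshold (perturbed-node style), symmetrized."""
    norms = np.linalg.norm(D, axis=0)
    scale = np.maximum(0.0, 1.0 - t / np.clip(norms, 1e-15, None))
    Z = D * scale[None, :]
    return (Z + Z.T) / 2.0


def fit_tvgl(correlations: list[np.ndarray], lambda_sparsity: float,
             lambda_smooth: float, rho: float = 1.0, max_iter: int = 800,
             tol: float = 1e-6) -> PrecisionSet:
    """Joint sparse precision estimation across ordered age bins by ADMM.

    Objective: sum_b [<R_b, Th_b> - logdet Th_b + lam1 ||Th_b||_1,offdiag]
    + lam2 sum_b psi(Th_b - Th_{b+1}) with psi a column-group norm.  With
    lambda_smooth = 0 each bin reduces to an independent graphical lasso.
    """
    if lambda_sparsity < 0 or lambda_smooth < 0:
        raise ValueError("penalties must be >= 0")
    B = len(correlations)
    Rs = []
    for R in correlations:
        R = np.asarray(R, float)
        w = np.linalg.eigvalsh(R)
        if w.min() <= 0:
            raise ValueError("correlation input not positive definite")
        Rs.append(R)
    p = Rs[0].shape[0]
    Theta = [np.linalg.inv(R + 1e-3 * np.eye(p)) for R in Rs]
    Z0 = [T.copy() for T in Theta]
    U0 = [np.zeros((p, p)) for _ in range(B)]
    W = [Theta[b].copy() for b in range(B - 1)]      # copy of Th_b
    V = [Theta[b + 1].copy() for b in range(B - 1)]  # copy of Th_{b+1}
    U1 = [np.zeros((p, p)) for _ in range(B - 1)]
    U2 = [np.zeros((p, p)) for _ in range(B - 1)]
    for it in range(max_iter):
        Theta_old = [T.copy() for T in Theta]
        for b in range(B):
            M = Z0[b] - U0[b]
            k = 1.0
            if b < B - 1:
                M = M + (W[b] - U1[b]); k += 1.0
            if b > 0:
                M = M + (V[b - 1] - U2[b - 1]); k += 1.0
            Theta[b] = _prox_logdet(Rs[b], M / k, rho * k)
        for b in range(B):
            Z0[b] = _soft_offdiag(Theta[b] + U0[b], lambda_sparsity / rho)
            U0[b] = U0[b] + Theta[b] - Z0[b]
        for b in range(B - 1):
            A = Theta[b] + U1[b]
            C = Theta[b + 1] + U2[b]
            if lambda_smooth == 0:
                W[b], V[b] = A, C
            else:
                D = _group_col_shrink(C - A, 2.0 * lambda_smooth / rho)
                S_ = A + C
                W[b] = (S_ - D) / 2.0
                V[b] = (S_ + D) / 2.0
            U1[b] = U1[b] + Theta[b] - W[b]
            U2[b] = U2[b] + Theta[b + 1] - V[b]
        prim = max(np.abs(Theta[b] - Z0[b]).max() for b in range(B))
        dual = max(np.abs(Theta[b] - Theta_old[b]).max() for b in range(B))
        if prim < tol and dual < tol and it > 10:
            break
    # report the sparse consensus variable (exact zeros from the l1 prox)
    return PrecisionSet(list(range(B)), Rs, [(Z + Z.T) / 2 for Z in Z0],
                        lambda_sparsity, lambda_smooth)


# ---------------------------------------------------------------------------
# resilience

def resilience(R: np.ndarray) -> float:
    """Negative multivariate mutual information of the Gaussian copula:
    1/2 log det R.  0 iff R is the identity, increasingly negative as
    dependence grows."""
    R = np.asarray(R, float)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    return 0.5 * float(logdet)


# ---------------------------------------------------------------------------
# consensus clustering

@dataclass
class ConsensusClusters:
    consensus: np.ndarray       # feature x feature co-clustering frequency at chosen k
    k: int
    assignments: np.ndarray
    exemplars: list[int]
    area: dict = field(default_factory=dict)        # k -> consensus CDF area
    delta_area: dict = field(default_factory=dict)  # k -> Monti relative delta


def _partial_corr_affinity(R: np.ndarray, ridge: float = 1e-2) -> np.ndarray:
    """Absolute partial-correlation affinity from a (ridge-stabilized)
    inverse correlation matrix."""
    p = R.shape[0]
    Th = np.linalg.inv(R + ridge * np.eye(p))
    d = np.sqrt(np.diag(Th))
    P = np.abs(-Th / np.outer(d, d))
    np.fill_diagonal(P, 1.0)
    return P


def _spectral(affinity: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import SpectralClustering
    sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                            assign_labels="kmeans", n_init=5,
                            random_state=int(seed % 2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.fit_predict(affinity)


def consensus_cluster(X: np.ndarray, B: int = 1000,
                      k_range=range(2, 13), seed: int = 0,
                      delta_threshold: float = 0.05) -> ConsensusClusters:
    """Bootstrap consensus spectral clustering of features.

    Each of B bootstrap resamples of runs re-estimates the dependency
    structure (nonparanormal correlation -> partial-correlation affinity)
    and is spectrally clustered at every k; the cluster count is chosen by
    the Monti delta-area criterion on the consensus CDF (largest k whose
    relative area increase exceeds ``delta_threshold``).  Exemplar of a
    cluster = member with maximal median consensus to its cluster."""
    if B < 2:
        raise ValueError("B must be >= 2")
    X = np.asarray(X, float)
    n, p = X.shape
    k_range = [k for k in k_range]
    if any(k < 2 or k > p - 1 for k in k_range):
        raise ValueError("k_range must lie within [2, p-1]")
    rng = np.random.default_rng(seed)
    counts = {k: np.zeros((p, p)) for k in k_range}
    for b in range(B):
        idx = rng.integers(0, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Rb = nonparanormal_corr(X[idx])
        Ab = _partial_corr_affinity(Rb)
        for k in k_range:
            lab = _spectral(Ab, k, seed + 7919 * b + k)
            same = lab[:, None] == lab[None, :]
            counts[k] += same
    consensus = {k: counts[k] / B for k in k_range}
    area, delta = {}, {}
    prev = None
    ks = sorted(k_range)
    for k in ks:
        M = consensus[k]
        iu = np.triu_indices(p, k=1)
        vals = np.sort(M[iu])
        # area under the empirical consensus CDF
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(vals, grid, side="right") / vals.size
        area[k] = float(np.trapezoid(cdf, grid))
        if prev is None:
            delta[k] = area[k]
        else:
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
        prev = area[k]
    chosen = ks[0]
    for k in ks:
        if delta[k] > delta_threshold:
            chosen = k
    M = consensus[chosen]
    lab = _spectral(M, chosen, seed + 1)
    exemplars = []
    for c in range(chosen):
        members = np.flatnonzero(lab == c)
        if members.size == 1:
            exemplars.append(int(members[0]))
            continue
        med = [float(np.median(M[m, members[members != m]])) for m in members]
        exemplars.append(int(members[int(np.argmax(med))]))
    return ConsensusClusters(M, chosen, lab, exemplars, area, delta)


# ---------------------------------------------------------------------------
# connectivity summaries

def cluster_connectivity(pset: PrecisionSet, assignments: np.ndarray) -> dict:
    """Per-bin, per-cluster summaries: inter-cluster connectivity (sum of
    |partial correlation| over edges crossing the cluster boundary) and
    intra-cluster resilience (1/2 log det of the cluster's sub-correlation
    matrix)."""
    assignments = np.asarray(assignments)
    p = pset.precisions[0].shape[0]
    if assignments.size != p:
        raise ValueError("assignments must cover all nodes")
    clusters = np.unique(assignments)
    inter = pd.DataFrame(index=pset.bins, columns=clusters, dtype=float)
    intra = pd.DataFrame(index=pset.bins, columns=clusters, dtype=float)
    for b, (P, R) in enumerate(zip(pset.partial_correlations(), pset.correlations)):
        A = np.abs(P.copy())
        np.fill_diagonal(A, 0.0)
        for c in clusters:
            mem = assignments == c
            inter.loc[pset.bins[b], c] = float(A[np.ix_(mem, ~mem)].sum())
            sub = R[np.ix_(mem, mem)]
            intra.loc[pset.bins[b], c] = resilience(nearest_correlation(sub))
    return {"inter_connectivity": inter, "intra_resilience": intra}


def resilience_curve(fm_values: np.ndarray, ages_months: np.ndarray,
                     min_runs: int = 20, min_shrinkage: float = 0.05,
                     min_eig: float = 1e-3) -> pd.DataFrame:
    """Overall resilience per 3-month age bin from the nonparanormal
    correlation of the per-bin feature matrix (bins with enough runs).

    When the feature count approaches the per-bin run count the raw
    correlation matrix is near-singular, so a single linear shrinkage
    toward the identity — the smallest intensity making every bin's matrix
    comfortably positive definite, shared across bins — is applied before
    taking the log-determinant.  A common intensity keeps the age bins
    comparable; shrinkage compresses the curve toward 0 but preserves its
    ordering."""
    from .features import assign_age_bins
    bins = assign_age_bins(ages_months)
    mats, used = [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < min_runs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R = nonparanormal_corr(fm_values[sel])
        mats.append(R)
        used.append((int(b), int(sel.sum())))
    if not mats:
        return pd.DataFrame(columns=["bin", "n_runs", "resilience"])
    alpha = min_shrinkage
    for R in mats:
        lam_min = float(np.linalg.eigvalsh(R).min())
        if lam_min < min_eig:
            alpha = max(alpha, (min_eig - lam_min) / (1.0 - lam_min))
    rows = []
    for (b, n), R in zip(used, mats):
        Rs = (1.0 - alpha) * R + alpha * np.eye(R.shape[0])
        rows.append({"bin": b, "n_runs": n, "resilience": resilience(Rs),
                     "shrinkage": alpha})
    return pd.DataFrame(rows)
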
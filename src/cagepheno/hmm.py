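"""Robust discrete-state HMM for behavioral-state segmentation of cage runs.

The model segments 3-minute bins into ``n_states`` behavioral states using 13
of the 14 base channels (body mass excluded).  Two robustness states are
appended to the chain: a *censored* state that models spurious zero readings
(high zero-probability, narrow emission at zero) and a *noise* state with
broad fixed dispersion that absorbs measurements implausible given the other
channels.  A per-analyzer additive offset on each gas channel is learned
jointly with the HMM parameters (batch correction for gas-sensor
calibration), identifiable up to a constant and therefore centered to mean
zero across analyzers.

Emissions are zero-inflated Gaussians per channel (count-like channels on a
log1p scale): a learned point mass at exactly zero plus a Gaussian for
nonzero values.  Cells masked by QC contribute nothing to the likelihood.
Fitting is EM (forward-backward in scaled linear space, numba-accelerated)
with k-means-initialized restarts; the training log-likelihood is
non-decreasing every iteration.  Model selection over the state count uses
held-out per-run log-likelihood and the one-standard-error rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .synth import BASE_CHANNELS, COUNT_LIKE_CHANNELS, GAS_CHANNELS, RawRun

HMM_CHANNELS = [c for c in BASE_CHANNELS if c != "BodyMass"]
_GAS_IDX = np.array([HMM_CHANNELS.index(c) for c in GAS_CHANNELS])
_LOG1P_IDX = np.array([HMM_CHANNELS.index(c) for c in COUNT_LIKE_CHANNELS])

_SIGMA_FLOOR = 1e-3
_PI_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# data preparation

def prepare_run(run: RawRun) -> dict:
    """Extract (transformed values, zero indicator, observed mask) from a
    cleaned run.  Count-like channels are log1p-transformed; exact zeros are
    modeled through the zero-inflation mass, not the Gaussian."""
    X = run.rows[HMM_CHANNELS].to_numpy(float).copy()
    zero = X == 0.0
    X[:, _LOG1P_IDX] = np.log1p(np.clip(X[:, _LOG1P_IDX], 0.0, None))
    qc_mask = getattr(run, "qc_mask", None)
    if qc_mask is not None:
        obs = qc_mask[HMM_CHANNELS].to_numpy() == 0
    else:
        obs = np.isfinite(X)
    obs = obs & np.isfinite(X)
    return {"X": X, "zero": zero, "obs": obs, "analyzer": run.analyzer_id,
            "run": run}


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _xi_sum(lik, T, alpha, beta, c):
    n, K = lik.shape
    xi = np.zeros((K, K))
    for t in range(n - 1):
        denom = c[t + 1]
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                xi[i, j] += ai * T[i, j] * lik[t + 1, j] * beta[t + 1, j] / denom
    return xi


@njit(cache=True)
def _forward(lik, T, pi):
    n, K = lik.shape
    alpha = np.empty((n, K))
    c = np.empty(n)
    a = pi * lik[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * lik[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


@njit(cache=True)
def _backward(lik, T, c):
    n, K = lik.shape
    beta = np.empty((n, K))
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        b = T @ (lik[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]
    return beta


# ---------------------------------------------------------------------------
# model

@dataclass
class RobustHMM:
    """Fitted robust HMM.  States 0..n_states-1 are behavioral; if
    ``robust_states`` then index n_states is 'censored' and n_states+1 is
    'noise'."""

    n_states: int
    robust_states: bool
    initial_probs: np.ndarray          # (K,)
    transition_matrix: np.ndarray      # (K, K)
    means: np.ndarray                  # (K, C) emission locations
    sigmas: np.ndarray                 # (K, C) emission dispersions
    zero_probs: np.ndarray             # (K, C) point mass at exactly 0
    analyzer_offsets: dict = field(default_factory=dict)  # id -> (n_gas,)
    update_mask: np.ndarray | None = None  # (K,) True where emissions learned
    loglik_trace: list = field(default_factory=list)
    seed: int = 0
    state_labels: list | None = None

    @property
    def n_total(self) -> int:
        return self.n_states + (2 if self.robust_states else 0)

    @property
    def censored_index(self):
        return self.n_states if self.robust_states else None

    @property
    def noise_index(self):
        return self.n_states + 1 if self.robust_states else None

    # -- serialization
    def to_json(self) -> str:
        d = {"n_states": self.n_states, "robust_states": self.robust_states,
             "initial_probs": self.initial_probs.tolist(),
             "transition_matrix": self.transition_matrix.tolist(),
             "means": self.means.tolist(), "sigmas": self.sigmas.tolist(),
             "zero_probs": self.zero_probs.tolist(),
             "analyzer_offsets": {a: v.tolist() for a, v in self.analyzer_offsets.items()},
             "seed": self.seed, "state_labels": self.state_labels,
             "channels": HMM_CHANNELS}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RobustHMM":
        d = json.loads(s)
        return cls(d["n_states"], d["robust_states"],
                   np.array(d["initial_probs"]), np.array(d["transition_matrix"]),
                   np.array(d["means"]), np.array(d["sigmas"]),
                   np.array(d["zero_probs"]),
                   {a: np.array(v) for a, v in d["analyzer_offsets"].items()},
                   seed=d["seed"], state_labels=d.get("state_labels"))


@dataclass
class StateSequence:
    run_id: str
    states: np.ndarray       # per-bin assignment (int), -1 never used
    posterior: np.ndarray    # posterior prob of the assignment
    labels: list | None = None


# ---------------------------------------------------------------------------
# emission log-likelihood

def _emission_loglik(model: RobustHMM, X, zero, obs, analyzer) -> np.ndarray:
    """(T, K) emission log-likelihoods; masked cells contribute nothing."""
    T_, C = X.shape
    K = model.n_total
    delta = model.analyzer_offsets.get(analyzer)
    Xadj = X
    if delta is not None and len(delta):
        Xadj = X.copy()
        Xadj[:, _GAS_IDX] -= delta[None, :]
    out = np.zeros((T_, K))
    use = obs
    nz = use & ~zero
    z = use & zero
    for k in range(K):
        mu, sg, pi0 = model.means[k], model.sigmas[k], model.zero_probs[k]
        # offsets apply to behavioral + noise states; censored stays at raw 0
        Xk = X if (model.robust_states and k == model.censored_index) else Xadj
        logphi = (-0.5 * np.log(2 * np.pi) - np.log(sg)[None, :]
                  - 0.5 * ((Xk - mu[None, :]) / sg[None, :]) ** 2)
        contrib = np.where(nz, np.log1p(-np.clip(pi0, 0, 1 - _PI_FLOOR))[None, :] + logphi, 0.0)
        contrib = np.where(z, np.log(np.clip(pi0, _PI_FLOOR, 1.0))[None, :], contrib)
        out[:, k] = contrib.sum(axis=1)
    return out


def _fb_run(model: RobustHMM, ll: np.ndarray):
    off = ll.max(axis=1)
    lik = np.exp(ll - off[:, None])
    alpha, c = _forward(lik, model.transition_matrix, model.initial_probs)
    beta = _backward(lik, model.transition_matrix, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = _xi_sum(lik, model.transition_matrix, alpha, beta, c)
    loglik = float(np.log(c).sum() + off.sum())
    return gamma, xi, loglik


def run_loglik(model: RobustHMM, prepared: dict) -> float:
    ll = _emission_loglik(model, prepared["X"], prepared["zero"],
                          prepared["obs"], prepared["analyzer"])
    off = ll.max(axis=1)
    lik = np.exp(ll - off[:, None])
    _, c = _forward(lik, model.transition_matrix, model.initial_probs)
    return float(np.log(c).sum() + off.sum())


# ---------------------------------------------------------------------------
# fitting

def _init_model(prepared: list[dict], n_states: int, robust_states: bool,
                seed: int) -> RobustHMM:
    from sklearn.cluster import KMeans
    rng = np.random.default_rng(seed)
    C = len(HMM_CHANNELS)
    # pool a subsample of observed timepoints
    chunks = []
    for p in prepared:
        X = p["X"]
        take = min(len(X), 2000)
        idx = rng.choice(len(X), take, replace=False)
        chunks.append(np.where(p["obs"][idx], X[idx], np.nan))
    P = np.vstack(chunks)
    col_mean = np.nanmean(P, axis=0)
    col_sd = np.nanstd(P, axis=0) + 1e-6
    Pf = np.where(np.isfinite(P), P, col_mean[None, :])
    Zs = (Pf - col_mean[None, :]) / col_sd[None, :]
    if n_states > 1:
        km = KMeans(n_clusters=n_states, n_init=1,
                    random_state=int(seed % 2**31)).fit(Zs)
        lab = km.labels_
    else:
        lab = np.zeros(len(Zs), dtype=int)
    K = n_states + (2 if robust_states else 0)
    means = np.tile(col_mean, (K, 1))
    sigmas = np.tile(col_sd, (K, 1))
    zero_probs = np.full((K, C), 0.05)
    for s in range(n_states):
        sel = lab == s
        if sel.sum() >= 2:
            means[s] = np.mean(Pf[sel], axis=0)
            sigmas[s] = np.clip(np.std(Pf[sel], axis=0), _SIGMA_FLOOR, None)
            zero_probs[s] = np.clip((Pf[sel] == 0).mean(axis=0), 0.01, 0.95)
    update = np.ones(K, dtype=bool)
    if robust_states:
        cen, noi = n_states, n_states + 1
        means[cen] = 0.0
        sigmas[cen] = np.clip(0.05 * col_sd, _SIGMA_FLOOR, None)
        zero_probs[cen] = 0.9
        means[noi] = col_mean
        sigmas[noi] = 5.0 * col_sd
        zero_probs[noi] = np.clip((Pf == 0).mean(axis=0), 0.01, 0.95)
        update[cen] = False   # location fixed at 0; zero mass still learned
        update[noi] = False   # broad fixed dispersion
    T = np.full((K, K), 0.2 / max(K - 1, 1)) + np.eye(K) * 0.8
    if robust_states:
        T[:, n_states:] = 0.01 / 2
        T /= T.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    analyzers = sorted({p["analyzer"] for p in prepared})
    offsets = {a: np.zeros(len(GAS_CHANNELS)) for a in analyzers}
    return RobustHMM(n_states, robust_states, pi, T, means, sigmas,
                     zero_probs, offsets, update, seed=seed)


def _em(model: RobustHMM, prepared: list[dict], max_iter: int,
        tol: float, update_offsets: bool) -> RobustHMM:
    K, C = model.n_total, len(HMM_CHANNELS)
    analyzers = sorted(model.analyzer_offsets)
    a_index = {a: i for i, a in enumerate(analyzers)}
    prev = -np.inf
    for it in range(max_iter):
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        w_nz = np.zeros((K, C)); wx = np.zeros((K, C)); wx2 = np.zeros((K, C))
        w_obs = np.zeros((K, C)); w_zero = np.zeros((K, C))
        off_num = np.zeros((len(analyzers), len(GAS_CHANNELS)))
        off_den = np.zeros((len(analyzers), len(GAS_CHANNELS)))
        total_ll = 0.0
        gammas = []
        for p in prepared:
            ll = _emission_loglik(model, p["X"], p["zero"], p["obs"], p["analyzer"])
            gamma, xi, lrun = _fb_run(model, ll)
            total_ll += lrun
            pi_acc += gamma[0]
            xi_acc += xi
            gammas.append(gamma)
            X, zero, obs = p["X"], p["zero"], p["obs"]
            delta = model.analyzer_offsets[p["analyzer"]]
            Xadj = X.copy()
            Xadj[:, _GAS_IDX] -= delta[None, :]
            nzmask = obs & ~zero
            for k in range(K):
                g = gamma[:, k][:, None]
                w_obs[k] += (g * obs).sum(axis=0)
                w_zero[k] += (g * (obs & zero)).sum(axis=0)
                if model.update_mask[k]:
                    gm = g * nzmask
                    w_nz[k] += gm.sum(axis=0)
                    wx[k] += (gm * np.where(nzmask, Xadj, 0.0)).sum(axis=0)
                    wx2[k] += (gm * np.where(nzmask, Xadj, 0.0) ** 2).sum(axis=0)
            if update_offsets:
                ai = a_index[p["analyzer"]]
                behav = range(model.n_states)
                for gi, ci in enumerate(_GAS_IDX):
                    m = nzmask[:, ci]
                    for k in behav:
                        g = gamma[m, k]
                        inv = 1.0 / model.sigmas[k, ci] ** 2
                        off_num[ai, gi] += (g * (X[m, ci] - model.means[k, ci])).sum() * inv
                        off_den[ai, gi] += g.sum() * inv
        model.loglik_trace.append(total_ll)
        # M-step
        model.initial_probs = np.clip(pi_acc / pi_acc.sum(), 1e-12, None)
        model.initial_probs /= model.initial_probs.sum()
        Tn = xi_acc + 1e-10
        model.transition_matrix = Tn / Tn.sum(axis=1, keepdims=True)
        for k in range(K):
            # Beta pseudo-counts: the censored state keeps its prior mass
            # at zero (0.9) absent evidence, behavioral/noise states a
            # weak prior near zero
            if model.robust_states and k == model.censored_index:
                a_k, b_k = 9.0, 1.0
            else:
                a_k, b_k = 0.01, 0.1
            denom = w_obs[k] + a_k + b_k
            model.zero_probs[k] = np.clip((w_zero[k] + a_k) / denom,
                                          _PI_FLOOR, 1 - _PI_FLOOR)
            if model.update_mask[k]:
                nz = np.clip(w_nz[k], 1e-12, None)
                mu = wx[k] / nz
                var = np.clip(wx2[k] / nz - mu ** 2, _SIGMA_FLOOR ** 2, None)
                enough = w_nz[k] > 1.0
                model.means[k] = np.where(enough, mu, model.means[k])
                model.sigmas[k] = np.where(enough, np.sqrt(var), model.sigmas[k])
        if update_offsets and len(analyzers) > 1:
            new = np.where(off_den > 0, off_num / np.clip(off_den, 1e-12, None), 0.0)
            center = new.mean(axis=0)
            new -= center[None, :]
            for a in analyzers:
                model.analyzer_offsets[a] = new[a_index[a]]
            # compensate centering so behavioral means stay consistent
            for k in range(model.n_states):
                model.means[k, _GAS_IDX] += center
        if total_ll - prev < tol * (abs(prev) + 1.0) and it >= 2:
            break
        prev = total_ll
    return model


def fit_robust_hmm(runs: list[RawRun], n_states: int,
                   robust_states: bool = True, n_restarts: int = 3,
                   max_iter: int = 50, tol: float = 1e-6, seed: int = 0,
                   learn_offsets: bool = True) -> RobustHMM:
    """Fit the robust HMM by multi-restart EM; returns the best-likelihood
    model.  ``runs`` must be QC-cleaned (masked cells are skipped)."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if not runs:
        raise ValueError("need at least one run")
    prepared = [prepare_run(r) for r in runs]
    if not any(p["obs"].any() for p in prepared):
        raise ValueError("all cells masked: insufficient data")
    learn_offsets = learn_offsets and len({p["analyzer"] for p in prepared}) > 1
    best = None
    for r in range(n_restarts):
        model = _init_model(prepared, n_states, robust_states, seed + 1000 * r)
        model = _em(model, prepared, max_iter, tol, learn_offsets)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    best.state_labels = label_states(best)
    return best


# ---------------------------------------------------------------------------
# model selection

def select_n_states(train_runs, val_runs, k_range=range(1, 11), seed: int = 0,
                    n_restarts: int = 2, max_iter: int = 40,
                    robust_states: bool = True) -> dict:
    """Choose the state count by the one-standard-error rule on held-out
    per-run log-likelihood: smallest k whose mean is within 1 SE (across
    validation runs, at the argmax k) of the maximum."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    if not train_runs or not val_runs:
        raise ValueError("both split halves must be non-empty")
    val_prepared = [prepare_run(r) for r in val_runs]
    means, ses, per_run = {}, {}, {}
    for k in k_range:
        model = fit_robust_hmm(train_runs, k, robust_states=robust_states,
                               n_restarts=n_restarts, max_iter=max_iter,
                               seed=seed + k)
        lls = np.array([run_loglik(model, p) for p in val_prepared])
        per_run[k] = lls
        means[k] = float(lls.mean())
        ses[k] = float(lls.std(ddof=1) / np.sqrt(len(lls))) if len(lls) > 1 else 0.0
    k_best = max(means, key=means.get)
    threshold = means[k_best] - ses[k_best]
    selected = min(k for k in k_range if means[k] >= threshold)
    return {"selected": selected, "argmax": k_best, "means": means,
            "ses": ses, "per_run": per_run}


# ---------------------------------------------------------------------------
# decoding and labeling

def decode(model: RobustHMM, run: RawRun) -> StateSequence:
    """Per-bin posterior-argmax state assignment under forward-backward."""
    p = prepare_run(run)
    if len(p["X"]) == 0:
        return StateSequence(f"{run.mouse_id}_r{run.run_number:02d}",
                             np.empty(0, int), np.empty(0))
    ll = _emission_loglik(model, p["X"], p["zero"], p["obs"], p["analyzer"])
    gamma, _, _ = _fb_run(model, ll)
    states = gamma.argmax(axis=1)
    post = gamma[np.arange(len(states)), states]
    return StateSequence(f"{run.mouse_id}_r{run.run_number:02d}",
                         states, post, labels=model.state_labels)


def label_states(model: RobustHMM) -> list[str]:
    """Deterministic naming of six behavioral states from emission profiles:
    Run = max wheel; Eat&Drink = max food+water among the rest; Eat = max
    food among the rest; Sleep = min activity (energy expenditure + movement);
    Rest = next lowest; Active = remainder.  Non-6-state models get generic
    labels.  Robustness states are always 'Censored'/'Noise'."""
    n = model.n_states
    extra = ["Censored", "Noise"] if model.robust_states else []
    if n != 6:
        return [f"state_{i + 1}" for i in range(n)] + extra
    ch = {c: HMM_CHANNELS.index(c) for c in HMM_CHANNELS}
    # expected emission value = (1 - pi0) * mean
    em = (1.0 - model.zero_probs[:n]) * model.means[:n]
    labels = [None] * n
    remaining = set(range(n))

    def take(idx, name):
        labels[idx] = name
        remaining.discard(idx)

    wheel = em[:, ch["WheelMeters"]]
    run_idx = int(np.argmax(wheel))
    take(run_idx, "Run")
    food, water = em[:, ch["Food"]], em[:, ch["Water"]]
    ed = max(remaining, key=lambda i: (food[i] + water[i], em[i, ch["EE"]]))
    take(ed, "EatDrink")
    eat = max(remaining, key=lambda i: (food[i], em[i, ch["EE"]]))
    take(eat, "Eat")
    activity = em[:, ch["EE"]] + em[:, ch["AllMeters"]]
    sleep = min(remaining, key=lambda i: (activity[i], -em[i, ch["EE"]]))
    take(sleep, "Sleep")
    rest = min(remaining, key=lambda i: (activity[i], -em[i, ch["EE"]]))
    take(rest, "Rest")
    take(next(iter(remaining)), "Active")
    return labels + extra


def match_states(model: RobustHMM, true_means: np.ndarray) -> np.ndarray:
    """Hungarian matching of fitted behavioral states to generative profiles
    (on transformed emission means); returns perm with perm[true] = fitted."""
    from scipy.optimize import linear_sum_assignment
    n = model.n_states
    tm = true_means.copy()
    tm[:, _LOG1P_IDX] = np.log1p(np.clip(tm[:, _LOG1P_IDX], 0, None))
    fitted = (1.0 - model.zero_probs[:n]) * model.means[:n]
    scale = tm.std(axis=0) + 1e-6
    cost = ((tm[:, None, :] / scale - fitted[None, :, :] / scale) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(n, dtype=int)
    perm[rows] = cols
    return perm
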
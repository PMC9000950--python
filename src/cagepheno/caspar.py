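"""CASPAR: combined age and survival prediction of aging rate.

An accelerated-failure-time-style model with a latent per-animal aging rate.
A reference lifespan distribution (Gumbel on log lifespan, fitted by maximum
likelihood on left-truncated, right-censored records) defines the remaining
lifespan of a "reference mouse" at any age.  A predictor F(X) maps a run's
feature vector to a predicted biological age; the per-run observed aging
rate is b_ij = F(X_ij) / A_ij (A_ij = chronological age in months), each
mouse has a latent rate b_j ~ N(1, sigma_beta^2) and b_ij ~ N(b_j,
sigma_eps^2).  Training maximizes, over mice that died,

    sum_runs log P(T_ij | age = F(X_ij))  +  log N(b_j-marginal of b_ij's)

where T_ij = log Y_ij - b_ij (Y_ij = time to death in months) is scored
against the log-remaining-life density of a reference mouse at age F(X_ij),
and the Gaussian factor marginalizes the latent rate in closed form
(covariance sigma_eps^2 I + sigma_beta^2 11').  sigma_beta interpolates
between a chronological-age clock (small sigma_beta) and a survival
regression (large sigma_beta).

F is a gradient-boosted tree ensemble (LightGBM) with this negative
log-likelihood as a custom objective (gradients by per-mouse central finite
differences); a linear learner is available for small tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# reference lifespan distribution

@dataclass
class ReferenceLifespanModel:
    location: float   # mu of Gumbel on log lifespan (log-months)
    scale: float      # s > 0
    loglik: float = np.nan
    n_used: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def _lifespan_loglik(mu: float, s: float, death_ages, censor_ages,
                     trunc_death, trunc_censor) -> float:
    g = stats.gumbel_r(mu, s)
    ll = 0.0
    if death_ages.size:
        ll += g.logpdf(np.log(death_ages)).sum()
        ok = trunc_death > 0
        ll -= g.logsf(np.log(trunc_death[ok])).sum()
    if censor_ages.size:
        ll += g.logsf(np.log(censor_ages)).sum()
        ok = trunc_censor > 0
        ll -= g.logsf(np.log(trunc_censor[ok])).sum()
    return float(ll)


def fit_reference_lifespan(records) -> ReferenceLifespanModel:
    """MLE of the Gumbel distribution on log lifespan from left-truncated
    (enrollment), right-censored lifespan records."""
    death_ages = np.array([r.event_age for r in records if r.event == "died"])
    censor_ages = np.array([r.event_age for r in records if r.event == "censored"])
    trunc_death = np.array([r.enrollment_age for r in records if r.event == "died"])
    trunc_censor = np.array([r.enrollment_age for r in records if r.event == "censored"])
    if death_ages.size == 0:
        raise ValueError("need at least one death event")
    logy = np.log(death_ages)
    x0 = np.array([logy.mean(), max(logy.std() * 0.7797, 1e-2)])

    def nll(theta):
        mu, log_s = theta
        return -_lifespan_loglik(mu, np.exp(log_s), death_ages, censor_ages,
                                 trunc_death, trunc_censor)

    res = optimize.minimize(nll, np.array([x0[0], np.log(x0[1])]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, s = float(res.x[0]), float(np.exp(res.x[1]))
    return ReferenceLifespanModel(mu, s, -float(res.fun),
                                  len(records), bool(res.success))


def observed_information_se(model: ReferenceLifespanModel, records,
                            h: float = 1e-4) -> np.ndarray:
    """Standard errors of (location, scale) from the numeric observed
    information at the MLE."""
    death_ages = np.array([r.event_age for r in records if r.event == "died"])
    censor_ages = np.array([r.event_age for r in records if r.event == "censored"])
    td = np.array([r.enrollment_age for r in records if r.event == "died"])
    tc = np.array([r.enrollment_age for r in records if r.event == "censored"])

    def ll(theta):
        return _lifespan_loglik(theta[0], theta[1], death_ages, censor_ages, td, tc)

    x = np.array([model.location, model.scale])
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            H[i, j] = (ll(x + e_i + e_j) - ll(x + e_i - e_j)
                       - ll(x - e_i + e_j) + ll(x - e_i - e_j)) / (4 * h * h)
    cov = np.linalg.inv(-H)
    return np.sqrt(np.diag(cov))


def remaining_life_logdensity(ref: ReferenceLifespanModel, age: float,
                              y) -> np.ndarray:
    """Log density of remaining lifespan y (months) for a reference mouse of
    the given age, i.e. total lifespan age+y conditional on survival past
    age.  Vectorized over y."""
    if age < 0:
        raise ValueError("age must be >= 0")
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("y must be > 0")
    g = stats.gumbel_r(ref.location, ref.scale)
    total = age + y
    ld = g.logpdf(np.log(total)) - np.log(total)
    if age > 0:
        lsf = g.logsf(np.log(age))
        if not np.isfinite(lsf) or lsf < -700:
            raise ValueError("survival past this age is numerically zero")
        ld = ld - lsf
    return ld


def log_remaining_logdensity(ref: ReferenceLifespanModel, age: float,
                             t) -> np.ndarray:
    """Density of T = log(remaining life) at predicted age (adds the e^t
    Jacobian to :func:`remaining_life_logdensity`)."""
    t = np.asarray(t, float)
    return remaining_life_logdensity(ref, age, np.exp(t)) + t


# ---------------------------------------------------------------------------
# Gaussian marginal over the latent aging rate

def gaussian_marginal_loglik(beta_hats: np.ndarray, sigma_beta_sq: float,
                             sigma_eps_sq: float) -> float:
    """Closed-form log of int prod_i N(b_i | b, se2) N(b | 1, sb2) db:
    a multivariate normal with mean 1 and covariance se2 I + sb2 11'."""
    b = np.asarray(beta_hats, float) - 1.0
    m = b.size
    se2, sb2 = float(sigma_eps_sq), float(sigma_beta_sq)
    # Sherman-Morrison: inv = I/se2 - (sb2/se2) 11' / (se2 + m sb2)
    ssum = b.sum()
    quad = (b @ b) / se2 - sb2 * ssum * ssum / (se2 * (se2 + m * sb2))
    logdet = (m - 1) * np.log(se2) + np.log(se2 + m * sb2)
    return float(-0.5 * (m * np.log(2 * np.pi) + logdet + quad))


def gaussian_marginal_quadrature(beta_hats: np.ndarray, sigma_beta_sq: float,
                                 sigma_eps_sq: float, n_points: int = 50) -> float:
    """Gauss-Hermite quadrature oracle for the same marginal."""
    b = np.asarray(beta_hats, float)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    sb = np.sqrt(sigma_beta_sq)
    vals = []
    for z, w in zip(nodes, weights):
        beta_j = 1.0 + sb * z
        ll = stats.norm.logpdf(b, beta_j, np.sqrt(sigma_eps_sq)).sum()
        vals.append(np.log(w) + ll)
    from scipy.special import logsumexp
    return float(logsumexp(vals) - 0.5 * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# dataset and objective

@dataclass
class CasparConfig:
    sigma_beta_sq: float = 9.0       # prior variance of the latent rate (sigma_beta=3)
    sigma_eps_sq: float = 1.0
    n_rounds: int = 200
    max_depth: int = 3
    learning_rate: float = 0.05
    min_data_in_leaf: int = 10
    n_splits: int = 15
    holdout_fraction: float = 0.10
    t_convention: str = "aft"        # aft: T = log Y + log b | literal: log Y - b | log_ratio: log Y - log b
    learner: str = "lgbm"            # lgbm | linear
    seed: int = 0

    def __post_init__(self):
        if self.sigma_beta_sq <= 0 or self.sigma_eps_sq <= 0:
            raise ValueError("variances must be > 0")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction in (0,1)")
        if self.t_convention not in ("aft", "literal", "log_ratio"):
            raise ValueError("t_convention must be aft|literal|log_ratio")


@dataclass
class CasparData:
    """Aligned run-level arrays for mice with observed deaths."""
    X: np.ndarray            # runs x features
    ages: np.ndarray         # A_ij, months
    ttd: np.ndarray          # Y_ij = time to death from the run, months
    mouse_index: np.ndarray  # dense 0..n_mice-1 per run
    mouse_ids: list
    feature_names: list


def build_caspar_data(values: pd.DataFrame, meta: pd.DataFrame,
                      lifespans: pd.DataFrame) -> CasparData:
    """Join features with metadata and lifespans, keeping only runs of mice
    that died; errors if a censored mouse slips in."""
    death = lifespans.set_index("mouse_id")
    keep, ages, ttd, mids = [], [], [], []
    for i, row in meta.iterrows():
        m = row["mouse_id"]
        if m not in death.index or death.loc[m, "event"] != "died":
            continue
        y = float(death.loc[m, "event_age"]) - float(row["age_months"])
        if y <= 0:
            continue
        keep.append(i)
        ages.append(float(row["age_months"]))
        ttd.append(y)
        mids.append(m)
    if not keep:
        raise ValueError("no runs from dead mice")
    uniq = sorted(set(mids))
    midx = {m: k for k, m in enumerate(uniq)}
    return CasparData(values.iloc[keep].to_numpy(float), np.array(ages),
                      np.array(ttd), np.array([midx[m] for m in mids]),
                      uniq, list(values.columns))


class _Objective:
    """Negative marginal log-likelihood as a function of raw scores g, with
    F = exp(g).

    The survival factor scores T against the log-remaining-life density of
    a reference mouse at age F(X); because each animal dies once, the
    survival term is averaged over the animal's runs (one death event per
    mouse), while the Gaussian rate-consistency factor couples all of its
    runs.  T conventions: 'aft' (default, T = log Y + log b: reference
    remaining life Z = b Y at the predicted age, the accelerated-failure-
    time reading), 'literal' (T = log Y - b) and 'log_ratio'
    (T = log Y - log b).

    Everything is vectorized per mouse via bincount, and gradients /
    Hessian diagonals come from central finite differences applied to one
    run position of every mouse simultaneously (2 * max_runs + 1 vector
    sweeps per call).
    """

    def __init__(self, data: CasparData, ref: ReferenceLifespanModel,
                 config: CasparConfig):
        self.d = data
        self.ref = ref
        self.cfg = config
        self.logY = np.log(data.ttd)
        self.mi = data.mouse_index
        self.n_mice = int(self.mi.max()) + 1
        self.m_counts = np.bincount(self.mi, minlength=self.n_mice).astype(float)
        # position of each run within its mouse (0-based)
        order = np.argsort(self.mi, kind="stable")
        pos = np.empty_like(self.mi)
        pos[order] = np.arange(len(self.mi)) - np.repeat(
            np.cumsum(np.concatenate([[0], self.m_counts[:-1].astype(int)])),
            self.m_counts.astype(int))
        self.pos = pos
        self.max_m = int(self.m_counts.max())

    def _gumbel_logpdf(self, z):
        u = (z - self.ref.location) / self.ref.scale
        return -np.log(self.ref.scale) - u - np.exp(-u)

    def _gumbel_logsf(self, z):
        u = (z - self.ref.location) / self.ref.scale
        with np.errstate(over="ignore"):
            sf = -np.expm1(-np.exp(-u))
        return np.log(np.clip(sf, 1e-300, None))

    def by_mouse(self, g: np.ndarray) -> np.ndarray:
        """Per-mouse negative log-likelihood vector."""
        F = np.exp(g)
        A = self.d.ages
        beta = F / A
        conv = self.cfg.t_convention
        if conv == "literal":
            T = self.logY - beta
        elif conv == "log_ratio":
            T = self.logY - np.log(np.clip(beta, 1e-8, None))
        else:  # aft
            T = self.logY + np.log(np.clip(beta, 1e-8, None))
        with np.errstate(over="ignore"):
            total = F + np.exp(T)
        ld = (self._gumbel_logpdf(np.log(total)) - np.log(total) + T
              - self._gumbel_logsf(np.log(np.clip(F, 1e-12, None))))
        ld = np.where(np.isfinite(ld), ld, -1e6)
        surv = np.bincount(self.mi, weights=ld, minlength=self.n_mice) / self.m_counts
        # closed-form Gaussian marginal per mouse (Sherman-Morrison)
        se2, sb2 = self.cfg.sigma_eps_sq, self.cfg.sigma_beta_sq
        b = beta - 1.0
        s1 = np.bincount(self.mi, weights=b, minlength=self.n_mice)
        s2 = np.bincount(self.mi, weights=b * b, minlength=self.n_mice)
        m = self.m_counts
        quad = s2 / se2 - sb2 * s1 * s1 / (se2 * (se2 + m * sb2))
        logdet = (m - 1) * np.log(se2) + np.log(se2 + m * sb2)
        gauss = -0.5 * (m * np.log(2 * np.pi) + logdet + quad)
        return -(surv + gauss)

    def value(self, g: np.ndarray) -> float:
        return float(self.by_mouse(g).sum())

    def grad_hess(self, g: np.ndarray, h: float = 1e-4):
        base = self.by_mouse(g)
        grad = np.zeros_like(g)
        hess = np.zeros_like(g)
        for p in range(self.max_m):
            sel = self.pos == p          # one run per mouse, all mice at once
            e = np.where(sel, h, 0.0)
            up = self.by_mouse(g + e)
            dn = self.by_mouse(g - e)
            mice = self.mi[sel]
            grad[sel] = (up[mice] - dn[mice]) / (2 * h)
            hess[sel] = (up[mice] - 2 * base[mice] + dn[mice]) / (h * h)
        bad = ~np.isfinite(hess) | (hess <= 1e-4)
        hess[bad] = 1.0  # damped curvature fallback
        grad[~np.isfinite(grad)] = 0.0
        return grad, hess


# ---------------------------------------------------------------------------
# model

@dataclass
class CasparModel:
    reference: ReferenceLifespanModel
    config: CasparConfig
    booster: object = None            # lightgbm.Booster or linear coef dict
    init_score: float = 0.0
    feature_names: list = field(default_factory=list)
    train_objective_trace: list = field(default_factory=list)

    def predict_biological_age(self, X: np.ndarray) -> np.ndarray:
        if self.booster is None:
            raise ValueError("model not fitted")
        if isinstance(self.booster, dict):
            g = X @ self.booster["w"] + self.booster["b"]
        else:
            g = self.booster.predict(X, raw_score=True) + self.init_score
        return np.exp(g)


def fit_caspar(data: CasparData, ref: ReferenceLifespanModel,
               config: CasparConfig) -> CasparModel:
    """Fit the biological-age predictor F by gradient boosting (or a linear
    learner) on the negative marginal log-likelihood."""
    obj = _Objective(data, ref, config)
    init = float(np.log(data.ages.mean()))
    model = CasparModel(ref, config, feature_names=data.feature_names,
                        init_score=init)
    if config.learner == "linear":
        Xs = np.nan_to_num(data.X)
        mu, sd = Xs.mean(0), Xs.std(0) + 1e-9
        Z = (Xs - mu) / sd
        p = Z.shape[1]

        def f(wb):
            return obj.value(Z @ wb[:p] + wb[p])

        res = optimize.minimize(f, np.zeros(p + 1), method="L-BFGS-B",
                                options={"maxiter": 300})
        w = res.x[:p] / sd
        b = res.x[p] - float(mu @ (res.x[:p] / sd))
        model.booster = {"w": w, "b": b}
        model.train_objective_trace = [float(res.fun)]
        return model

    import lightgbm as lgb

    def fobj(preds, _dataset):
        g = preds + init
        grad, hess = obj.grad_hess(g)
        return grad, hess

    def feval(preds, _dataset):
        return "neg_marginal_ll", obj.value(preds + init), False

    # small training sets: keep leaves feasible or LightGBM pre-filters
    # every feature away
    min_leaf = max(1, min(config.min_data_in_leaf, len(data.ages) // 8))
    params = {"objective": fobj, "max_depth": config.max_depth,
              "learning_rate": config.learning_rate,
              "min_data_in_leaf": min_leaf, "min_data_in_bin": 1,
              "feature_pre_filter": False,
              "num_leaves": 2 ** config.max_depth,
              "deterministic": True, "force_row_wise": True,
              "num_threads": 1, "seed": int(config.seed % 2**31),
              "verbosity": -1}
    train_set = lgb.Dataset(data.X, label=np.zeros(len(data.ages)),
                            free_raw_data=False)
    evals = {}
    booster = lgb.train(params, train_set, num_boost_round=config.n_rounds,
                        valid_sets=[train_set], valid_names=["train"],
                        feval=feval, callbacks=[lgb.record_evaluation(evals)])
    model.booster = booster
    if evals:
        model.train_objective_trace = list(evals["train"]["neg_marginal_ll"])
    return model


def feature_importance(model: CasparModel, top_n: int = 20) -> pd.DataFrame:
    """Gain-based feature importances, ranked, ties broken by name."""
    if model.booster is None or isinstance(model.booster, dict):
        return pd.DataFrame(columns=["feature", "gain"])
    gain = model.booster.feature_importance(importance_type="gain")
    names = [str(f) for f in model.feature_names] if model.feature_names else \
        model.booster.feature_name()
    df = pd.DataFrame({"feature": names[:len(gain)], "gain": gain})
    df = df.sort_values(["gain", "feature"], ascending=[False, True],
                        kind="mergesort").head(top_n).reset_index(drop=True)
    return df[df["gain"] > 0] if len(df) else df


# ---------------------------------------------------------------------------
# evaluation

def _pearson(a, b):
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def animal_splits(mouse_ids: list, n_splits: int, holdout_fraction: float,
                  seed: int) -> list[np.ndarray]:
    """Random full-animal holdout index sets (over mice), distinct across
    splits, each with >= 2 test mice."""
    rng = np.random.default_rng(seed)
    n = len(mouse_ids)
    k = max(2, int(round(holdout_fraction * n)))
    seen = set()
    splits = []
    while len(splits) < n_splits:
        test = tuple(sorted(rng.choice(n, k, replace=False).tolist()))
        if test in seen:
            continue
        seen.add(test)
        splits.append(np.array(test))
    return splits


def evaluate_splits(data: CasparData, ref: ReferenceLifespanModel,
                    sigma_beta_grid, config: CasparConfig) -> pd.DataFrame:
    """For each sigma_beta and each animal-holdout split: train on ~90% of
    mice, predict held-out runs, record Pearson correlation and R^2
    (squared correlation) of predicted biological age vs chronological age
    and vs time to death.  Reports per-sigma means, SEM and p = 2x median."""
    splits = animal_splits(data.mouse_ids, config.n_splits,
                           config.holdout_fraction, config.seed)
    rows = []
    for sb in sigma_beta_grid:
        cfg = CasparConfig(**{**config.__dict__, "sigma_beta_sq": float(sb) ** 2})
        for si, test_mice in enumerate(splits):
            test_mask = np.isin(data.mouse_index, test_mice)
            tr = _subset(data, ~test_mask)
            te = _subset(data, test_mask)
            model = fit_caspar(tr, ref, cfg)
            pred = model.predict_biological_age(te.X)
            r_age, p_age = _pearson(pred, te.ages)
            r_ttd, p_ttd = _pearson(pred, te.ttd)
            rows.append({"sigma_beta": float(sb), "split": si,
                         "r_age": r_age, "r_ttd": r_ttd,
                         "p_age": p_age, "p_ttd": p_ttd})
    per = pd.DataFrame(rows)
    agg = per.groupby("sigma_beta").agg(
        mean_r_age=("r_age", "mean"), sem_r_age=("r_age", "sem"),
        mean_r_ttd=("r_ttd", "mean"), sem_r_ttd=("r_ttd", "sem"),
        med_p_age=("p_age", "median"), med_p_ttd=("p_ttd", "median"),
    ).reset_index()
    agg["mean_R2_age"] = per.groupby("sigma_beta")["r_age"].apply(
        lambda s: float((s ** 2).mean())).to_numpy()
    agg["mean_R2_ttd"] = per.groupby("sigma_beta")["r_ttd"].apply(
        lambda s: float((s ** 2).mean())).to_numpy()
    agg["p_age"] = np.minimum(2 * agg.pop("med_p_age"), 1.0)
    agg["p_ttd"] = np.minimum(2 * agg.pop("med_p_ttd"), 1.0)
    agg.attrs["per_split"] = per
    return agg


def _subset(data: CasparData, mask: np.ndarray) -> CasparData:
    mids = [data.mouse_ids[k] for k in np.unique(data.mouse_index[mask])]
    remap = {data.mouse_ids.index(m): i for i, m in enumerate(mids)}
    return CasparData(data.X[mask], data.ages[mask], data.ttd[mask],
                      np.array([remap[k] for k in data.mouse_index[mask]]),
                      mids, data.feature_names)


def predicted_rates(model: CasparModel, data: CasparData) -> pd.DataFrame:
    """Per-run predicted biological age and rate b_ij; per-mouse b_j is the
    arithmetic mean of the mouse's b_ij."""
    F = model.predict_biological_age(data.X)
    bij = F / data.ages
    df = pd.DataFrame({"mouse_id": [data.mouse_ids[k] for k in data.mouse_index],
                       "age_months": data.ages, "ttd_months": data.ttd,
                       "predicted_age": F, "beta_ij": bij})
    df["beta_j"] = df.groupby("mouse_id")["beta_ij"].transform("mean")
    return df
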
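"""Feature engineering for cage runs.

From each QC'd, state-decoded run we derive 309 aggregate features in five
families (counts for the default 16-measurement / 6-state configuration):

1. overall          - run mean of each of 16 base measurements + occupancy
                      of each of 6 behavioral states           (16+6 = 22)
2. state_conditioned- measurement means conditioned on state  (16x6 = 96)
3. time_binned      - measurement means + occupancies in six 4-hour bins
                      aligned to lights-on                ((16+6)x6 = 132)
4. transition_ratio - pre/post ratio around each light transition
                                                         ((16+6)x2 = 44)
5. bout             - count, mean/max duration, mean/max inter-bout
                      interval for feeding, exercise, sleep   (5x3 = 15)

The 16 measurements are the 14 base channels plus WheelSpeed and PedSpeed
(distance per bin divided by bin duration).  Masked cells and bins assigned
to the robustness states are excluded from all means; only complete 24-hour
days of a run are used.  Two upstream corrections are applied first:
exposure (run-number) effects and body-mass normalization of gas channels
(to a 31 g reference; RQ untouched because it is a ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BASE_CHANNELS, BINS_PER_DAY, RawRun
from .hmm import StateSequence

MEASUREMENTS = BASE_CHANNELS + ["WheelSpeed", "PedSpeed"]
MASS_NORMALIZED_GAS = ["VO2", "VCO2", "EE", "VH2O"]  # RQ excluded: a ratio
REFERENCE_MASS_G = 31.0
BIN_HOURS = 3.0 / 60.0
DEFAULT_STATE_NAMES = ["Sleep", "Rest", "Eat", "EatDrink", "Run", "Active"]


# ---------------------------------------------------------------------------
# catalog

@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str           # overall | state_conditioned | time_binned | transition_ratio | bout
    measurement: str | None = None   # base measurement, or None for occupancy
    state: str | None = None
    time_bin: int | None = None      # 0..5 (4-h bins from lights-on)
    transition: str | None = None    # lights_on | lights_off
    bout_behavior: str | None = None
    bout_stat: str | None = None


BOUT_BEHAVIORS = ["feeding", "exercise", "sleep"]
BOUT_STATS = ["count", "mean_duration", "max_duration",
              "mean_interval", "max_interval"]


def build_catalog(state_names: list[str] | None = None,
                  measurements: list[str] | None = None) -> list[FeatureDef]:
    """The ordered feature catalog; 309 entries at the default config."""
    states = state_names or DEFAULT_STATE_NAMES
    meas = measurements or MEASUREMENTS
    defs: list[FeatureDef] = []
    for m in meas:
        defs.append(FeatureDef(f"mean_{m}", "overall", measurement=m))
    for s in states:
        defs.append(FeatureDef(f"occ_{s}", "overall", state=s))
    for m in meas:
        for s in states:
            defs.append(FeatureDef(f"{m}|{s}", "state_conditioned",
                                   measurement=m, state=s))
    for b in range(6):
        lab = f"h{4 * b:02d}-{4 * b + 4:02d}"
        for m in meas:
            defs.append(FeatureDef(f"{m}@{lab}", "time_binned",
                                   measurement=m, time_bin=b))
        for s in states:
            defs.append(FeatureDef(f"occ_{s}@{lab}", "time_binned",
                                   state=s, time_bin=b))
    for tr in ("lights_on", "lights_off"):
        for m in meas:
            defs.append(FeatureDef(f"ratio_{m}@{tr}", "transition_ratio",
                                   measurement=m, transition=tr))
        for s in states:
            defs.append(FeatureDef(f"ratio_occ_{s}@{tr}", "transition_ratio",
                                   state=s, transition=tr))
    for b in BOUT_BEHAVIORS:
        for st in BOUT_STATS:
            defs.append(FeatureDef(f"bout_{b}_{st}", "bout",
                                   bout_behavior=b, bout_stat=st))
    names = [d.name for d in defs]
    assert len(names) == len(set(names)), "catalog names must be unique"
    return defs


def catalog_frame(catalog: list[FeatureDef]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in catalog])


# ---------------------------------------------------------------------------
# per-run measurement table

def measurement_table(run: RawRun, states: StateSequence,
                      n_behavioral: int = 6) -> pd.DataFrame:
    """Bin-level table of 16 measurements (masked cells -> NaN), decoded
    state (robustness states -> -1), circadian hour, limited to complete
    24-h days."""
    n = len(run.rows)
    n_days = n // BINS_PER_DAY
    n_use = n_days * BINS_PER_DAY
    if n_use == 0:
        raise ValueError("run shorter than one full day")
    vals = run.rows[BASE_CHANNELS].iloc[:n_use].to_numpy(float).copy()
    qc_mask = getattr(run, "qc_mask", None)
    if qc_mask is not None:
        vals[qc_mask[BASE_CHANNELS].iloc[:n_use].to_numpy() != 0] = np.nan
    df = pd.DataFrame(vals, columns=BASE_CHANNELS)
    df["WheelSpeed"] = df["WheelMeters"] / BIN_HOURS / 1000.0  # km/h
    df["PedSpeed"] = df["PedMeters"] / BIN_HOURS / 1000.0
    st = np.asarray(states.states[:n_use]).copy()
    st[st >= n_behavioral] = -1
    df["state"] = st
    ts = run.rows["timestamp"].iloc[:n_use].to_numpy(float)
    df["circadian_hour"] = (ts / 60.0) % 24.0
    df["light"] = run.rows["light"].iloc[:n_use].to_numpy()
    return df


# ---------------------------------------------------------------------------
# corrections

def correct_exposure(tables: list[pd.DataFrame], run_numbers: list[int],
                     measurements: list[str] | None = None) -> list[pd.DataFrame]:
    """Regress out run-number (cage exposure) effects, with run-number x
    state interactions, from every measurement; the model value ~ state +
    run_number + run_number:state is saturated in state, so it reduces to a
    per-state slope in run number.  Values are adjusted to the first
    exposure (run_number = 1); state main effects are preserved."""
    meas = measurements or MEASUREMENTS
    if len(set(run_numbers)) < 2:
        import warnings
        warnings.warn("single run number present; exposure correction is a no-op")
        return [t.copy() for t in tables]
    big = pd.concat(
        [t[["state"] + meas].assign(_rn=rn) for t, rn in zip(tables, run_numbers)],
        ignore_index=True)
    slopes: dict[tuple[int, str], float] = {}
    for s, grp in big.groupby("state"):
        rn = grp["_rn"].to_numpy(float)
        for m in meas:
            y = grp[m].to_numpy(float)
            ok = np.isfinite(y)
            if ok.sum() < 10 or np.ptp(rn[ok]) == 0:
                slopes[(s, m)] = 0.0
                continue
            r, yy = rn[ok], y[ok]
            rbar = r.mean()
            denom = ((r - rbar) ** 2).sum()
            slopes[(s, m)] = float(((r - rbar) * (yy - yy.mean())).sum() / denom) if denom > 0 else 0.0
    out = []
    for t, rn in zip(tables, run_numbers):
        t2 = t.copy()
        svec = t2["state"].to_numpy()
        for m in meas:
            adj = np.array([slopes.get((s, m), 0.0) for s in svec])
            t2[m] = t2[m] - adj * (rn - 1)
        out.append(t2)
    return out


def normalize_gas_for_mass(tables: list[pd.DataFrame], body_masses: list[float],
                           reference_mass: float = REFERENCE_MASS_G) -> list[pd.DataFrame]:
    """Adjust VO2/VCO2/EE/VH2O to a common reference body mass via per-state
    linear regression on mass (mass + mass:state model); RQ is untouched."""
    ok_runs = [i for i, bm in enumerate(body_masses) if np.isfinite(bm)]
    if len(ok_runs) < len(body_masses):
        import warnings
        warnings.warn("runs without body mass are left unadjusted")
    big = pd.concat(
        [tables[i][["state"] + MASS_NORMALIZED_GAS].assign(_bm=body_masses[i])
         for i in ok_runs], ignore_index=True)
    slopes: dict[tuple[int, str], float] = {}
    for s, grp in big.groupby("state"):
        bm = grp["_bm"].to_numpy(float)
        for m in MASS_NORMALIZED_GAS:
            y = grp[m].to_numpy(float)
            ok = np.isfinite(y)
            if ok.sum() < 10 or np.ptp(bm[ok]) == 0:
                slopes[(s, m)] = 0.0
                continue
            b, yy = bm[ok], y[ok]
            bbar = b.mean()
            denom = ((b - bbar) ** 2).sum()
            slopes[(s, m)] = float(((b - bbar) * (yy - yy.mean())).sum() / denom) if denom > 0 else 0.0
    out = []
    for i, t in enumerate(tables):
        t2 = t.copy()
        bm = body_masses[i]
        if not np.isfinite(bm):
            out.append(t2)
            continue
        svec = t2["state"].to_numpy()
        for m in MASS_NORMALIZED_GAS:
            adj = np.array([slopes.get((s, m), 0.0) for s in svec])
            t2[m] = t2[m] - adj * (bm - reference_mass)
        out.append(t2)
    return out


# ---------------------------------------------------------------------------
# bouts

@dataclass(frozen=True)
class BoutSpec:
    """Bout detection on raw 3-minute streams (not HMM states)."""
    behavior: str
    onset_threshold: float    # channel units per 3-min bin
    max_gap: int = 1          # bins bridged into one bout
    min_duration: int = 2     # bins

    def __post_init__(self):
        if self.onset_threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")


DEFAULT_BOUT_SPECS = {
    "feeding": BoutSpec("feeding", onset_threshold=0.01),
    "exercise": BoutSpec("exercise", onset_threshold=1.0),
    "sleep": BoutSpec("sleep", onset_threshold=0.0),
}


def _bout_signal(table: pd.DataFrame, behavior: str, spec: BoutSpec) -> np.ndarray:
    if behavior == "feeding":
        return table["Food"].to_numpy(float) > spec.onset_threshold
    if behavior == "exercise":
        return table["WheelMeters"].to_numpy(float) > spec.onset_threshold
    if behavior == "sleep":
        beams = (table["XBreak"].fillna(0) + table["YBreak"].fillna(0)
                 + table["ZBreak"].fillna(0)).to_numpy(float)
        wheel = table["WheelMeters"].fillna(0).to_numpy(float)
        return (beams <= spec.onset_threshold) & (wheel <= spec.onset_threshold)
    raise ValueError(f"unknown behavior {behavior!r}")


def detect_bouts(table: pd.DataFrame, spec: BoutSpec) -> pd.DataFrame:
    """Maximal runs of bins meeting the onset condition, merging gaps
    <= max_gap bins, dropping bouts shorter than min_duration.  Returns a
    table with start, end (exclusive), duration (bins) and the interval to
    the previous bout's end."""
    active = np.asarray(_bout_signal(table, spec.behavior, spec), bool)
    if not active.any():
        return pd.DataFrame(columns=["start", "end", "duration", "interval"])
    d = np.diff(active.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(len(active))
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= spec.max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    merged = [(s, e) for s, e in merged if e - s >= spec.min_duration]
    rows = []
    prev_end = None
    for s, e in merged:
        rows.append({"start": s, "end": e, "duration": e - s,
                     "interval": (s - prev_end) if prev_end is not None else np.nan})
        prev_end = e
    return pd.DataFrame(rows)


def bout_features(table: pd.DataFrame,
                  specs: dict[str, BoutSpec] | None = None) -> dict[str, float]:
    specs = specs or DEFAULT_BOUT_SPECS
    out = {}
    for b in BOUT_BEHAVIORS:
        bouts = detect_bouts(table, specs[b])
        n = len(bouts)
        out[f"bout_{b}_count"] = float(n)
        dur = bouts["duration"].to_numpy(float) if n else np.array([])
        iv = bouts["interval"].dropna().to_numpy(float) if n else np.array([])
        out[f"bout_{b}_mean_duration"] = float(dur.mean()) if n else np.nan
        out[f"bout_{b}_max_duration"] = float(dur.max()) if n else np.nan
        out[f"bout_{b}_mean_interval"] = float(iv.mean()) if iv.size else np.nan
        out[f"bout_{b}_max_interval"] = float(iv.max()) if iv.size else np.nan
    return out


# ---------------------------------------------------------------------------
# extraction

def extract_features(table: pd.DataFrame, catalog: list[FeatureDef],
                     state_names: list[str] | None = None,
                     bout_specs: dict[str, BoutSpec] | None = None) -> np.ndarray:
    """Emit the catalog's feature vector for one run's measurement table.

    A state never occupied in the run yields NaN for its conditioned
    features (missing, never zero-filled).
    """
    states = state_names or DEFAULT_STATE_NAMES
    sidx = {name: i for i, name in enumerate(states)}
    meas = [m for m in MEASUREMENTS if m in table.columns]
    svec = table["state"].to_numpy()
    behav = svec >= 0
    N = len(table)

    overall_mean = {m: float(np.nanmean(table[m].to_numpy(float)[behav]))
                    if behav.any() and np.isfinite(table[m].to_numpy(float)[behav]).any()
                    else np.nan for m in meas}
    occ = {name: float((svec == i).sum()) / N for name, i in sidx.items()}

    cond_mean: dict[tuple[str, str], float] = {}
    for name, i in sidx.items():
        sel = svec == i
        for m in meas:
            x = table[m].to_numpy(float)[sel]
            cond_mean[(m, name)] = float(np.nanmean(x)) if np.isfinite(x).sum() else np.nan

    tb = np.floor(table["circadian_hour"].to_numpy() / 4.0).astype(int)
    tb = np.clip(tb, 0, 5)
    tbin_mean: dict[tuple[str, int], float] = {}
    tbin_occ: dict[tuple[str, int], float] = {}
    for b in range(6):
        sel = tb == b
        nb = sel.sum()
        for m in meas:
            x = table[m].to_numpy(float)[sel & behav]
            tbin_mean[(m, b)] = float(np.nanmean(x)) if np.isfinite(x).sum() else np.nan
        for name, i in sidx.items():
            tbin_occ[(name, b)] = float((svec[sel] == i).sum()) / nb if nb else np.nan

    ch = table["circadian_hour"].to_numpy()
    windows = {
        "lights_on": (((ch >= 22.0), (ch < 2.0))),
        "lights_off": (((ch >= 10.0) & (ch < 12.0), (ch >= 12.0) & (ch < 14.0))),
    }

    def win_mean(m, sel):
        x = table[m].to_numpy(float)[sel & behav]
        return float(np.nanmean(x)) if np.isfinite(x).sum() else np.nan

    def win_occ(name, sel):
        n = sel.sum()
        return float((svec[sel] == sidx[name]).sum()) / n if n else np.nan

    ratio_meas: dict[tuple[str, str], float] = {}
    ratio_occ: dict[tuple[str, str], float] = {}
    for tr, (pre, post) in windows.items():
        for m in meas:
            a, b_ = win_mean(m, pre), win_mean(m, post)
            ratio_meas[(m, tr)] = a / b_ if (np.isfinite(a) and np.isfinite(b_)
                                             and abs(b_) > 1e-12) else np.nan
        for name in sidx:
            a, b_ = win_occ(name, pre), win_occ(name, post)
            ratio_occ[(name, tr)] = a / b_ if (np.isfinite(a) and np.isfinite(b_)
                                               and b_ > 1e-12) else np.nan

    bouts = bout_features(table, bout_specs)

    vec = np.empty(len(catalog))
    for i, d in enumerate(catalog):
        if d.family == "overall":
            vec[i] = overall_mean.get(d.measurement, np.nan) if d.measurement else occ.get(d.state, np.nan)
        elif d.family == "state_conditioned":
            vec[i] = cond_mean.get((d.measurement, d.state), np.nan)
        elif d.family == "time_binned":
            if d.measurement:
                vec[i] = tbin_mean.get((d.measurement, d.time_bin), np.nan)
            else:
                vec[i] = tbin_occ.get((d.state, d.time_bin), np.nan)
        elif d.family == "transition_ratio":
            if d.measurement:
                vec[i] = ratio_meas.get((d.measurement, d.transition), np.nan)
            else:
                vec[i] = ratio_occ.get((d.state, d.transition), np.nan)
        elif d.family == "bout":
            vec[i] = bouts.get(d.name, np.nan)
        else:  # pragma: no cover
            raise ValueError(d.family)
    return vec


@dataclass
class FeatureMatrix:
    """Runs x features with per-run metadata (mouse, age, run number...)."""
    values: pd.DataFrame       # rows = runs, columns = catalog names
    meta: pd.DataFrame         # mouse_id, age_months, run_number, cohort, analyzer
    catalog: list[FeatureDef]

    def __post_init__(self):
        assert list(self.values.columns) == [d.name for d in self.catalog]
        assert len(self.values) == len(self.meta)


def build_feature_matrix(runs: list[RawRun], sequences: list[StateSequence],
                         lifespans: pd.DataFrame | None = None,
                         catalog: list[FeatureDef] | None = None,
                         state_names: list[str] | None = None,
                         apply_corrections: bool = True) -> FeatureMatrix:
    """Full feature stage: measurement tables -> exposure correction ->
    body-mass normalization -> 309-feature extraction per run."""
    from .synth import DAYS_PER_MONTH
    catalog = catalog or build_catalog(state_names)
    n_behav = 6 if state_names is None else len(state_names)
    tables = [measurement_table(r, s, n_behavioral=n_behav)
              for r, s in zip(runs, sequences)]
    body_masses = [float(np.nanmean(t["BodyMass"])) for t in tables]
    if apply_corrections:
        tables = correct_exposure(tables, [r.run_number for r in runs])
        tables = normalize_gas_for_mass(tables, body_masses)
    vecs = [extract_features(t, catalog, state_names) for t in tables]
    values = pd.DataFrame(np.vstack(vecs), columns=[d.name for d in catalog])
    cohort_by_mouse = {}
    if lifespans is not None:
        cohort_by_mouse = dict(zip(lifespans["mouse_id"], lifespans["cohort_id"]))
    meta = pd.DataFrame({
        "mouse_id": [r.mouse_id for r in runs],
        "age_months": [r.start_age_days / DAYS_PER_MONTH for r in runs],
        "run_number": [r.run_number for r in runs],
        "cohort": [cohort_by_mouse.get(r.mouse_id, "c0") for r in runs],
        "analyzer": [r.analyzer_id for r in runs],
        "body_mass": body_masses,
    })
    return FeatureMatrix(values, meta, catalog)


# ---------------------------------------------------------------------------
# age bins and trend tests

TERMINAL_POOL_MONTHS = 33.0


def assign_age_bins(ages_months: np.ndarray) -> np.ndarray:
    """3-month age bins from age 0; ages >= 33 months pool into the terminal
    bin (index 11)."""
    ages = np.asarray(ages_months, float)
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    bins = np.floor(ages / 3.0).astype(int)
    bins[ages >= TERMINAL_POOL_MONTHS] = int(TERMINAL_POOL_MONTHS // 3)
    return bins


def age_bin_label(b: int) -> str:
    if b >= int(TERMINAL_POOL_MONTHS // 3):
        return f"[{int(TERMINAL_POOL_MONTHS)},41)"
    return f"[{3 * b},{3 * b + 3})"


def age_trend_tests(fm: FeatureMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Kendall-tau trend test of every feature against age, Bonferroni
    adjusted over the tested features."""
    ages = fm.meta["age_months"].to_numpy(float)
    if len(ages) < 10 or len(np.unique(ages)) < 2:
        raise ValueError("need >= 10 runs spanning >= 2 ages")
    rows = []
    for name in fm.values.columns:
        y = fm.values[name].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 10 or np.nanstd(y[ok]) == 0:
            rows.append({"feature": name, "tau": np.nan, "p": np.nan})
            continue
        tau, p = stats.kendalltau(ages[ok], y[ok])
        rows.append({"feature": name, "tau": float(tau), "p": float(p)})
    df = pd.DataFrame(rows)
    m = int(df["p"].notna().sum())
    df["p_adj"] = np.minimum(df["p"] * m, 1.0)
    df["significant"] = df["p_adj"] < alpha
    return df


# ---------------------------------------------------------------------------
# l1 trend filtering (group-fused second differences)

def _second_diff_matrix(T: int) -> np.ndarray:
    D = np.zeros((T - 2, T))
    for t in range(T - 2):
        D[t, t], D[t, t + 1], D[t, t + 2] = 1.0, -2.0, 1.0
    return D


def trend_filter(X: np.ndarray, lam: float, rho: float = 1.0,
                 max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Solve min_Y 1/2 ||X-Y||_F^2 + lam * sum_t ||(D2 Y)_t||_2 by ADMM,
    where D2 takes second differences along rows (run index) and the l2
    norm couples features, yielding piecewise-linear fits with shared kink
    locations across features."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, float)
    T = X.shape[0]
    if lam == 0 or T < 3:
        return X.copy()
    D = _second_diff_matrix(T)
    A = np.eye(T) + rho * (D.T @ D)
    A_inv = np.linalg.inv(A)
    Z = D @ X
    U = np.zeros_like(Z)
    Y = X.copy()
    for _ in range(max_iter):
        Y_new = A_inv @ (X + rho * D.T @ (Z - U))
        DY = D @ Y_new
        V = DY + U
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        shrink = np.maximum(0.0, 1.0 - (lam / rho) / np.clip(norms, 1e-12, None))
        Z_new = shrink * V
        U = U + DY - Z_new
        if (np.linalg.norm(Y_new - Y) <= tol * (1 + np.linalg.norm(Y))
                and np.linalg.norm(Z_new - Z) <= tol * (1 + np.linalg.norm(Z))):
            Y, Z = Y_new, Z_new
            break
        Y, Z = Y_new, Z_new
    if np.all(Z == 0.0):
        # penalty strong enough to kill all curvature: exact solution is the
        # least-squares line per feature
        t = np.arange(T, dtype=float)
        G = np.column_stack([np.ones(T), t])
        coef, *_ = np.linalg.lstsq(G, X, rcond=None)
        return G @ coef
    return Y


def trend_filter_mouse(X: np.ndarray, lam: float, **kw) -> np.ndarray:
    """Standardize each feature across a mouse's runs, smooth with the
    group-fused trend filter, rescale back.  Mice with < 4 runs pass
    through unchanged; all-NaN or constant features pass through."""
    X = np.asarray(X, float)
    if X.shape[0] < 4 or lam == 0:
        return X.copy()
    out = X.copy()
    col_ok = np.array([np.isfinite(X[:, j]).all() and np.std(X[:, j]) > 0
                       for j in range(X.shape[1])])
    if not col_ok.any():
        return out
    sub = X[:, col_ok]
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    Y = trend_filter((sub - mu) / sd, lam, **kw)
    out[:, col_ok] = Y * sd + mu
    return out


def trend_filter_matrix(fm: FeatureMatrix, lam: float = 2.0) -> FeatureMatrix:
    """Apply the per-mouse trend filter across run index to a feature
    matrix (mice with >= 4 runs only, as-is otherwise)."""
    values = fm.values.copy()
    for mouse, idx in fm.meta.groupby("mouse_id").groups.items():
        order = fm.meta.loc[idx].sort_values("run_number").index
        X = values.loc[order].to_numpy(float)
        values.loc[order] = trend_filter_mouse(X, lam)
    return FeatureMatrix(values, fm.meta.copy(), fm.catalog)
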
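"""Synthetic metabolic-cage cohort generator.

Emulates the structure of an automated phenotyping study of aging mice:
multi-channel 3-minute cage time series with circadian structure, Markovian
latent behavioral states with state-specific emissions, per-analyzer gas
offsets, spurious-zero and burst sensor faults, age-dependent drift in state
occupancy and physiology, a latent per-animal aging rate, Gumbel (log
extreme-value) lifespans with staggered enrollment (left truncation) and
end-of-study right censoring, and polygenic effects over a simulated kinship.

Every quantity carries a known ground truth so downstream stages (QC, HMM,
feature engineering, networks, aging-rate regression, heritability) have a
recoverable target.  Fixing the seed fixes every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
BINS_PER_DAY = 480        # 3-minute cadence
BINS_PER_HOUR = 20
LIGHT_PERIOD_BINS = 240   # 12 h light / 12 h dark

BASE_CHANNELS = [
    "BodyMass", "Food", "Water", "WheelMeters", "PedMeters", "AllMeters",
    "XBreak", "YBreak", "ZBreak", "VO2", "VCO2", "EE", "RQ", "VH2O",
]
GAS_CHANNELS = ["VO2", "VCO2", "EE", "RQ", "VH2O"]
# channels whose emissions are count-like / heavily zero-inflated; the HMM
# models them on a log1p scale
COUNT_LIKE_CHANNELS = [
    "Food", "Water", "WheelMeters", "PedMeters", "AllMeters",
    "XBreak", "YBreak", "ZBreak",
]

STATE_NAMES_6 = ["Sleep", "Rest", "Eat", "EatDrink", "Run", "Active"]


@dataclass(frozen=True)
class ChannelSpec:
    """One of the 14 base 3-minute cage measurement channels."""

    name: str
    units: str
    valid_range: tuple[float, float]
    is_gas: bool = False
    cadence_minutes: int = 3

    def __post_init__(self):
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"{self.name}: valid_range low must be < high")
        if self.cadence_minutes != 3:
            raise ValueError("cadence fixed at 3 minutes")


def default_channel_specs() -> list[ChannelSpec]:
    """Permissive physiological ranges used for sensor-fault detection:
    0-10 for gas measurements, 5-80 g body mass, 0-2000 beam breaks;
    distance channels are bounded below at 0 only."""
    inf = float("inf")
    specs = [
        ChannelSpec("BodyMass", "g", (5.0, 80.0)),
        ChannelSpec("Food", "g", (0.0, inf)),
        ChannelSpec("Water", "g", (0.0, inf)),
        ChannelSpec("WheelMeters", "m", (0.0, inf)),
        ChannelSpec("PedMeters", "m", (0.0, inf)),
        ChannelSpec("AllMeters", "m", (0.0, inf)),
        ChannelSpec("XBreak", "count", (0.0, 2000.0)),
        ChannelSpec("YBreak", "count", (0.0, 2000.0)),
        ChannelSpec("ZBreak", "count", (0.0, 2000.0)),
        ChannelSpec("VO2", "mL/min", (0.0, 10.0), is_gas=True),
        ChannelSpec("VCO2", "mL/min", (0.0, 10.0), is_gas=True),
        ChannelSpec("EE", "kcal/hr", (0.0, 10.0), is_gas=True),
        ChannelSpec("RQ", "ratio", (0.0, 10.0), is_gas=True),
        ChannelSpec("VH2O", "mg/min", (0.0, 10.0), is_gas=True),
    ]
    return specs


# ---------------------------------------------------------------------------
# default generative state profiles

def default_state_profiles() -> tuple[np.ndarray, np.ndarray]:
    """(means, sds): 6 states x 14 channels, qualitatively matching the
    labeled behavioral states (Sleep, Rest, Eat, Eat&Drink, Run, Active).

    Units are per-3-minute-bin for intake/movement channels, rates for gas.
    """
    cols = {c: i for i, c in enumerate(BASE_CHANNELS)}
    means = np.zeros((6, 14))
    #                 Sleep  Rest   Eat    EatDrink  Run    Active
    prof = {
        "BodyMass":   [31.0, 31.0, 31.0, 31.0, 31.0, 31.0],
        "Food":       [0.00, 0.00, 0.060, 0.050, 0.000, 0.010],
        "Water":      [0.00, 0.00, 0.005, 0.050, 0.000, 0.010],
        "WheelMeters": [0.0, 0.0, 0.0, 0.0, 60.0, 8.0],
        "PedMeters":  [0.05, 0.40, 1.50, 2.00, 2.50, 6.00],
        "AllMeters":  [0.10, 0.80, 2.50, 3.20, 4.00, 9.00],
        "XBreak":     [2.0, 10.0, 30.0, 40.0, 50.0, 120.0],
        "YBreak":     [2.0, 8.0, 25.0, 35.0, 45.0, 110.0],
        "ZBreak":     [0.2, 2.0, 5.0, 8.0, 10.0, 30.0],
        "VO2":        [1.20, 1.40, 1.60, 1.80, 2.80, 2.40],
        "VCO2":       [0.96, 1.15, 1.47, 1.67, 2.46, 2.16],
        "EE":         [0.35, 0.42, 0.50, 0.55, 0.85, 0.72],
        "RQ":         [0.80, 0.82, 0.92, 0.93, 0.88, 0.90],
        "VH2O":       [0.50, 0.60, 0.80, 1.00, 1.40, 1.20],
    }
    for name, vals in prof.items():
        means[:, cols[name]] = vals
    # dispersion: proportional with a floor; body mass very tight
    sds = 0.15 * means + 0.02
    sds[:, cols["BodyMass"]] = 0.15
    return means, sds


def default_transition_matrices() -> tuple[np.ndarray, np.ndarray]:
    """Light- and dark-phase transition matrices (6 states, row-stochastic).

    Light phase is dominated by Sleep/Rest; the dark phase boosts Run/Active.
    """
    # order: Sleep Rest Eat EatDrink Run Active
    light = np.array([
        [0.92, 0.05, 0.01, 0.01, 0.002, 0.008],
        [0.25, 0.60, 0.06, 0.04, 0.01, 0.04],
        [0.10, 0.25, 0.45, 0.10, 0.02, 0.08],
        [0.08, 0.22, 0.12, 0.45, 0.03, 0.10],
        [0.02, 0.08, 0.05, 0.05, 0.60, 0.20],
        [0.05, 0.15, 0.08, 0.07, 0.15, 0.50],
    ])
    dark = np.array([
        [0.70, 0.12, 0.04, 0.04, 0.04, 0.06],
        [0.08, 0.42, 0.10, 0.08, 0.12, 0.20],
        [0.03, 0.10, 0.45, 0.12, 0.10, 0.20],
        [0.02, 0.08, 0.12, 0.45, 0.12, 0.21],
        [0.005, 0.02, 0.03, 0.035, 0.71, 0.20],
        [0.01, 0.05, 0.07, 0.07, 0.25, 0.55],
    ])
    light /= light.sum(axis=1, keepdims=True)
    dark /= dark.sum(axis=1, keepdims=True)
    return light, dark


def default_aging_effects() -> dict:
    """Age effects: additive emission drift (units per month of
    rate-adjusted age) and multiplicative occupancy drift on the log-odds of
    entering each state.  Signs follow the qualitative aging phenotypes:
    declining wheel running / energy expenditure / water loss, rising
    pedestrian movement, shift toward low-activity states."""
    emission_slopes = {c: 0.0 for c in BASE_CHANNELS}
    emission_slopes.update({
        "WheelMeters": -0.8,   # m/bin per month (Run-state wheel declines)
        "EE": -0.004,
        "VH2O": -0.008,
        "VO2": -0.010,
        "VCO2": -0.009,
        "Food": -0.0004,
        "Water": -0.0004,
        "PedMeters": 0.015,
        "AllMeters": 0.02,
        "YBreak": 0.4,
    })
    # per-month additive shift on destination-state log-odds
    occupancy_logodds = np.array([0.020, 0.018, 0.004, 0.002, -0.045, -0.030])
    return {"emission_slopes": emission_slopes,
            "occupancy_logodds": occupancy_logodds}


@dataclass
class CohortConfig:
    """Generative configuration of a synthetic cohort.

    Defaults emulate the study conditions: staggered enrollment, one 7-day
    run per 28-day cycle, six behavioral states with circadian transition
    structure, Gumbel lifespans on the log scale with median near 25 months,
    a latent per-animal aging rate with SD ``sigma_beta_true``, per-analyzer
    additive gas offsets, and rare spurious-zero / burst sensor faults.
    """

    n_mice: int = 40
    enrollment_ages: tuple[float, ...] = (3.0, 7.0, 14.0, 21.0, 25.0)  # months
    study_length: float = 18.0  # months of follow-up per mouse
    run_length_days: int = 7
    run_cycle_days: int = 28
    n_true_states: int = 6
    state_means: np.ndarray = field(default_factory=lambda: default_state_profiles()[0])
    state_sds: np.ndarray = field(default_factory=lambda: default_state_profiles()[1])
    transition_light: np.ndarray = field(default_factory=lambda: default_transition_matrices()[0])
    transition_dark: np.ndarray = field(default_factory=lambda: default_transition_matrices()[1])
    aging_effects: dict = field(default_factory=default_aging_effects)
    lifespan_location: float = float(np.log(25.0))  # log-months
    lifespan_scale: float = 0.25
    sigma_beta_true: float = 0.2
    fault_zero_rates: dict = field(default_factory=lambda: {c: 0.002 for c in GAS_CHANNELS})
    fault_burst_rates: dict = field(default_factory=lambda: {c: 0.001 for c in GAS_CHANNELS})
    burst_scale: float = 6.0  # bursts displace by ~scale x channel SD (heavy tailed)
    n_analyzers: int = 8
    analyzer_offset_sd: float = 0.25  # SD of per-analyzer gas-channel offsets
    channel_specs: list = field(default_factory=default_channel_specs)
    seed: int = 0

    def __post_init__(self):
        for name, T in (("transition_light", self.transition_light),
                        ("transition_dark", self.transition_dark)):
            T = np.asarray(T, float)
            if T.shape != (self.n_true_states, self.n_true_states):
                raise ValueError(f"{name} must be {self.n_true_states}x{self.n_true_states}")
            if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"{name} rows must sum to 1")
        if self.lifespan_scale <= 0:
            raise ValueError("lifespan_scale must be > 0")
        if self.sigma_beta_true < 0:
            raise ValueError("sigma_beta_true must be >= 0")
        if any(a < 0 for a in self.enrollment_ages):
            raise ValueError("enrollment ages must be >= 0")


@dataclass
class LifespanRecord:
    mouse_id: str
    enrollment_age: float       # months
    event_age: float            # months (death or censor)
    event: str                  # "died" | "censored"
    cohort_id: str = "c0"

    def __post_init__(self):
        if self.event_age < self.enrollment_age:
            raise ValueError("event_age must be >= enrollment_age")
        if self.event not in ("died", "censored"):
            raise ValueError("event must be died|censored")


@dataclass
class RawRun:
    """One mouse-week of 3-minute multichannel measurements.

    ``rows`` has columns timestamp (minutes from run start), light (0/1) and
    the 14 base channels.  ``truth`` (synthetic only) carries the generative
    state path, the sensor-fault mask, and the clean pre-fault values.
    """

    mouse_id: str
    run_number: int
    analyzer_id: str
    start_age_days: float
    rows: pd.DataFrame
    truth: dict | None = None

    @property
    def channels(self) -> pd.DataFrame:
        return self.rows[BASE_CHANNELS]

    @property
    def start_age_months(self) -> float:
        return self.start_age_days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# lifespans

def simulate_lifespans(n: int, location: float, scale: float,
                       enrollment: list[float] | np.ndarray,
                       study_length: float, seed: int,
                       cohort_ids: list[str] | None = None) -> list[LifespanRecord]:
    """Draw lifespans from exp(Gumbel(location, scale)) on log-months, with
    left truncation at enrollment (deaths before enrollment are resampled)
    and right censoring at enrollment + study_length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    enrollment = np.asarray(enrollment, float)
    if enrollment.size == 0:
        raise ValueError("enrollment schedule is empty")
    records = []
    for j in range(n):
        enroll = float(enrollment[j % enrollment.size])
        # left truncation: resample until survival past enrollment
        for _ in range(100_000):
            lifespan = float(np.exp(rng.gumbel(location, scale)))
            if lifespan > enroll:
                break
        else:  # pragma: no cover - unreachable at sane parameters
            raise RuntimeError("truncation resampling failed")
        horizon = enroll + study_length
        if lifespan > horizon:
            rec = LifespanRecord(f"m{j:04d}", enroll, horizon, "censored")
        else:
            rec = LifespanRecord(f"m{j:04d}", enroll, lifespan, "died")
        if cohort_ids is not None:
            rec.cohort_id = cohort_ids[j % len(cohort_ids)]
        records.append(rec)
    return records


def lifespan_frame(records: list[LifespanRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"mouse_id": [r.mouse_id for r in records],
         "enrollment_age": [r.enrollment_age for r in records],
         "event_age": [r.event_age for r in records],
         "event": [r.event for r in records],
         "cohort_id": [r.cohort_id for r in records]})


# ---------------------------------------------------------------------------
# runs

def _state_path(n_bins: int, light: np.ndarray, T_light: np.ndarray,
                T_dark: np.ndarray, occupancy_shift: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Sample a latent state path from the circadian-modulated Markov chain.

    ``occupancy_shift`` is an additive shift on destination log-odds
    (age x aging-rate effect on occupancy)."""
    K = T_light.shape[0]

    def shifted(T):
        logits = np.log(np.clip(T, 1e-12, None)) + occupancy_shift[None, :]
        P = np.exp(logits - logits.max(axis=1, keepdims=True))
        return P / P.sum(axis=1, keepdims=True)

    Tl, Td = shifted(T_light), shifted(T_dark)
    path = np.empty(n_bins, dtype=np.int64)
    # stationary-ish start: sleep-heavy if light
    p0 = Tl[0] if light[0] else Td[0]
    path[0] = rng.choice(K, p=p0)
    u = rng.random(n_bins)
    cum_l = np.cumsum(Tl, axis=1)
    cum_d = np.cumsum(Td, axis=1)
    for t in range(1, n_bins):
        cum = cum_l if light[t] else cum_d
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def simulate_run(mouse_id: str, run_number: int, start_age_days: float,
                 aging_rate: float, analyzer_id: str,
                 analyzer_offsets: dict[str, np.ndarray],
                 config: CohortConfig, seed: int,
                 body_mass: float = 31.0,
                 genetic_shift: np.ndarray | None = None) -> RawRun:
    """Simulate one cage run: latent circadian Markov path, state-specific
    Gaussian emissions shifted additively by aging_effects x age x
    aging_rate, analyzer offsets added to gas channels. Truth recorded."""
    if analyzer_id not in analyzer_offsets:
        raise KeyError(f"unknown analyzer id {analyzer_id!r}")
    rng = np.random.default_rng(seed)
    n_bins = config.run_length_days * BINS_PER_DAY
    tbins = np.arange(n_bins)
    light = ((tbins % BINS_PER_DAY) < LIGHT_PERIOD_BINS).astype(np.int8)
    age_months = start_age_days / DAYS_PER_MONTH

    eff = config.aging_effects
    occ_shift = np.asarray(eff["occupancy_logodds"], float) * age_months * aging_rate
    path = _state_path(n_bins, light, config.transition_light,
                       config.transition_dark, occ_shift, rng)

    means = config.state_means.copy()
    slopes = np.array([eff["emission_slopes"].get(c, 0.0) for c in BASE_CHANNELS])
    means = means + slopes[None, :] * age_months * aging_rate
    # per-mouse body mass replaces the profile constant
    bm = BASE_CHANNELS.index("BodyMass")
    means[:, bm] = body_mass
    if genetic_shift is not None:
        means = means + np.asarray(genetic_shift, float)[None, :]

    X = means[path] + config.state_sds[path] * rng.standard_normal((n_bins, 14))
    # structural zeros stay zero: states with zero mean intake/wheel emit 0
    zero_mask = config.state_means[path] == 0.0
    X[zero_mask] = 0.0
    # physical floor at 0 for everything except nothing (all channels >= 0)
    np.maximum(X, 0.0, out=X)
    # analyzer offsets on gas channels
    delta = analyzer_offsets[analyzer_id]
    for gi, c in enumerate(GAS_CHANNELS):
        X[:, BASE_CHANNELS.index(c)] += delta[gi]

    rows = pd.DataFrame(X, columns=BASE_CHANNELS)
    rows.insert(0, "light", light)
    rows.insert(0, "timestamp", tbins * 3.0)
    truth = {
        "states": path,
        "clean": rows[BASE_CHANNELS].copy(),
        "fault_mask": pd.DataFrame(np.zeros((n_bins, 14), dtype=bool),
                                   columns=BASE_CHANNELS),
        "aging_rate": aging_rate,
        "analyzer_offsets": {c: float(delta[gi]) for gi, c in enumerate(GAS_CHANNELS)},
    }
    return RawRun(mouse_id, run_number, analyzer_id, start_age_days, rows, truth)


def inject_sensor_faults(run: RawRun, zero_rates: dict[str, float],
                         burst_rates: dict[str, float], seed: int,
                         burst_scale: float = 6.0) -> RawRun:
    """Randomly zero cells (spurious sensor zeros) or displace them by a
    heavy-tailed burst.  The fault mask indexes exactly the altered cells;
    clean values are preserved in the truth bundle."""
    for rates in (zero_rates, burst_rates):
        for c, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"fault rate for {c} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = run.rows.copy()
    n = len(rows)
    mask = run.truth["fault_mask"].copy() if run.truth else pd.DataFrame(
        np.zeros((n, 14), dtype=bool), columns=BASE_CHANNELS)
    for c in BASE_CHANNELS:
        zr = zero_rates.get(c, 0.0)
        if zr > 0:
            hit = rng.random(n) < zr
            changed = hit & (rows[c].to_numpy() != 0.0)
            rows.loc[changed, c] = 0.0
            mask.loc[changed, c] = True
        br = burst_rates.get(c, 0.0)
        if br > 0:
            hit = rng.random(n) < br
            if hit.any():
                sd = float(np.std(run.truth["clean"][c])) if run.truth else float(np.std(rows[c]))
                sd = max(sd, 1e-3)
                disp = rng.standard_t(3, size=int(hit.sum())) * burst_scale * sd
                vals = rows.loc[hit, c].to_numpy() + np.abs(disp) * np.sign(
                    rng.standard_normal(int(hit.sum())) + 2.0)
                rows.loc[hit, c] = vals
                mask.loc[hit, c] = True
    truth = dict(run.truth) if run.truth else {}
    truth["fault_mask"] = mask
    return RawRun(run.mouse_id, run.run_number, run.analyzer_id,
                  run.start_age_days, rows, truth)


# ---------------------------------------------------------------------------
# genetics

def simulate_genetics(n_mice: int, n_markers: int, h2_targets: np.ndarray,
                      seed: int, n_subpops: int = 2, fst: float = 0.05,
                      family_size: int = 5, fst_family: float = 0.2) -> dict:
    """Biallelic dosages with hierarchical population structure (two-level
    Balding-Nichols: subpopulation then family), per-feature additive
    genetic values with variance h2 of a unit-variance phenotype, and the
    dosage-based kinship matrix.  Family blocks give the kinship enough
    relatedness contrast for variance-component estimation to be
    identifiable at cohort sizes of a few hundred animals.
    """
    h2 = np.atleast_1d(np.asarray(h2_targets, float))
    if np.any(h2 < 0) or np.any(h2 >= 1):
        raise ValueError("h2 targets must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, n_markers)
    subpop = np.repeat(np.arange(n_subpops), int(np.ceil(n_mice / n_subpops)))[:n_mice]
    n_fam = int(np.ceil(n_mice / family_size))
    family = np.repeat(np.arange(n_fam), family_size)[:n_mice]
    G = np.empty((n_mice, n_markers), dtype=np.int8)

    def drift(p, f):
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        return rng.beta(np.clip(a, 1e-3, None), np.clip(b, 1e-3, None))

    p_sub = {s: drift(p_anc, fst) for s in range(n_subpops)}
    for fam in range(n_fam):
        members = family == fam
        if not members.any():
            continue
        s = int(subpop[np.flatnonzero(members)[0]])
        p_fam = drift(p_sub[s], fst_family)
        G[members] = rng.binomial(2, p_fam[None, :],
                                  size=(int(members.sum()), n_markers))
    from .genetics import compute_kinship
    K = compute_kinship(G.astype(float))
    # genetic values: y_g = Z u with u ~ N(0, 1/m), rescaled to var h2
    freq = G.mean(axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * freq * (1 - freq), 1e-12))
    Z = (G - 2 * freq[None, :]) / sd[None, :]
    gvals = np.zeros((n_mice, h2.size))
    for f in range(h2.size):
        if h2[f] == 0:
            continue
        u = rng.standard_normal(n_markers) / np.sqrt(n_markers)
        g = Z @ u
        g = g / g.std(ddof=0) * np.sqrt(h2[f])
        gvals[:, f] = g - g.mean()
    return {"genotypes": G, "kinship": K, "genetic_values": gvals,
            "subpop": subpop, "family": family}


# ---------------------------------------------------------------------------
# cohort

def simulate_cohort(config: CohortConfig, with_genetics: bool = False,
                    n_markers: int = 1000, h2_targets=None) -> dict:
    """Simulate a full cohort: lifespans, per-mouse latent aging rates,
    scheduled runs (one per 28-day cycle until death/censor), sensor faults,
    and optionally genetics.  Deterministic for a fixed config.seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4, dtype=np.uint32)
    rng = np.random.default_rng(seeds[0])

    cohorts = [f"c{i}" for i in range(len(config.enrollment_ages))]
    records = simulate_lifespans(
        config.n_mice, config.lifespan_location, config.lifespan_scale,
        config.enrollment_ages, config.study_length, int(seeds[1]),
        cohort_ids=cohorts)
    aging_rates = 1.0 + config.sigma_beta_true * rng.standard_normal(config.n_mice)
    aging_rates = np.clip(aging_rates, 0.2, None)
    body_masses = np.clip(rng.normal(31.0, 5.0, config.n_mice), 16.0, 60.0)

    analyzer_ids = [f"a{i}" for i in range(config.n_analyzers)]
    offsets = {a: config.analyzer_offset_sd * rng.standard_normal(len(GAS_CHANNELS))
               for a in analyzer_ids}
    # identifiability: center offsets across analyzers per channel
    mat = np.array([offsets[a] for a in analyzer_ids])
    mat -= mat.mean(axis=0, keepdims=True)
    offsets = {a: mat[i] for i, a in enumerate(analyzer_ids)}

    genetics = None
    genetic_shift = None
    if with_genetics:
        h2 = np.atleast_1d(h2_targets if h2_targets is not None else np.full(14, 0.0))
        genetics = simulate_genetics(config.n_mice, n_markers, h2, int(seeds[2]))
        gv = genetics["genetic_values"]
        if gv.shape[1] >= 14:
            # per-mouse channel shifts = genetic value (var h2) + permanent
            # environmental individuality (var 1-h2), so the between-mouse
            # heritable share of a channel matches its h2 target
            g_rng = np.random.default_rng(int(seeds[2]) + 1)
            env = g_rng.standard_normal((config.n_mice, 14))
            env = (env - env.mean(0)) * np.sqrt(np.clip(1.0 - h2[:14], 0, 1))
            scale = np.array([config.state_means[:, i].mean() * 0.1 + 1e-3
                              for i in range(14)])
            genetic_shift = (gv[:, :14] + env) * scale[None, :14]

    runs: list[RawRun] = []
    run_rng = np.random.default_rng(seeds[3])
    for j, rec in enumerate(records):
        run_no = 0
        t = rec.enrollment_age  # months
        while t < rec.event_age:
            run_end = t + config.run_length_days / DAYS_PER_MONTH
            if run_end > rec.event_age:
                break
            run_no += 1
            analyzer = analyzer_ids[int(run_rng.integers(config.n_analyzers))]
            gshift = genetic_shift[j] if genetic_shift is not None else None
            run = simulate_run(
                rec.mouse_id, run_no, t * DAYS_PER_MONTH,
                float(aging_rates[j]), analyzer, offsets, config,
                seed=int(run_rng.integers(2**31)),
                body_mass=float(body_masses[j]), genetic_shift=gshift)
            run = inject_sensor_faults(
                run, config.fault_zero_rates, config.fault_burst_rates,
                seed=int(run_rng.integers(2**31)), burst_scale=config.burst_scale)
            runs.append(run)
            t += config.run_cycle_days / DAYS_PER_MONTH
    truth = {
        "aging_rates": aging_rates,
        "body_masses": body_masses,
        "analyzer_offsets": offsets,
    }
    return {"runs": runs, "lifespans": records, "truth": truth,
            "genetics": genetics, "config": config}


# ---------------------------------------------------------------------------
# i/o

def write_cohort(cohort: dict, outdir) -> list[str]:
    """Write runs as delimited tables plus a metadata table and a JSON truth
    sidecar; returns the list of files written (for the pipeline manifest)."""
    import json
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    meta = []
    for run in cohort["runs"]:
        fname = f"run_{run.mouse_id}_{run.run_number:02d}.csv"
        run.rows.to_csv(outdir / fname, index=False, float_format="%.6g")
        meta.append({"mouse_id": run.mouse_id, "run_number": run.run_number,
                     "analyzer_id": run.analyzer_id,
                     "start_age_days": round(run.start_age_days, 4),
                     "file": fname})
        written.append(str(outdir / fname))
    pd.DataFrame(meta).to_csv(outdir / "runs_meta.csv", index=False)
    lifespan_frame(cohort["lifespans"]).to_csv(
        outdir / "lifespans.csv", index=False, float_format="%.6g")
    truth = cohort["truth"]
    sidecar = {
        "aging_rates": [round(float(x), 8) for x in truth["aging_rates"]],
        "body_masses": [round(float(x), 8) for x in truth["body_masses"]],
        "analyzer_offsets": {a: [round(float(v), 8) for v in o]
                             for a, o in truth["analyzer_offsets"].items()},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    written += [str(outdir / "runs_meta.csv"), str(outdir / "lifespans.csv"),
                str(outdir / "truth.json")]
    return written
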
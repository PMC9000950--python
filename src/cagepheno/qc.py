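"""Quality control for cage runs.

Stages, applied per run: (1) drop the first 24 h of data (acclimation to the
cage) and reject runs left shorter than one full day; (2) range-check every
channel against permissive physiological bounds; (3) for the five gas
channels, remove the circadian component with a robust seasonal-trend
decomposition (24 h period) and flag residual outliers with the generalized
extreme studentized deviate (ESD) test at the 0.05 level, capped at 30% of
points; (4) reject a run if 30% or more of its checked cells are flagged.

Flagged cells are censored (masked), never modified or imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import (BASE_CHANNELS, BINS_PER_DAY, GAS_CHANNELS, ChannelSpec,
                    RawRun)

FLAG_OK = 0
FLAG_OUT_OF_RANGE = 1
FLAG_ESD_OUTLIER = 2
FLAG_CENSORED_MISSING = 3


@dataclass
class QCReport:
    run_id: str
    removed: bool
    removal_reason: str  # too_short | too_many_outliers | none
    outlier_fraction: float = 0.0
    per_channel_fraction: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.removed != (self.removal_reason != "none"):
            raise ValueError("removed must be true iff a reason is given")


def run_id(run: RawRun) -> str:
    return f"{run.mouse_id}_r{run.run_number:02d}"


# ---------------------------------------------------------------------------

def truncate_acclimation(run: RawRun):
    """Drop the first 24 h; reject (return QCReport) if < 1 full day remains."""
    n = len(run.rows)
    if n - BINS_PER_DAY < BINS_PER_DAY:  # "shorter than a full day" is strict
        return QCReport(run_id(run), True, "too_short")
    rows = run.rows.iloc[BINS_PER_DAY:].reset_index(drop=True)
    truth = None
    if run.truth is not None:
        truth = dict(run.truth)
        for key in ("clean", "fault_mask"):
            truth[key] = run.truth[key].iloc[BINS_PER_DAY:].reset_index(drop=True)
        truth["states"] = run.truth["states"][BINS_PER_DAY:]
    return RawRun(run.mouse_id, run.run_number, run.analyzer_id,
                  run.start_age_days + 1.0, rows, truth)


def apply_range_checks(run: RawRun, specs: list[ChannelSpec]) -> pd.DataFrame:
    """Flag cells outside each channel's closed [low, high] interval."""
    by_name = {s.name: s for s in specs}
    missing = [c for c in BASE_CHANNELS if c not in by_name]
    if missing:
        raise KeyError(f"channels without a spec: {missing}")
    mask = pd.DataFrame(np.zeros((len(run.rows), len(BASE_CHANNELS)), dtype=np.int8),
                        columns=BASE_CHANNELS)
    for c in BASE_CHANNELS:
        lo, hi = by_name[c].valid_range
        x = run.rows[c].to_numpy(float)
        bad = (x < lo) | (x > hi) | ~np.isfinite(x)
        mask.loc[bad, c] = FLAG_OUT_OF_RANGE
    return mask


def _rolling_median_periodic(x: np.ndarray, window: int, period: int) -> np.ndarray:
    """Centered rolling median with periodic edge padding (values one full
    period inward), so a perfectly periodic signal decomposes exactly."""
    import pandas as pd
    n = x.size
    pad = window // 2
    left = x[period - pad:period] if pad <= period else x[:period]
    right = x[n - period:n - period + pad]
    xp = np.concatenate([left, x, right])
    med = pd.Series(xp).rolling(window, center=True, min_periods=1).median().to_numpy()
    return med[pad:pad + n]


def decompose_circadian(series: np.ndarray, period: int = BINS_PER_DAY,
                        n_iter: int = 2) -> dict:
    """Robust seasonal-trend decomposition of one 3-minute channel series.

    Median-based: the trend is a centered rolling median over one full
    period (periodic edge padding), the seasonal component is the per-
    circadian-bin median of the detrended series across days (centered to
    zero mean), iterated.  series = trend + seasonal + residual on observed
    cells; medians keep isolated spikes in the residual.  NaNs are allowed
    and interpolated internally for the decomposition only.
    """
    x = np.asarray(series, float)
    if x.size < 2 * period:
        raise ValueError("series must span at least two periods")
    obs = np.isfinite(x)
    xi = x.copy()
    if not obs.all():
        if obs.sum() < period // 2:
            raise ValueError("too few observed points")
        idx = np.arange(x.size)
        xi[~obs] = np.interp(idx[~obs], idx[obs], x[obs])
    if np.ptp(xi) == 0.0:
        const = float(xi[0]) if xi.size else 0.0
        return {"trend": np.full_like(x, const), "seasonal": np.zeros_like(x),
                "residual": np.where(obs, x - const, np.nan)}
    n = xi.size
    phase = np.arange(n) % period
    n_days = int(np.ceil(n / period))
    pad_n = n_days * period
    seasonal = np.zeros(n)
    trend = np.zeros(n)
    window = period + 1
    keep = np.ones(n, dtype=bool)  # cells contributing to the components
    for _ in range(max(n_iter, 2)):
        work = np.where(keep, xi, np.nan)
        # robust interpolation over excluded cells for the trend pass
        if not keep.all():
            idx = np.arange(n)
            work = np.where(keep, xi, np.interp(idx, idx[keep], xi[keep]))
        trend = _rolling_median_periodic(work - seasonal, window, period)
        det_all = xi - trend
        Da = np.full(pad_n, np.nan)
        Da[:n] = det_all
        Da = Da.reshape(n_days, period)   # days x circadian bin, all cells
        Dk = np.full(pad_n, np.nan)
        Dk[:n] = np.where(keep, det_all, np.nan)
        Dk = Dk.reshape(n_days, period)   # kept cells only
        # plain per-bin mean over kept cells: full efficiency on clean data
        # (keeps the residual distribution calibrated for the ESD stage);
        # outliers were excluded from `keep` on the previous pass.  Bins
        # whose cells were all excluded fall back to the all-cell median.
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(Dk, axis=0)
            med = np.nanmedian(Da, axis=0)
        prof = np.where(np.isfinite(prof), prof, np.where(np.isfinite(med), med, 0.0))
        # circular local-quadratic smoothing: shrinks the profile's own-cell
        # weight (so moderate bursts are not absorbed into the seasonal) and
        # its estimation noise, while a 24 h harmonic is preserved to ~1e-8
        from scipy.signal import savgol_filter
        prof = savgol_filter(prof, min(9, period - 1), 2, mode="wrap")
        prof = prof - prof.mean()
        seasonal = prof[phase]
        # exclusion decision from leave-one-day-out per-bin means: unlike
        # the fitted profile these cannot absorb a cell's own spike, so a
        # burst stands at its full magnitude; on clean data the statistic
        # is homoscedastic Gaussian and the 4.5-sigma cut is a near no-op
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bin_sum = np.nansum(Dk, axis=0)
            bin_cnt = np.isfinite(Dk).sum(axis=0)
        in_sum = keep & np.isfinite(det_all)
        num = bin_sum[phase] - np.where(in_sum, det_all, 0.0)
        den = bin_cnt[phase].astype(float) - in_sum.astype(float)
        loo = np.where(den >= 1, num / np.maximum(den, 1.0), np.nan)
        resid_loo = det_all - loo
        ok = np.isfinite(resid_loo)
        mad = np.median(np.abs(resid_loo[ok] - np.median(resid_loo[ok])))
        sigma_loo = 1.4826 * mad
        if sigma_loo < 1e-12:
            break
        keep = ~ok | (np.abs(resid_loo) <= 4.5 * sigma_loo)
        if keep.sum() < n // 2:  # safety: never discard the bulk
            keep = np.ones(n, dtype=bool)
            break
    residual = np.where(obs, x - trend - seasonal, np.nan)
    return {"trend": trend, "seasonal": seasonal, "residual": residual}


def generalized_esd(residual: np.ndarray, alpha: float = 0.05,
                    max_frac: float = 0.30) -> np.ndarray:
    """Rosner's generalized ESD test; returns indices of flagged outliers.

    Iteratively removes the point maximizing |x - mean|/sd, comparing
    R_i to the t-based critical value lambda_i at level ``alpha``; all
    points up to the largest i with R_i > lambda_i are flagged, with at
    most floor(max_frac * n) flags.  Zero-variance input flags nothing.
    """
    x = np.asarray(residual, float)
    obs_idx = np.flatnonzero(np.isfinite(x))
    x = x[obs_idx]
    n = x.size
    if n < 10:
        return np.empty(0, dtype=np.int64)
    r_max = int(np.floor(max_frac * n))
    if r_max == 0 or np.std(x) == 0.0:
        return np.empty(0, dtype=np.int64)
    work = x.copy()
    alive = np.ones(n, dtype=bool)
    removed = np.empty(r_max, dtype=np.int64)
    stat = np.empty(r_max)
    # incremental mean/ssq for speed
    s1 = work.sum()
    s2 = (work ** 2).sum()
    m = n
    for i in range(r_max):
        mean = s1 / m
        var = max(s2 / m - mean * mean, 0.0)
        sd = np.sqrt(var * m / max(m - 1, 1))
        if sd == 0.0:
            r_max = i
            break
        dev = np.abs(work - mean)
        dev[~alive] = -np.inf
        k = int(np.argmax(dev))
        stat[i] = dev[k] / sd
        removed[i] = k
        alive[k] = False
        s1 -= work[k]
        s2 -= work[k] ** 2
        m -= 1
    # critical values
    flags = np.empty(0, dtype=np.int64)
    last = -1
    for i in range(r_max):
        ni = n - i  # points in play at step i (before removal)
        p = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t * t) * ni)
        if stat[i] > lam:
            last = i
    if last >= 0:
        flags = removed[:last + 1]
    return np.sort(obs_idx[flags])


# ---------------------------------------------------------------------------

def qc_run(run: RawRun, specs: list[ChannelSpec], alpha: float = 0.05,
           max_frac: float = 0.30, reject_frac: float = 0.30):
    """QC one run: truncation -> range checks -> gas-channel decompose+ESD.

    Returns (cleaned RawRun with a ``qc_mask`` attribute, QCReport) or
    (None, QCReport) on rejection.  Cell values are never modified.
    """
    out = truncate_acclimation(run)
    if isinstance(out, QCReport):
        return None, out
    run = out
    # massive sensor dropout: a gas channel that is >= reject_frac exact
    # zeros violates the ESD's contamination bound (outliers would mask
    # themselves), so the run is unusable and rejected outright; moderate
    # spurious zeros are left for the ESD and the HMM's censored state
    for c in GAS_CHANNELS:
        zfrac = float((run.rows[c].to_numpy(float) == 0.0).mean())
        if zfrac >= reject_frac:
            return None, QCReport(run_id(run), True, "too_many_outliers",
                                  zfrac, {c: zfrac})
    mask = apply_range_checks(run, specs)
    for c in GAS_CHANNELS:
        x = run.rows[c].to_numpy(float).copy()
        flagged = mask[c].to_numpy() != FLAG_OK
        x[flagged] = np.nan
        try:
            dec = decompose_circadian(x)
        except ValueError:
            mask.loc[~flagged, c] = FLAG_CENSORED_MISSING
            continue
        idx = generalized_esd(dec["residual"], alpha=alpha, max_frac=max_frac)
        col = mask[c].to_numpy()
        col[idx] = np.where(col[idx] == FLAG_OK, FLAG_ESD_OUTLIER, col[idx])
        mask[c] = col
    checked = mask[GAS_CHANNELS].to_numpy()
    frac_all = float((mask.to_numpy() != FLAG_OK).mean())
    frac_checked = float((checked != FLAG_OK).mean())
    per_channel = {c: float((mask[c].to_numpy() != FLAG_OK).mean())
                   for c in BASE_CHANNELS}
    if frac_checked >= reject_frac or frac_all >= reject_frac:
        return None, QCReport(run_id(run), True, "too_many_outliers",
                              max(frac_all, frac_checked), per_channel)
    cleaned = RawRun(run.mouse_id, run.run_number, run.analyzer_id,
                     run.start_age_days, run.rows, run.truth)
    cleaned.qc_mask = mask  # type: ignore[attr-defined]
    return cleaned, QCReport(run_id(run), False, "none",
                             max(frac_all, frac_checked), per_channel)


def qc_pipeline(runs: list[RawRun], specs: list[ChannelSpec] | None = None,
                alpha: float = 0.05, max_frac: float = 0.30) -> dict:
    """QC a list of runs; returns {"runs": kept cleaned runs, "reports": all}."""
    from .synth import default_channel_specs
    if specs is None:
        specs = default_channel_specs()
    kept, reports = [], []
    for run in runs:
        cleaned, report = qc_run(run, specs, alpha=alpha, max_frac=max_frac)
        reports.append(report)
        if cleaned is not None:
            kept.append(cleaned)
    return {"runs": kept, "reports": reports}


def report_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"run_id": [r.run_id for r in reports],
         "removed": [r.removed for r in reports],
         "removal_reason": [r.removal_reason for r in reports],
         "outlier_fraction": [round(r.outlier_fraction, 6) for r in reports]})
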
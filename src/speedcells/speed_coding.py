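"""Speed scores, shuffle classification, slopes, speed information, shifts.

The speed score of a cell is the Pearson correlation between its smoothed
instantaneous firing rate and the smoothed running speed over valid
2-50 cm/s bins. Significance comes from circularly time-shifting the
spike train by a random interval in [30 s, T - 30 s] (100 surrogates per
cell, full smoothing pipeline re-run per surrogate) and pooling surrogate
scores across cells: scores above the pooled 99th percentile mark p-Speed
cells, below the pooled 1st percentile n-Speed cells.

Temporal-shift convention: r(tau) correlates the rate at time t with the
speed at time t + tau, so a positive preferred shift means the firing
rate leads (predicts) speed - prospective coding - and a negative one
means the rate follows speed - retrospective coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import (
    DEFAULT_DT,
    SPEED_SMOOTH_SD,
    BinnedSeries,
    SpeedSeries,
    gaussian_smooth,
)
from .spatial_coding import skaggs_information

SHIFT_MAX = 1.536            # s, temporal shift range is [-1536, +1536] ms
SHUFFLE_MARGIN = 30.0        # s, minimum circular shift
N_SHUFFLES = 100
SPEED_TUNING_EDGES = np.arange(2.0, 50.0 + 1e-9, 4.0)   # 12 bins of 4 cm/s
MIN_VALID_BINS = 100


class RateSeries(BinnedSeries):
    """Smoothed instantaneous firing rate in Hz."""


@dataclass
class SpeedTuning:
    """Firing rate vs speed tuning curve (4 cm/s bins on [2, 50] cm/s)."""

    bin_edges: np.ndarray
    occupancy_p: np.ndarray    # p_i, sums to 1 over occupied bins
    rate: np.ndarray           # lambda_i, Hz (NaN for unoccupied bins)
    mean_rate: float           # lambda, Hz


@dataclass
class ShuffleNull:
    """Per-cell circular-shuffle surrogate speed scores."""

    scores: np.ndarray         # (n_shuffles,)
    n_spikes: int


@dataclass
class SpeedCellResult:
    """Everything the pipeline reports about one cell's speed coding."""

    speed_score: float
    cell_class: str = "non-speed"             # p-Speed / n-Speed / non-speed
    slope: float = np.nan                     # Hz per (cm/s)
    norm_slope: float = np.nan                # s/cm
    info_per_spike: float = np.nan            # bits/spike
    info_per_sec: float = np.nan              # bits/s
    mean_rate: float = np.nan                 # Hz over valid-speed bins
    shift_curve: np.ndarray | None = None     # r(tau), 121 entries
    shift_lags: np.ndarray | None = None      # s
    preferred_shift: float = np.nan           # s; NaN if excluded/undefined
    shift_excluded: bool = False              # argmax fell on the boundary
    normalized_curve: np.ndarray | None = None
    defined: bool = True
    tuning: SpeedTuning | None = None


def instantaneous_rate(
    spike_times: np.ndarray,
    n_bins: int,
    t0: float = 0.0,
    dt: float = DEFAULT_DT,
    sd: float = SPEED_SMOOTH_SD,
) -> RateSeries:
    """Smoothed instantaneous firing rate on the analysis grid.

    Spikes are counted in ``dt`` bins, divided by ``dt`` and smoothed with
    the same Gaussian kernel policy as the speed series (SD ``sd`` s,
    truncation 4 SD, edge renormalisation).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.floor((spike_times - t0) / dt).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    rate = gaussian_smooth(counts / dt, sd / dt)
    return RateSeries(t0, dt, rate)


def _shifted_pairs(
    rate: np.ndarray, speed: np.ndarray, mask: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rate at bin i paired with speed at bin i+k, where the speed mask
    (evaluated at the speed timestamp) holds; off-edge bins dropped."""
    n = len(rate)
    if k >= 0:
        r = rate[: n - k] if k else rate
        v = speed[k:]
        m = mask[k:]
    else:
        r = rate[-k:]
        v = speed[:k]
        m = mask[:k]
    ok = m & np.isfinite(r) & np.isfinite(v)
    return r[ok], v[ok]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def speed_score(rate: RateSeries, speed: SpeedSeries, min_bins: int = MIN_VALID_BINS) -> float:
    """Pearson correlation of rate and speed over valid-speed bins.

    NaN (undefined) when fewer than ``min_bins`` bins are jointly valid or
    either series has zero variance on the masked bins.
    """
    if len(rate) != len(speed) or rate.dt != speed.dt:
        raise ValueError("rate and speed series must share the binning")
    r, v = _shifted_pairs(rate.values, speed.values, speed.valid & rate.valid, 0)
    if len(r) < min_bins:
        return np.nan
    return _pearson(r, v)


def speed_slope(rate: RateSeries, speed: SpeedSeries) -> tuple[float, float]:
    """OLS slope of rate vs speed, and the mean-rate-normalised slope.

    Returns ``(slope, norm_slope)`` in Hz/(cm/s) and s/cm. The normalised
    slope regresses rate divided by its mean over the valid bins. NaN when
    the masked speed has zero variance.
    """
    r, v = _shifted_pairs(rate.values, speed.values, speed.valid & rate.valid, 0)
    if len(r) < 2 or v.std() == 0:
        return np.nan, np.nan
    slope = float(stats.linregress(v, r).slope)
    mean_rate = r.mean()
    norm_slope = float(stats.linregress(v, r / mean_rate).slope) if mean_rate > 0 else np.nan
    return slope, norm_slope


def speed_slope_at_shift(rate: RateSeries, speed: SpeedSeries, shift_s: float) -> float:
    """OLS slope of rate(t) vs speed(t + shift).

    Useful for recovering the speed gain of a prospectively or
    retrospectively coding unit at its preferred temporal shift, where
    the zero-lag slope would be attenuated by the lag.
    """
    k = int(round(shift_s / rate.dt))
    r, v = _shifted_pairs(rate.values, speed.values, speed.valid & rate.valid, k)
    if len(r) < 2 or v.std() == 0:
        return np.nan
    return float(stats.linregress(v, r).slope)


def speed_information(
    rate: RateSeries, speed: SpeedSeries, edges: np.ndarray = SPEED_TUNING_EDGES
) -> tuple[float, float, SpeedTuning]:
    """Skaggs-style information of the speed tuning curve.

    The tuning curve bins speed in 4 cm/s steps from 2 to 50 cm/s over the
    valid bins; p_i is occupancy probability, lambda_i the mean rate in
    bin i, lambda the occupancy-weighted overall mean. Returns
    (bits/spike, bits/s, tuning); both NaN when lambda = 0.
    """
    r, v = _shifted_pairs(rate.values, speed.values, speed.valid & rate.valid, 0)
    nb = len(edges) - 1
    idx = np.digitize(v, edges) - 1
    ok = (idx >= 0) & (idx < nb)
    idx, r_ok = idx[ok], r[ok]
    counts = np.bincount(idx, minlength=nb).astype(float)
    sums = np.bincount(idx, weights=r_ok, minlength=nb)
    occupied = counts > 0
    if not occupied.any():
        return np.nan, np.nan, SpeedTuning(edges, np.zeros(nb), np.full(nb, np.nan), np.nan)
    p = np.where(occupied, counts / counts[occupied].sum(), 0.0)
    lam = np.full(nb, np.nan)
    lam[occupied] = sums[occupied] / counts[occupied]
    lam_bar = float(np.sum(p[occupied] * lam[occupied]))
    tuning = SpeedTuning(edges, p, lam, lam_bar)
    per_spike, per_sec = skaggs_information(p[occupied], lam[occupied], lam_bar)
    return per_spike, per_sec, tuning


def temporal_shift_curve(
    rate: RateSeries,
    speed: SpeedSeries,
    max_shift: float = SHIFT_MAX,
    min_bins: int = MIN_VALID_BINS,
) -> tuple[np.ndarray, np.ndarray, float, bool, np.ndarray]:
    """Rate-speed correlation as a function of temporal shift.

    r(tau) = Pearson(rate(t), speed(t + tau)) for tau from -max_shift to
    +max_shift in steps of the bin size (121 lags by default). Positive
    preferred shift = prospective (rate predicts future speed). Returns
    ``(lags_s, curve, preferred_shift_s, excluded, normalized_curve)``;
    ``excluded`` is True when the argmax falls on either boundary, and the
    normalised curve is r(tau)/r(0) (all-NaN if r(0) = 0 or undefined).
    """
    dt = rate.dt
    kmax = int(round(max_shift / dt))
    ks = np.arange(-kmax, kmax + 1)
    mask = speed.valid & rate.valid
    curve = np.empty(len(ks))
    for j, k in enumerate(ks):
        r, v = _shifted_pairs(rate.values, speed.values, mask, int(k))
        curve[j] = _pearson(r, v) if len(r) >= min_bins else np.nan
    lags = ks * dt
    if np.all(~np.isfinite(curve)):
        return lags, curve, np.nan, False, np.full_like(curve, np.nan)
    jstar = int(np.nanargmax(curve))
    excluded = jstar in (0, len(ks) - 1)
    pref = np.nan if excluded else float(lags[jstar])
    r0 = curve[kmax]
    norm = curve / r0 if np.isfinite(r0) and r0 != 0 else np.full_like(curve, np.nan)
    return lags, curve, pref, excluded, norm


def shuffle_null(
    spike_times: np.ndarray,
    duration: float,
    speed: SpeedSeries,
    n_shuffles: int = N_SHUFFLES,
    margin: float = SHUFFLE_MARGIN,
    rng: np.random.Generator | None = None,
    dt: float = DEFAULT_DT,
    sd: float = SPEED_SMOOTH_SD,
) -> ShuffleNull:
    """Circular-shuffle null distribution of one cell's speed score.

    Each surrogate shifts every spike time by the same random interval
    drawn uniformly from [margin, duration - margin], wrapping the end of
    the session to the beginning, then re-runs the full rate pipeline
    (binning + smoothing) and recomputes the score against the untouched
    speed series.
    """
    if duration <= 2 * margin:
        raise ValueError("session too short for circular shuffling")
    rng = np.random.default_rng() if rng is None else rng
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = len(speed)
    scores = np.empty(n_shuffles)
    shifts = rng.uniform(margin, duration - margin, size=n_shuffles)
    for i, s in enumerate(shifts):
        surrogate = np.sort(np.mod(spike_times + s, duration))
        r = instantaneous_rate(surrogate, n_bins, speed.t0, dt, sd)
        scores[i] = speed_score(r, speed)
    return ShuffleNull(scores, len(spike_times))


@dataclass
class SpeedCellClasses:
    """Pooled shuffle thresholds and the resulting class labels."""

    classes: list[str]
    lower: float                # pooled 1st percentile
    upper: float                # pooled 99th percentile
    pooled_scores: np.ndarray = field(repr=False, default=None)  # type: ignore


def classify_speed_cells(
    scores: np.ndarray,
    nulls: list[ShuffleNull],
    percentiles: tuple[float, float] = (1.0, 99.0),
    pooled: bool = True,
) -> SpeedCellClasses:
    """Classify cells as p-Speed / n-Speed / non-speed.

    With ``pooled=True`` (the default), surrogate scores of all cells are
    pooled and each cell is compared against the pooled 1st/99th
    percentiles by strict inequality; per-cell thresholds otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    if pooled:
        pool = np.concatenate([n.scores for n in nulls])
        pool = pool[np.isfinite(pool)]
        lo, hi = np.percentile(pool, percentiles)
        classes = [
            "p-Speed" if s > hi else ("n-Speed" if s < lo else "non-speed")
            if np.isfinite(s)
            else "undefined"
            for s in scores
        ]
        return SpeedCellClasses(classes, float(lo), float(hi), pool)
    classes = []
    for s, null in zip(scores, nulls):
        finite = null.scores[np.isfinite(null.scores)]
        lo, hi = np.percentile(finite, percentiles)
        if not np.isfinite(s):
            classes.append("undefined")
        elif s > hi:
            classes.append("p-Speed")
        elif s < lo:
            classes.append("n-Speed")
        else:
            classes.append("non-speed")
    return SpeedCellClasses(classes, np.nan, np.nan, None)


def analyse_unit(
    spike_times: np.ndarray,
    speed: SpeedSeries,
    dt: float = DEFAULT_DT,
    sd: float = SPEED_SMOOTH_SD,
    max_shift: float = SHIFT_MAX,
) -> SpeedCellResult:
    """All speed-coding statistics for one unit (classification aside).

    The zero-lag entry of the shift curve is the speed score itself
    (identical code path), so r(0) == speed_score bit for bit.
    """
    rate = instantaneous_rate(spike_times, len(speed), speed.t0, dt, sd)
    lags, curve, pref, excluded, norm = temporal_shift_curve(rate, speed, max_shift)
    score = curve[len(curve) // 2]
    slope, norm_slope = speed_slope(rate, speed)
    per_spike, per_sec, tuning = speed_information(rate, speed)
    r, _ = _shifted_pairs(rate.values, speed.values, speed.valid & rate.valid, 0)
    return SpeedCellResult(
        speed_score=float(score),
        slope=slope,
        norm_slope=norm_slope,
        info_per_spike=per_spike,
        info_per_sec=per_sec,
        mean_rate=float(r.mean()) if len(r) else np.nan,
        shift_curve=curve,
        shift_lags=lags,
        preferred_shift=pref,
        shift_excluded=excluded,
        normalized_curve=norm,
        defined=bool(np.isfinite(score)),
        tuning=tuning,
    )
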
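"""Binned time series, position smoothing, speed and head direction.

Raw LED tracking (30 Hz) is turned into uniformly binned series at the
analysis resolution (25.6 ms): missing video frames are bridged by linear
interpolation, position is smoothed by local linear regression (lowess,
11-bin window), speed is the per-bin displacement divided by the bin size
and Gaussian-smoothed (SD 512 ms), and a validity mask restricts every
downstream statistic to locomotion at 2-50 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_DT = 0.0256          # s, analysis bin size
POSITION_SMOOTH_WIDTH = 11   # bins (281.6 ms) for the lowess position smoother
SPEED_SMOOTH_SD = 0.512      # s, Gaussian SD for speed (and rate) smoothing
SPEED_MIN = 2.0              # cm/s, slower periods treated as immobility
SPEED_MAX = 50.0             # cm/s, faster periods treated as tracking noise
MAX_TRACKING_GAP = 1.0       # s, longer tracking dropouts are masked invalid


@dataclass
class BinnedSeries:
    """A uniformly binned time series with a per-bin validity mask."""

    t0: float
    dt: float
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must have the same length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Bin centre times in seconds."""
        return self.t0 + (np.arange(len(self.values)) + 0.5) * self.dt


class SpeedSeries(BinnedSeries):
    """Smoothed running speed (cm/s); mask true for valid 2-50 cm/s bins."""


from functools import lru_cache


@lru_cache(maxsize=8)
def _edge_normalizer(n: int, sd_bins: float, truncate: float) -> np.ndarray:
    ones = np.ones(n)
    return ndimage.gaussian_filter1d(
        ones, sd_bins, mode="constant", cval=0.0, truncate=truncate
    )


def gaussian_smooth(
    values: np.ndarray,
    sd_bins: float,
    valid: np.ndarray | None = None,
    truncate: float = 4.0,
) -> np.ndarray:
    """Gaussian smoothing with edge (and missing-sample) renormalisation.

    The kernel is truncated at ``truncate`` SDs; near the series edges and
    around invalid samples the kernel mass falling outside the defined data
    is renormalised away, so a constant input stays constant everywhere.
    Invalid input bins come back NaN.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    all_valid = bool(valid.all())
    filled = values if all_valid else np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter1d(
        filled, sd_bins, mode="constant", cval=0.0, truncate=truncate
    )
    if all_valid:
        den = _edge_normalizer(len(values), float(sd_bins), float(truncate))
    else:
        den = ndimage.gaussian_filter1d(
            valid.astype(float), sd_bins, mode="constant", cval=0.0, truncate=truncate
        )
    out = np.full_like(filled, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    out[~valid] = np.nan
    return out


def _lowess_window(y: np.ndarray, x: np.ndarray, x0: float) -> float:
    """Tricube-weighted linear fit of (x, y) evaluated at x0."""
    d = np.abs(x - x0)
    dmax = d.max()
    if dmax == 0:
        return float(np.mean(y))
    w = (1 - (d / dmax) ** 3) ** 3
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        return float(ym)
    b = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(ym + b * (x0 - xm))


def lowess_smooth(values: np.ndarray, width: int = POSITION_SMOOTH_WIDTH) -> np.ndarray:
    """Local linear regression smoother over a centred ``width``-bin window.

    Mirrors the classic span-based lowess smoother: each point is replaced
    by a first-degree polynomial fit over its ``width`` nearest neighbours
    with tricube weights; near the edges the window slides to stay inside
    the series. NaN samples propagate (smooth before masking).
    """
    if width % 2 != 1:
        raise ValueError("width must be an odd number of bins")
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < width:
        warnings.warn("series shorter than smoothing window; returned unsmoothed")
        return y.copy()
    half = width // 2
    x = np.arange(n, dtype=float)

    # Interior bins: the window is centred and the tricube weights are
    # symmetric, so the slope term of the local fit vanishes at the centre
    # and the fit reduces to a weighted moving average (a convolution).
    d = np.abs(np.arange(-half, half + 1)) / half
    w = (1 - d**3) ** 3
    w /= w.sum()
    out = np.convolve(y, w[::-1], mode="same")

    # Edge bins (and any bin whose window touches a NaN) get the full
    # asymmetric-window weighted linear fit.
    finite = np.isfinite(y)
    bad = np.convolve((~finite).astype(float), np.ones(width), mode="same") > 0
    redo = np.zeros(n, dtype=bool)
    redo[:half] = True
    redo[n - half:] = True
    redo |= bad & finite
    for i in np.nonzero(redo)[0]:
        lo = min(max(i - half, 0), n - width)
        sl = slice(lo, lo + width)
        if np.any(~finite[sl]):
            out[i] = np.nan
            continue
        out[i] = _lowess_window(y[sl], x[sl], float(i))
    out[~finite] = np.nan
    return out


def interpolate_position(
    traj,
    dt: float = DEFAULT_DT,
    max_gap: float = MAX_TRACKING_GAP,
    led: str = "front",
) -> tuple[BinnedSeries, BinnedSeries]:
    """Resample one LED's track onto the analysis grid by linear interpolation.

    Missing video frames are bridged linearly; bins inside tracking gaps
    longer than ``max_gap`` seconds are masked invalid.
    """
    xy = traj.front_led_xy if led == "front" else traj.rear_led_xy
    ok = np.asarray(traj.missing, dtype=bool) == False  # noqa: E712
    ok &= np.all(np.isfinite(xy), axis=1)
    if led == "rear":
        ok &= ~np.all(xy == -1, axis=1)
    ts = np.asarray(traj.timestamps, dtype=float)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 valid tracking samples")
    tv = ts[ok]
    n_bins = int(np.floor((ts[-1] - ts[0]) / dt))
    centres = ts[0] + (np.arange(n_bins) + 0.5) * dt
    x = np.interp(centres, tv, xy[ok, 0])
    y = np.interp(centres, tv, xy[ok, 1])
    # mask bins that fall inside long tracking dropouts
    gap_len = np.diff(tv)
    valid = np.ones(n_bins, dtype=bool)
    for i in np.nonzero(gap_len > max_gap)[0]:
        valid &= ~((centres > tv[i]) & (centres < tv[i + 1]))
    valid &= (centres >= tv[0]) & (centres <= tv[-1])
    return (
        BinnedSeries(ts[0], dt, x, valid),
        BinnedSeries(ts[0], dt, y, valid),
    )


def smooth_position(series: BinnedSeries, width: int = POSITION_SMOOTH_WIDTH) -> BinnedSeries:
    """Lowess-smooth a position series (width defaults to 11 bins = 281.6 ms)."""
    vals = np.where(series.valid, series.values, np.nan)
    return BinnedSeries(series.t0, series.dt, lowess_smooth(vals, width), series.valid.copy())


def compute_speed(
    x: BinnedSeries,
    y: BinnedSeries,
    sd: float = SPEED_SMOOTH_SD,
    vmin: float = SPEED_MIN,
    vmax: float = SPEED_MAX,
) -> SpeedSeries:
    """Instantaneous running speed from smoothed position.

    Speed in bin i is the Euclidean displacement between bins i and i+1
    divided by the bin size, Gaussian-smoothed with SD ``sd`` seconds
    (kernel truncated at 4 SD, renormalised at edges). The mask keeps bins
    with valid tracking and vmin <= v <= vmax; the full series is smoothed
    first and masked afterwards.
    """
    if len(x) != len(y) or x.dt != y.dt:
        raise ValueError("x and y series must be aligned")
    dx = np.diff(x.values)
    dy = np.diff(y.values)
    v = np.hypot(dx, dy) / x.dt
    v = np.append(v, v[-1] if len(v) else 0.0)  # last bin repeats
    track_ok = x.valid & y.valid
    smoothed = gaussian_smooth(v, sd / x.dt, valid=track_ok)
    mask = track_ok & np.isfinite(smoothed) & (smoothed >= vmin) & (smoothed <= vmax)
    return SpeedSeries(x.t0, x.dt, np.where(np.isfinite(smoothed), smoothed, 0.0), mask)


def head_direction(traj, dt: float = DEFAULT_DT) -> BinnedSeries:
    """Per-bin head direction (radians in [0, 2pi)) from the two LEDs.

    Direction is atan2 of the front-minus-rear LED vector after both LEDs
    are interpolated onto the analysis grid.
    """
    rear_xy = np.asarray(traj.rear_led_xy, dtype=float)
    if rear_xy.size == 0 or np.all(~np.isfinite(rear_xy)) or np.all(rear_xy == -1):
        raise ValueError("rear LED absent; head direction unavailable")
    fx, fy = interpolate_position(traj, dt, led="front")
    rx, ry = interpolate_position(traj, dt, led="rear")
    n = min(len(fx), len(rx))
    ang = np.arctan2(fy.values[:n] - ry.values[:n], fx.values[:n] - rx.values[:n])
    ang = np.mod(ang, 2 * np.pi)
    valid = fx.valid[:n] & rx.valid[:n]
    return BinnedSeries(fx.t0, dt, ang, valid)
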
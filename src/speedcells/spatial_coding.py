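"""Rate maps, Skaggs information, spatial autocorrelograms, gridness.

Firing-rate maps bin position in 3 x 3 cm pixels during locomotion
(> 2 cm/s), smooth occupancy and spike-count maps separately with a
Gaussian kernel (SD 3 cm) and divide. The Skaggs information measures
(bits/spike and bits/s) are shared by the spatial, directional and speed
tuning analyses. The spatial autocorrelogram is the per-lag Pearson
correlation with edge correction, undefined where fewer than 20 bins
overlap, and the gridness score contrasts 60/120-degree rotational
correlations against 30/90/150 degrees over expanding annuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

RATE_MAP_BIN = 3.0        # cm
RATE_MAP_SD = 3.0         # cm, Gaussian kernel SD for occupancy/count maps
MIN_OVERLAP_BINS = 20     # autocorrelation undefined below this overlap
HD_BIN_DEG = 6.0          # head-direction bin size
GRIDNESS_ANGLES_ON = (60, 120)
GRIDNESS_ANGLES_OFF = (30, 90, 150)


@dataclass
class RateMap2D:
    """Smoothed 2-D firing-rate map with raw occupancy and counts."""

    bin_size: float
    occupancy_s: np.ndarray      # raw seconds per bin
    spike_count: np.ndarray      # raw spikes per bin
    smoothed_rate: np.ndarray    # Hz; NaN outside the visited area
    visited: np.ndarray          # bool


@dataclass
class AutoCorrMap:
    """Spatial autocorrelogram: r per lag, NaN where overlap < 20 bins."""

    r: np.ndarray
    n: np.ndarray
    bin_size: float


@dataclass
class GridnessResult:
    """Gridness = max over annuli of min(r60, r120) - max(r30, r90, r150)."""

    central_radius: float            # cm
    annulus_radii: np.ndarray        # cm, outer radii sampled
    annulus_scores: np.ndarray
    gridness: float
    defined: bool = True


def skaggs_information(p: np.ndarray, lam: np.ndarray, lam_bar: float) -> tuple[float, float]:
    """Skaggs information of a tuning curve, in bits/spike and bits/s.

    per-spike = sum_i p_i (lam_i/lam) log2(lam_i/lam);
    per-second = sum_i p_i lam_i log2(lam_i/lam); 0*log(0) := 0.
    NaN when the overall mean rate is zero or undefined.
    """
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not np.isfinite(lam_bar) or lam_bar <= 0:
        return np.nan, np.nan
    ratio = lam / lam_bar
    pos = ratio > 0
    log_ratio = np.zeros_like(ratio)
    log_ratio[pos] = np.log2(ratio[pos])
    per_spike = float(np.sum(p * ratio * log_ratio))
    per_sec = float(np.sum(p * lam * log_ratio))
    return per_spike, per_sec


def _smooth2d(values: np.ndarray, sd_bins: float) -> np.ndarray:
    return ndimage.gaussian_filter(values, sd_bins, mode="constant", cval=0.0, truncate=4.0)


def rate_map(
    spike_times: np.ndarray,
    x,
    y,
    run_mask: np.ndarray,
    arena_side: float,
    bin_size: float = RATE_MAP_BIN,
    sd: float = RATE_MAP_SD,
) -> RateMap2D:
    """Smoothed firing-rate map over the arena.

    ``x``/``y`` are binned position series; ``run_mask`` marks locomotion
    bins (> 2 cm/s and valid tracking). Occupancy and spike-count maps are
    smoothed individually (Gaussian SD ``sd`` cm) and divided; rate is
    defined only where the smoothed occupancy of visited bins is positive.
    """
    nb = int(np.ceil(arena_side / bin_size))
    run_mask = np.asarray(run_mask, dtype=bool)
    if not run_mask.any():
        raise ValueError("no locomotion bins; empty occupancy")
    xi = np.clip(np.floor(x.values / bin_size).astype(int), 0, nb - 1)
    yi = np.clip(np.floor(y.values / bin_size).astype(int), 0, nb - 1)
    occ = np.zeros((nb, nb))
    np.add.at(occ, (yi[run_mask], xi[run_mask]), x.dt)

    spike_times = np.asarray(spike_times, dtype=float)
    sidx = np.floor((spike_times - x.t0) / x.dt).astype(int)
    ok = (sidx >= 0) & (sidx < len(x)) & run_mask[np.clip(sidx, 0, len(x) - 1)]
    sidx = sidx[ok]
    counts = np.zeros((nb, nb))
    np.add.at(counts, (yi[sidx], xi[sidx]), 1.0)

    occ_s = _smooth2d(occ, sd / bin_size)
    cnt_s = _smooth2d(counts, sd / bin_size)
    visited = occ > 0
    rate = np.full((nb, nb), np.nan)
    good = visited & (occ_s > 0)
    rate[good] = cnt_s[good] / occ_s[good]
    return RateMap2D(bin_size, occ, counts, rate, visited)


def spatial_information(map2d: RateMap2D) -> tuple[float, float]:
    """Skaggs spatial information of a rate map (bits/spike, bits/s)."""
    occ = map2d.occupancy_s[map2d.visited]
    lam = map2d.smoothed_rate[map2d.visited]
    ok = np.isfinite(lam)
    occ, lam = occ[ok], lam[ok]
    if occ.sum() == 0:
        return np.nan, np.nan
    p = occ / occ.sum()
    return skaggs_information(p, lam, float(np.sum(p * lam)))


def directional_rate_map(
    spike_times: np.ndarray,
    hd,
    bin_deg: float = HD_BIN_DEG,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Head-direction tuning curve and its Skaggs information.

    Sorts head direction into 6-degree bins (60 bins over [0, 360)),
    divides spike counts by time occupancy per bin (no smoothing).
    Returns ``(bin_centers_rad, rate_hz, bits_per_spike, bits_per_sec)``;
    unvisited bins are NaN and excluded from the information sum.
    """
    nb = int(round(360.0 / bin_deg))
    width = 2 * np.pi / nb
    ang = np.mod(hd.values[hd.valid], 2 * np.pi)
    occ = np.bincount(np.minimum((ang / width).astype(int), nb - 1), minlength=nb) * hd.dt

    sidx = np.floor((np.asarray(spike_times, dtype=float) - hd.t0) / hd.dt).astype(int)
    ok = (sidx >= 0) & (sidx < len(hd)) & hd.valid[np.clip(sidx, 0, len(hd) - 1)]
    sang = np.mod(hd.values[sidx[ok]], 2 * np.pi)
    counts = np.bincount(np.minimum((sang / width).astype(int), nb - 1), minlength=nb)

    rate = np.full(nb, np.nan)
    vis = occ > 0
    rate[vis] = counts[vis] / occ[vis]
    centers = (np.arange(nb) + 0.5) * width
    if not vis.any():
        return centers, rate, np.nan, np.nan
    p = occ[vis] / occ[vis].sum()
    per_spike, per_sec = skaggs_information(p, rate[vis], float(np.sum(p * rate[vis])))
    return centers, rate, per_spike, per_sec


def autocorrelogram_2d(map2d: RateMap2D, min_overlap: int = MIN_OVERLAP_BINS) -> AutoCorrMap:
    """Edge-corrected Pearson spatial autocorrelogram of a rate map.

    For each spatial lag, the correlation is computed over the n bins
    where the rate is defined in both the original and the lag-shifted
    copy, using the standard product-moment formula with per-lag sums;
    lags with n < ``min_overlap`` are NaN.
    """
    lam = map2d.smoothed_rate
    ny, nx = lam.shape
    defined = np.isfinite(lam)
    z = np.where(defined, lam, 0.0)
    out_r = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    out_n = np.zeros((2 * ny - 1, 2 * nx - 1), dtype=int)
    for ty in range(-(ny - 1), ny):
        for tx in range(-(nx - 1), nx):
            ys = slice(max(0, ty), min(ny, ny + ty))
            xs = slice(max(0, tx), min(nx, nx + tx))
            ys2 = slice(max(0, -ty), min(ny, ny - ty))
            xs2 = slice(max(0, -tx), min(nx, nx - tx))
            m = defined[ys, xs] & defined[ys2, xs2]
            n = int(m.sum())
            out_n[ty + ny - 1, tx + nx - 1] = n
            if n < min_overlap:
                continue
            a = z[ys, xs][m]
            b = z[ys2, xs2][m]
            sa = n * np.sum(a * a) - np.sum(a) ** 2
            sb = n * np.sum(b * b) - np.sum(b) ** 2
            if sa <= 0 or sb <= 0:
                continue
            num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
            out_r[ty + ny - 1, tx + nx - 1] = num / np.sqrt(sa * sb)
    return AutoCorrMap(out_r, out_n, map2d.bin_size)


def _radial_profile(ac: AutoCorrMap) -> tuple[np.ndarray, np.ndarray]:
    """Mean correlation as a function of distance from the centre (one-bin rings)."""
    ny, nx = ac.r.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(yy - cy, xx - cx) * ac.bin_size
    rmax = d[np.isfinite(ac.r)].max() if np.isfinite(ac.r).any() else 0.0
    edges = np.arange(0, rmax + ac.bin_size, ac.bin_size)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi) & np.isfinite(ac.r)
        if m.any():
            centers.append(d[m].mean())
            means.append(ac.r[m].mean())
    return np.asarray(centers), np.asarray(means)


def _central_peak_radius(ac: AutoCorrMap, threshold: float = 0.2) -> float:
    """Radius of the central peak: first local minimum of the radial
    correlation profile or first crossing under ``threshold``, whichever
    comes first."""
    d, r = _radial_profile(ac)
    if len(d) < 3:
        raise ValueError("autocorrelogram too small to resolve the central peak")
    for i in range(1, len(d)):
        if r[i] < threshold:
            return float(d[i])
        if i < len(d) - 1 and r[i] < r[i - 1] and r[i] <= r[i + 1]:
            return float(d[i])
    return float(d[-1])


def _rotate_sample(ac_map: np.ndarray, points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Bilinear sample of the map at ``points`` rotated about the centre."""
    ny, nx = ac_map.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    a = np.deg2rad(angle_deg)
    dy = points[:, 0] - cy
    dx = points[:, 1] - cx
    ry = cy + np.cos(a) * dy - np.sin(a) * dx
    rx = cx + np.sin(a) * dy + np.cos(a) * dx
    # NaN (undefined) bins propagate through the bilinear weights, so any
    # sample touching an undefined bin comes back NaN and is excluded.
    return ndimage.map_coordinates(ac_map, np.vstack([ry, rx]), order=1, cval=np.nan)


def gridness(
    ac: AutoCorrMap,
    arena_side: float,
    annulus_step: float | None = None,
    annulus_margin: float = 10.0,
) -> GridnessResult:
    """Rotational-symmetry gridness score of a spatial autocorrelogram.

    Expanding annuli share the central-peak radius as inner radius; the
    outer radius grows in one-bin steps from central + ``annulus_margin``
    cm up to ``arena_side`` - ``annulus_margin`` cm. For each annulus the
    Pearson correlation between the ring and its rotation (bilinear
    interpolation) is taken at 60/120 degrees and at 30/90/150 degrees;
    the annulus score is min(r60, r120) - max(r30, r90, r150) and the
    gridness is the maximum annulus score.
    """
    step = annulus_step if annulus_step is not None else ac.bin_size
    try:
        r_central = _central_peak_radius(ac)
    except ValueError:
        return GridnessResult(np.nan, np.empty(0), np.empty(0), np.nan, False)
    ny, nx = ac.r.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(yy - cy, xx - cx) * ac.bin_size
    outer_radii = np.arange(r_central + annulus_margin, arena_side - annulus_margin + 1e-9, step)
    scores = []
    used = []
    for outer in outer_radii:
        ring = (d > r_central) & (d <= outer) & np.isfinite(ac.r)
        pts = np.column_stack(np.nonzero(ring)).astype(float)
        if len(pts) < MIN_OVERLAP_BINS:
            continue
        orig = ac.r[ring]
        corr = {}
        for ang in GRIDNESS_ANGLES_ON + GRIDNESS_ANGLES_OFF:
            rot = _rotate_sample(ac.r, pts, ang)
            ok = np.isfinite(rot) & np.isfinite(orig)
            if ok.sum() < MIN_OVERLAP_BINS:
                corr[ang] = np.nan
                break
            corr[ang] = stats.pearsonr(orig[ok], rot[ok]).statistic
        if any(not np.isfinite(corr.get(a, np.nan)) for a in GRIDNESS_ANGLES_ON + GRIDNESS_ANGLES_OFF):
            continue
        on = min(corr[a] for a in GRIDNESS_ANGLES_ON)
        off = max(corr[a] for a in GRIDNESS_ANGLES_OFF)
        scores.append(on - off)
        used.append(outer)
    if not scores:
        return GridnessResult(r_central, np.empty(0), np.empty(0), np.nan, False)
    scores = np.asarray(scores)
    return GridnessResult(r_central, np.asarray(used), scores, float(scores.max()), True)
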
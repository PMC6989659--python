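"""Theta epochs, spike theta phases, circular statistics, theta index.

Theta (5-11 Hz) epochs are detected from the ratio of theta-band power to
the power of nearby bands (1-4 Hz, 12-14 Hz) in short sliding windows.
Spike phases come from the Hilbert transform of the band-pass filtered
LFP, unwrapped and linearly interpolated at spike times; the convention
throughout is peaks = 0/2pi and troughs = pi (positive polarity up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .correlograms import autocorrelogram

THETA_BAND = (5.0, 11.0)
NEARBY_BANDS = ((1.0, 4.0), (12.0, 14.0))
THETA_INDEX_THRESHOLD = 0.2
MIN_SPIKES_THETA_INDEX = 100


@dataclass
class ThetaEpochs:
    """Sorted, non-overlapping [start, end] intervals of theta activity."""

    intervals: np.ndarray          # (n, 2) seconds
    reference: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if len(self.intervals) else 0.0

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside an epoch."""
        times = np.asarray(times, dtype=float)
        if len(self.intervals) == 0:
            return np.zeros(len(times), dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(times), dtype=bool)
        out[ok] = times[ok] <= self.intervals[idx[ok], 1]
        return out


@dataclass
class ThetaProfile:
    """Per-unit theta locking summary."""

    preferred_phase: float     # rad in [0, 2pi); 0 = LFP peak, pi = trough
    resultant_length: float    # R in [0, 1]
    n_spikes: int
    theta_index: float
    theta_modulated: bool
    defined: bool = True


def detect_theta_epochs(
    lfp,
    win: float = 2.0,
    step: float = 1.0,
    ratio_thresh: float = 2.0,
    min_dur: float = 1.0,
) -> ThetaEpochs:
    """Detect theta epochs from the band-power ratio in sliding windows.

    Each ``win``-second window (stepped by ``step``) is kept when the
    5-11 Hz power exceeds ``ratio_thresh`` times the summed 1-4 and
    12-14 Hz power; contiguous kept windows are merged and epochs shorter
    than ``min_dur`` are dropped.
    """
    x = np.asarray(lfp.samples, dtype=float)
    fs = lfp.rate
    nwin = int(round(win * fs))
    nstep = int(round(step * fs))
    if len(x) < nwin:
        raise ValueError("LFP shorter than one detection window")
    if np.all(x == 0):
        warnings.warn("all-zero LFP; no theta epochs")
        return ThetaEpochs(np.empty((0, 2)), lfp.region_layer)
    starts = np.arange(0, len(x) - nwin + 1, nstep)
    # Welch with four averaged segments per window keeps the band-power
    # ratio estimate stable enough for a fixed threshold.
    nperseg = nwin // 4
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    in_theta = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    in_near = np.zeros_like(in_theta)
    for lo, hi in NEARBY_BANDS:
        in_near |= (freqs >= lo) & (freqs <= hi)
    keep = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        _, p = signal.welch(x[s : s + nwin], fs, nperseg=nperseg)
        near = p[in_near].sum()
        keep[i] = near > 0 and (p[in_theta].sum() / near) > ratio_thresh
    intervals = []
    i = 0
    while i < len(starts):
        if keep[i]:
            j = i
            while j + 1 < len(starts) and keep[j + 1]:
                j += 1
            t0 = starts[i] / fs
            t1 = min(starts[j] / fs + win, len(x) / fs)
            if t1 - t0 >= min_dur:
                intervals.append((t0, t1))
            i = j + 1
        else:
            i += 1
    return ThetaEpochs(np.asarray(intervals, dtype=float).reshape(-1, 2), lfp.region_layer)


def bandpass_filter(x: np.ndarray, fs: float, band: tuple[float, float] = THETA_BAND) -> np.ndarray:
    """Zero-phase (forward-backward) 3rd-order Butterworth band-pass."""
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def instantaneous_phase(x: np.ndarray, fs: float, band: tuple[float, float] = THETA_BAND) -> np.ndarray:
    """Unwrapped instantaneous phase of the band-pass filtered signal.

    The analytic-signal angle is 0 at positive maxima of the filtered
    trace, matching the peak = 0 / trough = pi convention.
    """
    filt = bandpass_filter(x, fs, band)
    n = len(filt)
    analytic = signal.hilbert(filt, N=next_fast_len(n))[:n]
    return np.unwrap(np.angle(analytic))


def spike_theta_phase(
    lfp,
    epochs: ThetaEpochs,
    spike_times: np.ndarray,
    band: tuple[float, float] = THETA_BAND,
    speed_mask_fn=None,
) -> tuple[np.ndarray, int]:
    """Theta phase of each retained spike, in [0, 2pi).

    Spikes outside theta epochs (and, if ``speed_mask_fn`` is given,
    spikes for which it returns False) are excluded; the number of
    excluded spikes is returned alongside the phases.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    keep = epochs.contains(spike_times)
    if speed_mask_fn is not None:
        keep &= speed_mask_fn(spike_times)
    phase = instantaneous_phase(lfp.samples, lfp.rate, band)
    t = np.arange(len(phase)) / lfp.rate
    phases = np.mod(np.interp(spike_times[keep], t, phase), 2 * np.pi)
    return phases, int(np.sum(~keep))


def circular_stats(phases: np.ndarray) -> tuple[float, float]:
    """Preferred phase (circular mean, [0, 2pi)) and resultant length R."""
    phases = np.asarray(phases, dtype=float)
    if len(phases) == 0:
        return np.nan, np.nan
    z = np.exp(1j * phases).mean()
    return float(np.mod(np.angle(z), 2 * np.pi)), float(np.abs(z))


def theta_index(
    spike_times: np.ndarray,
    acg_bin: float = 0.005,
    min_spikes: int = MIN_SPIKES_THETA_INDEX,
) -> float:
    """Theta rhythmicity of a spike train from its autocorrelogram.

    Index = (P - T) / (P + T) with P the mean 5-ms-bin autocorrelogram
    count between 100 and 140 ms (one theta period) and T the mean count
    between 50 and 70 ms (half a period); 0 when P + T = 0, NaN when the
    train has fewer than ``min_spikes`` spikes.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) < min_spikes:
        return np.nan
    counts, edges = autocorrelogram(spike_times, acg_bin, 0.150)
    centers = (edges[:-1] + edges[1:]) / 2
    peak = counts[(centers > 0.100) & (centers < 0.140)].mean()
    trough = counts[(centers > 0.050) & (centers < 0.070)].mean()
    if peak + trough == 0:
        return 0.0
    return float((peak - trough) / (peak + trough))


def theta_profile(
    lfp,
    epochs: ThetaEpochs,
    spike_times: np.ndarray,
    speed_mask_fn=None,
    acg_bin: float = 0.005,
    min_spikes: int = MIN_SPIKES_THETA_INDEX,
) -> ThetaProfile:
    """Full theta locking summary for one unit.

    Phase statistics and the theta index both use only spikes emitted
    inside theta epochs while the animal is moving.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    keep = epochs.contains(spike_times)
    if speed_mask_fn is not None:
        keep &= speed_mask_fn(spike_times)
    retained = spike_times[keep]
    phases, _ = spike_theta_phase(lfp, epochs, spike_times, speed_mask_fn=speed_mask_fn)
    pref, r = circular_stats(phases)
    ti = theta_index(retained, acg_bin, min_spikes)
    defined = len(phases) > 0 and np.isfinite(ti)
    return ThetaProfile(
        preferred_phase=pref,
        resultant_length=r,
        n_spikes=len(phases),
        theta_index=ti,
        theta_modulated=bool(np.isfinite(ti) and ti > THETA_INDEX_THRESHOLD),
        defined=defined,
    )
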
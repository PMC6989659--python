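"""Spike-train auto- and cross-correlograms (raw coincidence counts)."""

from __future__ import annotations

import numpy as np


def cross_correlogram(
    pre: np.ndarray, post: np.ndarray, bin_size: float, max_lag: float
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of post-spike latencies relative to each pre spike.

    Returns ``(counts, edges)`` where ``edges`` spans [-max_lag, +max_lag]
    in steps of ``bin_size`` and ``counts[k]`` is the number of spike pairs
    with latency in ``[edges[k], edges[k+1])``. Both trains must be sorted.
    """
    n_bins = int(round(2 * max_lag / bin_size))
    # integer-multiple edges avoid half-ULP misbinning of exact lags
    edges = (np.arange(n_bins + 1) - n_bins // 2) * bin_size
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) == 0 or len(post) == 0:
        return np.zeros(n_bins, dtype=np.int64), edges
    lo = np.searchsorted(post, pre + edges[0])
    hi = np.searchsorted(post, pre + edges[-1])
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.zeros(n_bins, dtype=np.int64), edges
    rep_pre = np.repeat(pre, counts)
    starts = np.cumsum(counts) - counts
    flat = np.repeat(lo, counts) + np.arange(total) - np.repeat(starts, counts)
    diffs = post[flat] - rep_pre
    hist, _ = np.histogram(diffs, bins=edges)
    return hist.astype(np.int64), edges


def autocorrelogram(
    spikes: np.ndarray, bin_size: float, max_lag: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided spike autocorrelogram (positive lags, zero-lag excluded).

    Returns ``(counts, edges)`` with ``edges`` spanning (0, max_lag] in
    steps of ``bin_size``; counts are raw coincidence counts.
    """
    n_bins = int(round(max_lag / bin_size))
    edges = np.arange(n_bins + 1) * bin_size
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) < 2:
        return np.zeros(n_bins, dtype=np.int64), edges
    full, full_edges = cross_correlogram(spikes, spikes, bin_size, max_lag)
    # keep positive-lag half; self-pairs (lag 0) all fall in the first
    # positive bin, remove them
    half = full[n_bins:].copy()
    half[0] -= len(spikes)
    return half, edges
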
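"""Physiological cell typing.

Three layers of classification:

* excitatory/inhibitory - monosynaptic connections detected from
  cross-correlogram peaks/troughs against global bands built from
  spike-time jitter surrogates (uniform +/-5 ms, 1000 surrogates, 99%
  acceptance, significance window 1-5 ms); jitter-labelled units then
  seed a linear discriminant in the (trough-to-peak latency, waveform
  asymmetry) plane that labels the remaining units;
* hippocampal interneuron subtypes - putative PV- vs SOM-expressing
  cells from autocorrelogram burst index and refractory period (PV:
  bursty with refractory < 7 ms; SOM: non-bursty with refractory > 4 ms);
* EC2 principal subtypes - putative stellate vs pyramidal cells from
  theta locking (preferred phase, resultant length) relative to the
  local EC2 theta, using configurable decision regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .correlograms import autocorrelogram, cross_correlogram

CCG_BIN = 0.001            # s
CCG_MAX_LAG = 0.020        # s
JITTER_HALF_WIDTH = 0.005  # s
N_JITTER_SURROGATES = 1000
SIGNIFICANCE_WINDOW = (0.001, 0.005)   # s, latency window for verdicts
MIN_SPIKES_CCG = 50
MIN_SPIKES_ACG = 200
PV_REFRACTORY_MAX = 0.007  # s
SOM_REFRACTORY_MIN = 0.004  # s


@dataclass
class CcgTestResult:
    """Jitter-based monosynaptic connection test for one ordered pair."""

    ccg: np.ndarray
    edges: np.ndarray
    upper_band: np.ndarray
    lower_band: np.ndarray
    verdict: str               # excitatory / inhibitory / none
    insufficient: bool = False


@dataclass
class AcgFeatures:
    """Burst index in [-1, 1] and refractory period in seconds."""

    burst_index: float
    refractory_s: float
    defined: bool = True


@dataclass
class CellTypeLabel:
    ei: str = "unclassified"         # principal / interneuron / unclassified
    subtype: str = "unclassified"    # PV / SOM / stellate / pyramidal / unclassified
    low_confidence: bool = False


def jitter_ccg_test(
    pre: np.ndarray,
    post: np.ndarray,
    n_surrogates: int = N_JITTER_SURROGATES,
    jitter: float = JITTER_HALF_WIDTH,
    rng: np.random.Generator | None = None,
    same_electrode: bool = False,
    min_spikes: int = MIN_SPIKES_CCG,
) -> CcgTestResult:
    """Detect a monosynaptic connection from ``pre`` to ``post``.

    Every spike of both trains is independently perturbed on a uniform
    [-jitter, +jitter] interval; global 99% acceptance bands are the
    per-bin max/min of each surrogate cross-correlogram over the whole
    [-20, +20] ms interval. The verdict is excitatory when the observed
    CCG exceeds the upper band in any 1-ms bin at latency 1-5 ms, and
    inhibitory when at least one such bin falls below the lower band.
    For same-electrode pairs the 0-1 ms bin is never considered.
    """
    rng = np.random.default_rng() if rng is None else rng
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ccg, edges = cross_correlogram(pre, post, CCG_BIN, CCG_MAX_LAG)
    if len(pre) < min_spikes or len(post) < min_spikes:
        nan = np.full(len(ccg), np.nan)
        return CcgTestResult(ccg, edges, nan, nan, "none", insufficient=True)

    pre_j = np.sort(pre[None, :] + rng.uniform(-jitter, jitter, (n_surrogates, len(pre))), axis=1)
    post_j = np.sort(post[None, :] + rng.uniform(-jitter, jitter, (n_surrogates, len(post))), axis=1)
    surr = np.empty((n_surrogates, len(ccg)))
    for i in range(n_surrogates):
        surr[i], _ = cross_correlogram(pre_j[i], post_j[i], CCG_BIN, CCG_MAX_LAG)
    # global bands at 99% acceptance: per-surrogate extremum over the
    # whole interval, then the 99th percentile across surrogates
    upper = np.percentile(surr.max(axis=1), 99.0)
    lower = np.percentile(surr.min(axis=1), 1.0)
    upper_band = np.full(len(ccg), upper)
    lower_band = np.full(len(ccg), lower)

    centers = (edges[:-1] + edges[1:]) / 2
    lo, hi = SIGNIFICANCE_WINDOW
    win = (centers > lo) & (centers < hi)
    if same_electrode:
        win &= centers > CCG_BIN  # drop the 0-1 ms bin
    verdict = "none"
    if np.any(ccg[win] > upper):
        verdict = "excitatory"
    elif np.any(ccg[win] < lower):
        verdict = "inhibitory"
    return CcgTestResult(ccg, edges, upper_band, lower_band, verdict)


@dataclass
class WaveformSeparation:
    """Fitted E/I discriminant in the (trough-to-peak, asymmetry) plane."""

    weights: np.ndarray         # (2,) hyperplane normal
    intercept: float
    labels: list[str]
    low_confidence: np.ndarray  # bool per unit
    fitted: bool                # True when learned from jitter labels


def waveform_ei_separation(
    trough_to_peak: np.ndarray,
    asymmetry: np.ndarray,
    seed_labels: list[str | None],
    margin: float = 0.25,
    fallback_boundary: tuple[float, float, float] = (1.0, 0.0, -0.425),
    min_per_class: int = 5,
) -> WaveformSeparation:
    """Separate principal cells from interneurons by spike waveform.

    ``seed_labels`` carries 'excitatory'/'inhibitory' for jitter-labelled
    units and None elsewhere. With at least ``min_per_class`` labelled
    units per class a linear discriminant is fitted on the labelled
    subset; otherwise the configured fixed boundary
    (w_ttp, w_asym, intercept) is used. Every unit is labelled by the
    side of the hyperplane; units within ``margin`` (normalised distance)
    are flagged low-confidence.
    """
    x = np.column_stack([np.asarray(trough_to_peak, float), np.asarray(asymmetry, float)])
    seed_idx = [i for i, s in enumerate(seed_labels) if s in ("excitatory", "inhibitory")]
    ys = [seed_labels[i] for i in seed_idx]
    n_e = sum(1 for s in ys if s == "excitatory")
    n_i = sum(1 for s in ys if s == "inhibitory")
    if n_e >= min_per_class and n_i >= min_per_class:
        lda = LinearDiscriminantAnalysis()
        lda.fit(x[seed_idx], [1 if s == "excitatory" else 0 for s in ys])
        w = lda.coef_[0]
        b = float(lda.intercept_[0])
        fitted = True
    else:
        w = np.asarray(fallback_boundary[:2], dtype=float)
        b = float(fallback_boundary[2])
        fitted = False
    dist = (x @ w + b) / np.linalg.norm(w)
    labels = ["principal" if d > 0 else "interneuron" for d in dist]
    low_conf = np.abs(dist) < margin
    for i in np.nonzero(np.abs(dist) == 0)[0]:
        labels[i] = "unclassified"
    return WaveformSeparation(w, b, labels, low_conf, fitted)


def acg_features(
    spike_times: np.ndarray,
    bin_size: float = 0.001,
    min_spikes: int = MIN_SPIKES_ACG,
    peak_search_max: float = 0.050,
) -> AcgFeatures:
    """Burst index and refractory period from the 1-ms autocorrelogram.

    Burst amplitude = (mean ACG over 0-10 ms) - (mean ACG over 40-50 ms,
    the baseline); burst index = amplitude / max(peak, baseline), in [-1, 1].
    The refractory period is the first bin whose first-difference of the
    ACG (from 0 ms up to the global ACG peak within 0-50 ms) exceeds one
    SD of those differences.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) < min_spikes:
        return AcgFeatures(np.nan, np.nan, defined=False)
    counts, edges = autocorrelogram(spike_times, bin_size, peak_search_max)
    counts = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    # the burst peak is measured as the mean over the 0-10 ms window:
    # unbiased (zero) for a flat autocorrelogram, unlike the max bin
    peak = counts[centers < 0.010].mean()
    baseline = counts[(centers > 0.040) & (centers < 0.050)].mean()
    denom = max(peak, baseline)
    burst = 0.0 if denom == 0 else (peak - baseline) / denom

    peak_bin = int(np.argmax(counts))
    if peak_bin < 2:
        return AcgFeatures(float(burst), np.nan, defined=False)
    deriv = np.diff(counts[: peak_bin + 1])
    sd = deriv.std()
    refractory = np.nan
    if sd > 0:
        above = np.nonzero(deriv > sd)[0]
        if len(above):
            refractory = float(edges[above[0] + 1])
    return AcgFeatures(float(burst), refractory, defined=np.isfinite(refractory))


def classify_pv_som(features: AcgFeatures) -> str:
    """Putative PV / SOM interneuron subtype from ACG features.

    PV: positive burst index and refractory period shorter than 7 ms.
    SOM: negative burst index and refractory period longer than 4 ms.
    Anything else (including undefined features) is unclassified.
    """
    if not features.defined or not np.isfinite(features.refractory_s):
        return "unclassified"
    if features.burst_index > 0 and features.refractory_s < PV_REFRACTORY_MAX:
        return "PV"
    if features.burst_index < 0 and features.refractory_s > SOM_REFRACTORY_MIN:
        return "SOM"
    return "unclassified"


@dataclass
class PolarRegion:
    """A decision region in (preferred phase, resultant length) space.

    ``phase_interval`` is [lo, hi) in radians and may wrap past 2*pi;
    ``r_interval`` is [lo, hi] on the resultant length. Boundary points
    (either coordinate exactly on an edge) are deliberately excluded so
    boundary units stay unclassified.
    """

    label: str
    phase_interval: tuple[float, float]
    r_interval: tuple[float, float] = (0.0, 1.0)

    def contains(self, phase: float, r: float) -> bool:
        lo, hi = self.phase_interval
        p = np.mod(phase, 2 * np.pi)
        if lo <= hi:
            in_phase = lo < p < hi
        else:  # wrapped interval
            in_phase = p > lo or p < hi
        return bool(in_phase and self.r_interval[0] < r < self.r_interval[1])


# Synthetic default regions for the EC2 stellate/pyramidal split. These are
# NOT the published calbindin-calibrated parameters (which live in external
# released code); they encode only the qualitative picture - pyramidal cells
# lock strongly near the local theta trough, stellate cells more weakly and
# nearer the peak - and should be replaced from config for any real claim.
DEFAULT_EC2_REGIONS = [
    PolarRegion("pyramidal", (np.pi / 2, 3 * np.pi / 2), (0.1, 1.0)),
    PolarRegion("stellate", (3 * np.pi / 2, np.pi / 2), (0.0, 1.0)),
]


def classify_ec2_stellate_pyramidal(
    preferred_phase: float,
    resultant_length: float,
    regions: list[PolarRegion] | None = None,
) -> str:
    """Putative stellate vs pyramidal label for an EC2 principal cell.

    Membership is evaluated against decision regions in (preferred phase,
    R) space measured against the *local* EC2 theta; units outside every
    region - including units exactly on a region boundary - remain
    unclassified.
    """
    if not (np.isfinite(preferred_phase) and np.isfinite(resultant_length)):
        return "unclassified"
    regions = DEFAULT_EC2_REGIONS if regions is None else regions
    for region in regions:
        if region.contains(preferred_phase, resultant_length):
            return region.label
    return "unclassified"


def regions_from_config(entries: list[dict]) -> list[PolarRegion]:
    """Build EC2 decision regions from config entries.

    Each entry: ``{label, phase_interval: [lo, hi] (rad), r_interval: [lo, hi]}``.
    """
    return [
        PolarRegion(
            e["label"],
            tuple(e["phase_interval"]),
            tuple(e.get("r_interval", (0.0, 1.0))),
        )
        for e in entries
    ]
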
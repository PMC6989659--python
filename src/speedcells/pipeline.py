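"""Per-session and cohort-level orchestration.

``run_session`` sequences the full analysis for one SessionBundle:
kinematics (interpolated/smoothed position, speed, head direction),
theta epoch detection and per-unit theta profiles, per-unit speed-coding
statistics with circular-shuffle nulls, pooled speed-cell
classification, and autocorrelogram-based cell typing. ``summarize_cohort``
aggregates unit tables into per-group counts with exact (Clopper-Pearson)
binomial intervals and group means.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import cell_classification as cc
from . import kinematics as kin
from . import speed_coding as sc
from . import theta_analysis as ta


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the study defaults."""

    dt: float = kin.DEFAULT_DT
    smooth_sd: float = kin.SPEED_SMOOTH_SD
    vmin: float = kin.SPEED_MIN
    vmax: float = kin.SPEED_MAX
    n_shuffles: int = sc.N_SHUFFLES
    shuffle_margin: float = sc.SHUFFLE_MARGIN
    max_shift: float = sc.SHIFT_MAX
    theta_band: tuple[float, float] = ta.THETA_BAND
    theta_ratio_thresh: float = 2.0
    theta_min_dur: float = 1.0
    theta_acg_bin: float = 0.005
    min_spikes: int = 100
    seed: int = 0
    pooled_thresholds: bool = True
    percentiles: tuple[float, float] = (1.0, 99.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionResult:
    """Unit table, classification thresholds and the exclusion log."""

    units: pd.DataFrame
    lower_threshold: float
    upper_threshold: float
    exclusions: list[dict] = field(default_factory=list)
    config: AnalysisConfig | None = None


def run_session(session, config: AnalysisConfig | None = None) -> SessionResult:
    """Run the full per-unit analysis for one session.

    Deterministic under a fixed config seed; every excluded unit appears
    in the exclusion log with a reason, and every unit contributes
    exactly one row (undefined statistics are NaN-flagged, not dropped).
    """
    cfg = AnalysisConfig() if config is None else config
    rng = np.random.default_rng(cfg.seed)

    x_raw, y_raw = kin.interpolate_position(session.trajectory, cfg.dt)
    x = kin.smooth_position(x_raw)
    y = kin.smooth_position(y_raw)
    speed = kin.compute_speed(x, y, cfg.smooth_sd, cfg.vmin, cfg.vmax)

    lfp = session.lfp[0]
    epochs = ta.detect_theta_epochs(
        lfp, ratio_thresh=cfg.theta_ratio_thresh, min_dur=cfg.theta_min_dur
    )

    def moving(times: np.ndarray) -> np.ndarray:
        idx = np.floor((times - speed.t0) / speed.dt).astype(int)
        ok = (idx >= 0) & (idx < len(speed))
        out = np.zeros(len(times), dtype=bool)
        out[ok] = speed.valid[idx[ok]]
        return out

    rows: list[dict] = []
    exclusions: list[dict] = []
    nulls: list[sc.ShuffleNull] = []
    for unit in session.units:
        row: dict = {
            "unit_id": unit.unit_id,
            "region_layer": unit.region_layer,
            "n_spikes": unit.n_spikes,
        }
        if unit.n_spikes < cfg.min_spikes:
            exclusions.append({"unit_id": unit.unit_id, "reason": "too few spikes"})
            row.update(
                speed_score=np.nan, slope=np.nan, norm_slope=np.nan,
                info_per_spike=np.nan, info_per_sec=np.nan, mean_rate=np.nan,
                preferred_shift=np.nan, shift_excluded=False,
                preferred_phase=np.nan, resultant_length=np.nan,
                theta_index=np.nan, theta_modulated=False,
                burst_index=np.nan, refractory_ms=np.nan, defined=False,
            )
            rows.append(row)
            nulls.append(sc.ShuffleNull(np.full(cfg.n_shuffles, np.nan), unit.n_spikes))
            continue
        res = sc.analyse_unit(unit.spike_times, speed, cfg.dt, cfg.smooth_sd, cfg.max_shift)
        null = sc.shuffle_null(
            unit.spike_times, session.duration, speed,
            cfg.n_shuffles, cfg.shuffle_margin, rng, cfg.dt, cfg.smooth_sd,
        )
        nulls.append(null)
        profile = ta.theta_profile(
            lfp, epochs, unit.spike_times, speed_mask_fn=moving,
            acg_bin=cfg.theta_acg_bin,
        )
        feats = cc.acg_features(unit.spike_times)
        row.update(
            speed_score=res.speed_score,
            slope=res.slope,
            norm_slope=res.norm_slope,
            info_per_spike=res.info_per_spike,
            info_per_sec=res.info_per_sec,
            mean_rate=res.mean_rate,
            preferred_shift=res.preferred_shift,
            shift_excluded=res.shift_excluded,
            preferred_phase=profile.preferred_phase,
            resultant_length=profile.resultant_length,
            theta_index=profile.theta_index,
            theta_modulated=profile.theta_modulated,
            burst_index=feats.burst_index,
            refractory_ms=feats.refractory_s * 1000 if np.isfinite(feats.refractory_s) else np.nan,
            defined=res.defined,
        )
        rows.append(row)

    df = pd.DataFrame(rows)
    usable = [i for i, n in enumerate(nulls) if np.any(np.isfinite(n.scores))]
    if len(usable) >= 2:
        classes = sc.classify_speed_cells(
            df["speed_score"].to_numpy(),
            [nulls[i] for i in usable],
            cfg.percentiles,
            cfg.pooled_thresholds,
        )
        df["cell_class"] = classes.classes
        lo, hi = classes.lower, classes.upper
    else:
        df["cell_class"] = "undefined"
        lo = hi = np.nan
    return SessionResult(df, lo, hi, exclusions, cfg)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


def summarize_cohort(
    units: pd.DataFrame,
    group_cols: list[str],
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group speed-cell counts, exact binomial intervals and means.

    For each group: n, counts and fractions of p-Speed and n-Speed cells
    with 95% Clopper-Pearson intervals, and mean +/- SD of the requested
    value columns (defaults to score/slope/information/shift).
    """
    if value_cols is None:
        value_cols = [
            "speed_score", "slope", "norm_slope",
            "info_per_spike", "info_per_sec", "preferred_shift",
        ]
        value_cols = [c for c in value_cols if c in units.columns]
    out = []
    for key, grp in units.groupby(group_cols, dropna=False):
        if len(grp) == 0:
            continue
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        n = len(grp)
        rec["n"] = n
        for label, col_name in (("p-Speed", "p_speed"), ("n-Speed", "n_speed")):
            k = int((grp["cell_class"] == label).sum())
            lo, hi = clopper_pearson(k, n)
            rec[f"{col_name}_count"] = k
            rec[f"{col_name}_fraction"] = k / n
            rec[f"{col_name}_ci_low"] = lo
            rec[f"{col_name}_ci_high"] = hi
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rec[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out)
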
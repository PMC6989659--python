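"""Synthetic open-field sessions with known ground truth.

The generator emulates the statistical structure of a rat open-field
recording: a bounded 2-D trajectory whose speed follows a reflected
Ornstein-Uhlenbeck process spanning roughly 0-50 cm/s, an ~8 Hz theta
LFP with positive peaks at phase zero, and spike trains drawn as
inhomogeneous Poisson processes (exact thinning on a 1-ms grid) whose
rate combines a linear speed gain at a controllable temporal lag, a
von-Mises theta-phase gain normalised to unit mean, optional
place/grid/head-direction tuning, and controllable burst/refractory
structure. Every unit's true parameters are recorded verbatim so each
analysis stage can be validated by parameter recovery.

Lag convention: positive ``speed_lag_s`` makes the rate encode *future*
speed (rate leads speed - prospective); negative lags encode past speed
(retrospective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .session_io import LfpChannel, SessionBundle, SpikeTrain, TrajectoryRaw

FRAME_RATE = 30.0          # Hz video
LFP_RATE = 1250.0          # Hz
SIM_DT = 0.001             # s, rate-grid resolution for thinning
MIN_DURATION = 60.0        # s, below this the circular shuffle is empty

# Reflected-OU speed process; values chosen so ~90% of time falls in the
# analysable 2-50 cm/s band of a foraging rat.
OU_MEAN = 16.0             # cm/s
OU_THETA = 0.5             # 1/s mean reversion
OU_SIGMA = 8.0             # cm/s / sqrt(s)
HEADING_SIGMA = 1.2        # rad / sqrt(s), heading random-walk scale
LED_SEPARATION = 12.0      # cm, rear LED behind front along heading


@dataclass
class SyntheticGroundTruth:
    """True generative parameters of one synthetic unit."""

    baseline_rate: float                   # Hz
    speed_gain: float = 0.0                # Hz per (cm/s)
    speed_lag_s: float = 0.0               # + = prospective
    theta_kappa: float = 0.0
    theta_pref_phase: float = 0.0          # rad
    place_field: tuple[float, float, float] | None = None   # (cx, cy, width cm)
    grid: tuple[float, float, float, float] | None = None   # (spacing, orient, px, py)
    head_direction: tuple[float, float] | None = None       # (mean rad, kappa)
    burst_prob: float = 0.0
    burst_interval_s: float = 0.004
    refractory_s: float = 0.002
    region_layer: str = "CA1"
    unit_index: int = 0


@dataclass
class TrajectoryModel:
    """Parameters of the simulated foraging trajectory."""

    arena_side: float = 120.0
    speed_mean: float = OU_MEAN
    speed_theta: float = OU_THETA
    speed_sigma: float = OU_SIGMA
    heading_sigma: float = HEADING_SIGMA
    frame_rate: float = FRAME_RATE
    led_separation: float = LED_SEPARATION


def _unit_rng(seed: int, unit_index: int) -> np.random.Generator:
    # one stream per unit so adding units never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(unit_index)]))


def simulate_trajectory(
    model: TrajectoryModel, duration: float, seed: int
) -> TrajectoryRaw:
    """Simulate a two-LED foraging trajectory at the video frame rate.

    Speed is a reflected OU process; heading is a smoothed random walk
    with reflection off the arena walls. The rear LED sits
    ``led_separation`` cm behind the front LED along the heading.
    """
    if duration < MIN_DURATION:
        raise ValueError("duration must be at least 60 s for shuffle validity")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    dt = 1.0 / model.frame_rate
    n = int(round(duration * model.frame_rate)) + 1
    margin = model.led_separation + 2.0
    side = model.arena_side

    v = np.empty(n)
    phi = np.empty(n)
    x = np.empty(n)
    y = np.empty(n)
    v[0] = max(model.speed_mean + rng.normal(0, model.speed_sigma), 0.0)
    phi[0] = rng.uniform(0, 2 * np.pi)
    x[0] = rng.uniform(margin, side - margin)
    y[0] = rng.uniform(margin, side - margin)
    sq = np.sqrt(dt)
    for i in range(1, n):
        dv = -model.speed_theta * (v[i - 1] - model.speed_mean) * dt
        v[i] = abs(v[i - 1] + dv + model.speed_sigma * sq * rng.normal())
        phi[i] = phi[i - 1] + model.heading_sigma * sq * rng.normal()
        nx = x[i - 1] + v[i] * np.cos(phi[i]) * dt
        ny = y[i - 1] + v[i] * np.sin(phi[i]) * dt
        if nx < margin or nx > side - margin:
            phi[i] = np.pi - phi[i]
            nx = np.clip(nx, margin, side - margin)
        if ny < margin or ny > side - margin:
            phi[i] = -phi[i]
            ny = np.clip(ny, margin, side - margin)
        x[i], y[i] = nx, ny
    ts = np.arange(n) * dt
    front = np.column_stack([x, y])
    rear = front - model.led_separation * np.column_stack([np.cos(phi), np.sin(phi)])
    rear = np.clip(rear, 0.0, side)
    return TrajectoryRaw(ts, front, rear, np.zeros(n, dtype=bool))


def simulate_theta_lfp(
    duration: float,
    f0: float = 8.0,
    speed_fm: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    trajectory_speed: tuple[np.ndarray, np.ndarray] | None = None,
    rate: float = LFP_RATE,
    amplitude: float = 1000.0,
) -> LfpChannel:
    """An ~8 Hz theta LFP: (optionally speed-modulated) sinusoid + noise.

    Peaks are positive maxima, i.e. phase zero by the analysis
    convention. With ``speed_fm`` (Hz per cm/s) and a
    ``(times, speeds)`` pair, the instantaneous frequency is
    f0 + speed_fm * v(t).
    """
    if not 5.0 <= f0 <= 11.0:
        raise ValueError("f0 must lie in the 5-11 Hz theta band")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if speed_fm is not None and trajectory_speed is not None:
        vt, vv = trajectory_speed
        inst_f = f0 + speed_fm * np.interp(t, vt, vv)
        phase = 2 * np.pi * np.cumsum(inst_f) / rate
    else:
        phase = 2 * np.pi * f0 * t
    samples = amplitude * np.cos(phase)
    if noise_sd > 0:
        samples = samples + amplitude * noise_sd * rng.standard_normal(n)
    return LfpChannel(samples, rate, "EC3")


def _fine_speed_and_heading(
    traj: TrajectoryRaw, duration: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Speed, position and heading interpolated onto the 1-ms rate grid."""
    ts = traj.timestamps
    fx, fy = traj.front_led_xy[:, 0], traj.front_led_xy[:, 1]
    dt_frame = np.diff(ts)
    v_frame = np.hypot(np.diff(fx), np.diff(fy)) / dt_frame
    v_t = (ts[:-1] + ts[1:]) / 2
    tf = np.arange(int(round(duration / SIM_DT))) * SIM_DT
    v = np.interp(tf, v_t, v_frame)
    x = np.interp(tf, ts, fx)
    y = np.interp(tf, ts, fy)
    rx, ry = traj.rear_led_xy[:, 0], traj.rear_led_xy[:, 1]
    hd = np.arctan2(
        np.interp(tf, ts, fy - ry), np.interp(tf, ts, fx - rx)
    )
    return tf, v, np.column_stack([x, y]), hd


def _spatial_gain(truth: SyntheticGroundTruth, pos: np.ndarray, hd: np.ndarray) -> np.ndarray:
    gain = np.ones(len(pos))
    if truth.place_field is not None:
        cx, cy, width = truth.place_field
        d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
        gain = gain * np.exp(-d2 / (2 * width**2))
    if truth.grid is not None:
        spacing, orient, px, py = truth.grid
        k = 4 * np.pi / (np.sqrt(3) * spacing)
        g = np.zeros(len(pos))
        for ang in (orient, orient + np.pi / 3, orient + 2 * np.pi / 3):
            kx, ky = k * np.cos(ang), k * np.sin(ang)
            g = g + np.cos(kx * (pos[:, 0] - px) + ky * (pos[:, 1] - py))
        gain = gain * np.clip((g + 1.5) / 4.5, 0.0, None)
    if truth.head_direction is not None:
        mu, kappa = truth.head_direction
        gain = gain * np.exp(kappa * np.cos(hd - mu)) / i0(kappa)
    m = gain.mean()
    return gain / m if m > 0 else gain


def fine_covariates(
    trajectory: TrajectoryRaw,
    theta_lfp: LfpChannel | None,
    duration: float,
) -> dict:
    """Precompute the 1-ms-grid covariates shared by all units of a session."""
    tf, v, pos, hd = _fine_speed_and_heading(trajectory, duration)
    phase = None
    if theta_lfp is not None:
        from .theta_analysis import instantaneous_phase

        t_lfp = np.arange(len(theta_lfp.samples)) / theta_lfp.rate
        phase = np.interp(tf, t_lfp, instantaneous_phase(theta_lfp.samples, theta_lfp.rate))
    return {"tf": tf, "v": v, "pos": pos, "hd": hd, "phase": phase}


def simulate_unit(
    truth: SyntheticGroundTruth,
    trajectory: TrajectoryRaw,
    theta_lfp: LfpChannel | None,
    duration: float,
    seed: int,
    covariates: dict | None = None,
) -> SpikeTrain:
    """Draw one spike train from its ground-truth rate model by thinning.

    lambda(t) = max(0, baseline + gain * v(t + lag)) * g_theta(phi(t))
    * g_space(x(t)), piecewise-constant at 1 ms; g_theta is a von-Mises
    gain normalised to unit mean over phase; optional burst doublets are
    appended with the stated probability, and the absolute refractory
    period is enforced afterwards.
    """
    rng = _unit_rng(seed, truth.unit_index + 2)
    if covariates is None:
        covariates = fine_covariates(trajectory, theta_lfp, duration)
    v, pos, hd = covariates["v"], covariates["pos"], covariates["hd"]
    lag_bins = int(round(truth.speed_lag_s / SIM_DT))
    v_lagged = np.roll(v, -lag_bins)  # lambda(t) follows v(t + lag)
    if lag_bins > 0:
        v_lagged[-lag_bins:] = v[-1]
    elif lag_bins < 0:
        v_lagged[:-lag_bins] = v[0]
    lam = np.clip(truth.baseline_rate + truth.speed_gain * v_lagged, 0.0, None)
    if truth.theta_kappa > 0 and covariates["phase"] is not None:
        lam = lam * np.exp(
            truth.theta_kappa * np.cos(covariates["phase"] - truth.theta_pref_phase)
        ) / i0(truth.theta_kappa)
    if truth.place_field or truth.grid or truth.head_direction:
        lam = lam * _spatial_gain(truth, pos, hd)

    lam_max = float(lam.max())
    if lam_max <= 0:
        return SpikeTrain(f"synth{truth.unit_index}", np.empty(0), truth.region_layer)
    if lam_max > 1.0 / truth.refractory_s:
        import warnings

        warnings.warn("peak rate exceeds 1/refractory; requested rate unattainable")
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, n_cand))
    lam_at = lam[np.minimum((cand / SIM_DT).astype(int), len(lam) - 1)]
    spikes = cand[rng.uniform(0, lam_max, n_cand) < lam_at]
    if truth.burst_prob > 0 and len(spikes):
        doublet = spikes[rng.uniform(size=len(spikes)) < truth.burst_prob]
        spikes = np.sort(np.concatenate([spikes, doublet + truth.burst_interval_s]))
        spikes = spikes[spikes < duration]
    # enforce the absolute refractory period
    if len(spikes) > 1:
        keep = np.ones(len(spikes), dtype=bool)
        last = spikes[0]
        for i in range(1, len(spikes)):
            if spikes[i] - last < truth.refractory_s:
                keep[i] = False
            else:
                last = spikes[i]
        spikes = spikes[keep]
    return SpikeTrain(
        f"synth{truth.unit_index}", spikes, truth.region_layer, shank=1
    )


def simulate_session(
    truths: list[SyntheticGroundTruth],
    duration: float,
    seed: int,
    model: TrajectoryModel | None = None,
    theta_f0: float = 8.0,
    theta_noise_sd: float = 0.3,
    session_id: str = "synthetic",
) -> tuple[SessionBundle, list[SyntheticGroundTruth]]:
    """Build a full SessionBundle (trajectory, theta LFP, units) + truth."""
    model = TrajectoryModel() if model is None else model
    traj = simulate_trajectory(model, duration, seed)
    lfp = simulate_theta_lfp(duration, f0=theta_f0, noise_sd=theta_noise_sd, seed=seed)
    cov = fine_covariates(traj, lfp, duration)
    units = [simulate_unit(t, traj, lfp, duration, seed, covariates=cov) for t in truths]
    for i, (u, t) in enumerate(zip(units, truths)):
        u.unit_id = f"synth{i}"
        t.unit_index = i
    bundle = SessionBundle(session_id, model.arena_side, traj, [lfp], units, duration)
    return bundle, truths


def truth_records(truths: list[SyntheticGroundTruth]) -> list[dict]:
    """Flatten ground-truth objects into TSV-ready records."""
    out = []
    for t in truths:
        out.append(
            {
                "unit_index": t.unit_index,
                "region_layer": t.region_layer,
                "baseline_rate": t.baseline_rate,
                "speed_gain": t.speed_gain,
                "speed_lag_s": t.speed_lag_s,
                "theta_kappa": t.theta_kappa,
                "theta_pref_phase": t.theta_pref_phase,
                "burst_prob": t.burst_prob,
                "refractory_s": t.refractory_s,
            }
        )
    return out
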
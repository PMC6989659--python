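"""Neuroscope-style session reading and tabular output.

A recording session arrives as a directory of plain files per the classic
Neuroscope/Klusters layout: one spike-sample file (``<base>.res.<shank>``,
one integer acquisition-clock sample per line) and one cluster file
(``<base>.clu.<shank>``, first line = number of clusters, then one cluster
id per spike) per shank, a position file (``<base>.whl``, whitespace
separated front/rear LED coordinates per video frame, -1 marking missing
samples) and a flat-binary 16-bit little-endian interleaved LFP file
(``<base>.eeg``). A small YAML/JSON layout config declares sampling rates,
the channel-to-layer map, pixel scale and arena geometry.

All internal times are seconds as 64-bit floats; acquisition-clock
integers are preserved in provenance fields. Cluster ids 0 and 1 are
reserved for artifact/noise and dropped (Neuroscope community convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NOISE_CLUSTERS = (0, 1)


@dataclass
class SessionLayoutConfig:
    """Declares the on-disk dialect of one session directory."""

    sample_rate: float = 20000.0   # Hz, acquisition clock for .res files
    lfp_rate: float = 1250.0       # Hz, .eeg sampling rate
    video_rate: float = 30.0       # Hz, .whl frame rate
    px_to_cm: float = 1.0          # cm per pixel (~0.4 for typical setups)
    n_channels: int = 1            # interleaved channels in .eeg
    channel_layers: list[str] = field(default_factory=lambda: ["EC3"])
    shank_regions: dict[int, str] = field(default_factory=dict)
    arena_side: float = 120.0      # cm
    session_id: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionLayoutConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        raw["shank_regions"] = {int(k): v for k, v in raw.get("shank_regions", {}).items()}
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            "sample_rate": self.sample_rate,
            "lfp_rate": self.lfp_rate,
            "video_rate": self.video_rate,
            "px_to_cm": self.px_to_cm,
            "n_channels": self.n_channels,
            "channel_layers": list(self.channel_layers),
            "shank_regions": {int(k): v for k, v in self.shank_regions.items()},
            "arena_side": self.arena_side,
            "session_id": self.session_id,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class TrajectoryRaw:
    """Two-LED tracking at the video frame rate; -1/-1 rows are missing."""

    timestamps: np.ndarray        # s
    front_led_xy: np.ndarray      # (n, 2) cm
    rear_led_xy: np.ndarray       # (n, 2) cm
    missing: np.ndarray           # (n,) bool

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.front_led_xy = np.asarray(self.front_led_xy, dtype=float)
        self.rear_led_xy = np.asarray(self.rear_led_xy, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")


@dataclass
class LfpChannel:
    """One LFP channel at 1250 Hz; positive polarity is up."""

    samples: np.ndarray
    rate: float = 1250.0
    region_layer: str = "EC3"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")


@dataclass
class SpikeTrain:
    """One sorted unit: spike times in seconds, ascending."""

    unit_id: str
    spike_times: np.ndarray
    region_layer: str = ""
    shank: int = 0
    raw_samples: np.ndarray | None = None   # acquisition-clock provenance
    mean_waveform: np.ndarray | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if len(self.spike_times) and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class SessionBundle:
    """One recording session in memory."""

    session_id: str
    arena_side: float
    trajectory: TrajectoryRaw
    lfp: list[LfpChannel]
    units: list[SpikeTrain]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _read_int_lines(path: Path) -> np.ndarray:
    text = path.read_text().split()
    return np.asarray(text, dtype=np.int64) if text else np.empty(0, dtype=np.int64)


def read_session(path: str | Path, config: SessionLayoutConfig) -> SessionBundle:
    """Read one Neuroscope-style session directory into a SessionBundle.

    Spike samples are converted from the acquisition clock to seconds;
    clusters 0 and 1 (artifact/noise) are dropped; spikes beyond the LFP
    duration raise a warning and are clamped (the train is flagged).
    """
    path = Path(path)
    base = config.session_id or path.name
    eeg_path = path / f"{base}.eeg"
    whl_path = path / f"{base}.whl"
    for p in (eeg_path, whl_path):
        if not p.exists():
            raise FileNotFoundError(f"missing session file: {p}")

    raw = np.fromfile(eeg_path, dtype="<i2")
    nch = config.n_channels
    lfp_samples = raw.reshape(-1, nch)
    duration = lfp_samples.shape[0] / config.lfp_rate
    layers = list(config.channel_layers) + ["?"] * (nch - len(config.channel_layers))
    lfp = [
        LfpChannel(lfp_samples[:, c].astype(float), config.lfp_rate, layers[c])
        for c in range(nch)
    ]

    pos = np.loadtxt(whl_path, ndmin=2)
    if pos.shape[1] == 2:
        pos = np.hstack([pos, np.full_like(pos, -1.0)])
    missing = np.all(pos[:, :2] == -1, axis=1)
    front = np.where(pos[:, :2] == -1, np.nan, pos[:, :2]) * config.px_to_cm
    rear = np.where(pos[:, 2:4] == -1, np.nan, pos[:, 2:4]) * config.px_to_cm
    ts = np.arange(pos.shape[0]) / config.video_rate
    traj = TrajectoryRaw(ts, front, rear, missing)

    units: list[SpikeTrain] = []
    for res_path in sorted(path.glob(f"{base}.res.*")):
        shank = int(res_path.suffix.lstrip("."))
        clu_path = path / f"{base}.clu.{shank}"
        if not clu_path.exists():
            raise FileNotFoundError(f"missing cluster file: {clu_path}")
        samples = _read_int_lines(res_path)
        clu = _read_int_lines(clu_path)
        if len(clu) != len(samples) + 1:
            raise ValueError(
                f"malformed cluster file {clu_path}: expected "
                f"{len(samples) + 1} lines, got {len(clu)}"
            )
        clu = clu[1:]
        region = config.shank_regions.get(shank, "")
        for cid in np.unique(clu):
            if cid in NOISE_CLUSTERS:
                continue
            s = samples[clu == cid]
            t = s / config.sample_rate
            clamped = False
            if len(t) and t[-1] > duration:
                warnings.warn(
                    f"unit {shank}:{cid} has spikes beyond the LFP duration; clamped"
                )
                keep = t <= duration
                s, t = s[keep], t[keep]
                clamped = True
            units.append(
                SpikeTrain(
                    unit_id=f"sh{shank}_c{cid}",
                    spike_times=t,
                    region_layer=region,
                    shank=shank,
                    raw_samples=s,
                    clamped=clamped,
                )
            )
    return SessionBundle(base, config.arena_side, traj, lfp, units, duration)


def write_session(bundle: SessionBundle, path: str | Path, config: SessionLayoutConfig) -> None:
    """Write a SessionBundle as a Neuroscope-style fixture directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    base = bundle.session_id
    n = len(bundle.lfp[0].samples)
    lfp = np.zeros((n, config.n_channels), dtype="<i2")
    for c, ch in enumerate(bundle.lfp[: config.n_channels]):
        lfp[:, c] = np.clip(np.round(ch.samples), -32768, 32767).astype("<i2")
    lfp.tofile(path / f"{base}.eeg")

    front = np.where(np.isfinite(bundle.trajectory.front_led_xy),
                     bundle.trajectory.front_led_xy / config.px_to_cm, -1.0)
    rear = np.where(np.isfinite(bundle.trajectory.rear_led_xy),
                    bundle.trajectory.rear_led_xy / config.px_to_cm, -1.0)
    front[bundle.trajectory.missing] = -1.0
    rear[bundle.trajectory.missing] = -1.0
    np.savetxt(path / f"{base}.whl", np.hstack([front, rear]), fmt="%.6f")

    by_shank: dict[int, list[SpikeTrain]] = {}
    for u in bundle.units:
        by_shank.setdefault(u.shank, []).append(u)
    for shank, trains in sorted(by_shank.items()):
        samples: list[np.ndarray] = []
        cids: list[np.ndarray] = []
        for i, u in enumerate(trains):
            s = (
                u.raw_samples
                if u.raw_samples is not None
                else np.round(u.spike_times * config.sample_rate).astype(np.int64)
            )
            samples.append(np.asarray(s, dtype=np.int64))
            cids.append(np.full(len(s), i + 2, dtype=np.int64))
        all_s = np.concatenate(samples) if samples else np.empty(0, dtype=np.int64)
        all_c = np.concatenate(cids) if cids else np.empty(0, dtype=np.int64)
        order = np.argsort(all_s, kind="stable")
        np.savetxt(path / f"{base}.res.{shank}", all_s[order], fmt="%d")
        n_clu = (len(trains) + 2) if trains else 2
        with open(path / f"{base}.clu.{shank}", "w") as fh:
            fh.write(f"{n_clu}\n")
            fh.writelines(f"{c}\n" for c in all_c[order])
    config.to_file(path / "layout.yaml")


def write_unit_table(records: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write per-unit records as a TSV with full float precision.

    An empty record list yields a header-only file (``columns`` supplies
    the schema in that case).
    """
    path = Path(path)
    df = pd.DataFrame.from_records(records, columns=columns)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write unit table to {path}: {exc}") from exc


def read_unit_table(path: str | Path) -> pd.DataFrame:
    """Read a unit table written by :func:`write_unit_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
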
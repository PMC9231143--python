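"""Synthetic MMG + force generator.

Emulates an isometric knee-extension protocol: three accelerometer channels
(rectus femoris, vastus lateralis, vastus medialis) sampled at 1 kHz while the
subject holds one of eight force levels (10-80% of maximal voluntary
contraction, MVC) for 6 s.  Each MMG channel is modelled as band-limited
(5-100 Hz) Gaussian noise whose RMS amplitude grows monotonically with the
force level - the working premise of MMG-based force estimation, where signal
amplitude tracks motor-unit recruitment - plus white measurement noise.  The
force trace is the nominal level plus a slow sinusoidal drift and a smoothed
random wobble, with the total peak-to-peak excursion bounded well inside the
5% admission rule used for stable-segment selection.

The generator is fully seeded: identical (config, level, seed) triplets give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .signal_prep import bandpass_mmg, lowpass_force

__all__ = ["SyntheticConfig", "MMGRecording", "generate_trial", "generate_dataset"]

DEFAULT_LEVELS = tuple(round(0.1 * k, 2) for k in range(1, 9))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic protocol.

    Parameters
    ----------
    mvc_newtons : force scale; 300 N matches the range of a typical leg
        force-plate load cell.
    levels : fractions of MVC held in the eight trials (default 0.1..0.8).
    duration_s, fs : trial length and sampling rate (6 s at 1 kHz).
    n_channels, channel_labels : accelerometer count and muscle names.
    amp_gain_intercept, amp_gain_slope : the affine map from %MVC to MMG
        channel RMS, amp(l) = intercept + slope * l; strictly increasing in l
        whenever slope > 0.
    noise_sd : SD of the additive white measurement noise.
    fluctuation_frac : bound on the relative peak-to-peak force fluctuation
        (|force - nominal| <= fluctuation_frac / 2 * nominal), kept below the
        5% stable-segment admission rule.
    band : MMG passband realised by the package's own band-pass filter.
    """

    mvc_newtons: float = 300.0
    levels: tuple[float, ...] = DEFAULT_LEVELS
    duration_s: float = 6.0
    fs: float = 1000.0
    n_channels: int = 3
    channel_labels: tuple[str, ...] = ("RF", "VL", "VM")
    amp_gain_intercept: float = 0.2
    amp_gain_slope: float = 0.8
    noise_sd: float = 0.05
    fluctuation_frac: float = 0.04
    band: tuple[float, float] = (5.0, 100.0)
    drift_hz: float = 0.3

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"duration_s * fs must be an integer sample count, got {n}"
            )
        if not all(0.0 < l <= 1.0 for l in self.levels):
            raise ConfigError("all levels must lie in (0, 1]")
        if not 0.0 <= self.fluctuation_frac < 0.05:
            raise ConfigError(
                "fluctuation_frac must lie in [0, 0.05) to satisfy the "
                "stable-segment admission rule"
            )
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if len(self.channel_labels) != self.n_channels:
            raise ConfigError("channel_labels must match n_channels")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def amp_gain(self, level: float) -> float:
        """MMG channel RMS at a given fraction of MVC."""
        return self.amp_gain_intercept + self.amp_gain_slope * level


@dataclass
class MMGRecording:
    """A multichannel MMG trial with its synchronized force trace."""

    channels: np.ndarray
    force: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.force = np.asarray(self.force, dtype=float)
        if self.force.ndim != 1:
            raise DataError("force must be a 1-D vector")
        if self.channels.shape[1] != self.force.size:
            raise DataError(
                "channels and force must have identical sample counts "
                f"({self.channels.shape[1]} vs {self.force.size})"
            )
        if self.fs <= 0:
            raise DataError("fs must be positive")
        if self.channels.shape[0] < 1:
            raise DataError("at least one channel is required")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        cols = {"time_s": t}
        for label, ch in zip(self.channel_labels, self.channels):
            cols[f"mmg_{label}"] = ch
        cols["force_N"] = self.force
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "MMGRecording":
        df = pd.read_csv(path)
        mmg_cols = [c for c in df.columns if c.startswith("mmg_")]
        if not mmg_cols or "force_N" not in df.columns:
            raise DataError(
                f"{path}: expected columns mmg_<label>... and force_N"
            )
        if fs is None:
            if "time_s" not in df.columns or len(df) < 2:
                raise DataError(f"{path}: cannot infer fs without time_s")
            dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
            if dt <= 0:
                raise DataError(f"{path}: non-increasing time_s column")
            fs = 1.0 / dt
        return cls(
            channels=df[mmg_cols].to_numpy().T,
            force=df["force_N"].to_numpy(),
            fs=fs,
            channel_labels=tuple(c.removeprefix("mmg_") for c in mmg_cols),
            meta={"source": str(path)},
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, (np.random.Generator,)):
        return seed
    return np.random.default_rng(seed)


def generate_trial(level: float, cfg: SyntheticConfig, seed) -> MMGRecording:
    """Generate one seeded trial at ``level`` (fraction of MVC).

    Each channel is white Gaussian noise passed through the module band-pass
    (with 1 s of padding on either side so filter transients are discarded),
    rescaled to an exact RMS of ``cfg.amp_gain(level)``, plus white noise of
    SD ``cfg.noise_sd``.  The force trace is
    ``level * mvc * (1 + drift + wobble)`` with the combined deviation bounded
    by ``fluctuation_frac / 2``.
    """
    if not 0.0 < level <= 1.0:
        raise DataError(f"level must lie in (0, 1], got {level}")
    rng = _rng(seed)
    n = cfg.n_samples
    pad = int(round(cfg.fs))  # 1 s of padding per side against edge effects

    channels = np.empty((cfg.n_channels, n))
    target_rms = cfg.amp_gain(level)
    for c in range(cfg.n_channels):
        raw = rng.standard_normal(n + 2 * pad)
        shaped = bandpass_mmg(raw, cfg.fs, band=cfg.band)[pad : pad + n]
        rms = np.sqrt(np.mean(shaped**2))
        channels[c] = shaped * (target_rms / rms)
        if cfg.noise_sd > 0:
            channels[c] += cfg.noise_sd * rng.standard_normal(n)

    base = level * cfg.mvc_newtons
    if cfg.fluctuation_frac > 0:
        t = np.arange(n) / cfg.fs
        half = 0.5 * cfg.fluctuation_frac
        drift = np.sin(2 * np.pi * cfg.drift_hz * t + rng.uniform(0, 2 * np.pi))
        wobble = lowpass_force(rng.standard_normal(n + 2 * pad), cfg.fs)[
            pad : pad + n
        ]
        peak = np.max(np.abs(wobble))
        wobble = wobble / peak if peak > 0 else wobble
        dev = 0.5 * half * drift + 0.5 * half * wobble
        force = base * (1.0 + dev)
    else:
        force = np.full(n, base)

    return MMGRecording(
        channels=channels,
        force=force,
        fs=cfg.fs,
        channel_labels=cfg.channel_labels,
        meta={"level": level, "seed": seed, "config": asdict(cfg)},
    )


def generate_dataset(
    cfg: SyntheticConfig = SyntheticConfig(),
    trials_per_level: int = 9,
    seed: int = 0,
) -> list[MMGRecording]:
    """Generate ``trials_per_level`` trials at every configured level.

    Per-trial seeds are spawned deterministically from the master seed, so a
    fixed master seed reproduces the full dataset.  The default of 9 trials
    per level yields 54 windows per level under the default windowing, which
    downstream trimming reduces to 50 per level (400 windows over 8 levels).
    """
    if trials_per_level < 1:
        raise ConfigError("trials_per_level must be >= 1")
    recordings = []
    idx = 0
    for level in cfg.levels:
        for trial in range(trials_per_level):
            child = np.random.SeedSequence(entropy=(int(seed), idx))
            rec = generate_trial(level, cfg, np.random.default_rng(child))
            rec.meta.update(
                {"seed": (int(seed), idx), "trial": trial, "level": level}
            )
            recordings.append(rec)
            idx += 1
    return recordings


def write_dataset(recordings, out_dir) -> list[Path]:
    """Write one CSV per recording plus a manifest of seeds and levels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for i, rec in enumerate(recordings):
        path = out_dir / f"trial_{i:03d}.csv"
        rec.to_csv(path)
        paths.append(path)
        manifest.append(
            {
                "file": path.name,
                "level": rec.meta.get("level"),
                "seed": str(rec.meta.get("seed")),
                "fs": rec.fs,
            }
        )
    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    return paths
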
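"""Signal conditioning for MMG/force recordings.

MMG channels are band-pass filtered (fourth-order Butterworth, 5-100 Hz,
zero-phase), the force trace is low-pass filtered (third-order Butterworth,
2 Hz, zero-phase), a 6-s segment with relative force fluctuation below 5% is
selected, and the segment is cut into sliding windows (1000 samples, 100
samples shared between neighbours).  Features and targets are standardised
with a Z-score scaler fitted on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .exceptions import (
    ConfigError,
    DataError,
    NoStableSegmentError,
    NotFittedError,
)

__all__ = [
    "WindowSpec",
    "WindowSample",
    "ZScoreScaler",
    "bandpass_mmg",
    "lowpass_force",
    "select_stable_segment",
    "slide_windows",
    "preprocess",
    "fit_zscore",
    "apply_zscore",
]

MMG_BAND_HZ = (5.0, 100.0)
MMG_FILTER_ORDER = 4
FORCE_CUTOFF_HZ = 2.0
FORCE_FILTER_ORDER = 3


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``length`` samples per window, ``overlap``
    samples shared between consecutive windows (step = length - overlap)."""

    length: int = 1000
    overlap: int = 100

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError(f"window length must be positive, got {self.length}")
        if not 0 <= self.overlap < self.length:
            raise ConfigError(
                f"overlap must satisfy 0 <= overlap < length, got "
                f"overlap={self.overlap}, length={self.length}"
            )

    @property
    def step(self) -> int:
        return self.length - self.overlap


class WindowSample(NamedTuple):
    """One analysis window: channel data ``(n_channels, length)``, the mean
    force over the window, and the start index in the source recording."""

    data: np.ndarray
    force: float
    start: int


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError(f"expected a 1-D signal, got shape {x.shape}")
    return x


def _zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # sosfiltfilt needs more samples than its padding length
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise DataError(
            f"signal too short for zero-phase filtering: {x.size} samples, "
            f"need more than {padlen}"
        )
    return sps.sosfiltfilt(sos, x)


def bandpass_mmg(
    x,
    fs: float,
    band: tuple[float, float] = MMG_BAND_HZ,
    order: int = MMG_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass for MMG channels.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    passband magnitude response is squared and the phase response is zero;
    the effective attenuation order doubles.
    """
    x = _as_1d(x)
    if fs <= 2.0 * band[1]:
        raise ConfigError(
            f"sampling rate {fs} Hz too low: passband top {band[1]} Hz "
            "must lie below the Nyquist frequency"
        )
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return _zero_phase(sos, x)


def lowpass_force(
    x,
    fs: float,
    cutoff: float = FORCE_CUTOFF_HZ,
    order: int = FORCE_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass for the force trace."""
    x = _as_1d(x)
    if fs <= 2.0 * cutoff:
        raise ConfigError(
            f"sampling rate {fs} Hz too low for a {cutoff} Hz low-pass"
        )
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _zero_phase(sos, x)


def select_stable_segment(
    force,
    fs: float,
    duration_s: float = 6.0,
    max_fluct: float = 0.05,
) -> tuple[int, int]:
    """Earliest ``duration_s`` span whose relative force fluctuation
    (max - min) / mean is below ``max_fluct`` with a positive mean.

    Returns the half-open index range ``(start, stop)``.  Raises
    :class:`NoStableSegmentError` when no admissible span exists.
    """
    force = _as_1d(force)
    w = int(round(duration_s * fs))
    if w <= 0:
        raise ConfigError("duration_s * fs must be positive")
    if force.size < w:
        raise DataError(
            f"force trace has {force.size} samples, need at least {w}"
        )
    n_starts = force.size - w + 1
    # O(n) rolling extrema; entry j of the centered filter covers exactly
    # the window starting at j - w//2, so valid starts need no edge padding.
    half = w // 2
    cmax = maximum_filter1d(force, size=w, mode="nearest")
    cmin = minimum_filter1d(force, size=w, mode="nearest")
    wmax = cmax[half : half + n_starts]
    wmin = cmin[half : half + n_starts]
    csum = np.concatenate(([0.0], np.cumsum(force)))
    means = (csum[w:] - csum[:-w]) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        fluct = (wmax - wmin) / means
    ok = (means > 0) & (fluct < max_fluct)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise NoStableSegmentError(
            f"no {duration_s}-s window with relative fluctuation below "
            f"{max_fluct:g}"
        )
    start = int(idx[0])
    return start, start + w


def slide_windows(recording, spec: WindowSpec = WindowSpec()) -> list[WindowSample]:
    """Cut a recording into sliding windows.

    Window ``i`` starts at ``i * spec.step``; only windows fully inside the
    recording are produced.  Each window carries all channels and the mean of
    the force trace over the window.
    """
    channels = np.atleast_2d(np.asarray(recording.channels, dtype=float))
    force = _as_1d(recording.force)
    n = channels.shape[1]
    if force.size != n:
        raise DataError(
            f"force length {force.size} does not match channels length {n}"
        )
    if n < spec.length:
        raise DataError(
            f"recording has {n} samples, shorter than window length "
            f"{spec.length}"
        )
    out = []
    for start in range(0, n - spec.length + 1, spec.step):
        stop = start + spec.length
        out.append(
            WindowSample(
                data=channels[:, start:stop],
                force=float(force[start:stop].mean()),
                start=start,
            )
        )
    return out


def preprocess(recording, duration_s: float = 6.0, max_fluct: float = 0.05,
               select_stable: bool = True):
    """Filter a raw recording and crop it to its stable-force segment.

    Band-passes every MMG channel, low-passes the force trace, then keeps the
    earliest ``duration_s`` span whose filtered-force fluctuation is below
    ``max_fluct``.  Returns a new recording of the same type.
    """
    from .synthetic import MMGRecording

    fs = recording.fs
    channels = np.vstack([bandpass_mmg(ch, fs) for ch in recording.channels])
    force = lowpass_force(recording.force, fs)
    if select_stable:
        start, stop = select_stable_segment(force, fs, duration_s, max_fluct)
    else:
        start, stop = 0, force.size
    meta = dict(getattr(recording, "meta", {}) or {})
    meta["segment"] = (start, stop)
    return MMGRecording(
        channels=channels[:, start:stop],
        force=force[start:stop],
        fs=fs,
        channel_labels=tuple(recording.channel_labels),
        meta=meta,
    )


@dataclass
class ZScoreScaler:
    """Column-wise standardisation z = (x - mean) / sd with the n-1 sample SD.

    Zero-variance columns are dropped at fit time with a warning; the kept
    column mask is applied consistently by :meth:`transform`.
    """

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    kept_: np.ndarray | None = field(default=None, repr=False)
    n_features_in_: int | None = None

    def fit(self, X) -> "ZScoreScaler":
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if X.ndim != 2 or X.shape[0] < 2:
            raise DataError("fit requires a 2-D array with at least 2 rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        kept = sd > 0
        if not kept.all():
            warnings.warn(
                f"dropping {int((~kept).sum())} zero-variance column(s) "
                "before Z-scoring",
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[1]
        self.mean_ = mean[kept]
        self.sd_ = sd[kept]
        self.kept_ = kept
        return self

    def _check(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise NotFittedError("ZScoreScaler used before fit()")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        X = self._check(X)
        return (X[:, self.kept_] - self.mean_) / self.sd_

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z) -> np.ndarray:
        if self.mean_ is None:
            raise NotFittedError("ZScoreScaler used before fit()")
        Z = np.asarray(Z, dtype=float)
        squeeze = Z.ndim == 1
        if squeeze:
            Z = Z[:, None]
        out = Z * self.sd_ + self.mean_
        return out[:, 0] if squeeze else out


def fit_zscore(X) -> ZScoreScaler:
    return ZScoreScaler().fit(X)


def apply_zscore(scaler: ZScoreScaler, X) -> np.ndarray:
    return scaler.transform(X)
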
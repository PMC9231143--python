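"""Per-window MMG feature extraction.

Each analysis window of each channel yields 25 features in four groups:

* time domain (7): RMS, Pearson kurtosis, sample SD, slope-sign changes,
  mean absolute value, zero crossings, waveform length;
* frequency domain (2): mean power frequency (MPF) and median frequency
  (MDF) of the Welch spectrum;
* time-frequency (9): total wavelet-packet energy (WPE) and the energies of
  the 8 terminal bands of a 3-level db4 wavelet-packet decomposition, in
  natural frequency order (WP1 = lowest band);
* nonlinear dynamics (7): normalized Lempel-Ziv complexity of the
  median-binarized window, sample / approximate / fuzzy / distribution
  entropy, box-counting fractal dimension of the signal graph, and the
  largest Lyapunov exponent (Rosenstein divergence-curve slope).

Parameter conventions (the literature defaults, fixed here and logged with
every extraction): embedding m = 2 and tolerance r = 0.2 x SD for SampEn,
ApEn and FuzzyEn; FuzzyEn exponential membership with gradient 2; DistEn
with m = 2 and 512 histogram bins; Lyapunov embedding dimension 5 with the
delay at the first autocorrelation zero-crossing and a mean-period Theiler
exclusion.  A three-channel window therefore produces 75 named features,
channel-major ("<channel>_<feature>").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.spatial.distance import cdist, pdist
from scipy.stats import kurtosis as _pearson_kurtosis

from .exceptions import DataError, FeatureError
from .signal_prep import WindowSpec, preprocess, slide_windows

__all__ = [
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "TIMEFREQ_FEATURES",
    "NONLINEAR_FEATURES",
    "ALL_GROUPS",
    "FeatureMatrix",
    "time_domain",
    "freq_domain",
    "wavelet_packet",
    "nonlinear",
    "extract_window",
    "extract_all",
    "extract_dataset",
]

TIME_FEATURES = ("RMS", "kurtosis", "SD", "SSC", "MAV", "ZC", "WL")
FREQ_FEATURES = ("MPF", "MDF")
TIMEFREQ_FEATURES = ("WPE",) + tuple(f"WP{i}" for i in range(1, 9))
NONLINEAR_FEATURES = ("LZC", "SampEn", "ApEn", "FuzzyEn", "DistEn", "FD", "LyapExp")
ALL_GROUPS = ("time", "freq", "timefreq", "nonlinear")
_GROUP_NAMES = {
    "time": TIME_FEATURES,
    "freq": FREQ_FEATURES,
    "timefreq": TIMEFREQ_FEATURES,
    "nonlinear": NONLINEAR_FEATURES,
}

AMPLITUDE_FEATURES = ("RMS", "SD", "MAV", "WL")  # scale-carrying time-domain set
SPECTRAL_FEATURES = FREQ_FEATURES  # pure frequency-location set


# --------------------------------------------------------------------------
# time domain

def time_domain(x) -> dict[str, float]:
    """Seven time-domain features of one window.

    Zero-crossing convention: a sample equal to zero counts as positive; a
    crossing is a strict sign change between consecutive samples.  A
    slope-sign change at interior sample k requires
    (x[k] - x[k-1]) * (x[k] - x[k+1]) > 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DataError("time_domain needs a 1-D window of length >= 3")
    if np.all(x == x[0]):
        raise FeatureError("constant window: kurtosis undefined")
    diff = np.diff(x)
    sign = np.where(x >= 0, 1, -1)
    interior = x[1:-1]
    ssc = int(np.count_nonzero((interior - x[:-2]) * (interior - x[2:]) > 0))
    return {
        "RMS": float(np.sqrt(np.mean(x**2))),
        "kurtosis": float(_pearson_kurtosis(x, fisher=False, bias=True)),
        "SD": float(np.std(x, ddof=1)),
        "SSC": ssc,
        "MAV": float(np.mean(np.abs(x))),
        "ZC": int(np.count_nonzero(sign[1:] != sign[:-1])),
        "WL": float(np.sum(np.abs(diff))),
    }


# --------------------------------------------------------------------------
# frequency domain

def freq_domain(x, fs: float) -> dict[str, float]:
    """Mean power frequency (spectral centroid) and median frequency of the
    Welch spectrum (Hann window, segment min(n, 512), 50% overlap)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise DataError("freq_domain needs a 1-D window of length >= 64")
    if not np.any(x):
        raise FeatureError("all-zero window: spectrum undefined")
    nperseg = min(x.size, 512)
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)
    total = p.sum()
    if total <= 0:
        raise FeatureError("zero total spectral power")
    mpf = float((f * p).sum() / total)
    cum = np.cumsum(p)
    mdf = float(f[np.searchsorted(cum, total / 2.0)])
    return {"MPF": mpf, "MDF": mdf}


# --------------------------------------------------------------------------
# time-frequency domain

def wavelet_packet(x, wavelet: str = "db4", level: int = 3) -> dict[str, float]:
    """Band energies of a 3-level wavelet-packet decomposition.

    Terminal nodes are taken in natural frequency order, so WP1 is the lowest
    band; WPE is the total energy (the sum of the eight band energies by
    construction).
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(wavelet)
    if x.ndim != 1 or x.size < (2**level) * w.dec_len:
        raise DataError(
            f"wavelet_packet needs length >= {(2**level) * w.dec_len}"
        )
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="symmetric",
                            maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    energies = [float(np.sum(np.square(node.data))) for node in nodes]
    out = {"WPE": float(sum(energies))}
    out.update({f"WP{i + 1}": e for i, e in enumerate(energies)})
    return out


# --------------------------------------------------------------------------
# nonlinear dynamics

def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    if n <= 1:
        raise FeatureError(f"window too short to embed with m={m}, delay={delay}")
    idx = np.arange(n)[:, None] + np.arange(m) * delay
    return x[idx]


def _check_nonconstant(x) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 100:
        raise DataError("nonlinear features need a 1-D window of length >= 100")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise FeatureError("constant window: nonlinear features undefined")
    return x, sd


def lz76_complexity(s: str) -> int:
    """Number of phrases in the Lempel-Ziv (1976) exhaustive parse of a
    binary string, Kaspar-Schuster scan."""
    n = len(s)
    if n == 0:
        raise DataError("empty sequence")
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def binarize_median(x) -> str:
    """'1' where the sample exceeds the median, else '0'."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return "".join("1" if v > med else "0" for v in x)


def lempel_ziv(x) -> float:
    """Normalized LZ complexity c(n) * log2(n) / n of the median-binarized
    window; invariant under positive rescaling of the signal."""
    x, _ = _check_nonconstant(x)
    s = binarize_median(x)
    return lz76_complexity(s) * math.log2(len(s)) / len(s)


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with B (A) the number of template pairs of
    length m (m+1) within Chebyshev distance r, self-matches excluded and the
    same n - m templates used at both lengths."""
    x, sd = _check_nonconstant(x)
    if r is None:
        r = 0.2 * sd
    n = x.size
    tm = _embed(x, m)[: n - m]
    tm1 = _embed(x, m + 1)
    b = int(np.count_nonzero(pdist(tm, "chebyshev") <= r))
    a = int(np.count_nonzero(pdist(tm1, "chebyshev") <= r))
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) in the original self-match-inclusive form:
    phi(m) - phi(m+1) with phi the mean log fraction of templates within r."""
    x, sd = _check_nonconstant(x)
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        d = cdist(t, t, "chebyshev")
        frac = np.count_nonzero(d <= r, axis=1) / t.shape[0]
        return float(np.mean(np.log(frac)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x, m: int = 2, r: float | None = None, grad: int = 2) -> float:
    """FuzzyEn(m, r, n): templates are baseline-removed and similarity is the
    fuzzy membership exp(-(d^n)/r) of the Chebyshev distance d."""
    x, sd = _check_nonconstant(x)
    if r is None:
        r = 0.2 * sd
    n = x.size

    def phi(mm: int) -> float:
        t = _embed(x, mm)[: n - mm]
        t = t - t.mean(axis=1, keepdims=True)
        d = pdist(t, "chebyshev")
        return float(np.mean(np.exp(-(d**grad) / r)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        raise FeatureError("fuzzy entropy undefined: zero mean membership")
    return math.log(p_m) - math.log(p_m1)


def distribution_entropy(x, m: int = 2, bins: int = 512) -> float:
    """DistEn(m, B): Shannon entropy (base 2, normalized by log2 B) of the
    B-bin histogram of all pairwise Chebyshev distances between m-dimensional
    embedding vectors.  Bin edges span [0, max distance], which makes the
    value invariant under positive rescaling."""
    x, _ = _check_nonconstant(x)
    d = pdist(_embed(x, m), "chebyshev")
    dmax = d.max()
    if dmax == 0:
        raise FeatureError("all embedding vectors identical")
    hist, _ = np.histogram(d, bins=bins, range=(0.0, dmax))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() / math.log2(bins))


def fractal_dimension(x, n_scales: int = 6) -> float:
    """Box-counting dimension of the normalized signal graph.

    The graph is scaled into the unit square; for box sizes 2^-1 .. 2^-n the
    occupied boxes per time column are counted from the per-column vertical
    extent, and the dimension is the slope of log N against log(1/eps).
    """
    x, _ = _check_nonconstant(x)
    lo, hi = x.min(), x.max()
    y = (x - lo) / (hi - lo)
    t = np.linspace(0.0, 1.0, x.size)
    logs_n, logs_e = [], []
    for k in range(1, n_scales + 1):
        n_boxes = 2**k
        eps = 1.0 / n_boxes
        col = np.minimum((t * n_boxes).astype(int), n_boxes - 1)
        count = 0
        for c in range(n_boxes):
            seg = y[col == c]
            if seg.size == 0:
                continue
            rmin = min(int(seg.min() * n_boxes), n_boxes - 1)
            rmax = min(int(seg.max() * n_boxes), n_boxes - 1)
            count += rmax - rmin + 1
        logs_n.append(math.log(count))
        logs_e.append(math.log(1.0 / eps))
    slope = np.polyfit(logs_e, logs_n, 1)[0]
    return float(slope)


def _first_acf_zero(x: np.ndarray) -> int:
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[xc.size - 1 :]
    below = np.flatnonzero(acf <= 0)
    return int(below[0]) if below.size else max(1, x.size // 10)


def _mean_period(x: np.ndarray) -> int:
    f, p = sps.periodogram(x - x.mean())
    total = p.sum()
    if total <= 0:
        return 1
    mean_freq = float((f * p).sum() / total)  # cycles per sample
    if mean_freq <= 0:
        return 1
    return max(1, int(round(1.0 / mean_freq)))


def largest_lyapunov(
    x,
    m: int = 5,
    delay: int | None = None,
    theiler: int | None = None,
    k_max: int = 60,
    fit_len: int = 20,
) -> float:
    """Largest Lyapunov exponent (per sample) by the Rosenstein method.

    The series is delay-embedded (delay defaults to the first autocorrelation
    zero-crossing), each point is paired with its nearest neighbour outside a
    mean-period Theiler window, the mean log separation is followed for k_max
    steps, and the exponent is the least-squares slope over the first
    ``fit_len`` steps of the divergence curve.
    """
    x, _ = _check_nonconstant(x)
    if delay is None:
        delay = _first_acf_zero(x)
    if theiler is None:
        theiler = _mean_period(x)
    y = _embed(x, m, delay)
    n = y.shape[0]
    if n <= 2 * (theiler + 1):
        raise FeatureError("window too short for the requested embedding")
    d = cdist(y, y)
    idx = np.arange(n)
    d[np.abs(idx[:, None] - idx[None, :]) <= theiler] = np.inf
    nn = np.argmin(d, axis=1)
    finite = np.isfinite(d[idx, nn])
    k_max = min(k_max, n - 2)
    curve_k, curve_v = [], []
    for k in range(k_max + 1):
        ok = finite & (idx + k < n) & (nn + k < n)
        if not ok.any():
            break
        sep = np.linalg.norm(y[idx[ok] + k] - y[nn[ok] + k], axis=1)
        sep = sep[sep > 0]
        if sep.size == 0:
            continue
        curve_k.append(k)
        curve_v.append(float(np.mean(np.log(sep))))
    if len(curve_k) < 3:
        raise FeatureError("divergence curve too short for a slope fit")
    stop = min(fit_len + 1, len(curve_k))
    slope = np.polyfit(curve_k[:stop], curve_v[:stop], 1)[0]
    return float(slope)


def nonlinear(x) -> dict[str, float]:
    """The seven nonlinear-dynamics features of one window."""
    x, _ = _check_nonconstant(x)
    values = {
        "LZC": lempel_ziv(x),
        "SampEn": sample_entropy(x),
        "ApEn": approximate_entropy(x),
        "FuzzyEn": fuzzy_entropy(x),
        "DistEn": distribution_entropy(x),
        "FD": fractal_dimension(x),
        "LyapExp": largest_lyapunov(x),
    }
    bad = [k for k, v in values.items() if not math.isfinite(v)]
    if bad:
        raise FeatureError(f"non-finite nonlinear feature(s): {bad}")
    return values


# --------------------------------------------------------------------------
# assembly

def extract_window(x, fs: float, groups=ALL_GROUPS) -> dict[str, float]:
    """All requested feature groups for a single 1-D channel window, in the
    canonical order."""
    out: dict[str, float] = {}
    if "time" in groups:
        out.update(time_domain(x))
    if "freq" in groups:
        out.update(freq_domain(x, fs))
    if "timefreq" in groups:
        out.update(wavelet_packet(x))
    if "nonlinear" in groups:
        out.update(nonlinear(x))
    return out


def feature_names(channel_labels, groups=ALL_GROUPS) -> list[str]:
    names = []
    per_channel = [n for g in ALL_GROUPS if g in groups for n in _GROUP_NAMES[g]]
    for label in channel_labels:
        names.extend(f"{label}_{n}" for n in per_channel)
    return names


@dataclass
class FeatureMatrix:
    """Windows x named features, with the aligned per-window force targets."""

    features: pd.DataFrame
    force: np.ndarray
    provenance: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if len(self.features) != self.force.size:
            raise DataError("feature rows and force targets misaligned")
        if self.features.isna().any().any():
            raise DataError("feature matrix contains missing values")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    def select(self, columns) -> "FeatureMatrix":
        return FeatureMatrix(
            features=self.features[list(columns)].copy(),
            force=self.force.copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
            meta=dict(self.meta),
        )

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df["force_N"] = self.force
        if self.provenance is not None:
            for col in self.provenance.columns:
                df[f"prov_{col}"] = self.provenance[col].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "force_N" not in df.columns:
            raise DataError(f"{path}: missing force_N column")
        prov_cols = [c for c in df.columns if c.startswith("prov_")]
        prov = None
        if prov_cols:
            prov = df[prov_cols].rename(
                columns={c: c.removeprefix("prov_") for c in prov_cols}
            )
        feats = df.drop(columns=["force_N", *prov_cols])
        return cls(
            features=feats,
            force=df["force_N"].to_numpy(),
            provenance=prov,
            meta={"source": str(path)},
        )


def extract_all(
    windows,
    fs: float,
    channel_labels=None,
    groups=ALL_GROUPS,
    provenance: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Extract the feature matrix for a list of multichannel windows.

    Columns are channel-major (all features of channel 1, then channel 2, ...)
    with stable names ``<channel>_<feature>``.  Any per-feature failure is
    re-raised with the offending window index.
    """
    windows = list(windows)
    if not windows:
        raise DataError("no windows to extract features from")
    n_channels = np.atleast_2d(windows[0].data).shape[0]
    if channel_labels is None:
        channel_labels = [f"ch{i + 1}" for i in range(n_channels)]
    if len(channel_labels) != n_channels:
        raise DataError("channel_labels must match the window channel count")

    rows, force = [], []
    for w_idx, w in enumerate(windows):
        data = np.atleast_2d(w.data)
        row: dict[str, float] = {}
        for label, channel in zip(channel_labels, data):
            try:
                values = extract_window(channel, fs, groups)
            except Exception as exc:
                raise type(exc)(
                    f"window {w_idx}, channel {label}: {exc}"
                ) from exc
            row.update({f"{label}_{k}": v for k, v in values.items()})
        rows.append(row)
        force.append(w.force)

    df = pd.DataFrame(rows, columns=feature_names(channel_labels, groups))
    return FeatureMatrix(
        features=df,
        force=np.asarray(force),
        provenance=provenance,
        meta={"fs": fs, "groups": tuple(groups)},
    )


def extract_dataset(
    recordings,
    spec: WindowSpec = WindowSpec(),
    groups=ALL_GROUPS,
    windows_per_level: int | None = 50,
    do_preprocess: bool = True,
) -> FeatureMatrix:
    """Full dataset pipeline: filter + crop each recording, window it, cap the
    window count per force level, and extract features.

    With the default 8-level / 9-trial synthetic protocol and 1000/100
    windowing this yields exactly 400 windows (50 per level).
    """
    per_level: dict[float, list] = {}
    prov_rows = []
    fs = None
    labels = None
    for rec_idx, rec in enumerate(recordings):
        fs = rec.fs if fs is None else fs
        labels = tuple(rec.channel_labels) if labels is None else labels
        prepared = preprocess(rec) if do_preprocess else rec
        level = rec.meta.get("level", float("nan"))
        for w in slide_windows(prepared, spec):
            per_level.setdefault(level, []).append(
                (w, {"recording": rec_idx, "level": level, "start": w.start})
            )
    windows = []
    for level in sorted(per_level, key=lambda v: (math.isnan(v), v)):
        chosen = per_level[level]
        if windows_per_level is not None:
            chosen = chosen[:windows_per_level]
        for w, prov in chosen:
            windows.append(w)
            prov_rows.append(prov)
    return extract_all(
        windows,
        fs,
        channel_labels=labels,
        groups=groups,
        provenance=pd.DataFrame(prov_rows),
    )
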
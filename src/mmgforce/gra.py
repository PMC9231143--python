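"""Gray relational analysis (GRA) feature selection.

GRA scores how closely each comparison sequence (a feature observed over the
windows) tracks a reference sequence (the force target).  With difference
sequences Delta_i(k) = |F(k) - x_i(k)|, the relational coefficient is

    xi_i(k) = (min_min + rho * max_max) / (Delta_i(k) + rho * max_max)

where min_min and max_max are the global extremes of Delta over all features
and all time points, and rho in (0, 1) is the resolution coefficient
(default 0.5; resolution is sharpest for rho <= 0.5463).  The relational
degree r_i is the time average of xi_i(k); features are grouped into nested
combinations A-E by thresholding r_i at 0.6 / 0.75 / 0.8 / 0.85 / 0.9.

Both the force and the feature sequences must share a scale for Delta to be
meaningful, so :func:`feature_force_gra` Z-scores every column (and the
force) before computing degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .signal_prep import ZScoreScaler

__all__ = [
    "COMBINATION_THRESHOLDS",
    "GRAResult",
    "FeatureCombination",
    "relational_analysis",
    "select_combination",
    "feature_force_gra",
]

COMBINATION_THRESHOLDS = {"A": 0.60, "B": 0.75, "C": 0.80, "D": 0.85, "E": 0.90}


@dataclass
class GRAResult:
    """Difference sequences, relational coefficients and degrees."""

    delta: np.ndarray  # (n, m)
    xi: np.ndarray  # (n, m)
    r: np.ndarray  # (m,)
    rho: float
    feature_names: list[str]

    def ranking(self) -> pd.DataFrame:
        """Features sorted by decreasing relational degree."""
        df = pd.DataFrame({"feature": self.feature_names, "r": self.r})
        return df.sort_values("r", ascending=False, ignore_index=True)

    def membership_table(self) -> pd.DataFrame:
        """Per-feature boolean membership flags for combinations A-E."""
        df = pd.DataFrame({"feature": self.feature_names, "r": self.r})
        for label, thr in COMBINATION_THRESHOLDS.items():
            df[label] = self.r >= thr
        return df


@dataclass(frozen=True)
class FeatureCombination:
    """A thresholded feature subset (labels A-E, nested E within A)."""

    label: str
    threshold: float
    indices: tuple[int, ...]
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.indices)


def relational_analysis(F, X, rho: float = 0.5, feature_names=None) -> GRAResult:
    """Relational coefficients and degrees of each column of ``X`` against the
    reference sequence ``F``.

    Parameters
    ----------
    F : reference sequence, length n.
    X : comparison sequences as an (n, m) array or DataFrame (one column per
        feature).  Sequences are compared at face value; callers wanting
        scale-free degrees should standardise first (see
        :func:`feature_force_gra`).
    rho : resolution coefficient, in (0, 1).
    """
    if not 0.0 < rho < 1.0:
        raise ConfigError(f"rho must lie in (0, 1), got {rho}")
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size < 2:
        raise DataError("reference sequence must be 1-D with length >= 2")
    if X.ndim != 2 or X.shape[0] != F.size:
        raise DataError(
            f"comparison matrix must be (n, m) with n={F.size}, got {X.shape}"
        )
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]

    delta = np.abs(F[:, None] - X)
    dmin = float(delta.min())
    dmax = float(delta.max())
    if dmax == 0.0:
        xi = np.ones_like(delta)
    else:
        xi = (dmin + rho * dmax) / (delta + rho * dmax)
    r = xi.mean(axis=0)
    return GRAResult(delta=delta, xi=xi, r=r, rho=rho,
                     feature_names=list(feature_names))


def select_combination(result: GRAResult, label: str) -> FeatureCombination:
    """Features whose relational degree meets the labelled threshold
    (boundary inclusive).  Raises :class:`DataError` if none qualify."""
    if label not in COMBINATION_THRESHOLDS:
        raise ConfigError(
            f"unknown combination label {label!r}; expected one of "
            f"{sorted(COMBINATION_THRESHOLDS)}"
        )
    thr = COMBINATION_THRESHOLDS[label]
    idx = np.flatnonzero(result.r >= thr)
    if idx.size == 0:
        raise DataError(
            f"no features selected: no relational degree reaches the "
            f"combination-{label} threshold {thr}"
        )
    return FeatureCombination(
        label=label,
        threshold=thr,
        indices=tuple(int(i) for i in idx),
        names=tuple(result.feature_names[i] for i in idx),
    )


def feature_force_gra(feature_matrix, rho: float = 0.5) -> GRAResult:
    """GRA of a :class:`~mmgforce.features.FeatureMatrix` against its force
    targets, with every sequence Z-scored onto a common scale first."""
    raw = feature_matrix.features.to_numpy(dtype=float)
    scaler = ZScoreScaler().fit(raw)
    X = scaler.transform(raw)
    names = [
        c
        for c, keep in zip(feature_matrix.columns, scaler.kept_)
        if keep
    ]
    F = ZScoreScaler().fit_transform(feature_matrix.force)[:, 0]
    return relational_analysis(F, X, rho=rho, feature_names=names)
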
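"""Independent brute-force oracles used to cross-check the package.

Everything here is written from the defining formulas with plain loops and
no reuse of package internals, so agreement is evidence of correctness
rather than of shared code.
"""

from __future__ import annotations

import math

import numpy as np


def zc_enumeration(x) -> int:
    """Zero crossings by direct enumeration; zero counts as positive."""
    count = 0
    for a, b in zip(x[:-1], x[1:]):
        sa = 1 if a >= 0 else -1
        sb = 1 if b >= 0 else -1
        if sa != sb:
            count += 1
    return count


def ssc_enumeration(x) -> int:
    """Slope-sign changes by direct enumeration of interior samples."""
    count = 0
    for k in range(1, len(x) - 1):
        if (x[k] - x[k - 1]) * (x[k] - x[k + 1]) > 0:
            count += 1
    return count


def lz76_parse(s: str) -> int:
    """LZ76 exhaustive-history phrase count by naive substring search.

    Each phrase is the shortest extension of the current position that does
    not occur as a substring of everything before its last character; the
    final (possibly reproducible) phrase is counted.
    """
    n = len(s)
    phrases = 0
    pos = 0
    while pos < n:
        length = 1
        while pos + length <= n and s[pos : pos + length] in s[: pos + length - 1]:
            length += 1
        phrases += 1
        pos += length
    return phrases


def sampen_direct(x, m: int = 2, r: float | None = None) -> float:
    """SampEn by direct template counting (double loop, self-matches
    excluded, the same N-m templates at lengths m and m+1)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    n = len(x)
    n_templates = n - m
    b = a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def apen_direct(x, m: int = 2, r: float | None = None) -> float:
    """ApEn by the original definition (self-matches included)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    n = len(x)

    def phi(mm: int) -> float:
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def gra_direct(F, X, rho: float = 0.5):
    """Relational degrees by scalar loops over the defining formula."""
    F = np.asarray(F, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    delta = [[abs(F[k] - X[k, i]) for i in range(m)] for k in range(n)]
    flat = [d for row in delta for d in row]
    dmin, dmax = min(flat), max(flat)
    r = []
    for i in range(m):
        if dmax == 0:
            r.append(1.0)
            continue
        xi = [
            (dmin + rho * dmax) / (delta[k][i] + rho * dmax) for k in range(n)
        ]
        r.append(sum(xi) / n)
    return np.asarray(r)


def window_starts_enumeration(n_samples: int, length: int, step: int) -> list[int]:
    """All admissible window start indices by explicit scan."""
    starts = []
    s = 0
    while s + length <= n_samples:
        starts.append(s)
        s += step
    return starts


def stable_segment_scan(force, w: int, max_fluct: float):
    """Earliest admissible stable window by brute-force scan."""
    force = np.asarray(force, dtype=float)
    for s in range(len(force) - w + 1):
        seg = force[s : s + w]
        mean = seg.mean()
        if mean > 0 and (seg.max() - seg.min()) / mean < max_fluct:
            return s, s + w
    return None


def mantegna_phi(beta: float) -> float:
    """Mantegna scale factor from gamma-function arithmetic."""
    return (
        math.gamma(1 + beta)
        * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
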
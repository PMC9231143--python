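"""Cuckoo search (CS) and its improved variant (ICS).

CS is a Levy-flight metaheuristic: each nest (candidate solution) proposes a
move X + a0 * step * (X - x_best) with Mantegna-scheme heavy-tailed steps of
index beta, the proposal greedily replaces a randomly chosen nest when
better, and each nest is abandoned with probability Pa and rebuilt by a
biased random walk.  The global best is retained every iteration (elitism).

ICS keeps the same loop but (a) spreads the initial population with a Tent
chaotic map instead of i.i.d. uniform draws, and (b) replaces the fixed
a0 = 0.01 / Pa = 0.25 with schedules that decay over the run:

    a0(t) = a_min + (a_max - a_min)/2 * (cos(pi * ln(1 + (e-1) t/T)) + 1)
    Pa(t) = Pa_min + (Pa_max - Pa_min) * ((T - t)/T)^2

so early iterations explore (a0 = 0.2, Pa = 0.70) and late iterations
exploit (a0 = 0.001, Pa = 0.10).

The module also ships the four 2-D benchmark functions used to compare the
two algorithms (Rosenbrock, Griewank, cross-in-tray, Schaffer) and a
50-run summary harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, NumericalError

__all__ = [
    "CSParams",
    "ICSParams",
    "SearchTrace",
    "BenchmarkFunction",
    "levy_phi",
    "levy_step",
    "tent_map",
    "tent_sequence",
    "chaotic_init",
    "adaptive_a0",
    "adaptive_pa",
    "cs_search",
    "ics_search",
    "benchmark",
    "BENCHMARK_NAMES",
    "run_batch",
    "compare_runs",
]


def _check_bounds(bounds) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2:
        raise ConfigError("bounds must be a (dim, 2) array of [lower, upper]")
    if not np.all(b[:, 0] < b[:, 1]):
        raise ConfigError("every lower bound must be below its upper bound")
    return b


@dataclass(frozen=True)
class CSParams:
    """Plain cuckoo search settings (population 20, 200 iterations,
    Pa = 0.25, a0 = 0.01, beta = 1.5)."""

    bounds: tuple = ((-1.0, 1.0), (-1.0, 1.0))
    n_nests: int = 20
    T: int = 200
    beta: float = 1.5
    pa: float = 0.25
    a0: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        _check_bounds(self.bounds)
        if self.n_nests < 2:
            raise ConfigError("n_nests must be >= 2")
        if self.T < 1:
            raise ConfigError("T must be >= 1")
        if not 0.3 < self.beta <= 1.99:
            raise ConfigError(
                f"beta must lie in (0.3, 1.99], got {self.beta}"
            )
        if not 0.0 < self.pa < 1.0:
            raise ConfigError("pa must lie in (0, 1)")
        if self.a0 <= 0:
            raise ConfigError("a0 must be positive")

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass(frozen=True)
class ICSParams(CSParams):
    """Improved cuckoo search settings: Tent-chaotic initialization plus the
    adaptive a0/Pa schedules with their published constants."""

    a_min: float = 0.001
    a_max: float = 0.2
    pa_min: float = 0.1
    pa_max: float = 0.70

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 < self.a_min < self.a_max:
            raise ConfigError("need 0 < a_min < a_max")
        if not 0 < self.pa_min < self.pa_max < 1:
            raise ConfigError("need 0 < pa_min < pa_max < 1")


@dataclass
class SearchTrace:
    """Best-so-far fitness per iteration plus the final optimum."""

    best_fitness_history: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    seed: int
    n_evaluations: int

    def plot_convergence(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.best_fitness_history, **kwargs)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        return ax


# --------------------------------------------------------------------------
# Levy flights

def levy_phi(beta: float) -> float:
    """Mantegna scale factor
    phi = { Gamma(1+b) sin(pi b/2) / [Gamma((1+b)/2) b 2^((b-1)/2)] }^(1/b)."""
    if not 0.3 < beta <= 1.99:
        raise ConfigError(f"beta must lie in (0.3, 1.99], got {beta}")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(shape, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Mantegna steps phi * mu / |v|^(1/beta) with mu, v
    standard normal; the step-length tail decays like s^(-beta)."""
    phi = levy_phi(beta)
    mu = rng.standard_normal(shape)
    v = rng.standard_normal(shape)
    return phi * mu / np.abs(v) ** (1.0 / beta)


# --------------------------------------------------------------------------
# Tent map

_TENT_UNSTABLE = (0.0, 0.5, 2.0 / 3.0, 1.0)
_TENT_TOL = 1e-12


def tent_map(x):
    """Tent map on [0, 1]: 2x for x <= 1/2, else 2(1 - x)."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ConfigError("tent_map input must lie in [0, 1]")
    out = np.where(arr <= 0.5, 2.0 * arr, 2.0 * (1.0 - arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _tent_guard(x: float, rng: np.random.Generator) -> float:
    # The map's branches are exact in binary floating point, so every orbit
    # reaches 0 within ~53 iterations and the unstable set {0, 1/2, 2/3, 1}
    # absorbs it; re-seed from the RNG to keep the uniform invariant density.
    while any(abs(x - u) < _TENT_TOL for u in _TENT_UNSTABLE):
        x = rng.uniform(_TENT_TOL, 1.0 - _TENT_TOL)
    return x


def tent_sequence(n: int, rng: np.random.Generator, x0: float | None = None) -> np.ndarray:
    """``n`` Tent-map iterates starting from ``x0`` (random in (0, 1) when
    omitted), re-seeded away from the unstable set so long sequences keep the
    map's uniform invariant density."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    x = rng.uniform(0.0, 1.0) if x0 is None else float(x0)
    x = _tent_guard(x, rng)
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x = _tent_guard(tent_map(x), rng)
    return out


def chaotic_init(params: ICSParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Initial nest positions from per-dimension Tent sequences, affinely
    mapped into the search bounds (chaotic 0 -> lower bound, 1 -> upper)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    b = _check_bounds(params.bounds)
    cols = [
        b[j, 0] + tent_sequence(params.n_nests, rng) * (b[j, 1] - b[j, 0])
        for j in range(params.dim)
    ]
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# adaptive schedules

def _check_t(t: float, T: int) -> None:
    if not 0 <= t <= T:
        raise ConfigError(f"iteration t={t} outside [0, {T}]")


def adaptive_a0(t: float, p: ICSParams) -> float:
    """Step-control schedule, decaying from a_max at t=0 to a_min at t=T."""
    _check_t(t, p.T)
    u = math.log(1.0 + (math.e - 1.0) * t / p.T)
    return p.a_min + 0.5 * (p.a_max - p.a_min) * (math.cos(u * math.pi) + 1.0)


def adaptive_pa(t: float, p: ICSParams) -> float:
    """Discovery-probability schedule: quadratic decay from pa_max to pa_min."""
    _check_t(t, p.T)
    return p.pa_min + (p.pa_max - p.pa_min) * ((p.T - t) / p.T) ** 2


# --------------------------------------------------------------------------
# search loop

def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    f = np.asarray(objective(X), dtype=float)
    if f.shape != (X.shape[0],):
        raise NumericalError(
            f"objective must map (k, dim) to (k,), got {f.shape}"
        )
    if np.any(np.isnan(f)):
        raise NumericalError("objective returned NaN")
    return f


def _run(objective, p: CSParams, init, a0_of, pa_of) -> SearchTrace:
    rng = np.random.default_rng(p.seed)
    b = _check_bounds(p.bounds)
    lb, ub = b[:, 0], b[:, 1]
    n, dim = p.n_nests, p.dim

    X = init(rng)
    f = _evaluate(objective, X)
    n_evals = n
    i_best = int(np.argmin(f))
    best_x, best_f = X[i_best].copy(), float(f[i_best])
    history = [best_f]

    for t in range(1, p.T + 1):
        a0 = a0_of(t)
        pa = pa_of(t)

        # Levy-flight phase: propose a move per nest and keep the better egg
        # in that nest (greedy same-host comparison).
        cand = X + a0 * levy_step((n, dim), p.beta, rng) * (X - best_x)
        np.clip(cand, lb, ub, out=cand)
        fc = _evaluate(objective, cand)
        n_evals += n
        better = fc < f
        X[better] = cand[better]
        f[better] = fc[better]

        # Abandonment phase (standard empty-nests step): coordinates that
        # survive the Pa draw take a biased random walk along the difference
        # of two shuffled nests, with one shared step multiplier; rebuilt
        # nests are kept when better.
        keep = rng.random((n, dim)) > pa
        r1 = rng.permutation(n)
        r2 = rng.permutation(n)
        walk = X + rng.random() * (X[r1] - X[r2]) * keep
        np.clip(walk, lb, ub, out=walk)
        fw = _evaluate(objective, walk)
        n_evals += n
        better = fw < f
        X[better] = walk[better]
        f[better] = fw[better]

        i_best = int(np.argmin(f))
        if f[i_best] < best_f:
            best_f = float(f[i_best])
            best_x = X[i_best].copy()
        history.append(best_f)

    return SearchTrace(
        best_fitness_history=np.asarray(history),
        best_position=best_x,
        best_fitness=best_f,
        seed=p.seed,
        n_evaluations=n_evals,
    )


def cs_search(objective, params: CSParams) -> SearchTrace:
    """Plain cuckoo search: uniform initialization, fixed a0 and Pa.

    ``objective`` must accept a ``(k, dim)`` array of positions and return a
    ``(k,)`` array of fitness values (minimized).
    """
    b = _check_bounds(params.bounds)

    def init(rng):
        return rng.uniform(b[:, 0], b[:, 1], size=(params.n_nests, params.dim))

    return _run(objective, params, init, lambda t: params.a0, lambda t: params.pa)


def ics_search(objective, params: ICSParams) -> SearchTrace:
    """Improved cuckoo search: Tent-chaotic initialization plus the adaptive
    a0/Pa schedules; otherwise identical to :func:`cs_search`."""
    return _run(
        objective,
        params,
        lambda rng: chaotic_init(params, rng),
        lambda t: adaptive_a0(t, params),
        lambda t: adaptive_pa(t, params),
    )


# --------------------------------------------------------------------------
# benchmark functions

@dataclass(frozen=True)
class BenchmarkFunction:
    """A 2-D test objective with its known global minimum."""

    name: str
    bounds: tuple
    f_min: float
    argmin: tuple
    _fn: callable = field(repr=False)

    def evaluate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._fn(np.atleast_2d(X))

    def __call__(self, X) -> np.ndarray:
        return self.evaluate(X)


def _rosenbrock(X):
    x, y = X[..., 0], X[..., 1]
    return 100.0 * (y - x**2) ** 2 + (x - 1.0) ** 2


def _griewank(X):
    x, y = X[..., 0], X[..., 1]
    return (x**2 + y**2) / 4000.0 - np.cos(x) * np.cos(y / math.sqrt(2.0)) + 1.0


def _cross_in_tray(X):
    x, y = X[..., 0], X[..., 1]
    inner = np.abs(
        np.sin(x) * np.sin(y) * np.exp(np.abs(100.0 - np.hypot(x, y) / math.pi))
    )
    return -0.0001 * (inner + 1.0) ** 0.1


def _schaffer(X, denom_coeff: float = 0.01):
    x, y = X[..., 0], X[..., 1]
    rho2 = x**2 + y**2
    return 0.5 + (np.sin(np.sqrt(rho2)) ** 2 - 0.5) / (1.0 + denom_coeff * rho2) ** 2


_BENCHMARKS = {
    "rosenbrock": BenchmarkFunction(
        "rosenbrock", ((-2.048, 2.048), (-2.048, 2.048)), 0.0, (1.0, 1.0),
        _rosenbrock,
    ),
    "griewank": BenchmarkFunction(
        "griewank", ((-600.0, 600.0), (-600.0, 600.0)), 0.0, (0.0, 0.0),
        _griewank,
    ),
    "cross_in_tray": BenchmarkFunction(
        "cross_in_tray", ((-10.0, 10.0), (-10.0, 10.0)), -2.06261,
        (1.3491, 1.3491), _cross_in_tray,
    ),
    "schaffer": BenchmarkFunction(
        "schaffer", ((-10.0, 10.0), (-10.0, 10.0)), 0.0, (0.0, 0.0), _schaffer,
    ),
}
BENCHMARK_NAMES = tuple(_BENCHMARKS)


def benchmark(name: str) -> BenchmarkFunction:
    try:
        return _BENCHMARKS[name]
    except KeyError:
        raise ConfigError(
            f"unknown benchmark {name!r}; expected one of {BENCHMARK_NAMES}"
        ) from None


# --------------------------------------------------------------------------
# 50-run comparison harness

def _params_for(algo: str, fn: BenchmarkFunction, seed: int,
                n_nests: int, T: int):
    if algo == "cs":
        return CSParams(bounds=fn.bounds, n_nests=n_nests, T=T, seed=seed)
    if algo == "ics":
        return ICSParams(bounds=fn.bounds, n_nests=n_nests, T=T, seed=seed)
    raise ConfigError(f"unknown algorithm {algo!r}; expected 'cs' or 'ics'")


def run_batch(
    algo: str,
    function: str,
    n_runs: int = 50,
    master_seed: int = 0,
    n_nests: int = 20,
    T: int = 200,
) -> list[SearchTrace]:
    """Independently seeded runs (seed = master_seed + run index)."""
    fn = benchmark(function)
    traces = []
    for run in range(n_runs):
        p = _params_for(algo, fn, master_seed + run, n_nests, T)
        search = cs_search if algo == "cs" else ics_search
        traces.append(search(fn.evaluate, p))
    return traces


def compare_runs(
    algorithms=("cs", "ics"),
    functions=BENCHMARK_NAMES,
    n_runs: int = 50,
    master_seed: int = 0,
    n_nests: int = 20,
    T: int = 200,
) -> pd.DataFrame:
    """Optimal / worst / average / SD of the final best fitness per
    (algorithm, function) cell over ``n_runs`` seeded runs."""
    if n_runs < 2:
        raise ConfigError("n_runs must be >= 2 for an SD")
    rows = []
    for function in functions:
        for algo in algorithms:
            finals = np.array([
                tr.best_fitness
                for tr in run_batch(algo, function, n_runs, master_seed,
                                    n_nests, T)
            ])
            rows.append(
                {
                    "function": function,
                    "algorithm": algo,
                    "optimal": float(finals.min()),
                    "worst": float(finals.max()),
                    "average": float(finals.mean()),
                    "sd": float(finals.std(ddof=1)),
                    "n_runs": n_runs,
                    "master_seed": master_seed,
                }
            )
    return pd.DataFrame(rows)
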
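"""Closed-form quantities for the fully observed pure birth process.

For a PBP started at ``x1`` the population at a later time is
``x1 + NegativeBinomial(x1, upsilon)`` with ``upsilon = exp(-lambda * dt)``:

    P(X_{t2} = x2 | X_{t1} = x1)
        = C(x2 - 1, x1 - 1) * upsilon**x1 * (1 - upsilon)**(x2 - x1).

Products of this transition law give the likelihood of a discretely observed
path, and the Fisher information for ``lambda`` has the classical closed form

    FI = x0 * sum_i  Delta_i**2 / (exp(-lambda t_{i-1}) - exp(-lambda t_i)),

which this module evaluates and maximises over observation schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .params import ModelParams, Schedule

__all__ = [
    "transition_pmf",
    "log_likelihood",
    "fisher_information",
    "optimal_design",
    "asymptotic_design",
    "stationarity_residuals",
]


def transition_pmf(x1: int, x2: int, decay: float) -> float:
    """PBP transition probability ``P(X_{t2} = x2 | X_{t1} = x1)``.

    ``decay`` is ``exp(-lambda * (t2 - t1))`` and must lie in ``(0, 1]``.
    Returns 0 for ``x2 < x1`` (births only).  Evaluated in log space so large
    ``x2`` does not overflow the binomial coefficient.
    """
    if not (0.0 < decay <= 1.0):
        raise ValueError(f"decay must lie in (0, 1], got {decay}")
    if x1 < 1:
        raise ValueError(f"x1 must be >= 1, got {x1}")
    if x2 < x1:
        return 0.0
    if decay == 1.0:
        return 1.0 if x2 == x1 else 0.0
    log_binom = gammaln(x2) - gammaln(x1) - gammaln(x2 - x1 + 1)
    return float(
        math.exp(log_binom + x1 * math.log(decay) + (x2 - x1) * math.log1p(-decay))
    )


def log_likelihood(path, params: ModelParams, schedule: Schedule) -> float:
    """Log-likelihood of a fully observed PBP path at the schedule's times.

    ``path`` holds the population sizes at ``t_1, ..., t_n``; the initial size
    comes from ``params``.  Any decreasing segment has probability zero and
    yields ``-inf``.
    """
    path = tuple(int(x) for x in path)
    if len(path) != schedule.n:
        raise ValueError(
            f"path length {len(path)} does not match schedule length {schedule.n}"
        )
    total = 0.0
    prev = params.init_size
    for x, u in zip(path, schedule.decay(params.birth_rate)):
        p = transition_pmf(prev, x, u) if x >= prev >= 1 else 0.0
        if p == 0.0:
            return float("-inf")
        total += math.log(p)
        prev = x
    return total


def fisher_information(params: ModelParams, schedule: Schedule) -> float:
    """Fisher information for ``lambda`` from fully observed PBP counts.

    Zero-length segments contribute nothing (their 0/0 term has limit 0).
    """
    lam = params.birth_rate
    total = 0.0
    prev_t = 0.0
    for t in schedule.times:
        dt = t - prev_t
        if dt > 0.0:
            denom = math.exp(-lam * prev_t) - math.exp(-lam * t)
            total += dt * dt / denom
        prev_t = t
    return params.init_size * total


def _fi_free_times(free_times: np.ndarray, lam: float, horizon: float) -> float:
    ts = np.concatenate([np.sort(free_times), [horizon]])
    total = 0.0
    prev = 0.0
    for t in ts:
        dt = t - prev
        if dt > 0:
            total += dt * dt / (math.exp(-lam * prev) - math.exp(-lam * t))
        prev = t
    return total


def asymptotic_design(n: int, birth_rate: float, horizon: float) -> tuple[float, ...]:
    """Large-``n`` approximately optimal times for the fully observed PBP.

    ``s_i = (3/lambda) * log(1 + (i/n) * (exp(lambda tau / 3) - 1))``.
    As ``lambda -> 0`` this tends to equal spacing ``i tau / n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    lam = birth_rate
    g = math.expm1(lam * horizon / 3.0)
    return tuple(3.0 / lam * math.log1p(i / n * g) for i in range(1, n + 1))


def optimal_design(
    n: int, birth_rate: float, horizon: float, x0: int = 1
) -> tuple[tuple[float, ...], float]:
    """Maximise the PBP Fisher information over schedules with ``t_n = tau``.

    Returns ``(times, fi)``.  The last time is pinned to the horizon; the
    ``n - 1`` earlier times are optimised directly (1-D by dense scan plus
    bounded refinement, multi-D by SLSQP multistart from equal spacing and the
    asymptotic design).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = birth_rate
    if n == 1:
        params = ModelParams(lam, 1.0, x0)
        return (horizon,), fisher_information(params, Schedule((horizon,)))
    if n == 2:
        res = minimize_scalar(
            lambda t: -_fi_free_times(np.array([t]), lam, horizon),
            bounds=(1e-9 * horizon, horizon),
            method="bounded",
            options={"xatol": 1e-12},
        )
        grid = np.linspace(horizon / 200, horizon * (1 - 1 / 200), 199)
        vals = [_fi_free_times(np.array([t]), lam, horizon) for t in grid]
        i = int(np.argmax(vals))
        res2 = minimize_scalar(
            lambda t: -_fi_free_times(np.array([t]), lam, horizon),
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = min([res, res2], key=lambda r: r.fun)
        times = (float(best.x), horizon)
        return times, x0 * -best.fun
    # multi-dimensional: multistart local optimisation on sorted free times
    starts = [
        np.array([horizon * i / n for i in range(1, n)]),
        np.array(asymptotic_design(n, lam, horizon)[:-1]),
    ]
    best_x, best_f = None, -np.inf
    bounds = [(1e-9 * horizon, horizon)] * (n - 1)
    for s0 in starts:
        r = minimize(
            lambda x: -_fi_free_times(x, lam, horizon),
            s0,
            method="SLSQP",
            bounds=bounds,
            options={"ftol": 1e-14, "maxiter": 500},
        )
        if -r.fun > best_f:
            best_f, best_x = -r.fun, np.sort(r.x)
    times = tuple(float(t) for t in best_x) + (horizon,)
    return times, x0 * best_f


def _phi1(x: float) -> float:
    ex = math.exp(x)
    return x * (2 * ex - x - 2) / (ex - 1) ** 2


def _phi2(x: float) -> float:
    ex = math.exp(x)
    return x * ex * (2 * ex - x * ex - 2) / (ex - 1) ** 2


def stationarity_residuals(
    times, birth_rate: float
) -> tuple[float, ...]:
    """Residuals ``phi1(lambda Delta_i) - phi2(lambda Delta_{i+1})``.

    At an interior optimum of the PBP Fisher information these vanish for
    ``i = 1..n-1``; they serve as an independent optimality certificate for
    :func:`optimal_design`.
    """
    lam = birth_rate
    ts = [0.0] + [float(t) for t in times]
    gaps = [b - a for a, b in zip(ts, ts[1:])]
    return tuple(
        _phi1(lam * gaps[i]) - _phi2(lam * gaps[i + 1]) for i in range(len(gaps) - 1)
    )
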
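"""POPBP simulator, brute-force likelihood oracles, and rate estimation.

The simulator draws the latent pure-birth path on the observation-time
skeleton (each segment is a shifted negative-binomial step) and thins each
latent count binomially.  The brute-force oracles evaluate the likelihood
and its rate-derivative by direct truncated summation over all monotone
latent paths — independent of the generating-function recurrence, and used
to validate it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom, nbinom

from .gf import LikelihoodCache, build_coefficients, likelihood_recursive
from .params import ModelParams, Schedule

__all__ = [
    "TrajectorySample",
    "BruteForceConfig",
    "simulate_popbp",
    "simulate_counts",
    "likelihood_bruteforce",
    "derivative_bruteforce",
    "estimate_rate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrajectorySample:
    """One simulated realisation: latent path and thinned observations."""

    latent: tuple[int, ...]
    observed: tuple[int, ...]
    seed: int


def simulate_counts(
    params: ModelParams, schedule: Schedule, seed: int, reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simulation; returns ``(latent, observed)`` of shape (reps, n).

    Stream order (fixed, for bit reproducibility): one negative-binomial
    block per segment in time order, then one binomial thinning block per
    observation time in time order, each of length ``reps``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = schedule.n
    ups = schedule.decay(params.birth_rate)
    latent = np.empty((reps, n), dtype=np.int64)
    current = np.full(reps, params.init_size, dtype=np.int64)
    for i in range(n):
        if ups[i] < 1.0:
            current = current + rng.negative_binomial(current, ups[i])
        latent[:, i] = current
    observed = np.empty_like(latent)
    for i in range(n):
        observed[:, i] = rng.binomial(latent[:, i], params.detect_prob)
    return latent, observed


def simulate_popbp(
    params: ModelParams, schedule: Schedule, seed: int, reps: int
) -> list[TrajectorySample]:
    """Simulate ``reps`` POPBP observation vectors (see :func:`simulate_counts`)."""
    latent, observed = simulate_counts(params, schedule, seed, reps)
    return [
        TrajectorySample(tuple(map(int, latent[r])), tuple(map(int, observed[r])), seed)
        for r in range(reps)
    ]


@dataclass(frozen=True)
class BruteForceConfig:
    """Truncation of the latent-path sums at ``x <= cap``.

    ``tail_bound`` is the negative-binomial survival mass beyond the cap at
    the final observation time — a bound on the truncation error.
    """

    cap: int
    tail_bound: float

    @classmethod
    def for_model(
        cls, params: ModelParams, schedule: Schedule, tail_bound: float = 1e-12
    ) -> "BruteForceConfig":
        theta = schedule.theta(params.birth_rate, schedule.horizon)
        x0 = params.init_size
        cap = max(x0 + 10, int(x0 / theta))
        while nbinom.sf(cap - x0, x0, theta) >= tail_bound:
            cap = int(cap * 1.5) + 10
            if cap > 10_000_000:
                raise ValueError("cannot reach the requested tail bound")
        return cls(cap=cap, tail_bound=float(nbinom.sf(cap - x0, x0, theta)))


def _chain_matrices(params: ModelParams, schedule: Schedule, y, cap: int):
    """Per-segment transition*emission matrices and derivative weights."""
    ups = schedule.decay(params.birth_rate)
    gaps = schedule.gaps
    x = np.arange(1, cap + 1)
    mats = []
    for i, (u, d) in enumerate(zip(ups, gaps)):
        if u < 1.0:
            T = nbinom.pmf(x[None, :] - x[:, None], x[:, None], u)
            W = d * (x[None, :] * u - x[:, None]) / (1.0 - u)
        else:  # zero gap: deterministic transition, zero score weight
            T = np.eye(cap)
            W = np.zeros((cap, cap))
        B = binom.pmf(y[i], x, params.detect_prob)
        mats.append((T * B[None, :], W))
    return mats


def likelihood_bruteforce(
    y, params: ModelParams, schedule: Schedule, cfg: BruteForceConfig | None = None
) -> float:
    """Likelihood by direct summation over monotone latent paths up to the cap."""
    y = tuple(int(v) for v in y)
    if len(y) != schedule.n:
        raise ValueError("observation vector length must match the schedule")
    if cfg is None:
        cfg = BruteForceConfig.for_model(params, schedule)
    mats = _chain_matrices(params, schedule, y, cfg.cap)
    v = np.zeros(cfg.cap)
    v[params.init_size - 1] = 1.0
    for TB, _ in mats:
        v = v @ TB
    return float(v.sum())


def derivative_bruteforce(
    y, params: ModelParams, schedule: Schedule, cfg: BruteForceConfig | None = None
) -> float:
    """``dL/dlambda`` by direct summation of score-weighted path products.

    The per-segment score weight is ``Delta_j (x_j ups_j - x_{j-1}) /
    (1 - ups_j)`` — the ``lambda``-derivative of the log transition term.
    """
    y = tuple(int(v) for v in y)
    if len(y) != schedule.n:
        raise ValueError("observation vector length must match the schedule")
    if cfg is None:
        cfg = BruteForceConfig.for_model(params, schedule)
    mats = _chain_matrices(params, schedule, y, cfg.cap)
    v = np.zeros(cfg.cap)
    v[params.init_size - 1] = 1.0
    wv = np.zeros(cfg.cap)
    for TB, W in mats:
        wv = wv @ TB + v @ (W * TB)
        v = v @ TB
    return float(wv.sum())


def estimate_rate(
    observations,
    detect_prob: float,
    schedule: Schedule,
    bounds: tuple[float, float] = (1e-3, 10.0),
    x0: int = 1,
) -> float:
    """Maximum-likelihood birth rate from observed count vectors.

    Maximises the summed log recursive likelihood over ``lambda`` on
    ``bounds``.  All-zero data pushes the estimate to the lower bound (a
    warning is logged).
    """
    obs = [tuple(int(v) for v in y) for y in observations]
    if not obs:
        raise ValueError("need at least one observation vector")
    if all(all(v == 0 for v in y) for y in obs):
        log.warning("all observations are zero; estimate clipped to lower bound")
        return bounds[0]

    counts: dict[tuple[int, ...], int] = {}
    for y in obs:
        counts[y] = counts.get(y, 0) + 1

    def neg_loglik(lam: float) -> float:
        params = ModelParams(lam, detect_prob, x0)
        coeffs = build_coefficients(params, schedule)
        cache = LikelihoodCache()
        total = 0.0
        for y, c in counts.items():
            L = likelihood_recursive(y, coeffs, cache, x0=x0)
            if L <= 0.0:
                return math.inf
            total += c * math.log(L)
        return -total

    res = minimize_scalar(
        neg_loglik, bounds=bounds, method="bounded", options={"xatol": 1e-8}
    )
    return float(res.x)
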
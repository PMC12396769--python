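"""Schedule optimisation and drop values.

The feasible schedules form the simplex ``0 <= t_1 <= ... <= t_n = 1``
(horizon 1 without loss of generality; see :func:`rescale_design`).  The
objective is maximised stratum by stratum: the relative interior, plus every
boundary stratum obtained by tying groups of consecutive coordinates
together and/or pinning a suffix to 1.  Strata with any ``t_i = 0`` are
excluded — the initial population size is known, so an observation at time 0
carries no information.  One-dimensional strata are scanned densely and
refined with a bounded local search (a global-then-local emulation of a
branch-and-bound pass); higher-dimensional strata use deterministic
multistart local ascent.

A *drop value* ``D_i(lambda)`` is the detection probability at which the
optimal ``t_i`` first departs (discontinuously) from the horizon.  Drop
values are bracketed by bisection on ``p``; every optimisation performed
during any search tightens the brackets of *all* drop values, so intervals
for successive indices can only overlap by being identical.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .params import ModelParams

__all__ = [
    "DesignResult",
    "DropInterval",
    "optimize_schedule",
    "find_drop_values",
    "rescale_design",
    "DROP_DETECTION_TOL",
]

log = logging.getLogger(__name__)

#: ``t_i* < 1 - DROP_DETECTION_TOL`` counts as having dropped from the horizon.
DROP_DETECTION_TOL = 1e-4


@dataclass(frozen=True)
class DesignResult:
    """An optimised observation schedule and its objective value."""

    times: tuple[float, ...]
    fi_value: float
    region: str


@dataclass
class DropInterval:
    """Bisection bracket ``lower < D_i(lambda) < upper``."""

    index: int
    lower: float
    upper: float
    censored: bool = False  # t_i* already below 1 at the smallest probed p

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _strata(n: int):
    """Yield ``(label, n_free, block_sizes, n_pinned)`` for every stratum.

    ``block_sizes`` partitions the leading free coordinates into tied groups;
    the remaining ``n_pinned`` coordinates (a suffix) sit at the horizon.
    """
    for m in range(n):  # number of free coordinates among t_1..t_{n-1}
        n_pin = n - 1 - m
        if m == 0:
            yield "pinned", 0, (), n_pin
            continue
        # compositions of m into k ordered positive blocks
        for k in range(1, m + 1):
            for cuts in itertools.combinations(range(1, m), k - 1):
                edges = (0,) + cuts + (m,)
                blocks = tuple(b - a for a, b in zip(edges, edges[1:]))
                label = f"blocks={blocks},pinned={n_pin}"
                yield label, k, blocks, n_pin


def _assemble(values: Sequence[float], blocks, n_pin: int) -> tuple[float, ...]:
    out: list[float] = []
    for v, b in zip(values, blocks):
        out.extend([float(v)] * b)
    out.extend([1.0] * n_pin)
    out.append(1.0)
    return tuple(out)


def _optimize_1d(
    objective: Callable[[float], float],
    grid_points: int,
    xatol: float,
    extra_starts: Sequence[float] = (),
) -> tuple[float, float]:
    grid = list(np.linspace(1.0 / (grid_points + 1), 1.0 - 1.0 / (grid_points + 1), grid_points))
    grid.extend(v for v in extra_starts if 0.0 < v < 1.0)
    grid = sorted(set(grid))
    vals = [objective(v) for v in grid]
    i = int(np.argmax(vals))
    lo = grid[i - 1] if i > 0 else grid[0] / 2
    hi = grid[i + 1] if i + 1 < len(grid) else (1.0 + grid[-1]) / 2
    res = minimize_scalar(
        lambda v: -objective(v), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return grid[i], vals[i]


def optimize_schedule(
    n: int,
    params: ModelParams,
    evaluator: Callable[[tuple[float, ...]], float],
    grid_points: int = 81,
    xatol: float = 1e-7,
    warm_starts: Sequence[Sequence[float]] = (),
) -> DesignResult:
    """Maximise ``evaluator`` over schedules ``0 < t_1 <= ... <= t_n = 1``.

    ``evaluator`` maps a full time vector (ending at 1) to the objective.
    ``warm_starts`` supplies additional deterministic seed schedules (e.g.
    the solution at a neighbouring ``p`` during a sweep).  Ties between
    strata are broken by larger objective, then lexicographically smaller
    times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        times = (1.0,)
        return DesignResult(times, evaluator(times), "pinned")

    best: DesignResult | None = None
    warm = [tuple(w) for w in warm_starts]
    for label, k, blocks, n_pin in _strata(n):
        if k == 0:
            times = _assemble((), blocks, n_pin)
            fi = evaluator(times)
            cand = DesignResult(times, fi, label)
        elif k == 1:
            starts = [w[0] for w in warm if len(w) == n]
            v, fi = _optimize_1d(
                lambda v: evaluator(_assemble([v], blocks, n_pin)),
                grid_points,
                xatol,
                extra_starts=starts,
            )
            cand = DesignResult(_assemble([v], blocks, n_pin), fi, label)
        else:
            cand = _optimize_multi(evaluator, blocks, n_pin, k, warm, label)
        log.info(
            "stratum %s: fi=%.12g argmax=%s", label, cand.fi_value, cand.times
        )
        if (
            best is None
            or cand.fi_value > best.fi_value + 0.0
            or (cand.fi_value == best.fi_value and cand.times < best.times)
        ):
            best = cand
    return best


def _optimize_multi(evaluator, blocks, n_pin, k, warm, label) -> DesignResult:
    from .pbp import asymptotic_design  # deterministic seed

    def neg(v: np.ndarray) -> float:
        v = np.clip(np.sort(v), 1e-9, 1.0 - 1e-9)
        return -evaluator(_assemble(v, blocks, n_pin))

    seeds = [
        np.array([(j + 1) / (k + 1) for j in range(k)]),
        np.array(asymptotic_design(k + 1, 1.0, 1.0)[:-1]),
    ]
    for w in warm:
        if len(w) >= k:
            seeds.append(np.array(sorted(set(w[:k]))[:k]) if len(set(w[:k])) >= k else None)
    seeds = [s for s in seeds if s is not None and len(s) == k]
    best_v, best_f = None, -math.inf
    for s0 in seeds:
        r = minimize(
            neg, s0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
        )
        if -r.fun > best_f:
            best_f, best_v = -r.fun, np.clip(np.sort(r.x), 1e-9, 1.0 - 1e-9)
    times = _assemble(best_v, blocks, n_pin)
    return DesignResult(times, best_f, label)


def find_drop_values(
    n: int,
    birth_rate: float,
    evaluator_factory: Callable[[float], Callable[[tuple[float, ...]], float]],
    width: float = 1e-3,
    p_bounds: tuple[float, float] = (1e-3, 1.0 - 1e-9),
    grid_points: int = 81,
) -> list[DropInterval]:
    """Bracket every drop value ``D_i(lambda)``, ``i = 1..n-1``, by bisection.

    ``evaluator_factory(p)`` returns the objective for detection probability
    ``p``.  Each schedule optimisation updates the brackets of *all* indices
    simultaneously, so later searches start from tightened intervals and
    bracket intervals can only overlap by coinciding exactly.
    """
    if n < 2:
        raise ValueError("drop values need n >= 2")
    if width <= 0:
        raise ValueError("width must be positive")
    lo0, hi0 = p_bounds
    intervals = [DropInterval(i, lo0, hi0) for i in range(1, n)]
    warm: list[tuple[float, ...]] = []

    def probe(p: float) -> tuple[float, ...]:
        params = ModelParams(birth_rate, p)
        res = optimize_schedule(
            n, params, evaluator_factory(p), grid_points=grid_points,
            warm_starts=warm,
        )
        warm.clear()
        warm.append(res.times)
        log.info("drop probe p=%.9f -> argmax=%s fi=%.12g", p, res.times, res.fi_value)
        dropped = [res.times[i] < 1.0 - DROP_DETECTION_TOL for i in range(n - 1)]
        for iv, d in zip(intervals, dropped):
            if d:
                if p < iv.upper:
                    iv.upper = p
            else:
                if p > iv.lower:
                    iv.lower = p
        return res.times

    for iv in intervals:
        # establish censoring at the lower endpoint once
        if iv.lower == lo0:
            times = probe(lo0)
            if times[iv.index - 1] < 1.0 - DROP_DETECTION_TOL:
                iv.censored = True
                iv.lower = 0.0
                continue
        while iv.width > width:
            probe(0.5 * (iv.lower + iv.upper))
    return intervals


def rescale_design(
    design: DesignResult, horizon: float, birth_rate: float
) -> DesignResult:
    """Transport an optimal design from horizon 1 to an arbitrary horizon.

    If ``design`` is optimal for rate ``lambda`` on horizon 1, the scaled
    times ``horizon * t_i`` are optimal for rate ``lambda / horizon`` on the
    new horizon, and the information about the rescaled rate scales by
    ``horizon**2`` (``Var(lambda-hat / tau) = Var(lambda-hat) / tau**2``).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return DesignResult(
        tuple(horizon * t for t in design.times),
        design.fi_value * horizon**2,
        design.region,
    )
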
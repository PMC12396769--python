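"""Slice-summed Fisher information for the POPBP.

The Fisher information for the birth rate is the lattice sum

    FI = sum_y  (dL(y)/dlambda)**2 / L(y)

over all observation vectors ``y`` in ``N^n``.  Grouping vectors by total
count ``S = |y|`` ("slices", the weak compositions ``WC_n(S)``) turns the sum
into a series ``FI = sum_S SL_S`` in which each slice depends only on the
``n`` previous ones — the likelihood recurrence steps ``y -> y - c`` with
binary ``c`` lower the degree by at most ``n``.  Slices are stored as dense
arrays indexed by the lexicographic rank of the composition, and the series
is accumulated until new slices stop contributing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import pbp
from .gf import CoefficientSet, build_coefficients
from .params import ModelParams, Schedule

__all__ = [
    "composition_rank",
    "composition_unrank",
    "slice_size",
    "SliceTable",
    "compute_slice",
    "FisherResult",
    "fisher_information",
]


# ---------------------------------------------------------------------------
# ranking weak compositions (lexicographic on counts)
# ---------------------------------------------------------------------------

def slice_size(n: int, S: int) -> int:
    """``|WC_n(S)| = C(S + n - 1, n - 1)``."""
    return math.comb(S + n - 1, n - 1)


def composition_rank(y) -> int:
    """Lexicographic rank of ``y`` within the weak compositions of ``|y|``."""
    y = tuple(int(v) for v in y)
    if any(v < 0 for v in y):
        raise ValueError("counts must be nonnegative")
    n = len(y)
    S = sum(y)
    rank = 0
    remaining = S
    for i, v in enumerate(y[:-1]):
        k = n - i - 1  # positions after this one
        # compositions with a smaller value at this position
        rank += math.comb(remaining + k, k) - math.comb(remaining - v + k, k)
        remaining -= v
    return rank


def composition_unrank(r: int, n: int, S: int) -> tuple[int, ...]:
    """Inverse of :func:`composition_rank` on ``WC_n(S)``."""
    if not 0 <= r < slice_size(n, S):
        raise IndexError(f"rank {r} out of range for WC_{n}({S})")
    out = []
    remaining = S
    for i in range(n - 1):
        k = n - i - 1
        v = 0
        while True:
            block = math.comb(remaining - v + k - 1, k - 1)
            if r < block:
                break
            r -= block
            v += 1
        out.append(v)
        remaining -= v
    out.append(remaining)
    return tuple(out)


@lru_cache(maxsize=4096)
def _compositions(n: int, S: int) -> np.ndarray:
    """All of ``WC_n(S)`` in lexicographic order, shape ``(|WC_n(S)|, n)``."""
    if n == 1:
        return np.array([[S]], dtype=np.int64)
    blocks = []
    for v in range(S + 1):
        sub = _compositions(n - 1, S - v)
        first = np.full((sub.shape[0], 1), v, dtype=np.int64)
        blocks.append(np.hstack([first, sub]))
    return np.vstack(blocks)


@lru_cache(maxsize=16384)
def _shift_map(n: int, S: int, cmask: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices realising the slice-to-slice recurrence step ``y -> y - c``.

    For the binary offset ``c`` encoded by ``cmask`` returns ``(src, tgt)``:
    ``src`` are the ranks (in slice ``S``) of vectors with ``y >= c`` and
    ``tgt`` the ranks of ``y - c`` in slice ``S - |c|``.
    """
    c = np.array([(cmask >> k) & 1 for k in range(n)], dtype=np.int64)
    w = int(c.sum())
    Y = _compositions(n, S)
    ok = np.nonzero((Y >= c).all(axis=1))[0]
    Z = Y[ok] - c
    # vectorised lexicographic rank of each row of Z within WC_n(S - w)
    Sp = S - w
    rank = np.zeros(Z.shape[0], dtype=np.int64)
    remaining = np.full(Z.shape[0], Sp, dtype=np.int64)
    for i in range(n - 1):
        k = n - i - 1
        rank += _comb_vec(remaining + k, k) - _comb_vec(remaining - Z[:, i] + k, k)
        remaining -= Z[:, i]
    return ok, rank


def _comb_vec(m: np.ndarray, k: int) -> np.ndarray:
    """``C(m, k)`` elementwise for small fixed ``k`` (exact in int64)."""
    out = np.ones_like(m)
    for j in range(k):
        out = out * (m - j)
    return out // math.factorial(k)


@lru_cache(maxsize=4096)
def _binary_ranks(n: int, S: int) -> tuple[np.ndarray, int]:
    """Ranks of the binary compositions in slice ``S`` (empty if ``S > n``)."""
    if S > n:
        return np.empty(0, dtype=np.int64), 0
    Y = _compositions(n, S)
    idx = np.nonzero((Y <= 1).all(axis=1))[0]
    return idx, S


# ---------------------------------------------------------------------------
# slices
# ---------------------------------------------------------------------------

@dataclass
class SliceTable:
    """Likelihood and score values over one slice ``WC_n(S)``."""

    degree: int
    L: np.ndarray   # likelihood values, ranked lexicographically
    dL: np.ndarray  # dL/dlambda, aligned
    slice_sum: float  # SL_S = sum (dL)^2 / L   (0/0 terms -> 0)
    mass: float       # sum of L over the slice

    @property
    def size(self) -> int:
        return self.L.size


def _recurrence_arrays(coeffs: CoefficientSet):
    """Per-offset recurrence coefficients ``q_(0,c)`` and derivatives.

    Returns ``(masks, a, da, q0, dq0)`` where ``masks`` enumerates nonzero
    binary offsets ``c`` of the observed indices (the ``u_0``-constant part
    of ``Q_n``, as required for known initial size).
    """
    n = coeffs.order
    masks, a, da = [], [], []
    for m in range(1, 1 << n):
        qc = float(coeffs.q[m << 1])
        dqc = float(coeffs.dq[m << 1])
        if qc != 0.0 or dqc != 0.0:
            masks.append(m)
            a.append(qc)
            da.append(dqc)
    return masks, np.array(a), np.array(da), coeffs.normalizer, coeffs.dnormalizer


def compute_slice(
    S: int,
    coeffs: CoefficientSet,
    window: dict[int, SliceTable],
    chunks: int = 1,
) -> SliceTable:
    """Fill slice ``S`` from the ``n`` previous slices and sum its terms.

    ``window`` maps degree -> :class:`SliceTable` and must contain every
    slice ``S - |c|`` reachable by a nonzero offset (missing negative degrees
    are naturally absent).  Terms of the score sum are independent;
    ``chunks > 1`` splits the slice into contiguous blocks that are summed
    separately and then combined, which reproduces (to summation order) a
    parallel evaluation.
    """
    n = coeffs.order
    for back in range(1, n + 1):
        if S - back >= 0 and (S - back) not in window:
            raise ValueError(f"window is missing slice {S - back}")
    masks, a, da, q0, dq0 = _recurrence_arrays(coeffs)
    size = slice_size(n, S)
    L = np.zeros(size)
    T = np.zeros(size)  # q0 * dL before the -dq0*L correction
    if S <= n:
        idx, _ = _binary_ranks(n, S)
        if idx.size:
            p = coeffs.detect_prob
            py = coeffs.theta_tau * p**S * (1.0 - p) ** (n - S)
            L[idx] += py
            T[idx] += -coeffs.horizon * py
    for m, am, dam in zip(masks, a, da):
        w = bin(m).count("1")
        if S - w < 0:
            continue
        src, tgt = _shift_map(n, S, m)
        prev = window[S - w]
        L[src] += am * prev.L[tgt]
        T[src] += dam * prev.L[tgt] + am * prev.dL[tgt]
    L /= q0
    dL = (T - dq0 * L) / q0
    terms = np.where(L > 0.0, dL * dL / np.where(L > 0.0, L, 1.0), 0.0)
    if chunks <= 1:
        ssum = float(np.sum(terms))
        mass = float(np.sum(L))
    else:
        bounds = np.linspace(0, size, chunks + 1).astype(int)
        ssum = math.fsum(float(np.sum(terms[a:b])) for a, b in zip(bounds, bounds[1:]))
        mass = math.fsum(float(np.sum(L[a:b])) for a, b in zip(bounds, bounds[1:]))
    return SliceTable(degree=S, L=L, dL=dL, slice_sum=ssum, mass=mass)


# ---------------------------------------------------------------------------
# the series
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    """Outcome of the slice-summed Fisher information series."""

    value: float
    slices_used: int
    last_contribution: float
    converged: bool
    mass: float  # accumulated likelihood mass, a convergence diagnostic


class SliceConvergenceError(RuntimeError):
    """Raised when the series does not settle before the slice cap."""

    def __init__(self, partial: FisherResult):
        self.partial = partial
        super().__init__(
            f"slice series not converged after {partial.slices_used} slices "
            f"(partial FI {partial.value!r})"
        )


def fisher_information(
    params: ModelParams,
    schedule: Schedule,
    rel_tol: float = 1e-15,
    max_slices: int = 100_000,
    chunks: int = 1,
) -> FisherResult:
    """POPBP Fisher information for the birth rate by slice accumulation.

    Edge cases: ``p = 1`` is exactly the fully observed PBP and is delegated
    to its closed form; ``p = 0`` observations carry no information.  The
    series stops once a slice's contribution has stayed below
    ``rel_tol * FI`` for two consecutive slices (and at least ``n + 1``
    slices were taken), which at double precision reproduces stopping when
    the accumulated value no longer changes.
    """
    p = params.detect_prob
    n = schedule.n
    if p == 0.0:
        return FisherResult(0.0, 0, 0.0, True, 1.0)
    if p == 1.0:
        fi = pbp.fisher_information(params, schedule)
        return FisherResult(fi, 0, 0.0, True, 1.0)
    if params.init_size != 1:
        return _fisher_general_x0(params, schedule, rel_tol, max_slices)

    coeffs = build_coefficients(params, schedule)
    window: dict[int, SliceTable] = {}
    acc = 0.0
    comp = 0.0  # Kahan compensation across slices
    mass = 0.0
    small_streak = 0
    for S in range(max_slices):
        tab = compute_slice(S, coeffs, window, chunks=chunks)
        y = tab.slice_sum - comp
        t = acc + y
        comp = (t - acc) - y
        acc = t
        mass += tab.mass
        window[S] = tab
        window.pop(S - n, None)
        if S >= n + 1 and tab.slice_sum <= rel_tol * acc:
            small_streak += 1
            if small_streak >= 2:
                return FisherResult(acc, S + 1, tab.slice_sum, True, mass)
        else:
            small_streak = 0
    raise SliceConvergenceError(
        FisherResult(acc, max_slices, tab.slice_sum, False, mass)
    )


def _fisher_general_x0(
    params: ModelParams, schedule: Schedule, rel_tol: float, max_slices: int
) -> FisherResult:
    """Triangular fill over initial sizes ``0..x0`` (validation path).

    The full recurrence over ``(x0, y)`` needs, at level ``x0`` and degree
    ``S``, the same-degree values one level down (offsets with ``c_0 = 1``,
    ``c = 0``) and lower-degree values at both levels.
    """
    n = schedule.n
    x0 = params.init_size
    coeffs = build_coefficients(params, schedule)
    p = coeffs.detect_prob

    # per-offset coefficients over the full (n+1)-bit index set
    offs = []
    for m in range(1, 1 << (n + 1)):
        qc = float(coeffs.q[m])
        dqc = float(coeffs.dq[m])
        if qc != 0.0 or dqc != 0.0:
            offs.append((m & 1, m >> 1, qc, dqc))
    q0 = coeffs.normalizer
    dq0 = coeffs.dnormalizer

    windows: list[dict[int, tuple[np.ndarray, np.ndarray]]] = [
        {} for _ in range(x0 + 1)
    ]
    acc = 0.0
    mass = 0.0
    small_streak = 0
    last = 0.0
    for S in range(max_slices):
        size = slice_size(n, S)
        for level in range(x0 + 1):
            L = np.zeros(size)
            T = np.zeros(size)
            if level == 1 and S <= n:
                idx, _ = _binary_ranks(n, S)
                if idx.size:
                    py = coeffs.theta_tau * p**S * (1.0 - p) ** (n - S)
                    L[idx] += py
                    T[idx] += -coeffs.horizon * py
            if level > 0:
                for c0, m, qc, dqc in offs:
                    w = bin(m).count("1")
                    if S - w < 0 or level - c0 < 0:
                        continue
                    if m == 0:
                        prevL, prevdL = L_prev_level, dL_prev_level
                        L += qc * prevL
                        T += dqc * prevL + qc * prevdL
                    else:
                        src, tgt = _shift_map(n, S, m)
                        pl, pd = windows[level - c0][S - w]
                        L[src] += qc * pl[tgt]
                        T[src] += dqc * pl[tgt] + qc * pd[tgt]
            L = L / q0
            dL = (T - dq0 * L) / q0
            windows[level][S] = (L, dL)
            L_prev_level, dL_prev_level = L, dL
        Lx, dLx = windows[x0][S]
        terms = np.where(Lx > 0.0, dLx * dLx / np.where(Lx > 0.0, Lx, 1.0), 0.0)
        last = float(np.sum(terms))
        acc += last
        mass += float(np.sum(Lx))
        for level in range(x0 + 1):
            windows[level].pop(S - n, None)
        if S >= n + 1 and last <= rel_tol * acc:
            small_streak += 1
            if small_streak >= 2:
                return FisherResult(acc, S + 1, last, True, mass)
        else:
            small_streak = 0
    raise SliceConvergenceError(FisherResult(acc, max_slices, last, False, mass))
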
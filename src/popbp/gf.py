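"""Likelihood recurrence for the partially observable pure birth process.

The joint likelihood ``L(y_1, ..., y_n)`` of POPBP counts has a rational
generating function

    phi(u_0, ..., u_n) = u_0 * ups_1 ... ups_n * (p u_1 + q) ... (p u_n + q)
                         / (1 - Q_n),

where ``Q_n`` is built by the multiplicative recursion

    Q_0 = (1 - ups_1) + ups_1 u_0,
    Q_i = (1 - ups_{i+1}) + ups_{i+1} (p u_i + q) Q_{i-1},   ups_{n+1} := 1,

with ``ups_i = exp(-lambda (t_i - t_{i-1}))``.  ``Q_n`` has degree one in each
variable, so its ``2**(n+1)`` coefficients ``q_cbar`` (indexed by binary
multi-indices ``cbar``) turn rationality into a constant-coefficient linear
recurrence for the likelihood:

    L(ybar) = (1/q0) * ( p_ybar + sum_{cbar != 0} q_cbar * L(ybar - cbar) ),

``ybar = (x0, y)``, ``q0 = 1 - q_(0,...,0)``, and ``p_ybar`` the numerator
coefficient (nonzero only for ``x0 = 1`` and binary ``y``, where it equals
``exp(-lambda tau) * p**|y| * q**(n-|y|)``).  All recurrence coefficients are
nonnegative for ``p``, ``ups`` in ``[0, 1]``, so the forward recursion never
cancels.  For known initial size the recursion is run with ``L(x0=0, .) = 0``;
with ``x0 = 1`` every term with ``c_0 = 1`` vanishes and only the
``u_0``-constant coefficients of ``Q_n`` drive the recurrence.  (Setting
``u_0 = 1`` instead would collapse distinct powers of ``u_0`` and fails the
geometric sanity check ``L(y) = ups (1 - ups)**(y-1)`` at ``n = 1, p = 1``.)

Differentiating ``Q_i`` in ``lambda`` (``d ups / d lambda = -Delta * ups``)
gives a parallel recursion for the coefficients of ``dQ_n/dlambda`` and hence
for ``dL/dlambda``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams, Schedule

__all__ = [
    "CoefficientSet",
    "build_coefficients",
    "LikelihoodCache",
    "likelihood_recursive",
    "likelihood_derivative_recursive",
]


def _mul_affine(coeffs: np.ndarray, bit: int, p: float, q: float) -> np.ndarray:
    """Multiply a multilinear coefficient array by ``(p * u_bit + q)``."""
    out = q * coeffs
    idx = np.nonzero(np.arange(coeffs.size) & (1 << bit))[0]
    out[idx] += p * coeffs[idx ^ (1 << bit)]
    return out


@dataclass(frozen=True)
class CoefficientSet:
    """Coefficients of ``Q_n``, its ``lambda``-derivative, and the numerator.

    Arrays are indexed by the integer whose bit ``k`` is the exponent of
    ``u_k`` (bit 0 corresponds to the initial-size variable ``u_0``).
    """

    order: int                 # number of observations n
    detect_prob: float
    horizon: float
    q: np.ndarray              # coefficients of Q_n, length 2**(n+1)
    dq: np.ndarray             # coefficients of dQ_n/dlambda
    theta_tau: float           # exp(-lambda * tau), the numerator prefactor

    @property
    def normalizer(self) -> float:
        """``q0 = 1 - q_(0,...,0)``; the recurrence divides by this."""
        return 1.0 - float(self.q[0])

    @property
    def dnormalizer(self) -> float:
        """``d q0 / d lambda = -dq_(0,...,0)``."""
        return -float(self.dq[0])

    def q_coeff(self, cbar: tuple[int, ...]) -> float:
        """Coefficient of ``u^cbar`` in ``Q_n`` (``cbar`` has n+1 binary entries)."""
        return float(self.q[self._mask(cbar)])

    def dq_coeff(self, cbar: tuple[int, ...]) -> float:
        return float(self.dq[self._mask(cbar)])

    def numer_coeff(self, y: tuple[int, ...]) -> float:
        """Coefficient ``p_(1,y)`` of ``u_0 * u^y`` in the numerator.

        Nonzero only for binary ``y``: ``theta_tau * p**|y| * q**(n-|y|)``.
        """
        if len(y) != self.order:
            raise ValueError("index length must equal the order")
        if any(v not in (0, 1) for v in y):
            return 0.0
        k = sum(y)
        p = self.detect_prob
        return self.theta_tau * p**k * (1.0 - p) ** (self.order - k)

    def dnumer_coeff(self, y: tuple[int, ...]) -> float:
        """``d p_(1,y) / d lambda = -tau * p_(1,y)``."""
        return -self.horizon * self.numer_coeff(y)

    def _mask(self, cbar: tuple[int, ...]) -> int:
        if len(cbar) != self.order + 1:
            raise ValueError("multi-index must have n+1 entries")
        m = 0
        for k, c in enumerate(cbar):
            if c not in (0, 1):
                raise ValueError("multi-index entries must be 0 or 1")
            m |= c << k
        return m

    def to_json(self) -> str:
        """Serialise index -> coefficient maps (debugging aid)."""
        n1 = self.order + 1
        key = lambda m: "".join(str((m >> k) & 1) for k in range(n1))
        return json.dumps(
            {
                "order": self.order,
                "q": {key(m): float(f"{v:.17g}") for m, v in enumerate(self.q)},
                "dq": {key(m): float(f"{v:.17g}") for m, v in enumerate(self.dq)},
                "normalizer": float(f"{self.normalizer:.17g}"),
            },
            indent=2,
        )


def build_coefficients(params: ModelParams, schedule: Schedule) -> CoefficientSet:
    """Expand ``Q_n`` and ``dQ_n/dlambda`` by the multiplicative recursion."""
    n = schedule.n
    if n < 1:
        raise ValueError("need at least one observation")
    p = params.detect_prob
    q = 1.0 - p
    ups = schedule.decay(params.birth_rate)
    gaps = schedule.gaps

    size = 1 << (n + 1)
    Q = np.zeros(size)
    dQ = np.zeros(size)
    # Q_0 = (1 - ups_1) + ups_1 * u_0
    Q[0] = 1.0 - ups[0]
    Q[1] = ups[0]
    dQ[0] = gaps[0] * ups[0]
    dQ[1] = -gaps[0] * ups[0]
    for i in range(1, n + 1):
        # segment decay ups_{i,i+1}; beyond the horizon it is 1 (gap 0)
        u_next = ups[i] if i < n else 1.0
        d_next = gaps[i] if i < n else 0.0
        affQ = _mul_affine(Q, i, p, q)
        affdQ = _mul_affine(dQ, i, p, q)
        newQ = u_next * affQ
        newQ[0] += 1.0 - u_next
        # dQ_i = dups * ((p u_i + q) Q_{i-1} - 1) + ups * (p u_i + q) dQ_{i-1}
        newdQ = -d_next * u_next * affQ + u_next * affdQ
        newdQ[0] += d_next * u_next
        Q, dQ = newQ, newdQ

    theta_tau = math.exp(-params.birth_rate * schedule.horizon)
    return CoefficientSet(
        order=n,
        detect_prob=p,
        horizon=schedule.horizon,
        q=Q,
        dq=dQ,
        theta_tau=theta_tau,
    )


class LikelihoodCache:
    """Memo table for the reference (dict-based) recursion.

    Maps ``(x0, y)`` to ``(L, dL)``.  The dense slice engine in
    :mod:`popbp.fisher` is the fast path; this cache exists for direct
    evaluation of individual likelihood values and for cross-validation.
    """

    def __init__(self) -> None:
        self._tab: dict[tuple[int, tuple[int, ...]], tuple[float, float]] = {}

    def get(self, x0: int, y: tuple[int, ...]):
        return self._tab.get((x0, y))

    def put(self, x0: int, y: tuple[int, ...], L: float, dL: float) -> None:
        self._tab[(x0, y)] = (L, dL)


def _eval_recursive(
    x0: int, y: tuple[int, ...], coeffs: CoefficientSet, cache: LikelihoodCache
) -> tuple[float, float]:
    if x0 <= 0 or any(v < 0 for v in y):
        return 0.0, 0.0
    hit = cache.get(x0, y)
    if hit is not None:
        return hit
    n = coeffs.order
    q0 = coeffs.normalizer
    dq0 = coeffs.dnormalizer
    py = coeffs.numer_coeff(y) if x0 == 1 else 0.0
    dpy = -coeffs.horizon * py
    acc_L = py
    acc_dL = dpy
    dL_terms = 0.0
    for mask in range(1, 1 << (n + 1)):
        qc = float(coeffs.q[mask])
        dqc = float(coeffs.dq[mask])
        if qc == 0.0 and dqc == 0.0:
            continue
        c0 = mask & 1
        yc = tuple(y[k] - ((mask >> (k + 1)) & 1) for k in range(n))
        Lm, dLm = _eval_recursive(x0 - c0, yc, coeffs, cache)
        acc_L += qc * Lm
        dL_terms += dqc * Lm + qc * dLm
    L = acc_L / q0
    dL = (acc_dL + dL_terms - dq0 * L) / q0
    cache.put(x0, y, L, dL)
    return L, dL


def likelihood_recursive(
    y, coeffs: CoefficientSet, cache: LikelihoodCache | None = None, x0: int = 1
) -> float:
    """POPBP likelihood ``L(y)`` by the linear recurrence.

    ``y`` is the vector of observed counts; ``x0`` the known initial size.
    A shared :class:`LikelihoodCache` makes repeated evaluations linear in
    the number of new lattice points.
    """
    y = tuple(int(v) for v in y)
    if len(y) != coeffs.order:
        raise ValueError(f"observation vector must have length {coeffs.order}")
    if cache is None:
        cache = LikelihoodCache()
    return _eval_recursive(x0, y, coeffs, cache)[0]


def likelihood_derivative_recursive(
    y, coeffs: CoefficientSet, cache: LikelihoodCache | None = None, x0: int = 1
) -> float:
    """``dL(y)/dlambda`` by the differentiated recurrence (product rule)."""
    y = tuple(int(v) for v in y)
    if len(y) != coeffs.order:
        raise ValueError(f"observation vector must have length {coeffs.order}")
    if cache is None:
        cache = LikelihoodCache()
    return _eval_recursive(x0, y, coeffs, cache)[1]
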
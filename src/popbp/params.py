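"""Model parameters and observation schedules.

A pure birth process (PBP, or Yule process) with birth rate ``lambda`` is
observed at times ``t_1 <= ... <= t_n = tau``.  Under partial observation
(POPBP) each of the ``x`` individuals alive at an observation time is detected
independently with probability ``p``, so the recorded count is
``Binomial(x, p)``.  These two small frozen dataclasses carry the parameter
triple and the schedule together with the derived exponential decay factors
that appear throughout the likelihood algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """POPBP parameter triple (birth rate, detection probability, initial size).

    Parameters
    ----------
    birth_rate : float
        Birth rate ``lambda > 0`` per unit time.  Each individual splits at
        rate ``lambda``, so a population of size ``x`` grows at rate
        ``lambda * x``.
    detect_prob : float
        Probability ``p`` in ``[0, 1]`` of detecting any given individual at
        an observation time.  ``p = 1`` recovers the fully observed PBP,
        ``p = 0`` carries no information.
    init_size : int
        Known initial population size ``x0 >= 1`` at time 0.
    """

    birth_rate: float
    detect_prob: float = 1.0
    init_size: int = 1

    def __post_init__(self) -> None:
        if not self.birth_rate > 0:
            raise ValueError(f"birth_rate must be positive, got {self.birth_rate}")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError(
                f"detect_prob must lie in [0, 1], got {self.detect_prob}"
            )
        if not (isinstance(self.init_size, (int,)) and self.init_size >= 1):
            raise ValueError(f"init_size must be an integer >= 1, got {self.init_size}")

    @property
    def miss_prob(self) -> float:
        """Probability ``q = 1 - p`` of missing an individual."""
        return 1.0 - self.detect_prob


@dataclass(frozen=True)
class Schedule:
    """Ordered observation times ``0 < t_1 <= ... <= t_n = horizon``.

    Repeated times are legal (a zero gap means two independent detection
    rounds on the same population).  The decay factor over segment ``i`` is
    ``upsilon_i = exp(-lambda * (t_i - t_{i-1}))`` and ``theta(t) =
    exp(-lambda * t)``; both are supplied as methods because they depend on
    the birth rate.
    """

    times: tuple[float, ...]
    horizon: float = field(init=False)

    def __init__(self, times) -> None:
        ts = tuple(float(t) for t in times)
        if len(ts) == 0:
            raise ValueError("schedule needs at least one observation time")
        if ts[0] <= 0:
            raise ValueError(f"first observation time must be positive, got {ts[0]}")
        for a, b in zip(ts, ts[1:]):
            if b < a:
                raise ValueError(f"observation times must be nondecreasing: {ts}")
        object.__setattr__(self, "times", ts)
        object.__setattr__(self, "horizon", ts[-1])

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def gaps(self) -> tuple[float, ...]:
        """Segment lengths ``Delta_i = t_i - t_{i-1}`` with ``t_0 = 0``."""
        prev = 0.0
        out = []
        for t in self.times:
            out.append(t - prev)
            prev = t
        return tuple(out)

    def decay(self, birth_rate: float) -> tuple[float, ...]:
        """Per-segment decay factors ``upsilon_{i-1,i} = exp(-lambda Delta_i)``."""
        return tuple(math.exp(-birth_rate * d) for d in self.gaps)

    def theta(self, birth_rate: float, t: float) -> float:
        """``theta_t = exp(-lambda t)``, the survival factor from time 0."""
        return math.exp(-birth_rate * t)
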
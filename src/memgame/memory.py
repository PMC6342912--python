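"""Effective ("final") payoffs computed from remembered past payoffs.

Three variants transform a player's payoff history (entry 0 = current
payoff, entry m = the payoff evaluated m history ticks earlier) into the
effective payoff that enters the imitation rule:

``none``
    The current payoff, unchanged — the memoryless baseline.

``averaged``
    A geometrically weighted moving average::

        P_i = (P_0 + sum_{m=1}^{M} alpha^m P_m) / (1 + sum_{m=1}^{M} alpha^m)

    The decay factor ``alpha`` in [0, 1) sets both the weights and,
    indirectly, the memory length ``M``: lags are retained while their
    weight ``alpha^m`` stays at or above the 0.01 cutoff.  ``alpha = 0``
    recovers the baseline.

``delayed``
    With probability ``nu = exp(-tau / s)`` a single past payoff ``P_tau``
    replaces the current one; otherwise the current payoff is used.  The
    decay scale ``s = -100 / ln(0.01)`` (~21.71) makes a 100-step-old
    payoff acceptable only 1% of the time.  ``tau = 0`` recovers the
    baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DECAY_SCALE",
    "MemoryConfig",
    "memory_length",
    "averaged_payoff",
    "delay_acceptance",
    "effective_payoff",
]

#: Weight cutoff below which a lag is forgotten (averaged variant).
WEIGHT_THRESHOLD = 0.01

#: Natural decay scale of the delayed variant: -100 / ln(0.01).
DECAY_SCALE = -100.0 / math.log(0.01)

#: Hard cap on the averaged-variant window so the alpha -> 1 limit stays bounded.
MAX_WINDOW = 500


def memory_length(alpha: float, threshold: float = WEIGHT_THRESHOLD) -> int:
    """Largest lag ``m`` whose weight ``alpha**m`` stays at or above ``threshold``.

    ``alpha = 0`` gives 0 (only the current payoff survives; ``0**0 == 1``).
    The comparison is inclusive: a lag is retained while its weight has not
    gone strictly below the cutoff.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if alpha == 0.0:
        return 0
    # floor(log threshold / log alpha), guarded against rounding at the edge
    m = int(math.floor(math.log(threshold) / math.log(alpha)))
    while alpha ** (m + 1) >= threshold:
        m += 1
    while m > 0 and alpha**m < threshold:
        m -= 1
    return m


def delay_acceptance(tau: float) -> float:
    """Probability ``nu = exp(-tau / s)`` of using the tau-step-old payoff.

    Strictly decreasing in ``tau``; equals 1 at ``tau = 0`` and 0.01 at
    ``tau = 100`` by construction of the decay scale ``s``.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    return math.exp(-tau / DECAY_SCALE)


@dataclass(frozen=True)
class MemoryConfig:
    """Which memory rule is active and its parameters.

    Exactly one variant is active; parameters of the inactive variants are
    ignored.  Derived quantities: ``M`` (averaged window length from the
    weight cutoff, capped at ``max_window``) and ``nu`` (delayed-variant
    acceptance probability).

    Parameters
    ----------
    variant : {"none", "averaged", "delayed"}
    alpha : float
        Weight decay factor of the averaged variant, in [0, 1).
    tau : int
        Delay of the delayed variant, in payoff-evaluation ticks, >= 0.
    """

    variant: str = "none"
    alpha: float = 0.0
    tau: int = 0
    weight_threshold: float = field(default=WEIGHT_THRESHOLD)
    max_window: int = field(default=MAX_WINDOW)

    def __post_init__(self) -> None:
        if self.variant not in ("none", "averaged", "delayed"):
            raise ValueError(f"unknown memory variant {self.variant!r}")
        if self.variant == "averaged" and not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.variant == "delayed" and (self.tau < 0 or self.tau != int(self.tau)):
            raise ValueError(f"tau must be a non-negative integer, got {self.tau}")

    @property
    def M(self) -> int:
        """Averaged-variant memory length implied by the weight cutoff."""
        if self.variant != "averaged":
            return 0
        return min(memory_length(self.alpha, self.weight_threshold), self.max_window)

    @property
    def nu(self) -> float:
        """Delayed-variant acceptance probability exp(-tau/s)."""
        if self.variant != "delayed":
            return 1.0
        return delay_acceptance(self.tau)

    @property
    def history_capacity(self) -> int:
        """Payoff-history entries each site must retain: max lag + 1."""
        if self.variant == "averaged":
            return self.M + 1
        if self.variant == "delayed":
            return int(self.tau) + 1
        return 1

    @property
    def reference_lag(self) -> int:
        """Lag (in full MCS) of the past strategy used for weak/strong labels.

        The middle of the averaging window, ``ceil(M / 2)``, for the
        averaged variant; ``tau`` for the delayed variant; 0 (labels are
        always "strong") without memory.
        """
        if self.variant == "averaged":
            return (self.M + 1) // 2
        if self.variant == "delayed":
            return int(self.tau)
        return 0

    def weight_denominators(self) -> np.ndarray:
        """Normalization ``sum_{k=0}^{m} alpha^k`` for every usable window m.

        Built by the recurrence ``d[m] = 1 + alpha * d[m-1]`` so it is
        bit-identical to the Horner evaluation in :func:`averaged_payoff`.
        """
        denom = np.ones(self.M + 1, dtype=np.float64)
        for m in range(1, self.M + 1):
            denom[m] = 1.0 + self.alpha * denom[m - 1]
        return denom

    def to_dict(self) -> dict:
        return {"variant": self.variant, "alpha": self.alpha, "tau": self.tau}

    @classmethod
    def from_dict(cls, d: dict) -> "MemoryConfig":
        return cls(
            variant=d.get("variant", "none"),
            alpha=float(d.get("alpha", 0.0)),
            tau=int(d.get("tau", 0)),
        )


def averaged_payoff(history, alpha: float, M: int | None = None) -> float:
    """Geometrically weighted moving average of a payoff history.

    ``history`` lists payoffs most recent first.  The window is truncated
    to the available past entries and the weights renormalized, so the
    result is always a convex combination of the entries used.  Evaluated
    as a Horner recurrence from the oldest retained entry inward, which is
    the same arithmetic the compiled simulation kernel performs.
    """
    entries = np.asarray(history, dtype=np.float64)
    if entries.size == 0:
        raise ValueError("payoff history is empty")
    if M is None:
        M = memory_length(alpha) if alpha > 0 else 0
    n_use = min(M, entries.size - 1)
    acc = entries[n_use]
    for m in range(n_use - 1, -1, -1):
        acc = entries[m] + alpha * acc
    denom = 1.0
    for _ in range(n_use):
        denom = 1.0 + alpha * denom
    return acc / denom


def effective_payoff(history, config: MemoryConfig, rng: np.random.Generator | None = None) -> float:
    """Effective payoff of one player under the active memory rule.

    The delayed variant consumes exactly one uniform draw from ``rng``
    (required in that case); the other variants consume none.  When fewer
    than ``tau + 1`` entries exist the oldest available entry substitutes
    for the tau-step-old payoff.
    """
    entries = np.asarray(history, dtype=np.float64)
    if entries.size == 0:
        raise ValueError("payoff history is empty")
    if config.variant == "none":
        return float(entries[0])
    if config.variant == "averaged":
        return averaged_payoff(entries, config.alpha, config.M)
    # delayed
    if rng is None:
        raise ValueError("the delayed variant requires a random generator")
    u = rng.random()
    if config.tau > 0 and u < config.nu:
        return float(entries[min(config.tau, entries.size - 1)])
    return float(entries[0])
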
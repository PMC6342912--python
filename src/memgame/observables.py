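"""Cooperation density, weak/strong subgroups, and invasion-rate ledgers.

A player is *strong* if its current strategy agrees with its strategy at a
variant-specific reference lag in the past (the middle of the averaging
window, or the delay tau), and *weak* otherwise.  The four subgroups are
written C_C (strong cooperator), C_D (weak cooperator), D_D (strong
defector) and D_C (weak defector): first letter = current strategy,
subscript = past strategy.

Successful strategy adoptions between sites of different strategies are
*invasion events*; binned per full Monte Carlo step and keyed by the
(invader subgroup, invaded subgroup) pair they form the invasion ledger,
whose net cooperator gain tracks the change in cooperator count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .lattice import LatticeState
from .memory import MemoryConfig

__all__ = [
    "Subgroup",
    "InvasionLedger",
    "classify",
    "rho_c",
    "stationary_average",
]


class Subgroup(IntEnum):
    """Weak/strong strategy subgroups; integer codes match the kernel."""

    C_C = 0  # strong cooperator
    C_D = 1  # weak cooperator
    D_D = 2  # strong defector
    D_C = 3  # weak defector

    @property
    def strategy(self) -> int:
        """Current strategy: 1 (C) for C_C/C_D, 0 (D) for D_D/D_C."""
        return 1 if self in (Subgroup.C_C, Subgroup.C_D) else 0

    @property
    def strong(self) -> bool:
        return self in (Subgroup.C_C, Subgroup.D_D)

    @property
    def label(self) -> str:
        return self.name.replace("_", "")  # "CC", "CD", "DD", "DC"


def subgroup_of(current: int, reference: int) -> Subgroup:
    """Subgroup from a current strategy and the reference past strategy."""
    if current == 1:
        return Subgroup.C_C if reference == 1 else Subgroup.C_D
    return Subgroup.D_D if reference == 0 else Subgroup.D_C


def classify(state: LatticeState, site: tuple[int, int], mem: MemoryConfig) -> Subgroup:
    """Weak/strong subgroup of one site.

    The reference strategy is the per-MCS record ``mem.reference_lag``
    steps back; players with a shorter record are classified against their
    oldest record, so at time 0 every player is strong.
    """
    lag = mem.reference_lag
    current = int(state.strategies[site])
    if lag == 0 or not state.strat_records:
        return subgroup_of(current, current)
    reference = int(state.reference_strategies()[site])
    return subgroup_of(current, reference)


def rho_c(state: LatticeState) -> float:
    """Fraction of cooperators N_C / L^2."""
    return state.n_cooperators / state.n_sites


def stationary_average(trajectory, measure_window: int, absorbed: str | None = None) -> float:
    """Mean cooperator fraction over the final measurement window.

    If the run reached an absorbing state the absorbed value (0 or 1) is
    returned instead of a time average.
    """
    traj = np.asarray(trajectory, dtype=np.float64)
    if absorbed is not None:
        return {"C": 1.0, "D": 0.0}[absorbed]
    if measure_window > traj.size:
        raise ValueError(
            f"measurement window {measure_window} exceeds trajectory length {traj.size}"
        )
    if measure_window == 0:
        return float(traj[-1])
    return float(traj[-measure_window:].mean())


# The 8 directed invasion channels: (invader subgroup, invaded subgroup)
# with opposite strategies.  Kernel flat code = invader * 4 + invaded.
CHANNELS: tuple[tuple[Subgroup, Subgroup], ...] = tuple(
    (src, dst)
    for src in Subgroup
    for dst in Subgroup
    if src.strategy != dst.strategy
)


def channel_name(src: Subgroup, dst: Subgroup) -> str:
    """Ledger column label, e.g. ``"DD<-CC"`` for C_C invading D_D."""
    return f"{dst.label}<-{src.label}"


@dataclass
class InvasionLedger:
    """Per-MCS counts of successful adoptions between subgroups.

    ``counts`` has shape ``(n_mcs, 16)`` indexed flat by
    ``invader * 4 + invaded``; only the 8 mixed-strategy channels are ever
    populated.  The accumulated net cooperator gain — adoptions of C by
    defectors minus adoptions of D by cooperators — equals the change in
    cooperator count over the ledger window exactly.
    """

    counts: np.ndarray  # (n_mcs, 16) int64

    @classmethod
    def empty(cls, n_mcs: int = 0) -> "InvasionLedger":
        return cls(np.zeros((n_mcs, 16), dtype=np.int64))

    @property
    def n_mcs(self) -> int:
        return self.counts.shape[0]

    def new_bin(self) -> None:
        """Open the counting bin for the next MCS."""
        self.counts = np.vstack([self.counts, np.zeros((1, 16), dtype=np.int64)])

    def record_event(self, event) -> None:
        """Count one successful adoption in the current MCS bin.

        Rejects events between same-strategy subgroups (not invasions) and
        unsuccessful attempts.
        """
        if event.subgroup_j.strategy == event.subgroup_i.strategy:
            raise ValueError("same-strategy adoption is not an invasion event")
        if not event.adopted:
            raise ValueError("only successful adoptions are ledger events")
        if self.n_mcs == 0:
            self.new_bin()
        self.counts[-1, int(event.subgroup_j) * 4 + int(event.subgroup_i)] += 1

    def channel(self, src: Subgroup, dst: Subgroup) -> np.ndarray:
        """Per-MCS counts of ``src`` invading ``dst``."""
        return self.counts[:, int(src) * 4 + int(dst)]

    def net_channel(self, a: Subgroup, b: Subgroup) -> np.ndarray:
        """Per-MCS net flow of the bidirectional channel ``a <-> b``.

        Positive when the cooperator-strategy side invades more than it is
        invaded; ``a`` and ``b`` must hold opposite strategies.
        """
        if a.strategy == b.strategy:
            raise ValueError("net channel requires opposite-strategy subgroups")
        coop, defe = (a, b) if a.strategy == 1 else (b, a)
        return self.channel(coop, defe) - self.channel(defe, coop)

    def net_cooperator_gain(self) -> np.ndarray:
        """Per-MCS net cooperator gain: sum(D-side adopts C) - sum(C-side adopts D)."""
        gain = np.zeros(self.n_mcs, dtype=np.int64)
        for src, dst in CHANNELS:
            flow = self.counts[:, int(src) * 4 + int(dst)]
            gain += flow if src.strategy == 1 else -flow
        return gain

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-MCS table: one column per channel plus the net gain."""
        data = {"mcs": np.arange(1, self.n_mcs + 1)}
        for src, dst in CHANNELS:
            data[channel_name(src, dst)] = self.counts[:, int(src) * 4 + int(dst)]
        data["net_gain"] = self.net_cooperator_gain()
        return pd.DataFrame(data)
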
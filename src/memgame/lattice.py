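"""Toroidal square-lattice state for two-strategy social dilemmas.

Players occupy an ``L x L`` grid with periodic boundary conditions and the
von Neumann (4-site) neighborhood.  Each player is either a cooperator (C)
or a defector (D) and collects payoffs by playing a pairwise game with all
four neighbors.  The payoff matrix is parameterized by the temptation ``T``
and the sucker's payoff ``S``; the reward and punishment are fixed at
``R = 1`` and ``P = 0``, which places the three classic social dilemmas in
the quadrants of the (T, S) plane.

Coordinates are 0-based ``(row, column)`` pairs, row-major.  The neighbor
order is fixed as (up, down, left, right), where "up" decreases the row
index with wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Strategy",
    "GameParams",
    "LatticeState",
    "neighbors",
    "accrue_payoff",
    "init_random",
    "init_circular_domain",
    "lattice_to_text",
    "lattice_from_text",
]

#: Fixed neighbor displacement order: up, down, left, right.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))


class Strategy(IntEnum):
    """The two admissible strategies; no third state ever appears."""

    D = 0
    C = 1

    @property
    def letter(self) -> str:
        return "C" if self is Strategy.C else "D"


@dataclass(frozen=True)
class GameParams:
    """Payoff matrix of the two-strategy game.

    Only the temptation ``T`` and sucker's payoff ``S`` are free; the
    reward ``R = 1`` and punishment ``P = 0`` are fixed so that the
    (T, S) plane spans the harmony game, the stag-hunt, the snowdrift
    and the prisoner's dilemma.

    Parameters
    ----------
    T : float
        Temptation to defect against a cooperator, ``0 <= T <= 2``.
    S : float
        Sucker's payoff for cooperating against a defector,
        ``-1 <= S <= 1``.
    """

    T: float
    S: float
    R: float = field(default=1.0, init=False)
    P: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.T <= 2.0):
            raise ValueError(f"T must lie in [0, 2], got {self.T}")
        if not (-1.0 <= self.S <= 1.0):
            raise ValueError(f"S must lie in [-1, 1], got {self.S}")

    def pairwise(self, focal: int, other: int) -> float:
        """Payoff earned by ``focal`` against ``other`` in one encounter."""
        if focal == Strategy.C:
            return self.R if other == Strategy.C else self.S
        return self.T if other == Strategy.C else self.P

    @property
    def dilemma(self) -> str | None:
        """Social-dilemma class of this (T, S) point.

        Returns ``"PD"`` (prisoner's dilemma, T > 1 and S < 0), ``"SD"``
        (snowdrift, T > 1 and S > 0), ``"SH"`` (stag-hunt, T < 1 and
        S < 0), ``"HG"`` (harmony, T < 1 and S > 0), or ``None`` on the
        degenerate boundary lines T = 1 or S = 0, which belong to no
        quadrant and are excluded from quadrant averages.
        """
        if self.T == 1.0 or self.S == 0.0:
            return None
        if self.T > 1.0:
            return "PD" if self.S < 0.0 else "SD"
        return "SH" if self.S < 0.0 else "HG"


@dataclass
class LatticeState:
    """Strategies plus bounded per-site payoff and strategy histories.

    ``strategies`` is an ``(L, L)`` int8 array with 1 = cooperator and
    0 = defector.  Payoff histories tick on the Monte Carlo step clock: a
    player's payoff is re-evaluated whenever it takes part in an elementary
    step, and at every MCS boundary the value it currently holds is
    snapshotted into a bounded ring buffer, so snapshot ``m`` back is the
    payoff it held entering the step ``m`` full MCS ago.  Strategy records
    are per-MCS snapshots on the same boundary clock, used for the
    weak/strong classification.  Both buffers are bounded by the capacity
    demanded by the active memory configuration.
    """

    strategies: np.ndarray
    time: int = 0
    # last evaluated payoff per site, and whether one exists yet
    last_payoff: np.ndarray | None = None   # (N,) float64
    has_payoff: np.ndarray | None = None    # (N,) int8
    # per-MCS-boundary payoff snapshots: ring buffers, newest at snap_head
    snap_hist: np.ndarray | None = None     # (N, cap) float64
    snap_head: np.ndarray | None = None     # (N,) int64
    snap_len: np.ndarray | None = None      # (N,) int64
    # per-MCS strategy snapshots, oldest first, bounded length
    strat_records: list = field(default_factory=list)
    strat_record_cap: int = 1

    def __post_init__(self) -> None:
        self.strategies = np.ascontiguousarray(self.strategies, dtype=np.int8)
        if self.strategies.ndim != 2 or self.strategies.shape[0] != self.strategies.shape[1]:
            raise ValueError("strategies must be a square 2-D array")
        if self.L < 3:
            raise ValueError("lattice size L must be at least 3")
        vals = np.unique(self.strategies)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("strategies must contain only 0 (D) and 1 (C)")

    @property
    def L(self) -> int:
        return self.strategies.shape[0]

    @property
    def n_sites(self) -> int:
        return self.strategies.size

    @property
    def n_cooperators(self) -> int:
        return int(self.strategies.sum())

    def attach_histories(self, pay_capacity: int, record_capacity: int) -> None:
        """Allocate empty payoff/strategy history buffers for the active memory rule."""
        n = self.n_sites
        self.last_payoff = np.zeros(n, dtype=np.float64)
        self.has_payoff = np.zeros(n, dtype=np.int8)
        self.snap_hist = np.zeros((n, max(pay_capacity, 1)), dtype=np.float64)
        self.snap_head = np.zeros(n, dtype=np.int64)
        self.snap_len = np.zeros(n, dtype=np.int64)
        self.strat_record_cap = max(record_capacity, 1)
        self.strat_records = []

    def note_payoff(self, site_index: int, value: float) -> None:
        """Record a fresh payoff evaluation (becomes a snapshot at the MCS boundary)."""
        self.last_payoff[site_index] = value
        self.has_payoff[site_index] = 1

    def push_snapshots(self) -> None:
        """At an MCS boundary, snapshot every evaluated site's current payoff.

        Snapshot offset ``m`` (from the newest) is then the payoff the
        player held at the beginning of the step ``m`` full MCS before
        the next one — the history tick of the memory rules.
        """
        cap = self.snap_hist.shape[1]
        mask = self.has_payoff == 1
        head = np.where(self.snap_len > 0, (self.snap_head + 1) % cap, 0)
        idx = np.nonzero(mask)[0]
        self.snap_hist[idx, head[idx]] = self.last_payoff[idx]
        self.snap_head[idx] = head[idx]
        self.snap_len[idx] = np.minimum(self.snap_len[idx] + 1, cap)

    def payoff_history(self, site: tuple[int, int]) -> np.ndarray:
        """Payoff snapshots for ``site``, most recent first (entry 0 = current)."""
        idx = site[0] * self.L + site[1]
        n = int(self.snap_len[idx])
        cap = self.snap_hist.shape[1]
        head = int(self.snap_head[idx])
        return self.snap_hist[idx, (head - np.arange(n)) % cap]

    def record_strategies(self) -> None:
        """Append the per-MCS strategy snapshot, dropping beyond capacity."""
        self.strat_records.append(self.strategies.copy())
        while len(self.strat_records) > self.strat_record_cap:
            del self.strat_records[0]

    def reference_strategies(self) -> np.ndarray:
        """Strategy record at the classification reference lag.

        The record buffer keeps the last ``lag + 1`` per-MCS snapshots, so
        its oldest element is exactly the strategy ``lag`` steps ago (or
        the earliest available record before that many steps have passed).
        Before any record exists the current strategies are returned, so
        every player starts out "strong".
        """
        if not self.strat_records:
            return self.strategies
        return self.strat_records[0]

    def copy(self) -> "LatticeState":
        new = LatticeState(self.strategies.copy(), time=self.time)
        for name in ("last_payoff", "has_payoff", "snap_hist", "snap_head", "snap_len"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(new, name, arr.copy())
        new.strat_records = [r.copy() for r in self.strat_records]
        new.strat_record_cap = self.strat_record_cap
        return new


def _check_site(state: LatticeState, site: tuple[int, int]) -> None:
    r, c = site
    if not (0 <= r < state.L and 0 <= c < state.L):
        raise ValueError(f"site {site} outside [0, {state.L}) x [0, {state.L})")


def neighbors(state: LatticeState, site: tuple[int, int]) -> list[tuple[int, int]]:
    """The four von Neumann neighbors of ``site``, in (up, down, left, right) order.

    The lattice is toroidal, so every site has exactly four neighbors and
    the relation is symmetric.
    """
    _check_site(state, site)
    L = state.L
    r, c = site
    return [((r + dr) % L, (c + dc) % L) for dr, dc in NEIGHBOR_OFFSETS]


def accrue_payoff(state: LatticeState, site: tuple[int, int], params: GameParams) -> float:
    """Total payoff of ``site`` from playing the game with all four neighbors."""
    _check_site(state, site)
    focal = int(state.strategies[site])
    total = 0.0
    for nb in neighbors(state, site):
        total += params.pairwise(focal, int(state.strategies[nb]))
    return total


def init_random(L: int, seed: int | np.random.Generator | None = None) -> LatticeState:
    """Random 50/50 initial condition: each site independently C or D."""
    if L < 3:
        raise ValueError("lattice size L must be at least 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    strategies = (rng.random((L, L)) < 0.5).astype(np.int8)
    return LatticeState(strategies)


def init_circular_domain(L: int, radius: float | None = None) -> LatticeState:
    """A round cooperative domain centered on the lattice, surrounded by defectors.

    Sites within Euclidean distance ``radius`` (inclusive) of the central
    site ``(L//2, L//2)`` cooperate; all others defect.  The default radius
    is ``L // 4`` — large enough for a sizable domain without wrapping.
    A radius above ``L / 2`` is rejected because the domain would self-wrap
    across the periodic boundary.
    """
    if L < 3:
        raise ValueError("lattice size L must be at least 3")
    if radius is None:
        radius = L // 4
    if radius < 0 or radius > L / 2:
        raise ValueError(f"radius must lie in [0, L/2], got {radius}")
    center = L // 2
    rr, cc = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    inside = (rr - center) ** 2 + (cc - center) ** 2 <= radius**2
    return LatticeState(inside.astype(np.int8))


def lattice_to_text(state: LatticeState) -> str:
    """Render the strategy grid as delimited text, one lattice row per line."""
    return "\n".join(
        " ".join("C" if v else "D" for v in row) for row in state.strategies
    )


def lattice_from_text(text: str) -> LatticeState:
    """Parse a grid written by :func:`lattice_to_text`."""
    rows = [line.split() for line in text.strip().splitlines()]
    grid = np.array([[1 if tok == "C" else 0 for tok in row] for row in rows], dtype=np.int8)
    return LatticeState(grid)


def neighbor_index_table(L: int) -> np.ndarray:
    """Flat-index lookup table of shape ``(L*L, 4)`` in (up, down, left, right) order.

    Used by the compiled inner loop to avoid per-step modular arithmetic.
    """
    rr, cc = np.divmod(np.arange(L * L), L)
    cols = []
    for dr, dc in NEIGHBOR_OFFSETS:
        cols.append(((rr + dr) % L) * L + (cc + dc) % L)
    return np.stack(cols, axis=1).astype(np.int64)
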
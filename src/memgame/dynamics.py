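"""Asynchronous Monte Carlo evolution with Fermi-rule imitation.

One *elementary step*: (1) a uniformly random focal player i computes its
payoff against its four neighbors and pushes it onto its history; (2) a
uniformly random neighbor j does the same; (3) both payoffs are passed
through the active memory rule and i adopts j's strategy with the Fermi
probability ``W = 1 / (1 + exp((P_i - P_j) / K))``.  Repeating this L^2
times is one full Monte Carlo step (MCS), giving every player one revision
opportunity on average.

Random-stream contract (identical between this pure-Python reference path
and the compiled kernel): per elementary step, one uniform for the focal
site, one for the neighbor direction, one past-payoff acceptance draw each
for i and j (delayed variant only), and one adoption draw — consumed even
when the two strategies already agree, so streams stay aligned across
configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernel
from .lattice import GameParams, LatticeState, accrue_payoff, neighbor_index_table
from .memory import MemoryConfig, averaged_payoff
from .observables import InvasionLedger, Subgroup, stationary_average, subgroup_of

__all__ = [
    "DynamicsConfig",
    "AdoptionEvent",
    "RunResult",
    "fermi_probability",
    "elementary_step",
    "monte_carlo_step",
    "run",
]

_VARIANT_CODE = {"none": _kernel.VARIANT_NONE, "averaged": _kernel.VARIANT_AVERAGED,
                 "delayed": _kernel.VARIANT_DELAYED}


@dataclass(frozen=True)
class DynamicsConfig:
    """Update-rule and protocol parameters.

    ``K`` is the selection noise of the Fermi rule (default 0.1, the
    conventional choice for lattice imitation dynamics).  A run relaxes
    for ``relaxation_steps`` MCS and then time-averages the cooperator
    fraction over ``measure_steps`` MCS; with ``stop_at_absorption`` it
    halts as soon as the population fixates, reporting the absorbed value.
    """

    K: float = 0.1
    relaxation_steps: int = 10_000
    measure_steps: int = 20_000
    seed: int | None = None
    stop_at_absorption: bool = True

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.relaxation_steps < 0 or self.measure_steps < 0:
            raise ValueError("step counts must be non-negative")


@dataclass(frozen=True)
class AdoptionEvent:
    """Record of one imitation attempt between unlike strategies."""

    site_i: tuple[int, int]
    site_j: tuple[int, int]
    subgroup_i: Subgroup
    subgroup_j: Subgroup
    adopted: bool


def fermi_probability(p_i: float, p_j: float, K: float) -> float:
    """Probability that player i adopts player j's strategy.

    ``W = 1 / (1 + exp((p_i - p_j) / K))``: close to 1 when j outperforms
    i, 1/2 at equal payoffs, and strictly decreasing in ``p_i - p_j``.
    Evaluated in the overflow-safe branch form, stable for exponents of
    magnitude up to ~1000.
    """
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    x = (p_i - p_j) / K
    if x > 0.0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


def _ensure_histories(state: LatticeState, mem: MemoryConfig) -> None:
    if state.snap_hist is None or state.snap_hist.shape[1] < mem.history_capacity:
        state.attach_histories(mem.history_capacity, mem.reference_lag + 1)
    state.strat_record_cap = mem.reference_lag + 1
    if not state.strat_records:
        state.record_strategies()  # time-0 record: everyone starts strong


def _effective_from_state(state: LatticeState, idx: int, fresh: float,
                          mem: MemoryConfig, u_accept: float) -> float:
    """Effective payoff from the fresh evaluation plus boundary snapshots.

    History entry m (m >= 1) is snapshot offset m from the newest: the
    payoff the player held entering the step m full MCS back.  Mirrors
    the compiled kernel arithmetic exactly.
    """
    cap = state.snap_hist.shape[1]
    head = int(state.snap_head[idx])
    avail = int(state.snap_len[idx])
    if mem.variant == "averaged":
        n_use = min(mem.M, avail - 1) if avail > 0 else 0
        past = state.snap_hist[idx, (head - np.arange(1, n_use + 1)) % cap]
        return averaged_payoff(np.concatenate(([fresh], past)), mem.alpha, mem.M)
    if mem.variant == "delayed" and mem.tau > 0 and avail > 0 and u_accept < mem.nu:
        return float(state.snap_hist[idx, (head - min(mem.tau, avail - 1)) % cap])
    return fresh


def elementary_step(
    state: LatticeState,
    params: GameParams,
    mem: MemoryConfig,
    dyn: DynamicsConfig,
    rng: np.random.Generator,
) -> AdoptionEvent | None:
    """One elementary update; pure-Python reference for the compiled kernel.

    Returns an :class:`AdoptionEvent` when the focal player and the chosen
    neighbor hold different strategies (whether or not the adoption
    succeeded), else ``None``.  At most one strategy changes.
    """
    _ensure_histories(state, mem)
    L = state.L
    n = state.n_sites
    flat = state.strategies.reshape(-1)
    ndraws = _kernel.N_DRAWS[_VARIANT_CODE[mem.variant]]
    u = rng.random(ndraws)

    i = int(u[0] * n)
    site_i = divmod(i, L)
    p_now_i = accrue_payoff(state, site_i, params)
    state.note_payoff(i, p_now_i)

    nbr = neighbor_index_table(L)
    j = int(nbr[i, int(u[1] * 4.0)])
    site_j = divmod(j, L)
    p_now_j = accrue_payoff(state, site_j, params)
    state.note_payoff(j, p_now_j)

    u_i, u_j = (u[2], u[3]) if mem.variant == "delayed" else (0.0, 0.0)
    p_i = _effective_from_state(state, i, p_now_i, mem, u_i)
    p_j = _effective_from_state(state, j, p_now_j, mem, u_j)
    w = fermi_probability(p_i, p_j, dyn.K)
    u_adopt = u[ndraws - 1]  # consumed unconditionally

    if flat[i] == flat[j]:
        return None
    ref = state.reference_strategies().reshape(-1) if state.strat_records else flat
    lag = mem.reference_lag
    ref_i = int(ref[i]) if lag > 0 else int(flat[i])
    ref_j = int(ref[j]) if lag > 0 else int(flat[j])
    event = AdoptionEvent(
        site_i=site_i,
        site_j=site_j,
        subgroup_i=subgroup_of(int(flat[i]), ref_i),
        subgroup_j=subgroup_of(int(flat[j]), ref_j),
        adopted=bool(u_adopt < w),
    )
    if event.adopted:
        flat[i] = flat[j]
    return event


def monte_carlo_step(
    state: LatticeState,
    params: GameParams,
    mem: MemoryConfig,
    dyn: DynamicsConfig,
    rng: np.random.Generator,
) -> list[AdoptionEvent]:
    """L^2 elementary steps; increments time and appends the strategy record."""
    _ensure_histories(state, mem)
    events = [
        ev
        for _ in range(state.n_sites)
        if (ev := elementary_step(state, params, mem, dyn, rng)) is not None
    ]
    state.time += 1
    state.push_snapshots()
    state.record_strategies()
    return events


@dataclass
class RunResult:
    """Outcome of one simulation run.

    ``rho_trajectory[t]`` is the cooperator fraction after MCS ``t + 1``;
    ``channel_counts`` holds the per-MCS invasion events (flat subgroup
    channel index, see :class:`memgame.observables.InvasionLedger`).
    """

    state: LatticeState
    rho_trajectory: np.ndarray
    channel_counts: np.ndarray
    absorbed: str | None
    stationary_rho: float
    relaxation_steps: int
    measure_steps: int

    @property
    def ledger(self) -> InvasionLedger:
        return InvasionLedger(self.channel_counts)

    def trajectory_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mcs": np.arange(1, self.rho_trajectory.size + 1), "rho_c": self.rho_trajectory}
        )


def run(
    state: LatticeState,
    params: GameParams,
    mem: MemoryConfig | None = None,
    dyn: DynamicsConfig | None = None,
    rng: np.random.Generator | int | None = None,
    observers: Sequence[Callable[[LatticeState, int, float], None]] = (),
) -> RunResult:
    """Evolve ``state`` through relaxation plus measurement (compiled path).

    The stationary cooperator fraction is the time average over the
    measurement window, or the absorbed value (0 or 1) if the population
    fixated first — absorbing states are static, so stopping early is
    exact.  Observers are called after every MCS with
    ``(state, mcs_index, rho_c)``.  The state is evolved in place and also
    returned inside the result.
    """
    mem = mem or MemoryConfig()
    dyn = dyn or DynamicsConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(dyn.seed if rng is None else rng)

    variant = _VARIANT_CODE[mem.variant]
    ndraws = _kernel.N_DRAWS[variant]
    denom = mem.weight_denominators()
    nbr = neighbor_index_table(state.L)
    _ensure_histories(state, mem)

    n = state.n_sites
    flat = state.strategies.reshape(-1)
    total = dyn.relaxation_steps + dyn.measure_steps
    rho = np.empty(total, dtype=np.float64)
    counts = np.zeros((total, 16), dtype=np.int64)
    absorbed: str | None = None
    t_done = 0
    lag = mem.reference_lag

    for t in range(total):
        draws = rng.random((n, ndraws))
        if lag > 0 and state.strat_records:
            ref = state.reference_strategies().reshape(-1)
        else:
            ref = flat  # reference = current strategy: everyone strong
        _kernel.mcs_kernel(
            flat, nbr, params.T, params.S, dyn.K,
            variant, mem.alpha, mem.M, denom, int(mem.tau), mem.nu,
            state.last_payoff, state.has_payoff,
            state.snap_hist, state.snap_head, state.snap_len,
            ref, draws, counts[t],
        )
        state.time += 1
        state.push_snapshots()
        state.record_strategies()
        n_c = int(flat.sum())
        rho[t] = n_c / n
        t_done = t + 1
        for obs in observers:
            obs(state, state.time, rho[t])
        if n_c == 0 or n_c == n:
            absorbed = "C" if n_c == n else "D"
            if dyn.stop_at_absorption:
                break

    rho = rho[:t_done]
    counts = counts[:t_done]
    if absorbed is not None:
        stationary = 1.0 if absorbed == "C" else 0.0
    elif t_done == 0:
        stationary = flat.sum() / n
    else:
        window = min(dyn.measure_steps, rho.size)
        stationary = stationary_average(rho, window)
    return RunResult(
        state=state,
        rho_trajectory=rho,
        channel_counts=counts,
        absorbed=absorbed,
        stationary_rho=stationary,
        relaxation_steps=dyn.relaxation_steps,
        measure_steps=dyn.measure_steps,
    )
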
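"""Parameter sweeps and headline experiments.

High-level drivers that repeatedly call :func:`memgame.dynamics.run`:

* T-S plane sweeps of the stationary cooperator fraction (heat maps),
* quadrant averages over the three social dilemmas and their difference
  from a memoryless baseline,
* fixation experiments started from a prepared circular cooperative
  domain, and
* invasion-ledger experiments from random initial states.

Every cell of a sweep derives its own random seed from the base seed and
its grid coordinates, so results are independent of execution order and
reproducible cell by cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, RunResult, run
from .lattice import GameParams, init_circular_domain, init_random
from .memory import MemoryConfig
from .observables import Subgroup

__all__ = [
    "SweepSpec",
    "SweepResult",
    "sweep",
    "quadrant_average",
    "delta_vs_baseline",
    "fixation_experiment",
    "FixationResult",
    "ledger_experiment",
]

log = logging.getLogger(__name__)

DILEMMAS = ("SH", "SD", "PD")


def _cell_rng(base_seed: int, *indices: int) -> np.random.Generator:
    """Independent, order-insensitive stream for one sweep cell."""
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), *map(int, indices)]))


@dataclass(frozen=True)
class SweepSpec:
    """A grid of (T, S) games crossed with memory parameters and replicates.

    ``variant`` selects the memory rule; ``param_values`` lists the alpha
    (averaged) or tau (delayed) values to scan — ignored for ``none``.
    Defaults are desk-scale: trends in the T-S plane survive far smaller
    lattices and shorter windows than publication-quality heat maps need.
    """

    T_values: tuple = (0.5, 1.5)
    S_values: tuple = (-0.5, 0.5)
    variant: str = "none"
    param_values: tuple = (0,)
    L: int = 100
    n_seeds: int = 5
    base_seed: int = 0
    relaxation_steps: int = 2000
    measure_steps: int = 1000
    K: float = 0.1

    def __post_init__(self) -> None:
        if len(self.T_values) == 0 or len(self.S_values) == 0 or len(self.param_values) == 0:
            raise ValueError("sweep grids must be non-empty")
        for T in self.T_values:
            if not (0.0 <= T <= 2.0):
                raise ValueError(f"T value {T} outside [0, 2]")
        for S in self.S_values:
            if not (-1.0 <= S <= 1.0):
                raise ValueError(f"S value {S} outside [-1, 1]")
        if self.n_seeds < 1:
            raise ValueError("need at least one replicate seed")

    def memory_config(self, param) -> MemoryConfig:
        if self.variant == "averaged":
            return MemoryConfig(variant="averaged", alpha=float(param))
        if self.variant == "delayed":
            return MemoryConfig(variant="delayed", tau=int(param))
        return MemoryConfig()


@dataclass
class SweepResult:
    """Per-seed stationary cooperator fractions plus aggregation helpers."""

    table: pd.DataFrame  # columns: T, S, param, seed, rho, absorbed, dilemma

    def cell_means(self) -> pd.DataFrame:
        """Mean rho per (T, S, param) cell, reproducible from the table."""
        return (
            self.table.groupby(["T", "S", "param"], as_index=False)["rho"]
            .mean()
            .rename(columns={"rho": "rho_mean"})
        )

    def quadrant_means(self) -> pd.DataFrame:
        """Mean rho per (dilemma, param) over strictly-interior quadrant cells."""
        cells = self.cell_means()
        cells["dilemma"] = [
            GameParams(t, s).dilemma for t, s in zip(cells["T"], cells["S"])
        ]
        interior = cells.dropna(subset=["dilemma"])
        return (
            interior.groupby(["dilemma", "param"], as_index=False)["rho_mean"]
            .mean()
            .rename(columns={"rho_mean": "rho"})
        )


def sweep(spec: SweepSpec) -> SweepResult:
    """Run every (T, S, parameter, seed) combination from random initial states."""
    rows = []
    for pi, param in enumerate(spec.param_values):
        mem = spec.memory_config(param)
        for ti, T in enumerate(spec.T_values):
            for si, S in enumerate(spec.S_values):
                params = GameParams(T, S)
                for rep in range(spec.n_seeds):
                    rng = _cell_rng(spec.base_seed, pi, ti, si, rep)
                    state = init_random(spec.L, rng)
                    dyn = DynamicsConfig(
                        K=spec.K,
                        relaxation_steps=spec.relaxation_steps,
                        measure_steps=spec.measure_steps,
                    )
                    try:
                        result = run(state, params, mem, dyn, rng)
                    except Exception:  # pragma: no cover - defensive per-cell isolation
                        log.exception("sweep cell failed: T=%s S=%s param=%s rep=%s", T, S, param, rep)
                        continue
                    rows.append(
                        {
                            "T": T,
                            "S": S,
                            "param": param,
                            "seed": rep,
                            "rho": result.stationary_rho,
                            "absorbed": result.absorbed or "",
                            "dilemma": params.dilemma or "",
                        }
                    )
                    log.info(
                        "sweep cell T=%.3g S=%.3g param=%s rep=%d rho=%.4f%s",
                        T, S, param, rep, result.stationary_rho,
                        f" absorbed={result.absorbed}" if result.absorbed else "",
                    )
    return SweepResult(pd.DataFrame(rows))


def quadrant_average(result: SweepResult, dilemma: str) -> float:
    """Unweighted mean stationary rho over one dilemma's interior cells.

    ``dilemma`` is ``"SH"``, ``"SD"`` or ``"PD"``; cells on the boundary
    lines T = 1 or S = 0 belong to no quadrant and never contribute.
    """
    if dilemma not in DILEMMAS:
        raise ValueError(f"dilemma must be one of {DILEMMAS}, got {dilemma!r}")
    qm = result.quadrant_means()
    rows = qm[qm["dilemma"] == dilemma]
    if rows.empty:
        raise ValueError(f"sweep contains no interior {dilemma} cells")
    return float(rows["rho"].mean())


def delta_vs_baseline(curve: pd.Series) -> pd.Series:
    """Cooperation gain relative to the memoryless point of a parameter scan.

    ``curve`` maps the memory parameter (tau or alpha) to a mean rho; the
    entry at parameter 0 is the baseline and maps to exactly 0.
    """
    if 0 not in curve.index:
        raise ValueError("baseline entry at parameter 0 is missing")
    return curve - curve.loc[0]


@dataclass
class FixationResult:
    """Outcomes of prepared-domain runs: one label per seed.

    Labels are ``"C"`` (cooperator fixation), ``"D"`` (defector fixation)
    or ``"unresolved"`` when no absorbing state was reached within the
    step cap; unresolved runs keep their final rho rather than being
    dropped.
    """

    labels: list[str]
    final_rho: list[float]
    params: GameParams
    mem: MemoryConfig

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {k: self.labels.count(k) / n for k in ("C", "D", "unresolved")}

    @property
    def majority(self) -> str:
        counts = {k: self.labels.count(k) for k in set(self.labels)}
        return max(counts, key=counts.get)


def fixation_experiment(
    params: GameParams,
    mem: MemoryConfig,
    L: int = 101,
    radius: int = 25,
    n_seeds: int = 10,
    max_steps: int = 30_000,
    K: float = 0.1,
    base_seed: int = 0,
) -> FixationResult:
    """Evolve a round cooperative domain in a sea of defectors to fixation.

    Each seeded replicate runs with absorption stopping for at most
    ``max_steps`` MCS and is labelled by its final state.  This probes the
    memory-induced reversal of invasion fronts: under a short memory the
    domain is eaten by defectors, under a long one it expands to take over
    the lattice.
    """
    labels, finals = [], []
    for rep in range(n_seeds):
        rng = _cell_rng(base_seed, 101, rep)
        state = init_circular_domain(L, radius)
        dyn = DynamicsConfig(K=K, relaxation_steps=max_steps, measure_steps=0)
        result = run(state, params, mem, dyn, rng)
        if result.absorbed is not None:
            labels.append(result.absorbed)
        else:
            labels.append("unresolved")
        finals.append(result.rho_trajectory[-1] if result.rho_trajectory.size else 0.0)
        log.info(
            "fixation rep=%d T=%.3g S=%.3g %s -> %s (t=%d)",
            rep, params.T, params.S, mem.to_dict(), labels[-1], result.state.time,
        )
    return FixationResult(labels, finals, params, mem)


def ledger_experiment(
    params: GameParams,
    mem: MemoryConfig,
    L: int = 100,
    n_steps: int = 2000,
    n_runs: int = 3,
    K: float = 0.1,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Replicate-averaged invasion-rate curves from random initial states.

    Returns a per-MCS table with the mean count of every directed channel
    plus the mean net cooperator gain.  Runs that absorb early contribute
    zero events afterwards (an absorbed lattice produces no invasions),
    which keeps the replicate average well defined over the full window.
    """
    acc = np.zeros((n_steps, 16), dtype=np.float64)
    for rep in range(n_runs):
        rng = _cell_rng(base_seed, 555, rep)
        state = init_random(L, rng)
        dyn = DynamicsConfig(K=K, relaxation_steps=n_steps, measure_steps=0)
        result = run(state, params, mem, dyn, rng)
        t = result.channel_counts.shape[0]
        acc[:t] += result.channel_counts
    acc /= n_runs
    from .observables import CHANNELS, channel_name

    data = {"mcs": np.arange(1, n_steps + 1)}
    for src, dst in CHANNELS:
        data[channel_name(src, dst)] = acc[:, int(src) * 4 + int(dst)]
    net = np.zeros(n_steps)
    for src, dst in CHANNELS:
        flow = acc[:, int(src) * 4 + int(dst)]
        net += flow if src.strategy == 1 else -flow
    data["net_gain"] = net
    return pd.DataFrame(data)


def net_channel_curve(ledger_frame: pd.DataFrame, a: Subgroup, b: Subgroup) -> np.ndarray:
    """Net a<->b flow (cooperator side minus defector side) from a ledger table."""
    from .observables import channel_name

    coop, defe = (a, b) if a.strategy == 1 else (b, a)
    fwd = ledger_frame[channel_name(coop, defe)].to_numpy()
    back = ledger_frame[channel_name(defe, coop)].to_numpy()
    return fwd - back
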
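"""Compiled inner loop: one full Monte Carlo step of L^2 elementary updates.

The kernel consumes a pre-drawn matrix of uniforms so that the random
stream is owned by the caller (a numpy ``Generator`` in production, a
scripted array in tests) and is identical between this compiled path and
the pure-Python reference in :mod:`memgame.dynamics`.

Per elementary step the draw columns are, in order:

====== ==========================================================
column meaning
====== ==========================================================
0      focal site: ``i = floor(u * L^2)`` (row-major flat index)
1      neighbor direction: ``floor(u * 4)`` over (up, down, left, right)
2, 3   delayed variant only: past-payoff acceptance for i, then j
last   adoption Bernoulli against the Fermi probability W
====== ==========================================================

The adoption draw is consumed even when the two strategies already agree,
which keeps random streams aligned across parameter settings.

Payoff memory ticks on the MCS-boundary clock: ``last_pay`` holds each
site's most recent evaluation, and the caller snapshots it into the
``snap`` ring buffer after every MCS, so snapshot offset ``m`` is the
payoff a player held entering the step ``m`` full MCS back.  Effective
payoffs combine the fresh in-step evaluation (entry 0) with those
snapshots (entries 1, 2, ...).  Variants are encoded 0 = none,
1 = averaged, 2 = delayed; the averaged rule is a Horner recurrence from
the oldest retained entry, matching
:func:`memgame.memory.averaged_payoff` bit for bit.
"""

from __future__ import annotations

from numba import njit
import numpy as np

VARIANT_NONE = 0
VARIANT_AVERAGED = 1
VARIANT_DELAYED = 2

#: draw columns per elementary step, by variant code
N_DRAWS = {VARIANT_NONE: 3, VARIANT_AVERAGED: 3, VARIANT_DELAYED: 5}


@njit(cache=True)
def _accrue(strat, site, nbr_idx, T, S):
    """Payoff of ``site`` against its four neighbors; R = 1, P = 0 fixed."""
    total = 0.0
    s = strat[site]
    for k in range(4):
        sn = strat[nbr_idx[site, k]]
        if s == 1:
            total += 1.0 if sn == 1 else S
        else:
            total += T if sn == 1 else 0.0
    return total


@njit(cache=True)
def _fermi(p_i, p_j, K):
    """W = 1 / (1 + exp((p_i - p_j) / K)), overflow-guarded."""
    x = (p_i - p_j) / K
    if x > 0.0:
        e = np.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def _effective(fresh, snap, snap_head, snap_len, site,
               variant, alpha, M, denom, tau, nu, u_accept):
    # Entry m of the payoff history is snapshot offset m from the newest:
    # the payoff the player held entering the step m full MCS back.  Entry
    # 0 is the fresh in-step evaluation; offset 0 (the value entering the
    # current step) is superseded by it and never read.
    cap = snap.shape[1]
    head = snap_head[site]
    avail = snap_len[site]
    if variant == 1:  # averaged: Horner from the oldest retained entry
        n_use = min(M, avail - 1) if avail > 0 else 0
        if n_use <= 0:
            return fresh
        acc = snap[site, (head - n_use) % cap]
        for m in range(n_use - 1, 0, -1):
            acc = snap[site, (head - m) % cap] + alpha * acc
        return (fresh + alpha * acc) / denom[n_use]
    if variant == 2:  # delayed: a single past payoff with probability nu
        if tau > 0 and avail > 0 and u_accept < nu:
            lag = min(tau, avail - 1)
            return snap[site, (head - lag) % cap]
        return fresh
    return fresh


@njit(cache=True)
def _subgroup(current, reference):
    """0 = C_C, 1 = C_D, 2 = D_D, 3 = D_C."""
    if current == 1:
        return 0 if reference == 1 else 1
    return 2 if reference == 0 else 3


@njit(cache=True)
def mcs_kernel(
    strat,        # (N,) int8, mutated in place
    nbr_idx,      # (N, 4) int64 neighbor lookup
    T, S, K,
    variant, alpha, M, denom, tau, nu,
    last_pay, has_pay,               # (N,) float64 / int8, mutated in place
    snap, snap_head, snap_len,       # snapshot ring buffers (read-only here)
    ref_strat,    # (N,) int8 strategy record at the reference lag
    draws,        # (N, n_draws) uniforms
    channel_counts,  # (16,) int64, successful adoptions by (sub_j * 4 + sub_i)
):
    """Run L^2 elementary steps (one full MCS) in place.

    Channel counts index successful adoptions by invader subgroup
    (``sub_j``, whose strategy spreads) times 4 plus invaded subgroup
    (``sub_i``); only the 8 mixed-strategy combinations can occur.  The
    caller is responsible for snapshotting ``last_pay`` into the ring
    buffers after the MCS (``LatticeState.push_snapshots``).
    """
    n = strat.shape[0]
    adopt_col = draws.shape[1] - 1
    for step in range(n):
        i = int(draws[step, 0] * n)
        fresh_i = _accrue(strat, i, nbr_idx, T, S)
        last_pay[i] = fresh_i
        has_pay[i] = 1
        j = nbr_idx[i, int(draws[step, 1] * 4.0)]
        fresh_j = _accrue(strat, j, nbr_idx, T, S)
        last_pay[j] = fresh_j
        has_pay[j] = 1
        if variant == 2:
            u_i = draws[step, 2]
            u_j = draws[step, 3]
        else:
            u_i = 0.0
            u_j = 0.0
        p_i = _effective(fresh_i, snap, snap_head, snap_len, i,
                         variant, alpha, M, denom, tau, nu, u_i)
        p_j = _effective(fresh_j, snap, snap_head, snap_len, j,
                         variant, alpha, M, denom, tau, nu, u_j)
        w = _fermi(p_i, p_j, K)
        u_adopt = draws[step, adopt_col]  # consumed even for equal strategies
        if strat[i] != strat[j] and u_adopt < w:
            sub_i = _subgroup(strat[i], ref_strat[i])
            sub_j = _subgroup(strat[j], ref_strat[j])
            channel_counts[sub_j * 4 + sub_i] += 1
            strat[i] = strat[j]
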
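"""Hand-coded reference simulator used as an independent oracle.

Deliberately naive: dict-based lattice, explicit payoff-matrix lookups,
plain-formula logistic, list-based histories.  Shares no code with the
package; consumes the same pre-drawn uniforms as the compiled kernel so
traces can be compared step by step.
"""

import math


def payoff(grid, L, r, c, T, S):
    matrix = {(1, 1): 1.0, (1, 0): S, (0, 1): T, (0, 0): 0.0}
    total = 0.0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        total += matrix[(grid[(r, c)], grid[((r + dr) % L, (c + dc) % L)])]
    return total


def logistic(p_i, p_j, K):
    x = (p_i - p_j) / K
    if x > 0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


def weighted_average(entries, alpha, M):
    n_use = min(M, len(entries) - 1)
    weights = [1.0] + [alpha**m for m in range(1, n_use + 1)]
    return sum(w * e for w, e in zip(weights, entries)) / sum(weights)


def effective(fresh, snapshots, variant, alpha=0.0, M=0, tau=0, nu=1.0, u_accept=1.0):
    """Entry m of the history is snapshot offset m; entry 0 is ``fresh``."""
    if variant == "averaged" and snapshots:
        n_use = min(M, len(snapshots) - 1)
        return weighted_average([fresh] + snapshots[1 : n_use + 1], alpha, M)
    if variant == "delayed" and tau > 0 and snapshots and u_accept < nu:
        return snapshots[min(tau, len(snapshots) - 1)]
    return fresh


def run_mcs(grid, L, T, S, K, draws, variant="none", alpha=0.0, M=0, tau=0, nu=1.0, cap=1,
            snapshots=None, last=None):
    """One full Monte Carlo step; returns the trace of every elementary step.

    ``draws`` is an (L*L, k) array with k = 3 (none/averaged) or 5
    (delayed).  ``grid`` is a dict (r, c) -> strategy, mutated in place.
    """
    n = L * L
    snapshots = snapshots if snapshots is not None else {s: [] for s in range(n)}
    last = last if last is not None else {}
    trace = []
    for step in range(n):
        row = draws[step]
        i = int(row[0] * n)
        ri, ci = divmod(i, L)
        p_now_i = payoff(grid, L, ri, ci, T, S)
        last[i] = p_now_i
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(row[1] * 4.0)]
        rj, cj = (ri + dr) % L, (ci + dc) % L
        j = rj * L + cj
        p_now_j = payoff(grid, L, rj, cj, T, S)
        last[j] = p_now_j
        u_i, u_j = (row[2], row[3]) if variant == "delayed" else (1.0, 1.0)
        p_i = effective(p_now_i, snapshots[i], variant, alpha, M, tau, nu, u_i)
        p_j = effective(p_now_j, snapshots[j], variant, alpha, M, tau, nu, u_j)
        w = logistic(p_i, p_j, K)
        u_adopt = row[-1]
        adopted = grid[(ri, ci)] != grid[(rj, cj)] and u_adopt < w
        trace.append(
            {"i": (ri, ci), "j": (rj, cj), "p_now_i": p_now_i, "p_now_j": p_now_j,
             "p_i": p_i, "p_j": p_j, "W": w, "adopted": adopted}
        )
        if adopted:
            grid[(ri, ci)] = grid[(rj, cj)]
    for s in last:
        snapshots[s].insert(0, last[s])
        del snapshots[s][cap:]
    return trace, snapshots, last
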
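# memgame

Monte Carlo simulator for two-strategy social dilemmas on a periodic square
lattice in which strategy imitation is driven by **remembered past payoffs**
rather than by the current payoff alone.

## The scientific question

In spatial evolutionary games, players on an `L × L` torus are cooperators
(C) or defectors (D) and collect payoffs from their four von Neumann
neighbors using the standard bimatrix with reward `R = 1`, punishment
`P = 0`, temptation `T ∈ [0, 2]` and sucker's payoff `S ∈ [−1, 1]`
(prisoner's dilemma for `T > 1, S < 0`; snowdrift for `T > 1, S > 0`;
stag-hunt for `T < 1, S < 0`).  Evolution proceeds by asynchronous
imitation: a random focal player `i` and a random neighbor `j` evaluate
their payoffs, and `i` adopts `s_j` with the Fermi probability

    W = 1 / (1 + exp[(P_i − P_j) / K]),        K = 0.1.

This package studies what happens when the payoffs `P_i`, `P_j` entering
`W` are not the current payoffs but *effective* payoffs that incorporate
each player's history, in one of two ways:

* **Weighted moving average** with decay factor `α ∈ [0, 1)`:

      P_i = (P_{0,i} + Σ_{m=1..M} α^m P_{m,i}) / (1 + Σ_{m=1..M} α^m),

  where `P_{m,i}` is the payoff player `i` held `m` full Monte Carlo steps
  (MCS) back and the memory length `M` is the largest lag whose weight
  `α^m` stays at or above 0.01.

* **Probabilistic delayed payoff**: with probability `ν = exp(−τ/s)`,
  `s = −100/ln(0.01) ≈ 21.71`, the payoff from `τ` full MCS back replaces
  the current one (so a 100-step-old payoff is used only 1% of the time).

Both rules are strategy-neutral, yet they strongly promote cooperation:
freshly successful defectors cannot immediately exploit their high
temptation payoff, which decelerates defector invasion fronts while
cooperative domains keep growing.  The simulator exposes the
weak/strong-subgroup bookkeeping (players whose current strategy differs
from their past strategy are "weak") and per-channel invasion ledgers that
make this mechanism measurable.

## Worked example

The reversal of an invasion front by memory length alone, from a prepared
round cooperative domain (radius 25) in a sea of defectors at `T = 1.3`,
`S = −0.1`:

```bash
$ memgame run --T 1.3 --S -0.1 --L 101 --init circle --radius 25 \
              --variant avg --alpha 0.9 --relax 30000 --measure 0 --seed 1 --out demo
stationary rho_C = 1.0000 (absorbed C at MCS 1163)

$ memgame run --T 1.3 --S -0.1 --L 101 --init circle --radius 25 \
              --variant avg --alpha 0.5 --relax 30000 --measure 0 --seed 1 --out demo2
stationary rho_C = 0.0000 (absorbed D at MCS 634)
```

With the short memory (`α = 0.5`, window `M = 6`) defectors eliminate the
cooperative domain within 634 MCS; raising the decay factor to `α = 0.9`
(window `M = 43`) reverses the outcome and cooperators take over the whole
lattice.  The same experiment through the library:

```python
from memgame import (GameParams, MemoryConfig, DynamicsConfig,
                     init_circular_domain, run)

state = init_circular_domain(101, radius=25)
result = run(state, GameParams(T=1.3, S=-0.1),
             MemoryConfig("averaged", alpha=0.9),
             DynamicsConfig(relaxation_steps=30_000, measure_steps=0), rng=1)
print(result.absorbed, result.state.time, result.stationary_rho)
# C 1163 1.0
```

Other entry points: `memgame sweep` (T–S plane heat maps of the stationary
cooperator fraction), `memgame fixation` (seeded prepared-domain
experiments), `memgame ledger` (per-channel invasion-rate curves between
the weak/strong subgroups), `memgame render` (subgroup-colored snapshots).

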
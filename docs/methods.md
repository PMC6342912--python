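# Methods

## Model

Players occupy a toroidal `L × L` square lattice with the von Neumann
neighborhood.  Each player is a cooperator (C) or defector (D); a player's
payoff is the sum over its four neighbors of the pairwise game payoffs
with `R = 1`, `P = 0` fixed and `T ∈ [0, 2]`, `S ∈ [−1, 1]` free.  The
dilemma classifier assigns `T > 1, S < 0` to the prisoner's dilemma,
`T > 1, S > 0` to the snowdrift game and `T < 1, S < 0` to the stag-hunt;
points on the lines `T = 1` or `S = 0` belong to no quadrant and are
excluded from quadrant averages.

One *elementary step*: a uniformly random focal player `i` evaluates its
payoff, a uniformly random neighbor `j` evaluates its payoff, and `i`
adopts `s_j` with probability `W = 1/(1 + exp[(P_i − P_j)/K])`, where
`P_i`, `P_j` are *effective* payoffs (below).  `L²` elementary steps form
one full Monte Carlo step (MCS).  There is no mutation, so the homogeneous
states are absorbing.

## Payoff memory and the history clock

Effective payoffs are computed from per-player payoff histories under one
of three variants:

* `none` — the fresh evaluation, the memoryless baseline;
* `averaged` — geometrically weighted average with decay `α`; the window
  `M` is the largest lag with `α^m ≥ 0.01` (inclusive comparison; `M = 0`
  at `α = 0`; capped at 500 entries so the `α → 1` limit stays bounded,
  where the normalization still guarantees finite values);
* `delayed` — with probability `ν = exp(−τ/s)`, `s = −100/ln(0.01)`, the
  payoff from lag `τ` replaces the fresh one.

**History tick.**  Histories tick on the MCS-boundary clock.  A player's
payoff is re-evaluated whenever it takes part in an elementary step; at
every MCS boundary the value each evaluated player currently holds is
snapshotted into a bounded ring buffer.  History entry `m ≥ 1` is the
snapshot `m` boundaries back — the payoff the player held entering the
step `m` full MCS before the current one — and entry 0 is the fresh
in-step evaluation.  This convention was chosen over a per-evaluation
tick after direct comparison: per-evaluation histories age too quickly at
interfaces (a boundary site is evaluated roughly twice per MCS) and
cannot reproduce the delayed-rule reversal of invasion fronts at small
`τ`, whereas the boundary clock reproduces both reversals and makes the
payoff reference identical in kind to the strategy reference used for the
weak/strong classification.  Players keep their histories when they
switch strategy — the protective "weak cooperator" shield depends on it.

**Bootstrap.**  Before a player has enough snapshots, the averaged rule
truncates the window to the available entries and renormalizes; the
delayed rule substitutes the oldest available snapshot; players with no
snapshot yet use the fresh value.

**Random-stream contract.**  Per elementary step the simulation consumes,
in order: one uniform for the focal site, one for the neighbor direction
(fixed order up, down, left, right), one past-payoff acceptance draw each
for `i` and `j` (delayed variant only, drawn independently), and one
adoption draw — consumed even when the strategies already agree.  This
keeps seeded runs aligned across configurations, and makes `α = 0`
averaging bit-identical to the baseline.  The compiled kernel and the
pure-Python reference path consume the same pre-drawn matrices and agree
bit for bit; the averaged rule is evaluated as a Horner recurrence from
the oldest retained entry in both.

## Observables

`ρ_C` is the cooperator fraction; a run relaxes for a configurable number
of MCS and then time-averages `ρ_C` over a measurement window, or reports
the absorbed value if fixation occurred (absorbing states are static, so
stopping at absorption is exact and is enabled by default, also in
sweeps).

A player is **strong** if its current strategy equals its strategy at a
variant-specific reference lag on the per-MCS strategy record — the
middle of the averaging window `⌈M/2⌉` for the averaged variant, `τ` for
the delayed variant, zero (always strong) without memory; players with a
shorter record are classified against their oldest record, so everyone
starts strong.  Successful adoptions between unlike strategies are binned
per MCS into the 8 directed channels between the subgroups C_C, C_D, D_D,
D_C (invader → invaded, classified just before the adoption).  The
accumulated net cooperator gain of the ledger equals the change in
cooperator count exactly, which the tests assert per MCS.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `K` | Fermi selection noise | 0.1 (conventional for lattice imitation) |
| `L` | linear lattice size | 100 (101 for prepared-domain runs) |
| `α` | averaged-variant decay | — (scan parameter) |
| `τ` | delayed-variant lag, MCS | — (scan parameter) |
| weight cutoff | smallest retained `α^m` | 0.01 |
| `s` | delay-acceptance scale | −100/ln(0.01) ≈ 21.715 |
| relaxation / measurement | MCS | 10⁴ / 2·10⁴ (library defaults) |
| circular-domain radius | prepared initial state | `L/4` (25 at `L = 101`) |

Initial conditions: 50/50 random, or a round cooperative domain (inclusive
Euclidean distance from the central site; radii above `L/2` are rejected
because the domain would self-wrap).

## Problem sizes used in tests and the acceptance script

Desk-scale sizes, chosen once so the qualitative phenomena are
well-resolved: prepared-domain fixation experiments at `L = 101`, radius
25, a 3·10⁴-MCS cap and 10 (tests) or 5 (script) seeds; the delay scan on
a coarse 3×3 interior prisoner's-dilemma grid (`T ∈ {1.1, 1.35, 1.6}`,
`S ∈ {−0.1, −0.35, −0.6}`) at `L = 100` with 2000 + 1000 MCS and 5 (tests)
or 3 (script) seeds per cell; invasion-ledger experiments at `L = 100`
over 1500 MCS averaged over 3 runs.  Publication-scale settings (`L` up
to 800, 10⁴ + 2·10⁴ MCS, 1000-run ensembles) are reachable through the
same configuration objects.

## What the experiments do and do not show

The generator of all inputs is the simulator itself; there is no external
data.  The reproduced phenomena: the memoryless baseline loses
cooperation in the prisoner's dilemma quadrant; lengthening the averaging
window (`α` 0.5 → 0.9 at `T = 1.3, S = −0.1`) or choosing an intermediate
delay (`τ` 1 → 3 at `T = 1.3, S = −0.4`) reverses defector invasion into
cooperator fixation from the same prepared state; the delay scan has an
interior optimum (`τ = 3` beats both `τ = 0` and `τ = 50`); and during
cooperator take-over the weak-defector ↔ strong-cooperator channel
sustains a positive net flow.

Known limitation: the exact location of phase boundaries depends on the
history-clock convention, for which no unique definition exists once
"one round" must be mapped onto asynchronous updates.  Under the
MCS-boundary clock used here the averaged memory is slightly stronger
than under younger conventions; e.g. at `S = 0, α = 0.5` the
defector-dominance threshold sits near `T ≈ 1.35`, so `T = 1.2, S = 0,
α = 0.5` is a coexistence point (stationary `ρ_C ≈ 0.53`,
size-independent) and its invasion channels churn indefinitely instead of
dying out.  Quantitative comparisons of threshold locations between
implementations with different clock conventions are therefore not
meaningful; the qualitative reversals above are robust (they survived
every convention tested that reproduces the delayed-rule flip at all).

Square lattice only: no other topologies, no Moore neighborhood, no
synchronous updating, no mutation, and no per-player heterogeneity of the
memory parameters.
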
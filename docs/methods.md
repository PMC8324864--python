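# Methods

## The model

Agents accumulate a single fungible resource by playing an n-person dictator
game DG_{k,n} once per time step, and convert resources into offspring under
an interbirth-interval (IBI) constraint. The package implements three layers
of the same model:

1. **Closed-form analytics** (`dgevolve.analytic`). Under homogeneous play of
   offer `p`, the one-step payoff is a two-point mixture over roles — dictator
   with probability `k/n` keeping `R(1-p)`, recipient otherwise receiving
   `k p R/(n-k)` — with mean `kR/n = mu` for every `p` and variance

       sigma_p^2 = k R^2 (k + n p - n)^2 / (n^2 (n - k)).

   Roles are redrawn independently each step, so variance over a horizon of
   `tau0` steps is `tau0 * sigma_p^2` and the coefficient of variation of
   accumulated resources is `n sqrt(tau0 sigma_p^2) / (tau0 k R)`, which is
   algebraically the sd of the accumulation divided by its expectation. The
   CV is zero exactly at the equitable offer `p* = 1 - k/n` and shrinks as
   `1/sqrt(tau0)`. These expressions exclude the endowment noise `sigma_R`:
   that noise is an implementation device of the simulators (it prevents the
   expected return from being an exact divisor of the reproduction threshold),
   not part of the derivation, so Monte-Carlo cross-checks of the closed forms
   are run with `sigma_R = 0`.

2. **Simple agent model** (`dgevolve.homogeneous`). Independent lifetimes of
   one strategy, mean-field sampled: each step an agent draws its role
   Bernoulli(k/n); a dictator keeps `(1-p) R_i` with its own endowment draw,
   a recipient pools `k` independent endowment draws and receives
   `p * sum(R_i) / (n-k)`. No partner matching — the model measures a
   strategy against itself; offspring are counted, not instantiated.
   Per-strategy mean lifetime offspring and mean realized IBIs are normalized
   by the grand mean over the 11-strategy grid to give relative fitness and
   relative IBI tables.

3. **Evolutionary agent-based model** (`dgevolve.abm`). Explicit agents in
   groups on a toroidal grid (or one unstructured pool). Per step and per
   group: Bernoulli role assignment, then each dictator plays `n-k`
   recipients taken sequentially from the shuffled recipient list, the list
   being freshly re-shuffled whenever exhausted. This cycling procedure
   yields the four chance edge cases (no dictators; no recipients, in which
   case dictators keep their full endowment; too few dictators, leaving
   some recipients unplayed; too few recipients, so some are played more
   than once). Births obey a Moran-like cap: the parent always pays the
   offspring cost, but the newborn enters only while the population is below
   `N`. Offspring inherit the parent's offer, mutating at rate `r` uniformly
   to one of the ten *other* grid strategies, and disperse at rate `d` to a
   uniformly chosen other existing group. Lifespan expiry is the only
   removal mechanism. Groups reaching the fission threshold split into
   halves of sizes floor(g/2) and ceil(g/2); the parent keeps its cell, the
   daughter takes a uniformly drawn unoccupied cell (falling back to any
   cell in the pathological fully-occupied case).

## Reproduction bookkeeping

`I_o = tau0 * mu` resources produce one offspring. The IBI `tau` starts at
the optimum `tau0` and, on every step an agent's resources fall strictly
below `gamma * T * mu` (where `T` counts steps played since its own birth or
last birth), lengthens by `c * tau0`. Deficit additions are unbounded; `tau`
resets to `tau0` only at birth events, which also subtract `I_o` with full
carryover of any surplus. A birth requires both `x >= I_o` and `T >= tau`
(non-strict), with `tau` held as a real number and compared exactly.

**Within-step order** (fixed by design; the ordering of these phases is a
modeling choice): game payoffs -> `T` increment -> deficit check -> births in
randomized agent order under the cap -> aging and death -> fission -> empty
group removal. The stored clock is zeroed at a birth event and incremented
before the deficit check, so the first played step after a birth has `T = 1`
and the deficit threshold `gamma * T * mu` tracks the expectation of exactly
`T` played games. Newborns neither play nor age in the step of their birth.

Lifespans are `trunc(Gaussian(omega, sigma_omega))` clamped below at 1, with
`omega = 3 tau0` and `sigma_omega = 0.25 omega`. At these defaults the
expected lifetime offspring of an unconstrained agent is about 2.5 rather
than 3: offspring come in whole IBIs, so lifespan variation truncates the
final partial interval (the package's simulations reproduce this emergent
value; it is never hard-coded).

## Parameters

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| k, n | dictators / total players | per game | — |
| mu | expected per-agent per-step return | 5 | resources |
| R | base endowment, `n mu / k` | derived | resources |
| sigma_R | endowment noise sd | 0.1 R | resources |
| p | offer fraction, grid {0.0, …, 1.0} | — | — |
| tau0 | optimal IBI | 270 (or 730) | steps |
| I_o | offspring cost, `tau0 mu` | 1350 | resources |
| omega | mean lifespan, `3 tau0` | 810 | steps |
| sigma_omega | lifespan sd, `0.25 omega` | 202.5 | steps |
| c | IBI time cost per deficit step | 0.01 | fraction of tau0 |
| gamma | deficit cutoff | 0.9 | fraction of `T mu` |
| r | mutation rate | 0.01 | per birth |
| d | dispersal rate | 0.01 | per birth |
| N | population cap | 10,000 | agents |
| — | fission threshold | 20 | agents/group |
| — | grid | 100 x 100 | cells (toroidal) |
| — | simulation length | 1000 omega | steps |

`tau0 = 270` steps corresponds to daily games over a human-like gestation
period, `tau0 = 730` to a two-year gestation-plus-care interval.

## Numerical and design choices

- Role assignment is per-agent Bernoulli(k/n), not a fixed-count draw: this
  is what generates the matching edge cases, and it preserves the expected
  return `kR/n`.
- Endowment draws are floored at 0 (a >10-sigma event at the default noise;
  a safety contract only). All payoffs are real-valued; nothing is rounded.
- Per-purpose RNG streams (roles, games, lifespans, births, mutation,
  dispersal, fission) derive from one base seed via hashed labels, so
  changing snapshot cadence or logging cannot perturb the dynamics and every
  run is reproducible from its manifest.
- "Evolved mean offer" is the population mean offer averaged over the final
  10% of snapshots (snapshots default to every tau0 steps); reported group
  statistics are time averages over snapshots, and mean IBIs use completed
  intervals only.
- The initial population is a synchronized cohort (all age 0); early-run
  dynamics show cohort waves that wash out after a few lifespans.
- Mutation excludes the parent strategy; with ten alternatives, an all-`p=0`
  population under mutation alone floats at a mean offer of about
  `r/2 * 0.55`, the mutation–selection floor visible in unstructured runs.

## Scale choices

Desk-scale presets keep every mechanism and shrink only sizes: homogeneous
sweeps use 10,000 lifetimes per strategy (100,000 at full scale), and the
invasion suite uses N = 1000 in 100 groups of 10 with `tau0 = 30` over 100
mean lifespans (full scale: N = 10,000, 1000 groups, `tau0` 270/730, 1000
lifespans). At `tau0 = 30` the deficit penalty `c tau0` is 0.3 steps, and the
variance-reduction advantage of equitable offers is qualitatively identical.
Evolved mean offers at 100 lifespans are still early in the invasion
transient: take-off timing is highly stochastic, so desk runs under-state
the asymptotic offers and carry large replicate variance. The
structured-vs-unstructured contrast and the multi-dictator disadvantage are
already resolved at that horizon; separating the multi-recipient game
DG_1,3 from the one-to-one game DG_1,2 takes longer horizons (by ~400 mean
lifespans the full ordering — more recipients > one-to-one > more
dictators — is established).

## What the generated data does and does not show

All inputs are self-generated; there is no empirical calibration beyond the
parameter table above. Passing tests demonstrate the internal logic of the
model — variance reduction lowering deficit costs, and group-structured
assortment letting equitable strategies invade — not anything about human
generosity directly. Not modeled (by design): resource-based survival,
partial resource carryover, reciprocity, punishment, partner choice,
between-group games, and heterogeneous-strategy variance analytics (not
analytically tractable; the ABM covers that regime numerically).
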
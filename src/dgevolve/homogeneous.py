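"""The simple agent model: one offer strategy played against itself.

Each of ``n_agents`` independent lifetimes accumulates resources by playing a
DG_{k,n} every step against a notional homogeneous population of the same
strategy: the agent's role is drawn Bernoulli(k/n) each step and its payoff is
sampled mean-field (no explicit partner matching) — a dictator keeps
``(1-p) R_i`` with its own noisy endowment, a recipient receives
``p * (sum of k independent endowments) / (n-k)``.  This preserves the
expected return ``kR/n`` and the closed-form role variance while adding the
endowment noise.  Offspring are counted, not instantiated: the model exists
to measure the relative fitness of offer strategies played against
themselves, from which the per-strategy fitness and interbirth-interval
tables are built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import OFFER_GRID, GameSpec
from .reproduction import DeficitParams, ReproductionParams, draw_lifespan

__all__ = [
    "StrategyOutcome",
    "RelativeFitnessTable",
    "run_homogeneous",
    "run_strategy_sweep",
    "relative_fitness",
]


@dataclass
class StrategyOutcome:
    """Lifetime reproduction record of one strategy's homogeneous cohort."""

    offer: float
    offspring_counts: np.ndarray
    ibi_lengths: np.ndarray
    n_agents: int

    @property
    def mean_offspring(self) -> float:
        return float(np.mean(self.offspring_counts))

    @property
    def mean_ibi(self) -> float:
        if self.ibi_lengths.size == 0:
            return float("nan")
        return float(np.mean(self.ibi_lengths))


@dataclass
class RelativeFitnessTable:
    """Per-strategy relative fitness and relative IBI, grand-mean normalized."""

    game: GameSpec
    table: pd.DataFrame  # columns: p, mean_offspring, rel_fitness, mean_ibi, rel_ibi


def run_homogeneous(
    offer: float,
    spec: GameSpec,
    repro: ReproductionParams,
    deficit: DeficitParams,
    n_agents: int,
    rng: np.random.Generator,
) -> StrategyOutcome:
    """Simulate ``n_agents`` full lifetimes of one offer strategy.

    All lifetimes advance in lockstep; an agent leaves the loop when its age
    reaches its individually drawn lifespan (the only removal mechanism).
    Within each step the order is: payoff, clock increment, deficit check,
    birth check, aging.
    """
    if n_agents < 1:
        raise ValueError(f"n_agents must be >= 1, got {n_agents}")
    if not 0.0 <= offer <= 1.0:
        raise ValueError(f"offer must lie in [0, 1], got {offer}")

    k, n = spec.k, spec.n
    r_base, sd = spec.base_endowment, spec.endowment_sd
    mu = spec.expected_return
    i_o = repro.offspring_cost
    gamma, c_tau0 = deficit.cutoff, deficit.time_cost * repro.tau0

    x = np.zeros(n_agents)
    clock = np.zeros(n_agents, dtype=np.int64)
    tau = np.full(n_agents, float(repro.tau0))
    births = np.zeros(n_agents, dtype=np.int64)
    age = np.zeros(n_agents, dtype=np.int64)
    lifespan = draw_lifespan(repro, rng, size=n_agents)
    ibis: list[np.ndarray] = []

    alive = np.arange(n_agents)
    while alive.size:
        m = alive.size
        is_dict = rng.random(m) < spec.dictator_prob
        n_dict = int(is_dict.sum())
        n_rec = m - n_dict
        pay = np.empty(m)
        if sd > 0:
            pay[is_dict] = (1.0 - offer) * np.maximum(
                rng.normal(r_base, sd, n_dict), 0.0
            )
            pooled = np.maximum(rng.normal(r_base, sd, (n_rec, k)), 0.0).sum(axis=1)
        else:
            pay[is_dict] = (1.0 - offer) * r_base
            pooled = np.full(n_rec, k * r_base)
        pay[~is_dict] = offer * pooled / spec.n_recipients

        x[alive] += pay
        clock[alive] += 1
        in_deficit = x[alive] < gamma * clock[alive] * mu
        tau[alive[in_deficit]] += c_tau0

        born = (x[alive] >= i_o) & (clock[alive] >= tau[alive])
        b_idx = alive[born]
        if b_idx.size:
            ibis.append(clock[b_idx].astype(np.int64))
            births[b_idx] += 1
            x[b_idx] -= i_o
            clock[b_idx] = 0
            tau[b_idx] = repro.tau0

        age[alive] += 1
        alive = alive[age[alive] < lifespan[alive]]

    all_ibis = np.concatenate(ibis) if ibis else np.empty(0, dtype=np.int64)
    return StrategyOutcome(
        offer=float(offer),
        offspring_counts=births,
        ibi_lengths=all_ibis,
        n_agents=n_agents,
    )


def run_strategy_sweep(
    spec: GameSpec,
    repro: ReproductionParams,
    deficit: DeficitParams,
    n_agents: int,
    seed: int,
    offers: np.ndarray = OFFER_GRID,
) -> list[StrategyOutcome]:
    """Run :func:`run_homogeneous` for each offer with an independent stream."""
    from .io_config import make_rng

    outcomes = []
    for p in offers:
        rng = make_rng(seed, f"homog/{spec.label()}/p={float(p):.1f}")
        outcomes.append(run_homogeneous(float(p), spec, repro, deficit, n_agents, rng))
    return outcomes


def relative_fitness(
    outcomes: list[StrategyOutcome], game: GameSpec
) -> RelativeFitnessTable:
    """Normalize per-strategy means by their grand mean across the 11 strategies.

    Relative fitness is a strategy's mean lifetime offspring divided by the
    mean of the 11 strategy means; relative IBI is defined analogously from
    realized interbirth intervals.  A grand mean of zero offspring signals a
    degenerate run and raises.
    """
    if len(outcomes) != len(OFFER_GRID):
        raise ValueError(f"expected {len(OFFER_GRID)} strategy outcomes, got {len(outcomes)}")
    mean_off = np.array([o.mean_offspring for o in outcomes])
    grand = mean_off.mean()
    if grand == 0:
        raise ValueError("grand mean of offspring is zero; degenerate run")
    mean_ibi = np.array([o.mean_ibi for o in outcomes])
    grand_ibi = np.nanmean(mean_ibi)
    table = pd.DataFrame(
        {
            "p": [o.offer for o in outcomes],
            "mean_offspring": mean_off,
            "rel_fitness": mean_off / grand,
            "mean_ibi": mean_ibi,
            "rel_ibi": mean_ibi / grand_ibi,
            "n_agents": [o.n_agents for o in outcomes],
        }
    )
    return RelativeFitnessTable(game=game, table=table)
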
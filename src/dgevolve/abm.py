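"""Group-structured evolutionary agent-based model.

A population of at most ``N`` agents lives in groups placed on a toroidal
grid (or in one unstructured pool).  Each time step: every group plays a
DG_{k,n} round internally; clocks, deficits and interbirth intervals are
updated; birth-eligible agents reproduce in randomized order under a
Moran-like cap (a newborn enters only while the population is below ``N``,
otherwise it dies, though the parent still pays the offspring cost);
offspring inherit the parent's offer strategy, mutating at rate ``r`` to one
of the ten other grid strategies and dispersing at rate ``d`` to another
randomly selected group; agents age and are removed when their lifespan
expires (the sole removal mechanism); groups that reach the fission
threshold split into two roughly equal halves, the daughter group taking a
free grid cell; empty groups are deleted.

Group structure creates assortment: generous strategies cluster with their
own descendants, so the group-level advantage of low resource variance (fewer
deficit-lengthened interbirth intervals) can overcome the within-group cost
of giving resources away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import OFFER_GRID, GameSpec, assign_roles, play_round
from .io_config import PopulationConfig, RngFactory
from .reproduction import DeficitParams, ReproductionParams, draw_lifespan

__all__ = [
    "Population",
    "PopulationSnapshot",
    "RunResult",
    "init_population",
    "mutate_strategy",
    "step",
    "run_simulation",
]

logger = logging.getLogger(__name__)

_N_STRATEGIES = len(OFFER_GRID)


def mutate_strategy(parent_offer: float, rate: float, rng: np.random.Generator) -> float:
    """Offspring offer: the parent's, or (w.p. ``rate``) one of the 10 others.

    The mutation target is uniform over the grid strategies *excluding* the
    parent's own.
    """
    idx = int(np.round(parent_offer * 10))
    if not 0 <= idx < _N_STRATEGIES or abs(OFFER_GRID[idx] - parent_offer) > 1e-9:
        raise ValueError(f"parent offer {parent_offer} is not on the 11-point grid")
    if rng.random() < rate:
        idx = (idx + 1 + int(rng.integers(_N_STRATEGIES - 1))) % _N_STRATEGIES
    return float(OFFER_GRID[idx])


@dataclass
class PopulationSnapshot:
    """Population summary at one time step."""

    t: int
    population: int
    mean_offer: float
    strategy_freqs: np.ndarray  # 11 values summing to 1
    n_groups: int
    mean_group_size: float
    mean_ibi: float  # completed intervals since the previous snapshot; NaN if none


@dataclass
class Population:
    """Array-of-agents state plus group bookkeeping."""

    capacity: int
    structured: bool
    alive: np.ndarray
    strategy: np.ndarray  # index into OFFER_GRID
    x: np.ndarray
    clock: np.ndarray
    tau: np.ndarray
    age: np.ndarray
    lifespan: np.ndarray
    group: np.ndarray
    group_cells: dict[int, tuple[int, int] | None]
    next_group: int
    t: int = 0
    interval_ibis: list[np.ndarray] = field(default_factory=list)
    all_ibis: list[np.ndarray] = field(default_factory=list)
    n_discarded: int = 0
    n_fissions: int = 0

    @property
    def size(self) -> int:
        return int(self.alive.sum())

    def offers(self) -> np.ndarray:
        """Offer fraction of every slot (valid where alive)."""
        return OFFER_GRID[self.strategy]

    def snapshot(self) -> PopulationSnapshot:
        alive_idx = np.flatnonzero(self.alive)
        pop = alive_idx.size
        freqs = np.bincount(self.strategy[alive_idx], minlength=_N_STRATEGIES) / max(pop, 1)
        if self.structured:
            n_groups = len(self.group_cells)
        else:
            n_groups = 1 if pop else 0
        ibis = np.concatenate(self.interval_ibis) if self.interval_ibis else np.empty(0)
        self.interval_ibis = []
        return PopulationSnapshot(
            t=self.t,
            population=pop,
            mean_offer=float(OFFER_GRID[self.strategy[alive_idx]].mean()) if pop else float("nan"),
            strategy_freqs=freqs,
            n_groups=n_groups,
            mean_group_size=pop / n_groups if n_groups else float("nan"),
            mean_ibi=float(ibis.mean()) if ibis.size else float("nan"),
        )


def init_population(
    config: PopulationConfig,
    spec: GameSpec,
    repro: ReproductionParams,
    rngs: dict[str, np.random.Generator],
) -> Population:
    """All-non-generous starting population (every agent plays p = 0).

    Structured: ``n_initial_groups`` groups of ``initial_group_size`` agents
    placed in distinct random cells of the toroidal grid.  Unstructured: one
    implicit global pool.  Agents start with no resources, a fresh clock,
    the optimal IBI, age 0 and individually drawn lifespans.
    """
    n0 = config.initial_population
    cap = config.max_population
    alive = np.zeros(cap, dtype=bool)
    alive[:n0] = True
    group = np.zeros(cap, dtype=np.int64)
    if config.structured:
        n_cells = config.grid_shape[0] * config.grid_shape[1]
        flat = rngs["fission"].choice(n_cells, size=config.n_initial_groups, replace=False)
        group_cells: dict[int, tuple[int, int] | None] = {
            g: (int(c // config.grid_shape[1]), int(c % config.grid_shape[1]))
            for g, c in enumerate(flat)
        }
        group[:n0] = np.repeat(np.arange(config.n_initial_groups), config.initial_group_size)
        next_group = config.n_initial_groups
    else:
        group_cells = {0: None}
        next_group = 1
    return Population(
        capacity=cap,
        structured=config.structured,
        alive=alive,
        strategy=np.zeros(cap, dtype=np.int64),
        x=np.zeros(cap),
        clock=np.zeros(cap, dtype=np.int64),
        tau=np.full(cap, float(repro.tau0)),
        age=np.zeros(cap, dtype=np.int64),
        lifespan=_draw_lifespans(cap, repro, rngs["lifespans"]),
        group=group,
        group_cells=group_cells,
        next_group=next_group,
    )


def _draw_lifespans(m: int, repro: ReproductionParams, rng: np.random.Generator) -> np.ndarray:
    return draw_lifespan(repro, rng, size=m)


def _random_cell(
    pop: Population, config: PopulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """A random grid cell, preferring unoccupied ones (fallback: any cell)."""
    h, w = config.grid_shape
    occupied = {c for c in pop.group_cells.values() if c is not None}
    for _ in range(1000):
        cell = (int(rng.integers(h)), int(rng.integers(w)))
        if cell not in occupied:
            return cell
    return (int(rng.integers(h)), int(rng.integers(w)))


def step(
    pop: Population,
    config: PopulationConfig,
    spec: GameSpec,
    repro: ReproductionParams,
    deficit: DeficitParams,
    rngs: dict[str, np.random.Generator],
) -> dict[str, int]:
    """Advance the population one time step; returns event counts.

    Within-step order: games -> clock/deficit update -> births (randomized
    order, Moran cap) -> aging and death -> fission -> empty-group removal.
    """
    alive_idx = np.flatnonzero(pop.alive)
    if alive_idx.size == 0:
        pop.t += 1
        return {"births": 0, "discarded": 0, "deaths": 0, "fissions": 0}
    offers = pop.offers()

    # --- (1) games, within each group (or the whole pool)
    if pop.structured:
        order = np.argsort(pop.group[alive_idx], kind="stable")
        sorted_idx = alive_idx[order]
        gs = pop.group[sorted_idx]
        bounds = np.flatnonzero(np.diff(gs)) + 1
        blocks = np.split(sorted_idx, bounds)
    else:
        blocks = [alive_idx]
    rng_roles, rng_games = rngs["roles"], rngs["games"]
    for members in blocks:
        ids = [int(i) for i in members]
        roles = assign_roles(ids, spec, rng_roles)
        strategies = {i: offers[i] for i in roles.dictators}
        delta = play_round(roles, strategies, spec, rng_games)
        for aid, dv in delta.items():
            pop.x[aid] += dv

    # --- (2) clock increment and deficit rule
    pop.clock[alive_idx] += 1
    xa = pop.x[alive_idx]
    clocks = pop.clock[alive_idx]
    in_def = xa < deficit.cutoff * clocks * spec.expected_return
    pop.tau[alive_idx[in_def]] += deficit.time_cost * repro.tau0

    # --- (3) births in randomized order under the Moran cap
    eligible = alive_idx[(xa >= repro.offspring_cost) & (clocks >= pop.tau[alive_idx])]
    n_births = int(eligible.size)
    n_enter = 0
    if n_births:
        rng_b = rngs["births"]
        eligible = eligible[rng_b.permutation(n_births)]
        space = config.max_population - alive_idx.size
        parents_in = eligible[: max(space, 0)]
        n_enter = int(parents_in.size)
        pop.n_discarded += n_births - n_enter

        born_ibis = pop.clock[eligible].copy()
        pop.interval_ibis.append(born_ibis)
        pop.all_ibis.append(born_ibis)
        pop.x[eligible] -= repro.offspring_cost
        pop.clock[eligible] = 0
        pop.tau[eligible] = repro.tau0

        if n_enter:
            child_strat = pop.strategy[parents_in].copy()
            rng_m = rngs["mutation"]
            mut = rng_m.random(n_enter) < config.mutation_rate
            n_mut = int(mut.sum())
            if n_mut:
                shift = 1 + rng_m.integers(0, _N_STRATEGIES - 1, size=n_mut)
                child_strat[mut] = (child_strat[mut] + shift) % _N_STRATEGIES
            child_group = pop.group[parents_in].copy()
            if pop.structured:
                gids = np.fromiter(sorted(pop.group_cells), dtype=np.int64)
                if gids.size > 1:
                    rng_d = rngs["dispersal"]
                    disp = rng_d.random(n_enter) < config.dispersal_rate
                    n_disp = int(disp.sum())
                    if n_disp:
                        natal_pos = np.searchsorted(gids, child_group[disp])
                        pick = rng_d.integers(0, gids.size - 1, size=n_disp)
                        pick = pick + (pick >= natal_pos)
                        child_group[disp] = gids[pick]
            slots = np.flatnonzero(~pop.alive)[:n_enter]
            pop.alive[slots] = True
            pop.strategy[slots] = child_strat
            pop.x[slots] = 0.0
            pop.clock[slots] = 0
            pop.tau[slots] = repro.tau0
            pop.age[slots] = 0
            pop.group[slots] = child_group
            pop.lifespan[slots] = _draw_lifespans(n_enter, repro, rngs["lifespans"])

    # --- (4) aging and lifespan expiry (agents alive at step start only)
    pop.age[alive_idx] += 1
    dead = alive_idx[pop.age[alive_idx] >= pop.lifespan[alive_idx]]
    pop.alive[dead] = False

    # --- (5) fission of groups at the threshold
    n_fissions = 0
    if pop.structured:
        rng_f = rngs["fission"]
        while True:
            counts = np.bincount(pop.group[pop.alive], minlength=pop.next_group)
            big = np.flatnonzero(counts >= config.max_group_size)
            if big.size == 0:
                break
            for gid in big:
                members = np.flatnonzero(pop.alive & (pop.group == gid))
                members = members[rng_f.permutation(members.size)]
                movers = members[: members.size // 2]
                new_gid = pop.next_group
                pop.next_group += 1
                pop.group[movers] = new_gid
                pop.group_cells[new_gid] = _random_cell(pop, config, rng_f)
                n_fissions += 1
        # --- (6) empty-group removal
        counts = np.bincount(pop.group[pop.alive], minlength=pop.next_group)
        for gid in [g for g in pop.group_cells if counts[g] == 0]:
            del pop.group_cells[gid]
        if n_fissions and logger.isEnabledFor(logging.DEBUG):
            logger.debug("t=%d: %d fission(s), %d groups", pop.t, n_fissions, len(pop.group_cells))
    pop.n_fissions += n_fissions

    pop.t += 1
    return {
        "births": n_births,
        "discarded": n_births - n_enter,
        "deaths": int(dead.size),
        "fissions": n_fissions,
    }


@dataclass
class RunResult:
    """Snapshot time series and end-of-run summary of one simulation."""

    snapshots: pd.DataFrame
    summary: dict


def run_simulation(
    config: PopulationConfig,
    spec: GameSpec,
    repro: ReproductionParams,
    deficit: DeficitParams,
    seed: int,
    sim_length: int | None = None,
    snapshot_every: int | None = None,
) -> RunResult:
    """Run the evolutionary model for ``sim_length`` steps from an all-p=0 start.

    Defaults: ``sim_length = 1000 * mean lifespan`` (about 1000 generations)
    and one snapshot every ``tau0`` steps.  The "evolved mean offer" in the
    summary is the mean offer averaged over the final 10% of snapshots.
    """
    if sim_length is None:
        sim_length = config.sim_length
    if sim_length is None:
        sim_length = int(round(repro.mean_lifespan * 1000))
    if snapshot_every is None:
        snapshot_every = config.snapshot_every
    if snapshot_every is None:
        snapshot_every = max(int(repro.tau0), 1)

    factory = RngFactory(seed)
    rngs = {
        label: factory.stream(label)
        for label in ("roles", "games", "lifespans", "births", "mutation", "dispersal", "fission")
    }
    pop = init_population(config, spec, repro, rngs)
    snaps: list[PopulationSnapshot] = []
    for t in range(1, sim_length + 1):
        step(pop, config, spec, repro, deficit, rngs)
        if t % snapshot_every == 0 or t == sim_length:
            snaps.append(pop.snapshot())

    frame = pd.DataFrame(
        {
            "t": [s.t for s in snaps],
            "population": [s.population for s in snaps],
            "mean_offer": [s.mean_offer for s in snaps],
            "n_groups": [s.n_groups for s in snaps],
            "mean_group_size": [s.mean_group_size for s in snaps],
            "mean_ibi": [s.mean_ibi for s in snaps],
            **{
                f"freq_p{OFFER_GRID[i]:.1f}": [s.strategy_freqs[i] for s in snaps]
                for i in range(_N_STRATEGIES)
            },
        }
    )
    tail = max(1, int(np.ceil(0.1 * len(snaps))))
    all_ibis = np.concatenate(pop.all_ibis) if pop.all_ibis else np.empty(0)
    summary = {
        "seed": seed,
        "game": spec.label(),
        "structured": config.structured,
        "sim_length": sim_length,
        "evolved_mean_offer": float(np.nanmean(frame["mean_offer"].iloc[-tail:])),
        "final_population": int(frame["population"].iloc[-1]),
        "time_avg_n_groups": float(frame["n_groups"].mean()),
        "time_avg_group_size": float(np.nanmean(frame["mean_group_size"])),
        "mean_ibi": float(all_ibis.mean()) if all_ibis.size else float("nan"),
        "n_fissions": pop.n_fissions,
        "n_discarded_offspring": pop.n_discarded,
    }
    return RunResult(snapshots=frame, summary=summary)
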
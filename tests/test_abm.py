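"""Group-structured evolutionary model: invariants, edge cases, determinism."""

import numpy as np
import pytest

from dgevolve import DeficitParams, GameSpec, ReproductionParams, mutate_strategy
from dgevolve.abm import init_population, run_simulation, step
from dgevolve.io_config import PopulationConfig, RngFactory


def _rngs(seed=0):
    factory = RngFactory(seed)
    return {
        label: factory.stream(label)
        for label in ("roles", "games", "lifespans", "births", "mutation", "dispersal", "fission")
    }


@pytest.fixture
def tiny_setup():
    spec = GameSpec(k=1, n=2)
    repro = ReproductionParams.from_tau0(10, spec)
    deficit = DeficitParams(time_cost=0.01, cutoff=0.9)
    config = PopulationConfig(
        max_population=200,
        n_initial_groups=20,
        initial_group_size=10,
        grid_shape=(10, 10),
        sim_length=200,
        snapshot_every=10,
    )
    return spec, repro, deficit, config


def test_init_population(tiny_setup):
    spec, repro, _, config = tiny_setup
    pop = init_population(config, spec, repro, _rngs(1))
    assert pop.size == 200
    assert len(pop.group_cells) == 20
    # distinct cells, all offers 0, fresh clocks
    cells = list(pop.group_cells.values())
    assert len(set(cells)) == len(cells)
    alive = np.flatnonzero(pop.alive)
    assert np.all(pop.strategy[alive] == 0)
    assert np.all(pop.x[alive] == 0)
    assert np.all(pop.age[alive] == 0)
    assert np.all(pop.lifespan[alive] >= 1)


def test_init_population_deterministic(tiny_setup):
    spec, repro, _, config = tiny_setup
    a = init_population(config, spec, repro, _rngs(3))
    b = init_population(config, spec, repro, _rngs(3))
    assert np.array_equal(a.lifespan, b.lifespan)
    assert a.group_cells == b.group_cells


def test_init_unstructured(tiny_setup):
    spec, repro, _, _ = tiny_setup
    config = PopulationConfig(max_population=150, structured=False)
    pop = init_population(config, spec, repro, _rngs(0))
    assert pop.size == 150
    assert not pop.structured


def test_too_many_groups_for_grid():
    with pytest.raises(Exception):
        PopulationConfig(
            max_population=1000, n_initial_groups=200, initial_group_size=1, grid_shape=(10, 10)
        )


def test_mutate_strategy_contract(rng):
    assert mutate_strategy(0.3, 0.0, rng) == 0.3
    draws = {mutate_strategy(0.0, 1.0, rng) for _ in range(2000)}
    assert draws == {round(i / 10, 1) for i in range(1, 11)}  # never the parent
    counts = {}
    for _ in range(20_000):
        v = mutate_strategy(0.5, 1.0, rng)
        counts[v] = counts.get(v, 0) + 1
    freqs = np.array(list(counts.values())) / 20_000
    assert 0.5 not in counts
    assert np.all(np.abs(freqs - 0.1) < 0.02)
    with pytest.raises(ValueError):
        mutate_strategy(0.55, 0.1, rng)


def test_step_invariants_over_short_run(tiny_setup):
    spec, repro, deficit, config = tiny_setup
    rngs = _rngs(7)
    pop = init_population(config, spec, repro, rngs)
    for _ in range(120):
        step(pop, config, spec, repro, deficit, rngs)
        alive = np.flatnonzero(pop.alive)
        assert alive.size <= config.max_population
        # census identity: groups x mean size = population, sizes within bounds
        sizes = np.bincount(pop.group[alive], minlength=pop.next_group)
        sizes = sizes[sizes > 0]
        assert sizes.sum() == alive.size
        assert len(pop.group_cells) == len(sizes)
        assert sizes.max() <= config.max_group_size
        snap = pop.snapshot()
        assert snap.n_groups * snap.mean_group_size == pytest.approx(snap.population)
        assert snap.strategy_freqs.sum() == pytest.approx(1.0)
    assert pop.size > 0


def test_moran_cap_discards_offspring(tiny_setup):
    """At carrying capacity, births do not push the population above N."""
    spec, repro, deficit, config = tiny_setup
    rngs = _rngs(11)
    pop = init_population(config, spec, repro, rngs)
    events_total = 0
    for _ in range(60):
        ev = step(pop, config, spec, repro, deficit, rngs)
        events_total += ev["discarded"]
        assert pop.size <= config.max_population
    assert events_total > 0  # the cap actually bit during the run


def test_absorbing_state_without_mutation(tiny_setup):
    spec, repro, _, _ = tiny_setup
    config = PopulationConfig(
        max_population=100, structured=False, mutation_rate=0.0, dispersal_rate=0.0
    )
    deficit = DeficitParams(time_cost=0.0, cutoff=0.9)
    rngs = _rngs(2)
    pop = init_population(config, spec, repro, rngs)
    for _ in range(60):
        step(pop, config, spec, repro, deficit, rngs)
    alive = np.flatnonzero(pop.alive)
    assert np.all(pop.strategy[alive] == 0)


def test_fission_splits_group_at_threshold(tiny_setup):
    spec, repro, deficit, _ = tiny_setup
    config = PopulationConfig(
        max_population=40,
        n_initial_groups=2,
        initial_group_size=20,
        max_group_size=20,
        grid_shape=(5, 5),
    )
    rngs = _rngs(5)
    pop = init_population(config, spec, repro, rngs)
    cells_before = dict(pop.group_cells)
    step(pop, config, spec, repro, deficit, rngs)
    # both size-20 groups split into ~equal halves; parents keep their cells
    alive = np.flatnonzero(pop.alive)
    sizes = np.bincount(pop.group[alive], minlength=pop.next_group)
    occupied = sizes[sizes > 0]
    assert len(occupied) == 4
    assert set(occupied) <= {9, 10, 11}
    for gid, cell in cells_before.items():
        assert pop.group_cells[gid] == cell


def test_run_simulation_deterministic_and_snapshots(tiny_setup):
    spec, repro, deficit, config = tiny_setup
    a = run_simulation(config, spec, repro, deficit, seed=21)
    b = run_simulation(config, spec, repro, deficit, seed=21)
    assert a.snapshots.equals(b.snapshots)
    assert a.summary == b.summary
    c = run_simulation(config, spec, repro, deficit, seed=22)
    assert not a.snapshots.equals(c.snapshots)
    # snapshot cadence and bookkeeping
    assert list(a.snapshots["t"]) == list(range(10, 201, 10))
    assert (a.snapshots["population"] <= config.max_population).all()
    freq_cols = [c for c in a.snapshots.columns if c.startswith("freq_p")]
    assert len(freq_cols) == 11
    assert np.allclose(a.snapshots[freq_cols].sum(axis=1), 1.0)
    assert 0 <= a.summary["evolved_mean_offer"] <= 1
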
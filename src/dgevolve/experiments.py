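"""Reproducible experiment presets and orchestration.

A preset is a named grid of (game, tau0, c, gamma, group size, dispersal,
structure) cells with replicate counts and seed discipline.  Desk-scale
presets are the defaults and finish on a laptop; the ``-full`` presets carry
the full-scale study conditions (N = 10,000 agents, 100,000 homogeneous
lifetimes, simulations of 1000 mean lifespans) and are multi-hour runs to be
requested explicitly.  Every run writes a tidy long-format CSV plus a JSON
manifest recording each cell's configuration and seed, from which the run
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import run_simulation
from .analytic import CANONICAL_GAMES, cv_table
from .game import GameSpec
from .homogeneous import relative_fitness, run_strategy_sweep
from .io_config import PopulationConfig, RunManifest
from .reproduction import DeficitParams, ReproductionParams

__all__ = [
    "ExperimentCell",
    "ExperimentPreset",
    "PRESETS",
    "get_preset",
    "run_preset",
    "summarize",
]


@dataclass(frozen=True)
class ExperimentCell:
    """One condition: a game shape plus the varied model parameters."""

    k: int
    n: int
    tau0: float = 270
    time_cost: float = 0.01
    cutoff: float = 0.9
    structured: bool = True
    max_group_size: int = 20
    dispersal_rate: float = 0.01


@dataclass(frozen=True)
class ExperimentPreset:
    """A named grid of cells with replicate counts and scale parameters."""

    name: str
    kind: str  # "analytic" | "homogeneous" | "abm"
    cells: tuple[ExperimentCell, ...]
    replicates: int = 3
    n_agents: int = 10_000  # homogeneous cohort size per strategy
    max_population: int = 1000  # abm population cap
    n_initial_groups: int = 100
    initial_group_size: int = 10
    lifespan_multiples: int = 100  # abm sim_length = mean lifespan x this
    base_seed: int = 0
    description: str = ""

    def cell_seed(self, cell_index: int, replicate: int) -> int:
        """Deterministic per-(cell, replicate) seed below 2**31."""
        ss = np.random.SeedSequence([self.base_seed, cell_index, replicate])
        return int(ss.generate_state(1)[0] >> 1)


def _abm_cells(games, tau0s, structures, sizes=(20,), dispersals=(0.01,), c=0.01, gamma=0.9):
    return tuple(
        ExperimentCell(
            k=k, n=n, tau0=t, time_cost=c, cutoff=gamma,
            structured=s, max_group_size=g, dispersal_rate=d,
        )
        for t in tau0s for s in structures for g in sizes for d in dispersals
        for (k, n) in games
    )


_DESK_GAMES = ((1, 3), (1, 2), (2, 3))

PRESETS: dict[str, ExperimentPreset] = {}


def _register(p: ExperimentPreset) -> None:
    PRESETS[p.name] = p


_register(
    ExperimentPreset(
        name="cv-table",
        kind="analytic",
        cells=tuple(ExperimentCell(k=k, n=n, tau0=t) for (k, n) in CANONICAL_GAMES for t in (270, 730)),
        replicates=1,
        description="Coefficient-of-variation table: 5 games x 11 offers x tau0 in {270, 730}.",
    )
)
_register(
    ExperimentPreset(
        name="fitness-sweep-desk",
        kind="homogeneous",
        cells=tuple(ExperimentCell(k=k, n=n, tau0=270) for (k, n) in CANONICAL_GAMES),
        replicates=1,
        n_agents=10_000,
        description="Relative fitness/IBI of the 11 offers, 5 games, 10,000 lifetimes each.",
    )
)
_register(
    ExperimentPreset(
        name="fitness-sweep-full",
        kind="homogeneous",
        cells=tuple(
            ExperimentCell(k=k, n=n, tau0=t) for t in (270, 730) for (k, n) in CANONICAL_GAMES
        ),
        replicates=1,
        n_agents=100_000,
        description="Full-scale relative fitness sweep (100,000 lifetimes per strategy).",
    )
)
_register(
    ExperimentPreset(
        name="invasion-desk",
        kind="abm",
        cells=_abm_cells(_DESK_GAMES, tau0s=(30,), structures=(True, False)),
        replicates=3,
        max_population=1000,
        n_initial_groups=100,
        lifespan_multiples=100,
        description=(
            "Scaled-down invasion contrast: structured vs unstructured populations, "
            "N=1000, tau0=30, 100 lifespans."
        ),
    )
)
_register(
    ExperimentPreset(
        name="invasion-full",
        kind="abm",
        cells=_abm_cells(CANONICAL_GAMES, tau0s=(270, 730), structures=(True, False)),
        replicates=5,
        max_population=10_000,
        n_initial_groups=1000,
        lifespan_multiples=1000,
        description="Full-scale invasion analysis (multi-hour; explicit opt-in).",
    )
)
_register(
    ExperimentPreset(
        name="groupsize-desk",
        kind="abm",
        cells=_abm_cells(
            ((1, 3), (2, 3)), tau0s=(30,), structures=(True,),
            sizes=(20, 80), dispersals=(0.01, 0.05),
        ),
        replicates=2,
        max_population=1000,
        n_initial_groups=100,
        lifespan_multiples=100,
        description="Scaled-down group-size x dispersal grid.",
    )
)
_register(
    ExperimentPreset(
        name="groupsize-full",
        kind="abm",
        cells=_abm_cells(
            CANONICAL_GAMES, tau0s=(270,), structures=(True,),
            sizes=(20, 40, 80), dispersals=(0.01, 0.02, 0.03, 0.04, 0.05),
        ),
        replicates=5,
        max_population=10_000,
        n_initial_groups=1000,
        lifespan_multiples=1000,
        description="Full-scale group-size (20/40/80) x dispersal (0.01..0.05) grid.",
    )
)
_register(
    ExperimentPreset(
        name="sensitivity-desk",
        kind="abm",
        cells=tuple(
            ExperimentCell(k=2, n=3, tau0=30, time_cost=c, cutoff=g)
            for g in (0.9, 0.85, 0.8) for c in (0.01, 0.005)
        ),
        replicates=2,
        max_population=1000,
        n_initial_groups=100,
        lifespan_multiples=100,
        description="Scaled-down deficit-cutoff and time-cost sensitivity sweep (DG_2,3).",
    )
)
_register(
    ExperimentPreset(
        name="sensitivity-full",
        kind="abm",
        cells=tuple(
            ExperimentCell(k=2, n=3, tau0=270, time_cost=c, cutoff=g)
            for g in (0.9, 0.85, 0.8) for c in (0.01, 0.005)
        ),
        replicates=5,
        max_population=10_000,
        n_initial_groups=1000,
        lifespan_multiples=1000,
        description="Full-scale deficit sensitivity sweep (multi-hour; explicit opt-in).",
    )
)


def get_preset(name: str, base_seed: int | None = None, scale: float = 1.0) -> ExperimentPreset:
    """Look up a preset, optionally re-seeding and rescaling it."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    preset = PRESETS[name]
    changes: dict = {}
    if base_seed is not None:
        changes["base_seed"] = int(base_seed)
    if scale != 1.0:
        changes.update(
            n_agents=max(1, round(preset.n_agents * scale)),
            max_population=max(1, round(preset.max_population * scale)),
            n_initial_groups=max(1, round(preset.n_initial_groups * scale)),
            lifespan_multiples=max(1, round(preset.lifespan_multiples * scale)),
        )
    return dataclasses.replace(preset, **changes) if changes else preset


def _run_cell(preset: ExperimentPreset, ci: int, cell: ExperimentCell) -> list[dict]:
    spec = GameSpec(k=cell.k, n=cell.n)
    repro = ReproductionParams.from_tau0(cell.tau0, spec)
    deficit = DeficitParams(time_cost=cell.time_cost, cutoff=cell.cutoff)
    rows: list[dict] = []
    base = dict(dataclasses.asdict(cell), game=spec.label(), cell=ci)

    if preset.kind == "analytic":
        frame = cv_table(games=((cell.k, cell.n),), horizons=(cell.tau0,))
        for rec in frame.to_dict("records"):
            rows.append({**base, **rec, "replicate": 0, "seed": None})
    elif preset.kind == "homogeneous":
        seed = preset.cell_seed(ci, 0)
        outcomes = run_strategy_sweep(spec, repro, deficit, preset.n_agents, seed)
        table = relative_fitness(outcomes, spec).table
        for rec in table.to_dict("records"):
            rows.append({**base, **rec, "replicate": 0, "seed": seed})
    elif preset.kind == "abm":
        config = PopulationConfig(
            max_population=preset.max_population,
            n_initial_groups=preset.n_initial_groups,
            initial_group_size=preset.initial_group_size,
            max_group_size=cell.max_group_size,
            dispersal_rate=cell.dispersal_rate,
            structured=cell.structured,
            sim_length=int(round(repro.mean_lifespan * preset.lifespan_multiples)),
        )
        for rep in range(preset.replicates):
            seed = preset.cell_seed(ci, rep)
            result = run_simulation(config, spec, repro, deficit, seed=seed)
            rows.append({**base, "replicate": rep, "seed": seed, **result.summary})
    else:
        raise ValueError(f"unknown preset kind {preset.kind!r}")
    return rows


def run_preset(preset: ExperimentPreset | str, out_dir: str | Path | None = None) -> dict:
    """Execute every cell x replicate of a preset with independent seeds.

    Returns a bundle ``{"preset", "results": DataFrame, "errors": {...}}``;
    failures are recorded per cell and the run continues.  When ``out_dir``
    is given, writes ``results.csv`` and ``manifest.json`` there.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rows: list[dict] = []
    errors: dict[int, str] = {}
    for ci, cell in enumerate(preset.cells):
        try:
            rows.extend(_run_cell(preset, ci, cell))
        except Exception as exc:  # noqa: BLE001 — partial failure is recorded
            errors[ci] = f"{type(exc).__name__}: {exc}"
    results = pd.DataFrame(rows)
    bundle = {"preset": preset, "results": results, "errors": errors}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "results.csv"
        results.to_csv(csv_path, index=False)
        manifest = RunManifest(
            config={
                "preset": dataclasses.asdict(preset),
                "errors": errors,
            },
            seeds=[
                preset.cell_seed(ci, rep)
                for ci in range(len(preset.cells))
                for rep in range(preset.replicates)
            ],
        )
        manifest.register_output(csv_path)
        manifest.write(out_dir / "manifest.json")
        bundle["out_dir"] = str(out_dir)
    return bundle


def summarize(bundle: dict) -> dict:
    """Per-cell aggregates and ordering checks as a machine-readable report.

    For simulation presets this reports each cell's evolved mean offer
    (mean and sd over replicates) and checks the two qualitative orderings:
    structured above unstructured at matched parameters, and multi-recipient
    games above the one-dictator-one-recipient game above multi-dictator
    games among structured cells.
    """
    results: pd.DataFrame = bundle["results"]
    if results.empty:
        raise ValueError("empty result bundle")
    preset: ExperimentPreset = bundle["preset"]
    report: dict = {"preset": preset.name, "kind": preset.kind, "n_rows": int(len(results))}
    if preset.kind != "abm":
        return report

    agg = (
        results.groupby(
            ["cell", "game", "k", "n", "tau0", "structured", "max_group_size", "dispersal_rate"],
            as_index=False,
        )
        .agg(mean_evolved_offer=("evolved_mean_offer", "mean"),
             sd_evolved_offer=("evolved_mean_offer", "std"),
             replicates=("evolved_mean_offer", "size"))
    )
    report["cells"] = agg.to_dict("records")

    match_keys = ["game", "tau0", "max_group_size", "dispersal_rate"]
    s = agg[agg["structured"]].set_index(match_keys)["mean_evolved_offer"]
    u = agg[~agg["structured"]].set_index(match_keys)["mean_evolved_offer"]
    common = s.index.intersection(u.index)
    if len(common):
        report["structured_gt_unstructured"] = {
            str(idx): bool(s[idx] > u[idx]) for idx in common
        }
        report["structured_gt_unstructured_all"] = bool(all(s[i] > u[i] for i in common))

    struct = agg[agg["structured"]]
    if len(struct):
        def _class(row):
            if row["n"] - row["k"] > 1:
                return "multi_recipient"
            if row["k"] > 1:
                return "multi_dictator"
            return "single_pair"

        by_class = struct.assign(cls=struct.apply(_class, axis=1)).groupby("cls")[
            "mean_evolved_offer"
        ].mean()
        report["class_means"] = by_class.to_dict()
        if {"multi_recipient", "single_pair", "multi_dictator"} <= set(by_class.index):
            report["recipient_gt_pair_gt_dictator"] = bool(
                by_class["multi_recipient"] > by_class["single_pair"] > by_class["multi_dictator"]
            )
    return report
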
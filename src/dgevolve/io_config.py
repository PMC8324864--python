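"""Configuration, seeded RNG streams, and result serialization.

Every stochastic component draws from a labelled stream derived from one base
seed, so that e.g. changing snapshot cadence or adding logging cannot perturb
the dynamics, and any run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .game import GameSpec
from .reproduction import DeficitParams, ReproductionParams

__all__ = [
    "ConfigError",
    "PopulationConfig",
    "RunConfig",
    "RngFactory",
    "make_rng",
    "load_config",
    "serialize_config",
    "RunManifest",
]


class ConfigError(ValueError):
    """A configuration field violated its constraint."""


# ---------------------------------------------------------------------------
# RNG provisioning


def make_rng(seed: int, stream_label: str) -> np.random.Generator:
    """Independent reproducible generator for (seed, label).

    The label is hashed (CRC-32) into the seed sequence, so distinct labels
    give uncorrelated streams and the same pair always replays identically.
    """
    key = zlib.crc32(stream_label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


class RngFactory:
    """Hands out labelled RNG streams for one run; rejects duplicate labels."""

    def __init__(self, seed: int | None = None):
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        self.seed = int(seed)
        self._labels: set[str] = set()

    def stream(self, label: str) -> np.random.Generator:
        if label in self._labels:
            raise ValueError(f"duplicate RNG stream label {label!r}")
        self._labels.add(label)
        return make_rng(self.seed, label)


# ---------------------------------------------------------------------------
# Population / run configuration


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level knobs of the evolutionary agent-based model.

    Defaults are the full-scale study conditions: 10,000 agents in 1000
    groups of 10 on a 100 x 100 toroidal grid, fission threshold 20,
    mutation and dispersal at 0.01, and a simulation length of 1000 mean
    lifespans (set at run time from the reproduction parameters when left
    ``None``).
    """

    max_population: int = 10_000
    mutation_rate: float = 0.01
    dispersal_rate: float = 0.01
    max_group_size: int = 20
    grid_shape: tuple[int, int] = (100, 100)
    structured: bool = True
    n_initial_groups: int = 1000
    initial_group_size: int = 10
    sim_length: int | None = None
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.max_population < 1:
            raise ConfigError(f"max_population must be >= 1, got {self.max_population}")
        for name in ("mutation_rate", "dispersal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.max_group_size < 2:
            raise ConfigError(f"max_group_size must be >= 2, got {self.max_group_size}")
        if self.structured:
            cells = self.grid_shape[0] * self.grid_shape[1]
            if cells < self.n_initial_groups:
                raise ConfigError(
                    f"grid has {cells} cells but {self.n_initial_groups} initial groups"
                )
            if self.n_initial_groups < 1 or self.initial_group_size < 1:
                raise ConfigError("need at least one group of at least one agent")
            if self.n_initial_groups * self.initial_group_size > self.max_population:
                raise ConfigError("initial population exceeds max_population")

    @property
    def initial_population(self) -> int:
        if self.structured:
            return self.n_initial_groups * self.initial_group_size
        return self.max_population

    def scaled(self, scale: float) -> "PopulationConfig":
        """Shrink population, group count and simulation length jointly."""
        if scale <= 0:
            raise ConfigError(f"scale must be > 0, got {scale}")
        if scale == 1.0:
            return self
        return dataclasses.replace(
            self,
            max_population=max(1, round(self.max_population * scale)),
            n_initial_groups=max(1, round(self.n_initial_groups * scale)),
            sim_length=None if self.sim_length is None else max(1, round(self.sim_length * scale)),
        )


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration bundle for one simulation run."""

    game: GameSpec
    reproduction: ReproductionParams
    deficit: DeficitParams
    population: PopulationConfig
    seed: int = 0

    @property
    def sim_length(self) -> int:
        if self.population.sim_length is not None:
            return self.population.sim_length
        return int(round(self.reproduction.mean_lifespan * 1000))

    @property
    def snapshot_every(self) -> int:
        if self.population.snapshot_every is not None:
            return self.population.snapshot_every
        return int(self.reproduction.tau0)


_GAME_KEYS = {"k", "n", "mu", "endowment_sd"}
_REPRO_KEYS = {"tau0", "offspring_cost", "mean_lifespan", "lifespan_sd"}
_DEFICIT_KEYS = {"time_cost", "cutoff"}
_POP_KEYS = {f.name for f in dataclasses.fields(PopulationConfig)}


def _build(section: str, data: dict, allowed: set[str]) -> dict:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {section} field(s): {sorted(unknown)}")
    return dict(data)


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file, dict, or defaults.

    Unspecified fields take the standard study defaults (mu=5, sigma_R=0.1R,
    tau0=270, omega=3 tau0, sigma_omega=0.25 omega, r=d=0.01, gamma=0.9,
    c=0.01, N=10,000).  Violations raise :class:`ConfigError` naming the
    offending field.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, dict):
        data = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    unknown = set(data) - {"game", "reproduction", "deficit", "population", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")

    game_kw = _build("game", data.get("game", {}), _GAME_KEYS)
    game_kw.setdefault("k", 1)
    game_kw.setdefault("n", 2)
    try:
        game = GameSpec(**game_kw)
    except ValueError as exc:
        raise ConfigError(f"game: {exc}") from exc

    repro_kw = _build("reproduction", data.get("reproduction", {}), _REPRO_KEYS)
    tau0 = repro_kw.pop("tau0", 270)
    base = ReproductionParams.from_tau0(tau0, game)
    try:
        repro = dataclasses.replace(base, **repro_kw)
    except ValueError as exc:
        raise ConfigError(f"reproduction: {exc}") from exc

    deficit_kw = _build("deficit", data.get("deficit", {}), _DEFICIT_KEYS)
    try:
        deficit = DeficitParams(**deficit_kw)
    except ValueError as exc:
        raise ConfigError(f"deficit: {exc}") from exc

    pop_kw = _build("population", data.get("population", {}), _POP_KEYS)
    if "grid_shape" in pop_kw:
        pop_kw["grid_shape"] = tuple(pop_kw["grid_shape"])
    population = PopulationConfig(**pop_kw)

    return RunConfig(
        game=game,
        reproduction=repro,
        deficit=deficit,
        population=population,
        seed=int(data.get("seed", 0)),
    )


def serialize_config(config: RunConfig) -> dict:
    """Plain-dict form of a RunConfig; round-trips through :func:`load_config`."""
    return {
        "game": {
            "k": config.game.k,
            "n": config.game.n,
            "mu": config.game.mu,
            "endowment_sd": config.game.endowment_sd,
        },
        "reproduction": dataclasses.asdict(config.reproduction),
        "deficit": dataclasses.asdict(config.deficit),
        "population": {
            **dataclasses.asdict(config.population),
            "grid_shape": list(config.population.grid_shape),
        },
        "seed": config.seed,
    }


# ---------------------------------------------------------------------------
# Manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: resolved config, seeds, and output checksums."""

    config: dict
    seeds: list[int]
    version: str = "0.1.0"
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    outputs: dict[str, dict] = field(default_factory=dict)

    def register_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = {
            "sha256": _sha256(path),
            "bytes": path.stat().st_size,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))
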
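"""One time step of an n-person dictator game DG_{k,n}.

A DG_{k,n} has ``k`` dictators and ``n - k`` recipients.  Each time step every
participating agent is independently assigned the dictator role with
probability ``k/n``; each dictator receives a (noisy) endowment ``R_i`` and
gives away a fraction ``p`` of it, split evenly among ``n - k`` recipients
taken sequentially from a shuffled recipient list.  Because role assignment is
Bernoulli rather than a fixed-count draw, a round can by chance have no
dictators, no recipients, too few of either — the four edge cases handled by
:func:`play_round`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = [
    "OFFER_GRID",
    "GameSpec",
    "RoleAssignment",
    "assign_roles",
    "draw_endowment",
    "play_round",
]

#: The 11-point offer-strategy grid used throughout: {0.0, 0.1, ..., 1.0}.
OFFER_GRID: np.ndarray = np.round(np.arange(11) * 0.1, 1)
OFFER_GRID.setflags(write=False)


@dataclass(frozen=True)
class GameSpec:
    """Shape and endowment of a DG_{k,n}.

    Parameters
    ----------
    k : int
        Number of dictators per game, ``1 <= k < n``.
    n : int
        Total number of players per game.
    mu : float, default 5.0
        Expected per-agent per-step return.  The base endowment is tied to it
        by ``R = n * mu / k`` so that the expected return ``k R / n`` equals
        ``mu`` for every game shape.
    endowment_sd : float, optional
        Standard deviation of the per-dictator endowment noise.  Defaults to
        ``0.1 * R``; pass 0 for deterministic endowments.
    """

    k: int
    n: int
    mu: float = 5.0
    endowment_sd: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and isinstance(self.n, (int, np.integer))):
            raise ValueError("k and n must be integers")
        if not 1 <= self.k < self.n:
            raise ValueError(f"require 1 <= k < n, got k={self.k}, n={self.n}")
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.endowment_sd is None:
            object.__setattr__(self, "endowment_sd", 0.1 * self.base_endowment)
        elif self.endowment_sd < 0:
            raise ValueError(f"endowment_sd must be >= 0, got {self.endowment_sd}")

    @property
    def base_endowment(self) -> float:
        """Base endowment ``R = n * mu / k``."""
        return self.n * self.mu / self.k

    @property
    def n_recipients(self) -> int:
        """Recipients per game, ``n - k``."""
        return self.n - self.k

    @property
    def dictator_prob(self) -> float:
        """Per-agent probability of drawing the dictator role, ``k / n``."""
        return self.k / self.n

    @property
    def expected_return(self) -> float:
        """Expected per-agent per-step return ``k R / n`` (= mu)."""
        return self.k * self.base_endowment / self.n

    def label(self) -> str:
        return f"DG_{self.k},{self.n}"


@dataclass
class RoleAssignment:
    """Shuffled dictator and recipient lists for one round."""

    dictators: list[Hashable] = field(default_factory=list)
    recipients: list[Hashable] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.dictators) & set(self.recipients)
        if overlap:
            raise ValueError(f"agents in both roles: {sorted(overlap)!r}")


def assign_roles(
    agent_ids: Sequence[Hashable], spec: GameSpec, rng: np.random.Generator
) -> RoleAssignment:
    """Assign each agent the dictator role independently with probability k/n.

    Both resulting lists are independently shuffled, giving the randomized
    list order the matching procedure in :func:`play_round` relies on.
    """
    ids = list(agent_ids)
    if not ids:
        raise ValueError("agent_ids must be non-empty")
    mask = rng.random(len(ids)) < spec.dictator_prob
    dictators = [a for a, m in zip(ids, mask) if m]
    recipients = [a for a, m in zip(ids, mask) if not m]
    rng.shuffle(dictators)
    rng.shuffle(recipients)
    return RoleAssignment(dictators=dictators, recipients=recipients)


def draw_endowment(
    spec: GameSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw dictator endowment(s) ``R_i ~ Gaussian(R, sigma_R)``, floored at 0.

    At the default ``sigma_R = 0.1 R`` a negative draw is a >10-sigma event;
    the floor is a safety contract, not a distributional change.
    """
    if spec.endowment_sd == 0:
        if size is None:
            return spec.base_endowment
        return np.full(size, spec.base_endowment)
    draws = rng.normal(spec.base_endowment, spec.endowment_sd, size=size)
    return np.maximum(draws, 0.0)


def play_round(
    roles: RoleAssignment,
    strategies: Mapping[Hashable, float],
    spec: GameSpec,
    rng: np.random.Generator,
) -> dict[Hashable, float]:
    """Play one round; return the per-agent resource change.

    Each dictator ``i`` draws an endowment ``R_i``, keeps ``R_i (1 - p_i)``
    and gives ``p_i R_i / (n - k)`` to each of ``n - k`` recipients taken
    sequentially from the shuffled recipient list; when the list is exhausted
    it is freshly re-shuffled and traversal restarts.  Edge cases: with no
    dictators all deltas are 0; with no recipients each dictator keeps its
    full endowment; with too few dictators unplayed recipients get 0; with too
    few recipients some recipients are played more than once.
    """
    delta: dict[Hashable, float] = {a: 0.0 for a in roles.dictators}
    for a in roles.recipients:
        delta[a] = 0.0
    for a in roles.dictators:
        if a not in strategies:
            raise KeyError(f"no strategy for dictator {a!r}")

    if not roles.dictators:
        return delta

    if not roles.recipients:
        # no one to play: dictators keep all of their endowed resources
        for a in roles.dictators:
            delta[a] += float(draw_endowment(spec, rng))
        return delta

    queue = list(roles.recipients)
    pos = 0
    per_game = spec.n_recipients
    for a in roles.dictators:
        r_i = float(draw_endowment(spec, rng))
        p = strategies[a]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"offer for {a!r} outside [0, 1]: {p}")
        delta[a] += r_i * (1.0 - p)
        share = p * r_i / per_game
        for _ in range(per_game):
            if pos >= len(queue):
                rng.shuffle(queue)
                pos = 0
            delta[queue[pos]] += share
            pos += 1
    return delta
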
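"""Per-agent reproductive bookkeeping under interbirth-interval constraints.

An agent needs ``I_o`` resources and at least ``tau`` time steps since its own
birth (or its last birth) to produce an offspring.  The interbirth interval
``tau`` starts at the optimum ``tau0`` and lengthens by ``c * tau0`` on every
step the agent runs a resource deficit, i.e. whenever its accumulated
resources fall strictly below a fraction ``gamma`` of the expected
accumulation ``T * mu`` after ``T`` played steps.  ``tau`` resets to ``tau0``
only at birth events; deficit additions are unbounded, so a persistently
unlucky agent can carry ``tau`` beyond its own lifespan.

The scalar operations here accept numpy arrays transparently; the simulators
in :mod:`dgevolve.homogeneous` and :mod:`dgevolve.abm` apply them to whole
agent populations at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import GameSpec

__all__ = [
    "ReproductionParams",
    "DeficitParams",
    "AgentState",
    "expected_accumulation",
    "deficit_mask",
    "update_ibi",
    "check_birth",
    "apply_birth",
    "draw_lifespan",
]


@dataclass(frozen=True)
class ReproductionParams:
    """Reproductive constants: optimal IBI, offspring cost and lifespan law.

    Defaults follow ``offspring_cost = tau0 * mu``, ``mean_lifespan = 3 tau0``
    (so an agent can optimally reproduce about three times) and
    ``lifespan_sd = 0.25 * mean_lifespan``.
    """

    tau0: float
    offspring_cost: float
    mean_lifespan: float
    lifespan_sd: float

    def __post_init__(self) -> None:
        if self.tau0 < 1:
            raise ValueError(f"tau0 must be >= 1, got {self.tau0}")
        if self.offspring_cost <= 0:
            raise ValueError(f"offspring_cost must be > 0, got {self.offspring_cost}")
        if self.mean_lifespan <= 0 or self.lifespan_sd < 0:
            raise ValueError("mean_lifespan must be > 0 and lifespan_sd >= 0")

    @classmethod
    def from_tau0(cls, tau0: float, spec: GameSpec) -> "ReproductionParams":
        """Standard parameterization: I_o = tau0*mu, omega = 3*tau0, sigma = 0.25*omega."""
        omega = 3.0 * tau0
        return cls(
            tau0=tau0,
            offspring_cost=tau0 * spec.expected_return,
            mean_lifespan=omega,
            lifespan_sd=0.25 * omega,
        )


@dataclass(frozen=True)
class DeficitParams:
    """Deficit rule constants: time cost ``c`` and deficit cutoff ``gamma``."""

    time_cost: float = 0.01
    cutoff: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_cost <= 1.0:
            raise ValueError(f"time_cost c must lie in [0, 1], got {self.time_cost}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff gamma must lie in (0, 1), got {self.cutoff}")


@dataclass
class AgentState:
    """One agent's strategy and reproductive bookkeeping.

    ``clock`` counts the steps played since the agent's own birth or its last
    birth event (1 during the first played step); ``ibi`` is the current,
    possibly deficit-lengthened, interbirth interval.
    """

    strategy: float
    ibi: float
    resources: float = 0.0
    clock: int = 1
    age: int = 0
    lifespan: int = 0
    group: int | None = None


def expected_accumulation(clock, spec: GameSpec):
    """Expected resources after ``clock`` played steps: ``T * k R / n = T * mu``."""
    return clock * spec.expected_return


def deficit_mask(resources, clock, spec: GameSpec, deficit: DeficitParams):
    """True where resources fall strictly below ``gamma`` of expected accumulation."""
    return resources < deficit.cutoff * expected_accumulation(clock, spec)


def update_ibi(
    agent: AgentState,
    spec: GameSpec,
    deficit: DeficitParams,
    repro: ReproductionParams,
) -> AgentState:
    """Lengthen the agent's IBI by ``c * tau0`` if it runs a deficit this step.

    The comparison is strict (no penalty when resources exactly meet the
    threshold).  ``tau`` resets to ``tau0`` only at birth events, handled by
    :func:`apply_birth`.
    """
    if deficit_mask(agent.resources, agent.clock, spec, deficit):
        agent.ibi = agent.ibi + deficit.time_cost * repro.tau0
    return agent


def check_birth(agent: AgentState, repro: ReproductionParams) -> bool:
    """True iff resources >= I_o and the clock has reached the current IBI."""
    return bool(agent.resources >= repro.offspring_cost and agent.clock >= agent.ibi)


def apply_birth(agent: AgentState, repro: ReproductionParams) -> AgentState:
    """Consume ``I_o`` resources and reset clock and IBI after a birth.

    Surplus resources carry over in full; the clock restarts so the next
    played step has ``clock = 1`` and the IBI returns to the optimum tau0.
    """
    if not check_birth(agent, repro):
        raise ValueError("apply_birth called without the birth condition holding")
    agent.resources -= repro.offspring_cost
    agent.clock = 0
    agent.ibi = repro.tau0
    return agent


def draw_lifespan(
    repro: ReproductionParams, rng: np.random.Generator, size: int | None = None
):
    """Integer lifespan(s): trunc(Gaussian(omega, sigma_omega)), floored at 1.

    Truncation is toward zero; a draw below 1 (a >3-sigma event at the default
    sigma_omega = 0.25 omega) is clamped to 1.
    """
    draws = rng.normal(repro.mean_lifespan, repro.lifespan_sd, size=size)
    trunc = np.trunc(draws)
    clamped = np.maximum(trunc, 1.0)
    if size is None:
        return int(clamped)
    return clamped.astype(np.int64)
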
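"""Closed-form quantities for homogeneous DG_{k,n} play.

When every agent plays the same offer ``p``, the one-step payoff is a two-point
mixture over roles: with probability ``k/n`` the agent is a dictator keeping
``R(1-p)``, otherwise a recipient receiving ``k p R / (n-k)``.  The mean is
``kR/n`` regardless of ``p``; the variance collapses to

    sigma_p^2 = k R^2 (k + n p - n)^2 / (n^2 (n - k))

which is zero exactly at the equitable offer ``p = 1 - k/n``.  Because roles
are redrawn independently each step, variance accumulates linearly over a
reproductive horizon of ``tau0`` steps, and the coefficient of variation of
accumulated resources,

    CV = n sqrt(tau0 sigma_p^2) / (tau0 k R),

shrinks as ``1/sqrt(tau0)``.  These expressions deliberately exclude the
endowment noise sigma_R used by the simulators, which is an implementation
device rather than part of the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import OFFER_GRID, GameSpec

__all__ = [
    "VarianceReport",
    "equitable_offer",
    "per_step_variance",
    "accumulated_variance",
    "coefficient_of_variation",
    "variance_report",
    "offspring_cost",
    "optimal_offspring",
    "cv_table",
]


@dataclass(frozen=True)
class VarianceReport:
    """Variance analytics for one (game, offer, horizon) combination."""

    offer: float
    horizon: float
    per_step_variance: float
    accumulated_variance: float
    cv: float


def _check_offer(offer: float) -> None:
    if not 0.0 <= offer <= 1.0:
        raise ValueError(f"offer must lie in [0, 1], got {offer}")


def equitable_offer(spec: GameSpec) -> float:
    """The offer ``p = 1 - k/n`` equalizing expected resources across players.

    At this offer a dictator keeps ``R k / n`` and each recipient receives
    ``R k / n``: every player nets the expected return, and the one-step
    payoff variance vanishes.
    """
    return 1.0 - spec.k / spec.n


def per_step_variance(spec: GameSpec, offer: float) -> float:
    """One-step payoff variance under homogeneous play of ``offer``.

    Deterministic endowment (sigma_R excluded); zero iff ``offer`` is the
    equitable offer.
    """
    _check_offer(offer)
    k, n, r = spec.k, spec.n, spec.base_endowment
    return k * r**2 * (k + n * offer - n) ** 2 / (n**2 * (n - k))


def accumulated_variance(spec: GameSpec, offer: float, horizon: float) -> float:
    """Variance of resources accumulated over ``horizon`` independent steps."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return horizon * per_step_variance(spec, offer)


def coefficient_of_variation(spec: GameSpec, offer: float, horizon: float) -> float:
    """CV of accumulated resources: sqrt(accumulated variance) / (horizon * mu).

    Dimensionless; strictly decreasing in ``offer`` below the equitable offer
    and strictly increasing above it, with minimum 0 at ``1 - k/n``.
    """
    sd = np.sqrt(accumulated_variance(spec, offer, horizon))
    return spec.n * sd / (horizon * spec.k * spec.base_endowment)


def variance_report(spec: GameSpec, offer: float, horizon: float) -> VarianceReport:
    """Bundle per-step/accumulated variance and CV for one configuration."""
    return VarianceReport(
        offer=offer,
        horizon=horizon,
        per_step_variance=per_step_variance(spec, offer),
        accumulated_variance=accumulated_variance(spec, offer, horizon),
        cv=coefficient_of_variation(spec, offer, horizon),
    )


def offspring_cost(horizon: float, spec: GameSpec) -> float:
    """Resource cost of one offspring, ``I_o = tau0 * k R / n = tau0 * mu``.

    Defined so that the optimal interbirth interval tau0 coincides with the
    expected time to accumulate the resources for one offspring.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return horizon * spec.expected_return


def optimal_offspring(lifespan: float, spec: GameSpec, offspring_cost: float) -> float:
    """Expected lifetime offspring ``m = omega * k R / (n * I_o)``.

    Lifetime expected accumulation divided by the per-offspring cost; with
    ``I_o = tau0 * mu`` this is simply ``omega / tau0``.
    """
    if lifespan < 0:
        raise ValueError(f"lifespan must be >= 0, got {lifespan}")
    if offspring_cost <= 0:
        raise ValueError(f"offspring_cost must be > 0, got {offspring_cost}")
    return lifespan * spec.expected_return / offspring_cost


#: The five canonical game shapes studied throughout: from multi-dictator
#: (bystander effect) to multi-recipient (congestible altruism).
CANONICAL_GAMES: tuple[tuple[int, int], ...] = ((3, 4), (2, 3), (1, 2), (1, 3), (1, 4))


def cv_table(
    games: tuple[tuple[int, int], ...] = CANONICAL_GAMES,
    horizons: tuple[float, ...] = (270, 730),
    offers: np.ndarray = OFFER_GRID,
    mu: float = 5.0,
):
    """Tidy table of (game, p, tau0, variance, CV) over games x offers x horizons."""
    import pandas as pd

    rows = []
    for k, n in games:
        spec = GameSpec(k=k, n=n, mu=mu)
        for tau0 in horizons:
            for p in offers:
                rep = variance_report(spec, float(p), tau0)
                rows.append(
                    {
                        "game": spec.label(),
                        "k": k,
                        "n": n,
                        "p": float(p),
                        "tau0": tau0,
                        "per_step_variance": rep.per_step_variance,
                        "accumulated_variance": rep.accumulated_variance,
                        "cv": rep.cv,
                    }
                )
    return pd.DataFrame(rows)
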
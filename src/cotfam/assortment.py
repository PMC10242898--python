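"""Closed-form assortative-mating algebra.

The phenotypic partner correlation ``d`` splits into a genetic covariance
component ``r_g = rho_A * a^2`` and an environmental component
``r_e = rho_E * e^2``.  Assortment on a heritable trait also inflates the
additive genetic variance across generations: with a constant correlation
``m`` between mates' breeding values the recursion

    V(t+1) = V0/2 + V(t) * (1 + m) / 2

rises from the random-mating base ``V0`` toward the equilibrium
``V0 / (1 - m)`` (Lynch & Walsh-style single-trait equilibrium), i.e. a
``100 * (1/(1-m) - 1)`` percent increase.  A single generation of
assortment gives ``1 + m/2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model_core import ModelError

__all__ = [
    "AssortmentSummary",
    "InflationMode",
    "spousal_summary",
    "am_variance_inflation",
    "variance_recursion",
]


class InflationMode(str, Enum):
    EQUILIBRIUM = "EQUILIBRIUM"
    ONE_GENERATION = "ONE_GENERATION"


@dataclass(frozen=True)
class AssortmentSummary:
    """Spousal phenotypic correlation and its decomposition."""

    d: float
    g_component: float
    e_component: float
    percent_genetic: float | None
    m_breeding: float | None

    def __post_init__(self):
        if abs(self.d - (self.g_component + self.e_component)) > 1e-12:
            raise ModelError("components do not sum to the phenotypic correlation")


def spousal_summary(rho_A: float, rho_E: float, a2: float, e2: float) -> AssortmentSummary:
    """Decompose the spousal phenotypic correlation.

    ``g_component = rho_A * a2`` and ``e_component = rho_E * e2`` sum to the
    partner correlation ``d``; ``percent_genetic`` is the genetic share of
    ``d`` (undefined, ``None``, when ``d`` is zero); ``m_breeding`` is the
    implied correlation of breeding values, ``g_component / a2``.
    """
    if not (0.0 <= a2 <= 1.0 and 0.0 <= e2 <= 1.0 and a2 + e2 <= 1.0 + 1e-12):
        raise ModelError(f"variance shares a2={a2}, e2={e2} invalid (each in [0,1], sum <= 1)")
    g_comp = rho_A * a2
    e_comp = rho_E * e2
    d = g_comp + e_comp
    return AssortmentSummary(
        d=d,
        g_component=g_comp,
        e_component=e_comp,
        percent_genetic=(100.0 * g_comp / d) if d != 0 else None,
        m_breeding=(g_comp / a2) if a2 > 0 else None,
    )


def am_variance_inflation(
    r_g: float, mode: InflationMode | str = InflationMode.EQUILIBRIUM
) -> float:
    """Percent increase in additive genetic variance due to assortment.

    ``EQUILIBRIUM`` compares the assortative-mating equilibrium with the
    random-mating base population (ratio ``1/(1 - r_g)``); ``ONE_GENERATION``
    applies a single round of assortment (ratio ``1 + r_g/2``).  ``r_g`` is
    the correlation between mates' breeding values, assumed constant.
    """
    mode = InflationMode(mode)
    if r_g >= 1.0:
        raise ModelError(f"no equilibrium exists for breeding-value correlation {r_g} >= 1")
    if mode == InflationMode.EQUILIBRIUM:
        ratio = 1.0 / (1.0 - r_g)
    else:
        ratio = 1.0 + r_g / 2.0
    return 100.0 * (ratio - 1.0)


def variance_recursion(m: float, n_generations: int, v0: float = 1.0) -> np.ndarray:
    """Forward-simulate additive variance under constant breeding-value
    correlation ``m``: ``V(t+1) = v0/2 + V(t)*(1+m)/2`` starting at ``v0``.

    Converges to the fixed point ``v0/(1-m)`` — the equilibrium that
    :func:`am_variance_inflation` expresses as a percent increase.
    """
    if abs(m) >= 1.0:
        raise ModelError("breeding-value correlation must lie in (-1, 1)")
    v = np.empty(n_generations + 1)
    v[0] = v0
    for t in range(n_generations):
        v[t + 1] = v0 / 2.0 + v[t] * (1.0 + m) / 2.0
    return v
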
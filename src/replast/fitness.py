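"""Reward/penalty mappings and terminal expected fitness of a mature phenotype.

A phenotype is a pair of non-negative specialization counts ``(y0, y1)``
toward the two phenotypic targets P0 and P1. At maturity, fitness is

    pi(Y) = pi0 + phi(Y) - psi(Y)

where the expected reward ``phi`` applies the reward mapping ``f`` to the
trait matching each environmental state, weighted by the posterior belief,
and the expected penalty ``psi`` applies the penalty mapping to the
mismatched trait:

    phi = P(E0|D) * f_r(y0) + P(E1|D) * f_r(y1)
    psi = P(E0|D) * f_p(y1) + P(E1|D) * f_p(y0)

Three mapping shapes are supported (linear, diminishing, increasing); the
nonlinear shapes are normalized so that ``f(T_ont) = T_ont``, i.e., maximal
attainable fitness is the ontogeny duration regardless of shape. Reward and
penalty carry independent mappings so that mixed ecologies (e.g., increasing
rewards with diminishing penalties) are expressible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "MAPPING_KINDS",
    "MappingSpec",
    "FitnessSpec",
    "Phenotype",
    "mapping_value",
    "expected_fitness",
]

MAPPING_KINDS = ("linear", "diminishing", "increasing")


class Phenotype(NamedTuple):
    """Net specialization counts toward P0 and P1."""

    y0: int
    y1: int


@dataclass(frozen=True)
class MappingSpec:
    """One phenotype-to-fitness mapping.

    Parameters
    ----------
    kind : {"linear", "diminishing", "increasing"}
        Shape of the mapping.
    t_ont : int
        Ontogeny duration; sets the normalization of the nonlinear shapes.
    beta : float
        Curvature rate of the nonlinear shapes (default 0.2).
    """

    kind: str
    t_ont: int
    beta: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in MAPPING_KINDS:
            raise ValueError(f"unknown mapping kind {self.kind!r}")
        if self.t_ont < 1:
            raise ValueError("t_ont must be >= 1")

    @property
    def alpha(self) -> float:
        """Normalization constant ensuring f(t_ont) = t_ont."""
        b, t = self.beta, self.t_ont
        if self.kind == "diminishing":
            return t / (1.0 - math.exp(-b * t))
        if self.kind == "increasing":
            return t / (math.exp(b * t) - 1.0)
        return 1.0


def mapping_value(m: MappingSpec, y: float) -> float:
    """Evaluate the mapping at ``y`` specializations.

    Fractional ``y`` is accepted so that the generalist reference strategy
    ("halfway toward each target") is well-defined at odd ontogeny durations;
    optimal policies themselves only ever hold integer counts.
    """
    if y < 0:
        raise ValueError(f"specialization count must be >= 0, got {y}")
    if m.kind == "linear":
        return float(y)
    if m.kind == "diminishing":
        return m.alpha * (1.0 - math.exp(-m.beta * y))
    return m.alpha * (math.exp(m.beta * y) - 1.0)


@dataclass(frozen=True)
class FitnessSpec:
    """Reward and penalty mappings plus the baseline fitness constant."""

    reward: MappingSpec
    penalty: MappingSpec
    baseline: float = 0.0

    @staticmethod
    def make(
        t_ont: int,
        reward_kind: str = "linear",
        penalty_kind: str = "linear",
        beta: float = 0.2,
        baseline: float = 0.0,
    ) -> "FitnessSpec":
        return FitnessSpec(
            reward=MappingSpec(reward_kind, t_ont, beta),
            penalty=MappingSpec(penalty_kind, t_ont, beta),
            baseline=baseline,
        )


def expected_fitness(
    ph: Phenotype, posterior_e1: float, fs: FitnessSpec
) -> float:
    """Terminal expected fitness ``pi0 + phi - psi`` of a mature phenotype.

    ``posterior_e1`` is the organism's belief P(E1 | cues) at the end of
    ontogeny; rewards accrue to the trait matching each state, penalties to
    the mismatched trait, with equal unit weights.
    """
    if not 0.0 <= posterior_e1 <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {posterior_e1}")
    p1 = posterior_e1
    p0 = 1.0 - p1
    phi = p0 * mapping_value(fs.reward, ph.y0) + p1 * mapping_value(fs.reward, ph.y1)
    psi = p0 * mapping_value(fs.penalty, ph.y1) + p1 * mapping_value(fs.penalty, ph.y0)
    return fs.baseline + phi - psi
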
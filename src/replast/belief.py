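"""Exact Bayesian inference over a binary environmental state from binary cues.

Organisms are born into a patch whose state is either ``E0`` or ``E1`` and
stays fixed for life. Each period they sample one binary cue (``C0`` or
``C1``) whose reliability ``r = P(Cx | Ex)`` is symmetric across states.
Because cues are conditionally i.i.d., the posterior over the environment
depends only on the *number* of ``C1`` cues seen, not their order — so the
pair ``(t, n1)`` is a sufficient statistic and the whole belief space is a
small triangular lattice.

Posteriors are computed in log space so that long ontogenies with highly
reliable cues do not underflow; ``reliability`` may sit at the endpoints 0.5
(cues carry no information) and 1.0 (a single cue reveals the state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnvPrior",
    "CueModel",
    "BeliefState",
    "posterior_from_counts",
    "cue_predictive",
]


@dataclass(frozen=True)
class EnvPrior:
    """Evolutionary prior probability of being born into state ``E1``."""

    p_e1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e1 <= 1.0:
            raise ValueError(f"p_e1 must lie in [0, 1], got {self.p_e1}")

    @property
    def p_e0(self) -> float:
        return 1.0 - self.p_e1


@dataclass(frozen=True)
class CueModel:
    """Symmetric cue-emission model: ``P(C0|E0) = P(C1|E1) = reliability``."""

    reliability: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.reliability <= 1.0:
            raise ValueError(
                f"reliability must lie in [0.5, 1], got {self.reliability}"
            )

    def p_cue_given_env(self, cue: int, env: int) -> float:
        """P(cue | env) with cue, env coded 0/1."""
        return self.reliability if cue == env else 1.0 - self.reliability


def posterior_from_counts(
    prior: EnvPrior, cues: CueModel, n1: int, t: int
) -> float:
    """Posterior probability of ``E1`` after observing ``n1`` C1-cues in ``t`` draws.

    Implements Bayes' rule on the binomial likelihood; exchangeability in the
    cue order holds by construction. Computed via log-likelihood differences
    for numerical robustness at long horizons.

    Raises
    ------
    ValueError
        If ``n1`` is outside ``[0, t]``, or the observation is impossible
        (mixed cues under ``reliability == 1``).
    """
    if t < 0 or not 0 <= n1 <= t:
        raise ValueError(f"need 0 <= n1 <= t, got n1={n1}, t={t}")
    p1 = prior.p_e1
    r = cues.reliability
    if t == 0 or r == 0.5 or p1 in (0.0, 1.0):
        # No data, uninformative cues, or a dogmatic prior: posterior == prior.
        return p1
    n0 = t - n1
    if r == 1.0:
        # Perfectly reliable cues: one cue settles the state.
        if n1 > 0 and n0 > 0:
            raise ValueError(
                "mixed cues are impossible under reliability 1.0"
            )
        return 1.0 if n1 > 0 else 0.0
    # log-weight difference log w0 - log w1; both priors are in (0, 1) here.
    log_ratio = (
        math.log(1.0 - p1)
        - math.log(p1)
        + (n0 - n1) * (math.log(r) - math.log(1.0 - r))
    )
    # two-branch logistic: exp never sees a positive argument
    if log_ratio >= 0.0:
        e = math.exp(-log_ratio)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(log_ratio))


def cue_predictive(posterior_e1: float, cues: CueModel) -> float:
    """Posterior-predictive probability that the *next* cue is ``C1``.

    Marginalizes the emission model over the current belief:
    ``P(C1) = b * r + (1 - b) * (1 - r)``.
    """
    if not 0.0 <= posterior_e1 <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {posterior_e1}")
    r = cues.reliability
    return posterior_e1 * r + (1.0 - posterior_e1) * (1.0 - r)


@dataclass(frozen=True)
class BeliefState:
    """Sufficient statistic of the cue history: periods elapsed and C1 count."""

    t: int
    n1: int

    def posterior_e1(self, prior: EnvPrior, cues: CueModel) -> float:
        return posterior_from_counts(prior, cues, self.n1, self.t)
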
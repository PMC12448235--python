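"""Non-plastic reference strategies and the construction-only policy.

The fitness value of reversibility is assessed by comparing the optimal
policy against three references: an otherwise-optimal policy that can only
construct (never deconstruct), a specialist that spends all of ontogeny
specializing toward the prior's modal state, and a generalist that
specializes halfway toward each target. With equal reward and penalty
mappings the generalist's matched rewards and mismatched penalties cancel
exactly, so its expected fitness is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fitness import mapping_value
from .policy import Mode, ModelParams, Policy, solve

__all__ = [
    "BaselineResult",
    "specialist_fitness",
    "generalist_fitness",
    "no_deconstruction_policy",
    "normalized_fitness",
    "compare_strategies",
]


@dataclass(frozen=True)
class BaselineResult:
    strategy: str
    expected_fitness: float
    normalized_fitness: float


def specialist_fitness(params: ModelParams) -> float:
    """Expected fitness of full specialization toward the prior's modal state.

    The specialist constructs the same target every period, ending with
    ``t_ont`` specializations toward the state the prior deems more likely.
    At an uninformative prior (0.5) the population splits in half between the
    two targets and the population mean is reported; by symmetry of the
    expected-fitness expression both halves earn the same amount, so the mean
    equals either half's value.
    """
    T = params.t_ont
    p1 = params.prior.p_e1
    f_r = mapping_value(params.fitness.reward, T)
    f_p = mapping_value(params.fitness.penalty, T)
    p_likely = max(p1, 1.0 - p1)
    if p1 == 0.5:
        # Each half matches with probability 0.5; the average over halves.
        return params.fitness.baseline + 0.5 * f_r - 0.5 * f_p
    return params.fitness.baseline + p_likely * f_r - (1.0 - p_likely) * f_p


def generalist_fitness(params: ModelParams) -> float:
    """Expected fitness of specializing halfway toward each target.

    Evaluates the mappings at the (possibly fractional) midpoint
    ``t_ont / 2`` on each trait; the environmental weighting drops out
    because the phenotype is symmetric:
    ``f_reward(T/2) - f_penalty(T/2)`` regardless of the prior.
    """
    half = params.t_ont / 2.0
    f_r = mapping_value(params.fitness.reward, half)
    f_p = mapping_value(params.fitness.penalty, half)
    return params.fitness.baseline + f_r - f_p


def no_deconstruction_policy(params: ModelParams) -> Policy:
    """Optimal policy restricted to incremental, irreversible construction."""
    constrained = ModelParams(
        prior=params.prior,
        cues=params.cues,
        t_ont=params.t_ont,
        fitness=params.fitness,
        mode=Mode.NONE,
    )
    return solve(constrained)


def normalized_fitness(value: float, params: ModelParams, scheme: str = "unit") -> float:
    """Map raw expected fitness onto a comparison scale.

    ``"unit"`` (default) divides by ``t_ont``, so 1 means perfect matching
    and 0 the guaranteed-by-waiting floor (with baseline 0, optimal values
    are non-negative). ``"affine"`` maps the full attainable range
    ``[-t_ont, t_ont]`` onto [0, 1]. Both are order-preserving.
    """
    T = params.t_ont
    if scheme == "unit":
        return value / T
    if scheme == "affine":
        return (value + T) / (2.0 * T)
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def compare_strategies(
    params: ModelParams, scheme: str = "unit"
) -> list[BaselineResult]:
    """Fitness of the optimal policy and all reference strategies at one cell.

    Returns one row per strategy: the optimal policy in the cell's own mode,
    the construction-only policy, the specialist, and the generalist.
    """
    rows = []
    opt = solve(params)
    rows.append(
        BaselineResult(
            f"optimal_{params.mode.value}",
            opt.root_value,
            normalized_fitness(opt.root_value, params, scheme),
        )
    )
    if params.mode != Mode.NONE:
        nd = no_deconstruction_policy(params)
        rows.append(
            BaselineResult(
                "no_deconstruction_policy",
                nd.root_value,
                normalized_fitness(nd.root_value, params, scheme),
            )
        )
    for name, fn in (("specialist", specialist_fitness), ("generalist", generalist_fitness)):
        v = fn(params)
        rows.append(BaselineResult(name, v, normalized_fitness(v, params, scheme)))
    return rows
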
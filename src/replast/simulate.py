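"""Forward simulation of developing organisms and the clone-separation assay.

Agents draw a true environmental state from the prior, then each period
sample a cue from that state's emission distribution, update their cue
counts, and execute an action drawn uniformly from the solved policy's tied
optimal set. Alongside the net phenotype ``(y0, y1)`` each agent keeps four
bookkeeping counters — periods spent constructing toward each target
(``y0C``, ``y1C``) and periods spent deconstructing each target (``y0D``,
``y1D``; one per deconstruct action, also in the complete-deconstruction
regime) — which feed the three plasticity distances.

The clone-separation assay duplicates each agent at a chosen period; from
that point the clone receives, for the scheme's window, the complement of
the original's cues ("when one organism samples C0, its clone samples C1"),
then both are compared. The mean normalized phenotypic distance over pairs,
as a function of the separation time, is the plasticity curve whose shape
reveals sensitive periods: distance in construction counters, in
deconstruction counters, and in the net phenotype ("total").

Randomness is fully reproducible: all cue and tie-break draws come from
bulk-generated matrices whose rows act as per-agent substreams, derived from
the master seed; clones use substreams independent of the originals from the
separation point onward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fitness import Phenotype, expected_fitness
from .policy import Action, Mode, ModelParams, Policy

__all__ = [
    "Agent",
    "ClonePair",
    "SeparationScheme",
    "simulate_agents",
    "clone_experiment",
    "plasticity_distances",
    "mature_phenotype_distribution",
    "PhenotypeDistribution",
    "agent_fitness",
]

# Integer action codes for the tight simulation loop.
_WAIT, _C0, _C1, _D0, _D1 = 0, 1, 2, 3, 4
_ACTION_CODE = {
    Action.WAIT: _WAIT,
    Action.CONSTRUCT_P0: _C0,
    Action.CONSTRUCT_P1: _C1,
    Action.DECONSTRUCT_P0: _D0,
    Action.DECONSTRUCT_P1: _D1,
}
_CODE_ACTION = {v: k for k, v in _ACTION_CODE.items()}


@dataclass(slots=True)
class Agent:
    """One simulated developmental history."""

    env: int
    cues: list[int]
    actions: list[Action]
    ph: Phenotype
    y0C: int
    y1C: int
    y0D: int
    y1D: int
    #: state after each period t = 0..t_ont: (n1, y0, y1, y0C, y1C, y0D, y1D)
    snapshots: list[tuple[int, int, int, int, int, int, int]] = field(repr=False, default_factory=list)

    @property
    def y0(self) -> int:
        return self.ph.y0

    @property
    def y1(self) -> int:
        return self.ph.y1

    @property
    def waits(self) -> int:
        return len(self.actions) - (self.y0C + self.y1C + self.y0D + self.y1D)

    @property
    def ever_deconstructed(self) -> bool:
        return (self.y0D + self.y1D) > 0


@dataclass(frozen=True)
class SeparationScheme:
    """Configuration of the clone-separation assay.

    ``window=None`` separates permanently (complementary cues until
    maturity); an integer window separates temporarily for that many
    periods, after which the clone samples the original's cues again.
    ``measure`` picks the comparison point: end of ontogeny (default) or
    immediately after the separation window closes.
    ``normalizer``: ``"table"`` uses denominators ``2*sqrt(T_ont)`` for the
    total/construction distances and ``2*sqrt(T_ont/2)`` for deconstruction;
    ``"max"`` instead divides all three by the maximal possible Euclidean
    distance ``T_ont*sqrt(2)``.
    """

    window: int | None = None
    measure: str = "end"
    normalizer: str = "table"

    def __post_init__(self) -> None:
        if self.window is not None and self.window < 1:
            raise ValueError("separation window must be >= 1")
        if self.measure not in ("end", "post_window"):
            raise ValueError(f"unknown measurement point {self.measure!r}")
        if self.measure == "post_window" and self.window is None:
            raise ValueError("post_window measurement requires a finite window")
        if self.normalizer not in ("table", "max"):
            raise ValueError(f"unknown normalizer {self.normalizer!r}")


@dataclass(frozen=True)
class ClonePair:
    original: Agent
    clone: Agent
    separation_time: int
    scheme: SeparationScheme


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Empirical joint distribution of mature phenotypes."""

    table: pd.DataFrame  # columns: y0, y1, deconstruction_periods, frequency
    fraction_deconstructed: float
    n: int


def _decision_table(policy: Policy) -> dict:
    """Map decision states to tuples of integer action codes."""
    return {
        tuple(d): tuple(_ACTION_CODE[a] for a in acts)
        for d, (_, acts) in policy._decisions.items()
    }


def _step(code: int, mode_complete: bool, y0, y1, y0C, y1C, y0D, y1D):
    if code == _WAIT:
        pass
    elif code == _C0:
        y0 += 1
        y0C += 1
    elif code == _C1:
        y1 += 1
        y1C += 1
    elif code == _D0:
        y0 = 0 if mode_complete else y0 - 1
        y0D += 1
    else:
        y1 = 0 if mode_complete else y1 - 1
        y1D += 1
    return y0, y1, y0C, y1C, y0D, y1D


def simulate_agents(
    policy: Policy,
    params: ModelParams | None = None,
    n: int = 10_000,
    seed: int = 0,
    env: int | None = None,
) -> list[Agent]:
    """Simulate ``n`` agents developing under a solved policy.

    Each agent draws its environment from the prior (or uses the pinned
    ``env`` override for conditional analyses), samples cues, and follows
    the policy with uniform tie-breaking. Deterministic given ``seed``.
    """
    params = policy.params if params is None else params
    if params != policy.params:
        raise ValueError("policy was solved for different parameters")
    if n < 1:
        raise ValueError("n must be >= 1")
    T = params.t_ont
    r = params.cues.reliability
    dec = _decision_table(policy)
    complete = params.mode == Mode.COMPLETE
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    if env is None:
        envs = (rng.random(n) < params.prior.p_e1).astype(np.int8)
    else:
        envs = np.full(n, env, dtype=np.int8)
    cue_u = rng.random((n, T))
    tie_u = rng.random((n, T))
    p_c1 = np.where(envs == 1, r, 1.0 - r)
    cue_mat = (cue_u < p_c1[:, None]).astype(np.int8)

    agents: list[Agent] = []
    for i in range(n):
        cues = [int(c) for c in cue_mat[i]]
        ties = tie_u[i]
        n1 = y0 = y1 = y0C = y1C = y0D = y1D = 0
        snaps = [(0, 0, 0, 0, 0, 0, 0)]
        actions = []
        for t in range(T):
            n1 += cues[t]
            opts = dec[(t + 1, n1, y0, y1)]
            code = opts[0] if len(opts) == 1 else opts[int(ties[t] * len(opts))]
            actions.append(_CODE_ACTION[code])
            y0, y1, y0C, y1C, y0D, y1D = _step(code, complete, y0, y1, y0C, y1C, y0D, y1D)
            snaps.append((n1, y0, y1, y0C, y1C, y0D, y1D))
        agents.append(
            Agent(
                env=int(envs[i]),
                cues=cues,
                actions=actions,
                ph=Phenotype(y0, y1),
                y0C=y0C,
                y1C=y1C,
                y0D=y0D,
                y1D=y1D,
                snapshots=snaps,
            )
        )
    return agents


def agent_fitness(agent: Agent, params: ModelParams, realized: bool = False) -> float:
    """Terminal fitness of a simulated agent.

    Default is the belief-weighted expected fitness (the quantity the policy
    optimizes); ``realized=True`` instead scores the phenotype against the
    agent's true environmental state (same mean, higher variance).
    """
    if realized:
        post = float(agent.env)
    else:
        n1 = agent.snapshots[-1][0]
        post = params.posterior(n1, params.t_ont)
    return expected_fitness(agent.ph, post, params.fitness)


def plasticity_distances(o, c, t_ont: int, normalizer: str = "table") -> tuple[float, float, float]:
    """Three normalized Euclidean distances between an original and its clone.

    Total distance compares the net phenotypes, construction distance the
    periods spent constructing, and deconstruction distance the periods
    spent deconstructing each target. The default denominators are
    ``2*sqrt(t_ont)`` (total, construction) and ``2*sqrt(t_ont/2)``
    (deconstruction); ``normalizer="max"`` divides all three by the maximal
    possible distance ``t_ont*sqrt(2)`` instead.
    """
    d_tot = math.hypot(o.y0 - c.y0, o.y1 - c.y1)
    d_con = math.hypot(o.y0C - c.y0C, o.y1C - c.y1C)
    d_dec = math.hypot(o.y0D - c.y0D, o.y1D - c.y1D)
    if normalizer == "table":
        z = 2.0 * math.sqrt(t_ont)
        zd = 2.0 * math.sqrt(t_ont / 2.0)
        return d_tot / z, d_con / z, d_dec / zd
    if normalizer == "max":
        z = t_ont * math.sqrt(2.0)
        return d_tot / z, d_con / z, d_dec / z
    raise ValueError(f"unknown normalizer {normalizer!r}")


@dataclass(slots=True)
class _Counts:
    """Lightweight counter bundle with the Agent distance interface."""

    y0: int
    y1: int
    y0C: int
    y1C: int
    y0D: int
    y1D: int


def _replay_clone(
    dec: dict,
    complete: bool,
    T: int,
    orig_cues: Sequence[int],
    start: tuple[int, int, int, int, int, int, int],
    t_sep: int,
    window: int | None,
    ties: np.ndarray,
) -> tuple[_Counts, list[tuple[int, int, int, int, int, int, int]]]:
    """Replay a clone from the separation point under complemented cues."""
    n1, y0, y1, y0C, y1C, y0D, y1D = start
    snaps = []
    end_flip = T if window is None else min(T, t_sep - 1 + window)
    for t in range(t_sep - 1, T):
        cue = orig_cues[t]
        if t < end_flip:
            cue = 1 - cue
        n1 += cue
        opts = dec[(t + 1, n1, y0, y1)]
        code = opts[0] if len(opts) == 1 else opts[int(ties[t - t_sep + 1] * len(opts))]
        y0, y1, y0C, y1C, y0D, y1D = _step(code, complete, y0, y1, y0C, y1C, y0D, y1D)
        snaps.append((n1, y0, y1, y0C, y1C, y0D, y1D))
    return _Counts(y0, y1, y0C, y1C, y0D, y1D), snaps


def clone_experiment(
    policy: Policy,
    params: ModelParams | None = None,
    n: int = 10_000,
    seed: int = 0,
    scheme: SeparationScheme = SeparationScheme(),
) -> pd.DataFrame:
    """Clone-separation assay across all separation times.

    For each separation time ``t`` in ``1..t_ont``, every simulated original
    is cloned with its pre-``t`` history; from period ``t`` the clone's cue
    is the complement of the original's (for the scheme's window), both
    continue under the policy with independent tie-break draws, and the
    three plasticity distances are averaged over the ``n`` pairs at the
    measurement point.

    Returns a tidy frame with columns ``separation_time``, ``total``,
    ``construction``, ``deconstruction``.

    The assay is undefined at reliability 1.0, where complementary cues are
    impossible under the model.
    """
    params = policy.params if params is None else params
    if params != policy.params:
        raise ValueError("policy was solved for different parameters")
    if params.cues.reliability == 1.0:
        raise ValueError("clone assay undefined for perfectly reliable cues")
    T = params.t_ont
    dec = _decision_table(policy)
    complete = params.mode == Mode.COMPLETE
    originals = simulate_agents(policy, params, n=n, seed=seed)

    rows = []
    for t_sep in range(1, T + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC10_E, t_sep]))
        ties = rng.random((n, T - t_sep + 1))
        if scheme.measure == "post_window":
            t_meas = min(T, t_sep - 1 + scheme.window)
        else:
            t_meas = T
        tot = con = decn = 0.0
        for i, o in enumerate(originals):
            counts, snaps = _replay_clone(
                dec, complete, T, o.cues, o.snapshots[t_sep - 1], t_sep, scheme.window, ties[i]
            )
            if t_meas == T:
                c_counts = counts
                o_counts = _Counts(*o.snapshots[T][1:])
            else:
                c_counts = _Counts(*snaps[t_meas - t_sep][1:])
                o_counts = _Counts(*o.snapshots[t_meas][1:])
            d_t, d_c, d_d = plasticity_distances(
                o_counts, c_counts, T, normalizer=scheme.normalizer
            )
            tot += d_t
            con += d_c
            decn += d_d
        rows.append(
            {
                "separation_time": t_sep,
                "total": tot / n,
                "construction": con / n,
                "deconstruction": decn / n,
            }
        )
    return pd.DataFrame(rows)


def make_clone_pair(
    policy: Policy,
    original: Agent,
    t_sep: int,
    seed: int = 0,
    scheme: SeparationScheme = SeparationScheme(),
) -> ClonePair:
    """Build one fully materialized :class:`ClonePair` (inspection helper)."""
    params = policy.params
    T = params.t_ont
    dec = _decision_table(policy)
    complete = params.mode == Mode.COMPLETE
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC10_E, t_sep]))
    ties = rng.random(T - t_sep + 1)
    counts, snaps = _replay_clone(
        dec, complete, T, original.cues, original.snapshots[t_sep - 1], t_sep, scheme.window, ties
    )
    end_flip = T if scheme.window is None else min(T, t_sep - 1 + scheme.window)
    cues = list(original.cues[: t_sep - 1]) + [
        (1 - c if t_sep - 1 <= t < end_flip else c)
        for t, c in enumerate(original.cues[t_sep - 1 :], start=t_sep - 1)
    ]
    clone = Agent(
        env=original.env,
        cues=cues,
        actions=[],
        ph=Phenotype(counts.y0, counts.y1),
        y0C=counts.y0C,
        y1C=counts.y1C,
        y0D=counts.y0D,
        y1D=counts.y1D,
        snapshots=list(original.snapshots[:t_sep]) + snaps,
    )
    return ClonePair(original, clone, t_sep, scheme)


def mature_phenotype_distribution(
    policy: Policy,
    params: ModelParams | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> PhenotypeDistribution:
    """Empirical joint frequencies of mature phenotypes.

    Tabulates ``(y0, y1, total deconstruction periods)`` across ``n``
    simulated agents and reports the fraction that ever deconstructed —
    the prevalence-of-deconstruction statistic.
    """
    params = policy.params if params is None else params
    agents = simulate_agents(policy, params, n=n, seed=seed)
    counts: dict[tuple[int, int, int], int] = {}
    n_dec = 0
    for a in agents:
        key = (a.y0, a.y1, a.y0D + a.y1D)
        counts[key] = counts.get(key, 0) + 1
        if a.ever_deconstructed:
            n_dec += 1
    table = pd.DataFrame(
        [
            {"y0": k[0], "y1": k[1], "deconstruction_periods": k[2], "frequency": v / n}
            for k, v in sorted(counts.items())
        ]
    )
    return PhenotypeDistribution(table=table, fraction_deconstructed=n_dec / n, n=n)
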
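"""Optimal developmental policies by backward induction over belief states.

The developmental decision problem is a finite-horizon Markov decision
process on the state ``(t, n1, y0, y1)``: periods elapsed, count of C1 cues
observed, and net specialization counts toward the two targets. Cue order is
collapsed by exchangeability and the phenotype path by Markov sufficiency —
terminal fitness depends only on the posterior belief and the net counts —
so even a 20-period ontogeny has a small, exactly enumerable state space.

Each period the organism first samples a cue, updates its belief, and then
chooses one of up to five actions: construct toward P0 or P1, deconstruct
previous increments toward P0 or P1, or wait. Three action regimes are
supported:

* ``NONE`` — irreversible construction only (construct/wait);
* ``INCREMENTAL`` — deconstruction removes one increment per period;
* ``COMPLETE`` — deconstruction removes *all* increments toward one target
  in a single period (this regime replaces, rather than augments, the
  one-step deconstruct actions).

Fitness accrues only at maturity (no discounting, no mortality); the value
of a state is the expected terminal fitness under optimal continuation,
computed exactly by stochastic dynamic programming. Ties among actions are
recorded explicitly (the simulator resolves them uniformly at random).

``brute_force_value`` provides an independent expectimax oracle that
enumerates every cue sequence and every feasible action sequence without
state merging; it exists for testing the solver at small horizons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, NamedTuple

from .belief import CueModel, EnvPrior, cue_predictive, posterior_from_counts
from .fitness import FitnessSpec, Phenotype, expected_fitness

__all__ = [
    "Action",
    "Mode",
    "ModelParams",
    "DevState",
    "Policy",
    "available_actions",
    "apply_action",
    "solve",
    "brute_force_value",
    "policy_expected_fitness",
    "reach_probabilities",
    "TIE_REL_TOL",
]

#: Two action values tie when |dV| <= TIE_REL_TOL * max(1, |V_max|).
TIE_REL_TOL = 1e-9

#: Largest horizon the expectimax oracle will attempt.
BRUTE_FORCE_MAX_T = 6


class Action(str, Enum):
    WAIT = "wait"
    CONSTRUCT_P0 = "construct_p0"
    CONSTRUCT_P1 = "construct_p1"
    DECONSTRUCT_P0 = "deconstruct_p0"
    DECONSTRUCT_P1 = "deconstruct_p1"


class Mode(str, Enum):
    """Deconstruction regime."""

    NONE = "none"
    INCREMENTAL = "incremental"
    COMPLETE = "complete"


class DevState(NamedTuple):
    """A decision-time state: ``t`` cues observed, ``n1`` of them C1, phenotype pre-action."""

    t: int
    n1: int
    y0: int
    y1: int

    @property
    def ph(self) -> Phenotype:
        return Phenotype(self.y0, self.y1)


@dataclass(frozen=True)
class ModelParams:
    """One point in the model's parameter space."""

    prior: EnvPrior
    cues: CueModel
    t_ont: int
    fitness: FitnessSpec
    mode: Mode = Mode.INCREMENTAL

    def __post_init__(self) -> None:
        if self.t_ont < 1:
            raise ValueError("t_ont must be >= 1")

    @staticmethod
    def make(
        prior: float = 0.5,
        reliability: float = 0.75,
        t_ont: int = 10,
        reward_kind: str = "linear",
        penalty_kind: str = "linear",
        mode: Mode | str = Mode.INCREMENTAL,
        beta: float = 0.2,
        baseline: float = 0.0,
    ) -> "ModelParams":
        """Convenience constructor from scalar parameters."""
        return ModelParams(
            prior=EnvPrior(prior),
            cues=CueModel(reliability),
            t_ont=t_ont,
            fitness=FitnessSpec.make(t_ont, reward_kind, penalty_kind, beta, baseline),
            mode=Mode(mode),
        )

    def posterior(self, n1: int, t: int) -> float:
        return posterior_from_counts(self.prior, self.cues, n1, t)


def available_actions(state, mode: Mode) -> tuple[Action, ...]:
    """Actions feasible in a state under the given regime.

    ``state`` may be a :class:`DevState`, a :class:`Phenotype`, or any object
    with ``y0``/``y1`` attributes; availability depends only on the current
    net counts. Deconstruct actions are unavailable (not silent no-ops) when
    the corresponding count is zero.
    """
    base = (Action.WAIT, Action.CONSTRUCT_P0, Action.CONSTRUCT_P1)
    if mode == Mode.NONE:
        return base
    extra = []
    if state.y0 >= 1:
        extra.append(Action.DECONSTRUCT_P0)
    if state.y1 >= 1:
        extra.append(Action.DECONSTRUCT_P1)
    return base + tuple(extra)


def apply_action(state, a: Action, mode: Mode) -> Phenotype:
    """Phenotype after executing ``a``; deconstruction semantics follow ``mode``."""
    y0, y1 = state.y0, state.y1
    if a == Action.WAIT:
        return Phenotype(y0, y1)
    if a == Action.CONSTRUCT_P0:
        return Phenotype(y0 + 1, y1)
    if a == Action.CONSTRUCT_P1:
        return Phenotype(y0, y1 + 1)
    if mode == Mode.NONE:
        raise ValueError(f"{a} unavailable without deconstruction")
    if a == Action.DECONSTRUCT_P0:
        if y0 < 1:
            raise ValueError("nothing to deconstruct toward P0")
        return Phenotype(0 if mode == Mode.COMPLETE else y0 - 1, y1)
    if a == Action.DECONSTRUCT_P1:
        if y1 < 1:
            raise ValueError("nothing to deconstruct toward P1")
        return Phenotype(y0, 0 if mode == Mode.COMPLETE else y1 - 1)
    raise ValueError(f"unknown action {a!r}")


class Policy:
    """Solved optimal policy for one :class:`ModelParams` point.

    Holds exact state values and, for every reachable decision state, the
    full set of tied optimal actions. Decision states are indexed
    ``(t, n1, y0, y1)`` with ``t`` in ``1..t_ont`` counting cues observed at
    decision time (the cue-then-decide order of each period); the phenotype
    is the one held *before* acting.
    """

    def __init__(
        self,
        params: ModelParams,
        values: list[dict[tuple[int, int, int], float]],
        decisions: dict[DevState, tuple[float, tuple[Action, ...]]],
    ) -> None:
        self.params = params
        self._values = values  # per t: (n1, y0, y1) -> value after t decisions
        self._decisions = decisions

    @property
    def root_value(self) -> float:
        """Expected terminal fitness before the first cue is sampled."""
        return self._values[0][(0, 0, 0)]

    def value(self, t: int, n1: int, y0: int, y1: int) -> float:
        """Value of the post-decision state (t periods completed)."""
        return self._values[t][(n1, y0, y1)]

    def optimal_actions(self, t: int, n1: int, y0: int, y1: int) -> tuple[Action, ...]:
        """Tied optimal actions at a decision state (t-th cue just observed)."""
        return self._decisions[DevState(t, n1, y0, y1)][1]

    def decision_value(self, t: int, n1: int, y0: int, y1: int) -> float:
        return self._decisions[DevState(t, n1, y0, y1)][0]

    def decision_states(self) -> Iterator[DevState]:
        return iter(self._decisions)

    def states(self, t: int) -> Iterator[tuple[int, int, int]]:
        """Post-decision states (n1, y0, y1) reachable after ``t`` periods."""
        return iter(self._values[t])

    # Forward analyses ----------------------------------------------------

    def reach_probabilities(self, decision: bool = False) -> dict:
        """Occupancy probabilities under the policy with uniform tie-breaking.

        With ``decision=False`` (default), returns probabilities over
        post-decision states keyed ``(t, n1, y0, y1)``; probabilities at each
        ``t`` sum to one. With ``decision=True``, returns probabilities over
        decision states instead (the quantity behind decision-space plots).
        """
        p = self.params
        occ: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
        out: dict[tuple, float] = {}
        dec_out: dict[DevState, float] = {}
        for key, pr in occ.items():
            out[(0,) + key] = pr
        for t in range(p.t_ont):
            nxt: dict[tuple[int, int, int], float] = {}
            for (n1, y0, y1), prob in occ.items():
                belief = p.posterior(n1, t)
                pc1 = cue_predictive(belief, p.cues)
                for c, pc in ((1, pc1), (0, 1.0 - pc1)):
                    if pc <= 0.0:
                        continue
                    d = DevState(t + 1, n1 + c, y0, y1)
                    dec_out[d] = dec_out.get(d, 0.0) + prob * pc
                    acts = self._decisions[d][1]
                    w = prob * pc / len(acts)
                    for a in acts:
                        ph = apply_action(d, a, p.mode)
                        k = (n1 + c, ph.y0, ph.y1)
                        nxt[k] = nxt.get(k, 0.0) + w
            occ = nxt
            for key, pr in occ.items():
                out[(t + 1,) + key] = pr
        return dec_out if decision else out

    def expected_fitness(self) -> float:
        """Exact forward-pass expected terminal fitness (equals ``root_value``)."""
        p = self.params
        occ = self.reach_probabilities()
        total = 0.0
        for (t, n1, y0, y1), prob in occ.items():
            if t != p.t_ont:
                continue
            post = p.posterior(n1, p.t_ont)
            total += prob * expected_fitness(Phenotype(y0, y1), post, p.fitness)
        return total

    # Export --------------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable export of the decision space.

        Keys are ``"t,n1,y0,y1"`` decision states; each entry carries the
        state value, the tied optimal action set, the probability of reaching
        the state under the policy, and the posterior belief — the data
        behind decision-space (Fig-1 style) visualizations.
        """
        p = self.params
        reach = self.reach_probabilities(decision=True)
        states = {}
        for d, (val, acts) in self._decisions.items():
            states[f"{d.t},{d.n1},{d.y0},{d.y1}"] = {
                "value": val,
                "optimal_set": sorted(a.value for a in acts),
                "reach_probability": reach.get(d, 0.0),
                "posterior": p.posterior(d.n1, d.t),
            }
        return {
            "params": {
                "prior": p.prior.p_e1,
                "reliability": p.cues.reliability,
                "t_ont": p.t_ont,
                "reward_mapping": p.fitness.reward.kind,
                "penalty_mapping": p.fitness.penalty.kind,
                "beta": p.fitness.reward.beta,
                "baseline": p.fitness.baseline,
                "mode": p.mode.value,
            },
            "root_value": self.root_value,
            "states": states,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _reachable_layers(params: ModelParams) -> list[set[tuple[int, int, int]]]:
    """Forward-enumerate post-decision states (n1, y0, y1) per period."""
    layers: list[set[tuple[int, int, int]]] = [{(0, 0, 0)}]
    for t in range(params.t_ont):
        nxt: set[tuple[int, int, int]] = set()
        for n1, y0, y1 in layers[t]:
            belief = params.posterior(n1, t)
            pc1 = cue_predictive(belief, params.cues)
            ph = Phenotype(y0, y1)
            succ = [apply_action(ph, a, params.mode) for a in available_actions(ph, params.mode)]
            for c, pc in ((1, pc1), (0, 1.0 - pc1)):
                if pc <= 0.0:
                    continue
                for s in succ:
                    nxt.add((n1 + c, s.y0, s.y1))
        layers.append(nxt)
    return layers


def solve(params: ModelParams) -> Policy:
    """Compute the optimal policy by backward induction.

    Terminal values at ``t = t_ont`` are the expected fitness of the mature
    phenotype under the terminal posterior; earlier values take the
    posterior-predictive expectation over the next cue of the best available
    action's continuation value. All actions within the tie tolerance of the
    maximum are retained in the optimal set.
    """
    T = params.t_ont
    layers = _reachable_layers(params)
    values: list[dict[tuple[int, int, int], float]] = [dict() for _ in range(T + 1)]
    for n1, y0, y1 in layers[T]:
        post = params.posterior(n1, T)
        values[T][(n1, y0, y1)] = expected_fitness(Phenotype(y0, y1), post, params.fitness)
    decisions: dict[DevState, tuple[float, tuple[Action, ...]]] = {}
    for t in range(T - 1, -1, -1):
        vt1 = values[t + 1]
        for n1, y0, y1 in layers[t]:
            belief = params.posterior(n1, t)
            pc1 = cue_predictive(belief, params.cues)
            ph = Phenotype(y0, y1)
            acts = available_actions(ph, params.mode)
            val = 0.0
            for c, pc in ((1, pc1), (0, 1.0 - pc1)):
                if pc <= 0.0:
                    continue
                d = DevState(t + 1, n1 + c, y0, y1)
                cached = decisions.get(d)
                if cached is None:
                    qs = [
                        (vt1[(d.n1,) + apply_action(ph, a, params.mode)], a)
                        for a in acts
                    ]
                    vmax = max(q for q, _ in qs)
                    tol = TIE_REL_TOL * max(1.0, abs(vmax))
                    opt = tuple(a for q, a in qs if q >= vmax - tol)
                    cached = (vmax, opt)
                    decisions[d] = cached
                val += pc * cached[0]
            values[t][(n1, y0, y1)] = val
    return Policy(params, values, decisions)


def brute_force_value(params: ModelParams) -> float:
    """Optimal expected fitness by explicit expectimax enumeration.

    Recurses over every cue sequence and every feasible action sequence with
    no state merging or memoization; the belief is carried by sequential
    single-cue Bayes updates, a deliberately different computation path from
    the solver's count-based posterior. Cost grows as ``(2 * |actions|)^T``,
    so horizons above ``BRUTE_FORCE_MAX_T`` are refused. Testing oracle only.
    """
    T = params.t_ont
    if T > BRUTE_FORCE_MAX_T:
        raise ValueError(
            f"brute force refuses t_ont={T} > {BRUTE_FORCE_MAX_T}"
        )
    r = params.cues.reliability

    def update(belief: float, cue: int) -> float:
        like1 = r if cue == 1 else 1.0 - r
        like0 = 1.0 - r if cue == 1 else r
        z = belief * like1 + (1.0 - belief) * like0
        return belief * like1 / z

    def rec(t: int, belief: float, ph: Phenotype) -> float:
        if t == T:
            return expected_fitness(ph, belief, params.fitness)
        pc1 = cue_predictive(belief, params.cues)
        total = 0.0
        for c, pc in ((1, pc1), (0, 1.0 - pc1)):
            if pc <= 0.0:
                continue
            b = update(belief, c)
            best = max(
                rec(t + 1, b, apply_action(ph, a, params.mode))
                for a in available_actions(ph, params.mode)
            )
            total += pc * best
        return total

    return rec(0, params.prior.p_e1, Phenotype(0, 0))


def policy_expected_fitness(p: Policy, params: ModelParams | None = None) -> float:
    """Exact expected terminal fitness of a solved policy (forward pass)."""
    if params is not None and params is not p.params and params != p.params:
        raise ValueError("policy was solved for different parameters")
    return p.expected_fitness()


def reach_probabilities(p: Policy, params: ModelParams | None = None, decision: bool = False) -> dict:
    """State-occupancy probabilities under ``p`` (see :meth:`Policy.reach_probabilities`)."""
    if params is not None and params is not p.params and params != p.params:
        raise ValueError("policy was solved for different parameters")
    return p.reach_probabilities(decision=decision)
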
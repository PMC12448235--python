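# Methods

## Model

The environment is a binary latent state, fixed within a lifetime, drawn at
birth from the evolutionary prior `P(E1)`. Each of `T_ont` developmental
periods the organism samples one conditionally i.i.d. binary cue with
symmetric reliability `r ∈ [0.5, 1]`, then takes one action. The state of
the decision problem is `(t, n1, y0, y1)`: periods elapsed, C1-cue count,
and the net specialization counts toward the two phenotypic targets. Two
collapses make this exact and cheap: cue *order* is irrelevant to the
posterior (exchangeability), and the phenotype *path* is irrelevant to
terminal fitness (Markov sufficiency of the net counts). A 20-period
ontogeny has on the order of 10^5 states and solves in well under a second.

Each period follows a cue-then-decide order: the cue is observed, the
belief updated, then the action chosen. An organism therefore makes exactly
`T_ont` decisions and holds at most `T_ont` specializations at maturity,
which is what makes the mapping normalization `f(T_ont) = T_ont` the
attainable maximum.

Action regimes: `none` (construct/wait only), `incremental` (deconstruct
actions remove one increment), `complete` (deconstruct actions zero one
trait's count in a single period; the regimes are alternative model
versions, so `complete` replaces rather than augments the one-step
deconstructs). A deconstruct action is *unavailable* when its trait count
is zero rather than a silent no-op — otherwise it would artificially tie
with waiting everywhere.

Terminal fitness is `π0 + φ − ψ` with belief-weighted rewards on the
matched trait and penalties on the mismatched trait. Reward and penalty
carry independent mapping shapes (linear / diminishing / increasing,
curvature `β = 0.2`, each normalized to `f(T_ont) = T_ont`), so all nine
reward-penalty ecologies are expressible. The baseline `π0` defaults to 0
and shifts all values uniformly without changing any argmax. Construction
and deconstruction are cost-free; the only constraint is the finite
ontogeny. There is no mortality, no discounting, and no within-generation
environmental change, and organisms are assumed adapted to (not estimating)
the prior and reliability.

## Solver and numerics

Backward induction over forward-reachable states. Reachability is
enumerated first (cue branches with zero predictive probability are pruned,
which is what makes the `r = 1` limit well-defined), then values propagate
from the terminal layer. Posteriors are evaluated in log space with a
two-branch logistic so that long horizons at high reliability neither
underflow nor overflow; `r = 0.5` and `r = 1` and dogmatic priors are exact
special cases.

Two actions tie when their continuation values differ by at most
`1e-9 · max(1, |V_max|)`. Exact float equality would fragment genuinely
tied symmetric branches; a relative tolerance keeps e.g. the flat-prior
mirror ties intact. The full tied set is stored per state and the simulator
draws uniformly from it.

Two independent cross-checks guard the solver: a brute-force expectimax
oracle that enumerates every cue and action sequence with no memoization
(horizons ≤ 6; its belief is carried by sequential single-cue updates, a
different code path from the count-based posterior), and an exact forward
pass whose expected terminal fitness must reproduce the root value to
1e-12.

## Reference strategies

The construction-only policy is the optimum of the `none` regime. The
specialist constructs the prior's modal target every period; at a flat
prior the population splits in half between the targets and the population
mean is reported (both halves earn the same by symmetry). The generalist
holds `T_ont/2` on each trait, evaluated fractionally at odd durations; its
environmental weighting cancels, leaving `f_r(T/2) − f_p(T/2)` (zero for
equal mappings). Comparison plots normalize fitness by `T_ont` (so 1 is
perfect matching); because the normalization behind published comparisons
of this kind is not uniquely determined, an affine alternative mapping
`[-T_ont, T_ont] → [0, 1]` is available via `normalized_fitness(...,
scheme="affine")`. Both preserve ordering.

## Simulation and the clone-separation assay

Agents draw their true state from the prior (an override pins it for
conditional analyses), sample cues from the emission model, and follow the
policy with uniform tie-breaking. Four counters are kept per agent:
periods spent constructing each target (`y0C`, `y1C`) and periods spent
deconstructing each (`y0D`, `y1D`); in the complete regime `yxD` counts
deconstruction *periods*, not units removed. Conservation
(`constructs + deconstructs + waits = T_ont`) is asserted in tests.

The assay clones each agent at separation time `t ∈ {1..T_ont}`; the clone
inherits the full pre-`t` history and from period `t` receives the
complement of the original's cue, permanently or for a finite window
(temporary separation), after which it re-samples the original's cues.
Distances are measured at the end of ontogeny by default or right after the
window closes. Three normalized Euclidean distances are averaged over the
10,000 pairs: net phenotype and construction counters divided by
`2·sqrt(T_ont)`, deconstruction counters by `2·sqrt(T_ont/2)`. These
denominators are smaller than the maximal possible distance
`T_ont·sqrt(2)`, so curves may exceed 1; `SeparationScheme(normalizer="max")`
selects the maximal-distance normalization instead. The assay is undefined
at `r = 1`, where complementary cues are impossible, and the package
refuses it rather than extrapolating.

Randomness: all cue and tie-break draws come from bulk matrices generated
from seeded `SeedSequence` streams, one row per agent; clones use a stream
keyed by the separation time, independent of the originals' draws, so
original and clone behave identically before separation and break ties
independently after it (whether real clones would share tie-break noise is
undecidable from the model; independence is the weaker assumption).

## What the simulations do and do not show

The generator *is* the model's ecology: binary state, symmetric
conditionally i.i.d. cues, fitness only at maturity. Passing tests
demonstrate internal optimality and the qualitative structure of sensitive
periods under those assumptions — they say nothing about organisms facing
autocorrelated cues, within-life environmental change, costly plasticity,
or graded environments, all of which are outside the model class.

## Problem sizes and defaults

Defaults mirror the standard parameter grid: priors {0.5, 0.7, 0.9},
reliabilities {0.55, 0.75, 0.95}, durations {5, 10, 20}, 10,000 agents per
simulated condition. The test suite exercises full 10,000-agent assays at
`T_ont = 10` for the headline shape checks and smaller populations
(200–4,000) for distributional unit tests, sized so the entire suite runs
in seconds while keeping Monte-Carlo error well inside the asserted
margins (3 standard errors where a mean is compared to an exact value).

## Known limitations

* Curves under the default normalizer are not bounded by 1 (see above).
* The deconstruction-prevalence statistic is defined as the fraction of
  simulated organisms whose history contains at least one deconstruct
  action; per-period frequencies would be an alternative reading and can be
  derived from the exported phenotype tables.
* The tie tolerance is a numerical choice; policies at knife-edge parameter
  values (exact ties broken by float rounding) should be checked at a
  tightened tolerance before interpretation.
* The brute-force oracle is exponential and intentionally refuses horizons
  above 6.
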
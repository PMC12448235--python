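"""Solve one optimal developmental policy and inspect its decision space.

An organism develops for 10 periods at a flat prior (P(E1) = 0.5) with
moderately reliable cues (0.75), able to deconstruct one specialization per
period. We solve the policy exactly and look at what it prescribes.
"""

from replast import ModelParams, brute_force_value, solve

params = ModelParams.make(prior=0.5, reliability=0.75, t_ont=10, mode="incremental")
policy = solve(params)

print(f"root value (expected terminal fitness): {policy.root_value:.4f}")
print(f"  -> {policy.root_value / params.t_ont:.1%} of the perfect-matching maximum")

# A tiny cell where the optimum can be checked by hand (and by brute force):
small = ModelParams.make(prior=0.5, reliability=0.75, t_ont=2, mode="incremental")
print(f"\nT=2 root value: {solve(small).root_value:.4f} "
      f"(expectimax oracle: {brute_force_value(small):.4f})")
print("Interpretation: construct toward the first cue; with probability 0.625 the")
print("second cue agrees (posterior 0.9, fitness 1.6), else all options tie at 0.")

# What does the policy do after three agreeing cues, holding two specializations?
state = (3, 3, 0, 2)  # t=3 cues seen, all C1, phenotype (y0=0, y1=2)
acts = policy.optimal_actions(*state)
post = params.posterior(3, 3)
print(f"\nafter 3 C1 cues (posterior {post:.3f}) holding (0,2): "
      f"optimal actions = {[a.value for a in acts]}")

# And in a conflicted state: 2 C1 + 2 C0 cues while specialized toward P1.
state = (4, 2, 0, 2)
acts = policy.optimal_actions(*state)
print(f"after 2 C1 + 2 C0 cues (posterior {params.posterior(2, 4):.2f}) holding (0,2): "
      f"optimal actions = {[a.value for a in acts]}")
print("Ties are resolved uniformly at random during development.")
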
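"""How much fitness does the ability to deconstruct buy?

Compares optimal policies under the three action regimes with two
non-plastic references at an environmentally uncertain cell (flat prior,
moderately reliable cues, 10-period ontogeny).
"""

from replast import (
    ModelParams,
    generalist_fitness,
    normalized_fitness,
    solve,
    specialist_fitness,
)

cell = dict(prior=0.5, reliability=0.75, t_ont=10)

print(f"{'strategy':<28}{'fitness':>10}{'normalized':>12}")
for mode in ("none", "incremental", "complete"):
    p = ModelParams.make(mode=mode, **cell)
    v = solve(p).root_value
    print(f"{'optimal (' + mode + ')':<28}{v:>10.4f}{normalized_fitness(v, p):>12.4f}")

p = ModelParams.make(**cell)
for name, fn in (("specialist", specialist_fitness), ("generalist", generalist_fitness)):
    v = fn(p)
    print(f"{name:<28}{v:>10.4f}{normalized_fitness(v, p):>12.4f}")

print("\nIncremental deconstruction matches the construction-only optimum (it is")
print("only chosen in ties); complete deconstruction adds a small advantage by")
print("letting late, better-informed organisms erase a misbuilt trait at once.")
print("All plastic policies dwarf the non-plastic references under uncertainty.")
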
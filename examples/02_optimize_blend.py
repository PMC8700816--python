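"""Find the blend that jointly minimizes all four responses.

Fits the four published response-surface models (droplet size and DPPH
IC50 on the sqrt scale, both colony counts raw), builds minimize-goals
bounded by each response's observed range, and maximizes the geometric-
mean (Derringer-Suich) desirability over the three-oil composition
simplex.  The overall desirability D is 1 only where every response sits
at its observed best, and 0 wherever any response is at its observed
worst.
"""

from mixsurf import DesirabilityGoal, fit, optimize
from mixsurf.datasets import RESPONSES, load_nanoemulsion, published_models

design, responses = load_nanoemulsion()
fits = {
    name: fit(design, responses[name], spec)
    for name, spec in published_models().items()
}
goals = {
    name: DesirabilityGoal(
        "minimize", float(responses[name].min()), float(responses[name].max())
    )
    for name in RESPONSES
}

opt = optimize(fits, goals, grid_step=0.005)
names = design.component_names
print("optimal lipid-phase composition:")
for n, pct in zip(names, opt.percentages):
    print(f"  {n}: {pct:.2f}%")
print(f"overall desirability D = {opt.overall:.4f}")
for name in fits:
    print(
        f"  {name}: predicted {opt.predictions[name]:.4g} "
        f"(individual desirability {opt.individual[name]:.3f})"
    )
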
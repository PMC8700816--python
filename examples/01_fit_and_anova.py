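"""Fit a Scheffe mixture model and read its ANOVA.

Loads the bundled 17-run essential-oil nanoemulsion study, fits the
8-term reduced-cubic model for the Sauter mean droplet diameter on the
square-root scale, and prints the fitted equation, fit statistics and the
mixture ANOVA.  The lack-of-fit F compares model misfit against the
pure-error scatter of the replicated runs; a non-significant value (p >
0.05) means the polynomial is adequate for these data.
"""

from mixsurf import ModelSpec, anova, fit, parse_term
from mixsurf.datasets import load_nanoemulsion, published_anova_terms

design, responses = load_nanoemulsion()
spec = ModelSpec(
    "d32_um",
    [parse_term(t) for t in published_anova_terms()["d32_um"]],
    transform="sqrt",
    units="um",
)
res = fit(design, responses["d32_um"], spec)

print(res.equation())
print(
    f"R2 = {100 * res.r2:.2f}%  R2_adj = {100 * res.r2_adj:.2f}%  "
    f"R2_pred = {100 * res.r2_pred:.2f}%  SD = {res.sd:.4f}"
)
print()
print(anova(res).to_text())
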
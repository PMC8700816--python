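"""Simulate responses from a known surface and recover it by refitting.

Generates a synthetic response table on the bundled 17-run design from a
quadratic Scheffe surface with Gaussian noise on the sqrt scale, refits
the full model, and backward-eliminates non-significant interaction
terms.  With a noiseless draw the coefficients come back exactly; with
noise, the model-reduction step should keep only genuinely non-zero
terms.
"""

import numpy as np

from mixsurf import (
    ModelSpec,
    SimulationConfig,
    fit,
    reduce_model,
    scheffe_terms,
    simulate_responses,
    term_name,
)
from mixsurf.datasets import load_nanoemulsion

design, _ = load_nanoemulsion()
truth = np.array([3.3, 3.1, 4.0, 0.0, 0.0, -2.2])  # AB and AC truly absent
spec = ModelSpec("y", scheffe_terms(3, "quadratic"), transform="sqrt")
cfg = SimulationConfig(
    design=design,
    models={"y": spec},
    coefficients={"y": truth.copy()},
    noise_sd={"y": 0.05},
    seed=7,
)
table = simulate_responses(cfg)
print("simulated responses (first 5 runs):")
print(table.head().round(3))

full = fit(design, table["y"], spec)
print(f"\nfull-model coefficients: {np.round(full.coefficients, 3)}")
reduced = reduce_model(design, table["y"], spec, alpha=0.05)
print("terms kept after backward elimination:",
      [term_name(t) for t in reduced.terms])
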
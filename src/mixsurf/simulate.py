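"""Synthetic mixture-design datasets with known ground truth.

Responses are generated from a Scheffe surface on the model's transformed
scale with additive Gaussian noise, then back-transformed — the same
structure the fitting machinery assumes, so simulated datasets exercise
every stage (fitting, ANOVA, model reduction, optimization) with a known
answer.  Noise on the transformed scale means original-scale noise is
skewed for sqrt/log models, as in the real assays these surfaces model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .models import ModelSpec, model_matrix

__all__ = ["SimulationConfig", "simulate_responses"]

#: default transformed-scale noise levels giving fits of realistic quality
#: (residual mean squares comparable to the bundled study's ANOVA tables)
DEFAULT_NOISE_SD = 0.05


@dataclass
class SimulationConfig:
    """A design plus, per response, a true model, coefficients and noise level.

    ``coefficients[name]`` is the true coefficient vector on the
    transformed scale of ``models[name]``; ``noise_sd[name]`` is the
    Gaussian noise standard deviation on that same scale.
    """

    design: MixtureDesign
    models: dict[str, ModelSpec]
    coefficients: dict[str, np.ndarray]
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, spec in self.models.items():
            beta = np.asarray(self.coefficients[name], dtype=float)
            if beta.shape != (len(spec.terms),):
                raise ValueError(
                    f"{name}: coefficient vector length {beta.shape} does not "
                    f"match the {len(spec.terms)} model terms"
                )
            self.coefficients[name] = beta
            sd = self.noise_sd.setdefault(name, DEFAULT_NOISE_SD)
            if sd < 0:
                raise ValueError(f"{name}: noise_sd must be non-negative")


def simulate_responses(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw one response table from the configured true surfaces.

    For each run, transformed response = model row . coefficients +
    N(0, noise_sd), back-transformed to original units.  Deterministic
    given ``cfg.seed``.  A draw that is negative on the sqrt scale (so its
    back-transform would be ill-defined as a monotone map) is resampled
    once, then clamped to zero with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    X = cfg.design.as_array()
    out = {}
    for name, spec in cfg.models.items():
        mean = model_matrix(X, spec.terms) @ cfg.coefficients[name]
        sd = cfg.noise_sd[name]
        z = mean + rng.normal(0.0, sd, size=mean.shape) if sd > 0 else mean.copy()
        if spec.transform.name in ("sqrt", "ln", "inverse_sqrt"):
            bad = z <= 0 if spec.transform.name != "sqrt" else z < 0
            if bad.any():
                z[bad] = mean[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
                still = z < 0 if spec.transform.name == "sqrt" else z <= 0
                if still.any():
                    warnings.warn(
                        f"{name}: {int(still.sum())} transformed draw(s) clamped at 0",
                        RuntimeWarning,
                    )
                    z[still] = 0.0 if spec.transform.name == "sqrt" else np.nan
        out[name] = np.asarray(spec.transform.inverse(z), dtype=float)
    return pd.DataFrame(out, index=pd.Index(cfg.design.run_ids, name="run"))
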
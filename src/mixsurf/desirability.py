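"""Derringer-Suich desirability functions and multi-response optimization.

Each fitted response surface is mapped to an individual desirability
d in [0, 1] by a monotone ramp encoding its goal (minimize, maximize, hit
a target, or stay in range); the overall desirability is the importance-
weighted geometric mean, so a single infeasible response vetoes a blend.
The optimum is located by dense evaluation on a barycentric grid of the
composition simplex followed by derivative-free polish of the best grid
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import Blend, simplex_grid
from .fit import FitResult
from .models import model_matrix

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability_value",
    "overall_desirability",
    "optimize",
    "desirability_grid",
]


@dataclass
class DesirabilityGoal:
    """Goal parameters for one response (Derringer-Suich form).

    ``low``/``high`` bound the acceptable range in response units;
    ``target`` defaults to ``low`` for minimize and ``high`` for maximize.
    ``weight`` shapes the ramp (1 = linear); ``importance`` is the
    geometric-mean exponent.
    """

    direction: str  # minimize | maximize | target | in_range
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize", "target", "in_range"):
            raise ValueError(f"unknown goal direction {self.direction!r}")
        if self.low > self.high:
            raise ValueError("low bound exceeds high bound")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.importance < 1:
            raise ValueError("importance must be >= 1")
        if self.target is None:
            self.target = self.low if self.direction == "minimize" else self.high
        if not self.low <= self.target <= self.high:
            raise ValueError("target must lie within [low, high]")


def desirability_value(yhat, goal: DesirabilityGoal):
    """Individual desirability of predicted value(s) under ``goal``; in [0, 1]."""
    y = np.asarray(yhat, dtype=float)
    L, T, U, w = goal.low, goal.target, goal.high, goal.weight
    if goal.direction == "minimize":
        if U == T:
            raise ValueError("degenerate minimize goal: high == target (zero-width ramp)")
        d = np.clip((U - y) / (U - T), 0.0, 1.0) ** w
    elif goal.direction == "maximize":
        if T == L:
            raise ValueError("degenerate maximize goal: target == low (zero-width ramp)")
        d = np.clip((y - L) / (T - L), 0.0, 1.0) ** w
    elif goal.direction == "target":
        if T == L or U == T:
            raise ValueError("degenerate target goal: zero-width ramp")
        left = np.clip((y - L) / (T - L), 0.0, 1.0)
        right = np.clip((U - y) / (U - T), 0.0, 1.0)
        d = np.where(y <= T, left, right) ** w
    else:  # in_range
        d = ((y >= L) & (y <= U)).astype(float)
    d = np.clip(d, 0.0, 1.0)
    return float(d) if np.isscalar(yhat) else d


def overall_desirability(ds, importances=None) -> float:
    """Importance-weighted geometric mean ``(prod d_i^r_i)^(1/sum r_i)``."""
    d = np.asarray(ds, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("individual desirabilities must lie in [0, 1]")
    r = np.ones_like(d) if importances is None else np.asarray(importances, float)
    if (d == 0).any():
        return 0.0
    return float(np.exp((r * np.log(d)).sum() / r.sum()))


@dataclass
class OptimizationResult:
    """The argmax blend with its overall and per-response desirabilities."""

    blend: Blend
    overall: float
    predictions: dict[str, float]
    individual: dict[str, float]
    grid_step: float
    n_polished: int
    seed: int
    grid_best: float = np.nan
    feasible: bool = True

    @property
    def percentages(self) -> tuple[float, ...]:
        return tuple(100.0 * f for f in self.blend.fractions)


def _predict_batch(fitres: FitResult, X: np.ndarray) -> np.ndarray:
    """Back-transformed predictions at every row of the (n, q) grid."""
    z = model_matrix(X, fitres.model.terms) @ fitres.coefficients
    if fitres.model.transform.name == "sqrt":
        z = np.clip(z, 0.0, None)
    return np.asarray(fitres.model.transform.inverse(z), dtype=float)


def _overall_batch(fits, goals, X: np.ndarray) -> np.ndarray:
    logd = np.zeros(X.shape[0])
    dead = np.zeros(X.shape[0], dtype=bool)
    rsum = 0.0
    for name, fr in fits.items():
        g = goals[name]
        d = desirability_value(_predict_batch(fr, X), g)
        dead |= d == 0
        with np.errstate(divide="ignore"):
            logd += g.importance * np.where(d > 0, np.log(d), 0.0)
        rsum += g.importance
    D = np.exp(logd / rsum)
    D[dead] = 0.0
    return D


def optimize(
    fits: dict[str, FitResult],
    goals: dict[str, DesirabilityGoal],
    grid_step: float = 0.005,
    n_polish: int = 10,
    seed: int = 0,
) -> OptimizationResult:
    """Maximize overall desirability over the composition simplex.

    Evaluates every barycentric grid point at spacing ``grid_step``, then
    polishes the ``n_polish`` best grid points with Nelder-Mead in the
    q-1 free coordinates (projected back onto the simplex).  Deterministic
    given ``seed``; the grid/polish scheme itself uses no randomness, the
    seed is recorded for replay metadata.
    """
    names = list(fits)
    if set(goals) != set(names):
        raise ValueError("fits and goals must cover the same responses")
    q = fits[names[0]].design.q
    if any(fr.design.q != q for fr in fits.values()):
        raise ValueError("all fitted models must share one component basis")

    grid = simplex_grid(q, grid_step)
    D = _overall_batch(fits, goals, grid)
    grid_best = float(D.max())
    feasible = grid_best > 0.0

    def neg_overall(free: np.ndarray) -> float:
        x = np.append(free, 1.0 - free.sum())
        if (x < -1e-9).any():
            return 1.0  # outside the simplex
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s <= 0:
            return 1.0
        return -float(_overall_batch(fits, goals, (x / s)[None, :])[0])

    best_x = grid[int(np.argmax(D))]
    best_val = grid_best
    if feasible:
        top = np.argsort(-D)[:n_polish]
        for i in top:
            res = minimize(
                neg_overall,
                grid[i][: q - 1],
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
            )
            if -res.fun > best_val:
                free = np.clip(np.append(res.x, 1.0 - res.x.sum()), 0.0, None)
                best_x = free / free.sum()
                best_val = -res.fun

    blend = Blend(best_x)
    preds = {n: _predict_batch(fr, blend.as_array()[None, :]).item() for n, fr in fits.items()}
    indiv = {n: float(desirability_value(preds[n], goals[n])) for n in names}
    return OptimizationResult(
        blend=blend,
        overall=best_val,
        predictions=preds,
        individual=indiv,
        grid_step=grid_step,
        n_polished=n_polish if feasible else 0,
        seed=seed,
        grid_best=grid_best,
        feasible=feasible,
    )


def desirability_grid(
    fits: dict[str, FitResult],
    goals: dict[str, DesirabilityGoal],
    grid_step: float = 0.02,
) -> pd.DataFrame:
    """Numeric ternary/simplex grid for external contour plotting.

    Columns: the q fractions, one prediction and one desirability column
    per response, and the overall desirability ``D``.
    """
    names = list(fits)
    q = fits[names[0]].design.q
    grid = simplex_grid(q, grid_step)
    comp = fits[names[0]].design.component_names
    out = pd.DataFrame(grid, columns=comp)
    for n in names:
        yhat = _predict_batch(fits[n], grid)
        out[f"yhat_{n}"] = yhat
        out[f"d_{n}"] = desirability_value(yhat, goals[n])
    out["D"] = _overall_batch(fits, goals, grid)
    return out
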
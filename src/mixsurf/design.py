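"""Experimental designs on the composition simplex.

A mixture experiment varies the *proportions* of q components under the
constraint that the proportions sum to one, so the design region is the
(q-1)-simplex rather than a hypercube.  This module provides the design
containers (:class:`Blend`, :class:`MixtureDesign`), candidate-point
generation, the I-optimality criterion (average scaled prediction variance
over the simplex), a point-exchange search for I-efficient run subsets, and
replicate augmentation so that fitted models carry pure-error degrees of
freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Blend",
    "MixtureDesign",
    "CandidateSet",
    "simplex_grid",
    "candidate_set",
    "i_criterion",
    "coordinate_exchange",
    "augment_replicates",
]

#: tolerance on the sum of input fractions before renormalization
SUM_TOL = 1e-5
#: tolerance at which two blends are considered the same composition
MATCH_TOL = 1e-6


@dataclass(frozen=True)
class Blend:
    """A point on the composition simplex: q fractions summing to 1.

    Input fractions may be off by up to ``1e-5`` in their sum (rounding in
    published tables); they are renormalized to sum exactly to 1.
    """

    fractions: tuple[float, ...]

    def __init__(self, fractions) -> None:
        arr = np.asarray(fractions, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a blend needs at least two component fractions")
        if (arr < -1e-12).any():
            raise ValueError(f"negative fraction in blend {arr.tolist()}")
        total = arr.sum()
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(
                f"fractions sum to {total:.6g}, not 1 (tolerance {SUM_TOL:g})"
            )
        arr = np.clip(arr, 0.0, None) / arr.sum()
        object.__setattr__(self, "fractions", tuple(arr.tolist()))

    @property
    def q(self) -> int:
        return len(self.fractions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def matches(self, other: "Blend", tol: float = MATCH_TOL) -> bool:
        return (
            self.q == other.q
            and max(abs(a - b) for a, b in zip(self.fractions, other.fractions)) <= tol
        )


@dataclass
class MixtureDesign:
    """An ordered list of blends with run labels and replicate structure.

    ``replicate_groups`` partitions run indices into groups of identical
    compositions (equality at 1e-6 after renormalization); it is derived
    automatically and yields the pure-error degrees of freedom
    ``sum(len(g) - 1)`` used by the lack-of-fit ANOVA.
    """

    runs: list[Blend]
    run_ids: list[str] = field(default_factory=list)
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("design has no runs")
        q = self.runs[0].q
        if any(b.q != q for b in self.runs):
            raise ValueError("all blends must have the same number of components")
        if not self.run_ids:
            self.run_ids = [str(i + 1) for i in range(len(self.runs))]
        if len(self.run_ids) != len(self.runs):
            raise ValueError("run_ids length must match number of runs")
        if not self.component_names:
            self.component_names = [f"x{i + 1}" for i in range(q)]
        if len(self.component_names) != q:
            raise ValueError("component_names length must match component count")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def q(self) -> int:
        return self.runs[0].q

    def as_array(self) -> np.ndarray:
        """(n_runs, q) array of renormalized fractions."""
        return np.array([b.fractions for b in self.runs], dtype=float)

    @property
    def replicate_groups(self) -> list[list[int]]:
        """Partition of run indices into groups of identical blends."""
        groups: list[list[int]] = []
        for i, b in enumerate(self.runs):
            for g in groups:
                if b.matches(self.runs[g[0]]):
                    g.append(i)
                    break
            else:
                groups.append([i])
        return groups

    @property
    def n_distinct(self) -> int:
        return len(self.replicate_groups)

    @property
    def pure_error_df(self) -> int:
        return self.n_runs - self.n_distinct


@dataclass
class CandidateSet:
    """Candidate blends for design construction (lattice + interior points)."""

    blends: list[Blend]

    def __post_init__(self) -> None:
        if not self.blends:
            raise ValueError("candidate set is empty")
        q = self.blends[0].q
        # must contain every vertex so any Scheffe model is estimable in principle
        for i in range(q):
            vertex = Blend(tuple(1.0 if j == i else 0.0 for j in range(q)))
            if not any(b.matches(vertex) for b in self.blends):
                raise ValueError(f"candidate set is missing vertex {i + 1}")

    @property
    def q(self) -> int:
        return self.blends[0].q

    def as_array(self) -> np.ndarray:
        return np.array([b.fractions for b in self.blends], dtype=float)


def _dedupe(blends: list[Blend], tol: float = MATCH_TOL) -> list[Blend]:
    out: list[Blend] = []
    for b in blends:
        if not any(b.matches(o, tol) for o in out):
            out.append(b)
    return out


def simplex_grid(q: int, step: float) -> np.ndarray:
    """All barycentric grid points of the (q-1)-simplex with spacing ``step``.

    Returns an (n_points, q) array; ``1/step`` must be (close to) an integer.
    """
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer for a barycentric grid")
    pts = []
    for combo in itertools.combinations(range(m + q - 1), q - 1):
        # stars and bars: counts between the chosen bars
        prev = -1
        counts = []
        for c in combo:
            counts.append(c - prev - 1)
            prev = c
        counts.append(m + q - 2 - prev)
        pts.append([c / m for c in counts])
    return np.asarray(pts, dtype=float)


def candidate_set(q: int, lattice_levels) -> CandidateSet:
    """Lattice-based candidate points plus centroid and axial check blends.

    Enumerates every simplex point whose coordinates are all drawn from
    ``lattice_levels`` and sum to 1, then adds the overall centroid and the
    q axial points (centroid shifted halfway toward each vertex), and
    deduplicates at 1e-6.
    """
    if q < 2:
        raise ValueError("need at least two mixture components")
    levels = sorted(set(float(v) for v in lattice_levels))
    if not levels:
        raise ValueError("empty lattice: no usable candidate basis")
    if any(v < 0 or v > 1 for v in levels):
        raise ValueError("lattice levels must lie in [0, 1]")

    blends: list[Blend] = []
    for combo in itertools.product(levels, repeat=q):
        if abs(sum(combo) - 1.0) <= SUM_TOL:
            blends.append(Blend(combo))
    centroid = np.full(q, 1.0 / q)
    blends.append(Blend(centroid))
    for i in range(q):
        vertex = np.zeros(q)
        vertex[i] = 1.0
        blends.append(Blend((centroid + vertex) / 2.0))
    return CandidateSet(_dedupe(blends))


def _information_inverse(X: np.ndarray) -> np.ndarray:
    xtx = X.T @ X
    # reciprocal condition below 1e-10 means the model is not estimable
    if np.linalg.cond(xtx) > 1e10:
        raise np.linalg.LinAlgError(
            "design is rank-deficient for this model (non-estimable)"
        )
    return np.linalg.inv(xtx)


def i_criterion(design: MixtureDesign, terms, eval_grid: np.ndarray | None = None) -> float:
    """Average scaled prediction variance of ``design`` for a Scheffe model.

    Computes ``mean over g of f(g)' (X'X)^-1 f(g)`` where f is the term
    expansion and X the design model matrix.  ``eval_grid`` defaults to a
    uniform barycentric grid of step 0.02.  Lower is better (I-optimality).
    """
    from .models import model_matrix

    X = model_matrix(design.as_array(), terms)
    if X.shape[0] < X.shape[1]:
        raise np.linalg.LinAlgError("fewer runs than model terms: criterion undefined")
    inv = _information_inverse(X)
    if eval_grid is None:
        eval_grid = simplex_grid(design.q, 0.02)
    F = model_matrix(np.asarray(eval_grid, dtype=float), terms)
    return float(np.mean(np.einsum("ij,jk,ik->i", F, inv, F)))


def coordinate_exchange(
    candidates: CandidateSet,
    n_runs: int,
    terms,
    n_starts: int = 10,
    seed: int = 0,
    eval_grid: np.ndarray | None = None,
) -> MixtureDesign:
    """Greedy point-exchange search for an I-efficient n-run design.

    From each of ``n_starts`` random initial subsets, repeatedly swap one
    design run for one candidate whenever the I-criterion strictly
    decreases, until no improving swap exists; the best design over all
    starts is returned.  Deterministic given ``seed``.
    """
    from .models import model_matrix

    cand = candidates.as_array()
    n_cand = cand.shape[0]
    p = len(list(terms))
    if n_runs < p:
        raise ValueError(f"n_runs={n_runs} is below the {p} model terms: infeasible")
    if n_runs > n_cand:
        raise ValueError("n_runs exceeds the number of candidate blends")
    if eval_grid is None:
        eval_grid = simplex_grid(candidates.q, 0.02)
    Fc = model_matrix(cand, terms)
    Fg = model_matrix(np.asarray(eval_grid, dtype=float), terms)

    def crit(idx: np.ndarray) -> float:
        X = Fc[idx]
        try:
            inv = _information_inverse(X)
        except np.linalg.LinAlgError:
            return np.inf
        return float(np.mean(np.einsum("ij,jk,ik->i", Fg, inv, Fg)))

    rng = np.random.default_rng(seed)
    best_idx, best_val = None, np.inf
    if n_runs == n_cand:
        best_idx, best_val = np.arange(n_cand), crit(np.arange(n_cand))
    else:
        for _ in range(n_starts):
            idx = rng.choice(n_cand, size=n_runs, replace=False)
            val = crit(idx)
            improved = True
            while improved:
                improved = False
                for pos in range(n_runs):
                    for c in range(n_cand):
                        trial = idx.copy()
                        trial[pos] = c
                        v = crit(trial)
                        if v < val - 1e-12:
                            idx, val = trial, v
                            improved = True
            if val < best_val:
                best_idx, best_val = idx, val
    if best_idx is None or not np.isfinite(best_val):
        raise np.linalg.LinAlgError("no estimable design found from candidates")
    blends = [candidates.blends[i] for i in np.sort(best_idx)]
    return MixtureDesign(runs=blends)


def augment_replicates(
    design: MixtureDesign, n_total: int, terms=None, policy: str = "leverage"
) -> MixtureDesign:
    """Duplicate existing runs until the design has ``n_total`` runs.

    Replicates supply the pure-error degrees of freedom needed for the
    lack-of-fit test.  The centroid (the most interior blend) is replicated
    first; remaining slots go to the highest-leverage blends under
    ``terms`` (default: the linear Scheffe terms), cycling if needed.
    """
    if n_total < design.n_runs:
        raise ValueError("n_total is below the current run count")
    if n_total == design.n_runs:
        return design
    from .models import model_matrix, scheffe_terms

    if terms is None:
        terms = scheffe_terms(design.q, "linear")
    X = model_matrix(design.as_array(), terms)
    H = X @ _information_inverse(X) @ X.T
    lev = np.diag(H)

    arr = design.as_array()
    centroid_dist = np.abs(arr - 1.0 / design.q).sum(axis=1)
    order = [int(np.argmin(centroid_dist))]
    for i in np.argsort(-lev):
        if int(i) not in order:
            order.append(int(i))

    runs = list(design.runs)
    ids = list(design.run_ids)
    k = 0
    while len(runs) < n_total:
        src = order[k % len(order)]
        runs.append(design.runs[src])
        ids.append(f"{design.run_ids[src]}r{k + 1}")
        k += 1
    return MixtureDesign(runs=runs, run_ids=ids, component_names=design.component_names)
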
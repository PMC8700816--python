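"""Scheffe mixture-polynomial terms, model matrices and response transforms.

Because mixture fractions sum to one, Scheffe canonical polynomials carry
no intercept: the linear blending part is ``sum_i beta_i x_i``, binary
synergy/antagonism enters through ``beta_ij x_i x_j``, and asymmetric
binary curvature through the cubic difference terms
``delta_ij x_i x_j (x_i - x_j)``.  Responses may be modeled on a
transformed scale (square root, log, ...); the transform is part of the
model specification and predictions are back-transformed.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TermSpec",
    "ResponseTransform",
    "ModelSpec",
    "TRANSFORMS",
    "get_transform",
    "scheffe_terms",
    "model_matrix",
    "parse_term",
    "term_name",
]

_KINDS = ("linear", "quadratic", "cubic_diff", "cubic_triple")


@dataclass(frozen=True)
class TermSpec:
    """One term of a Scheffe polynomial, identified by kind and component indices.

    kinds: ``linear`` (x_i), ``quadratic`` (x_i x_j), ``cubic_diff``
    (x_i x_j (x_i - x_j)), ``cubic_triple`` (x_i x_j x_k); indices are
    0-based and strictly increasing.
    """

    kind: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        n_expected = {"linear": 1, "quadratic": 2, "cubic_diff": 2, "cubic_triple": 3}
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) != n_expected[self.kind]:
            raise ValueError(f"{self.kind} term needs {n_expected[self.kind]} indices")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("term indices must be strictly increasing")

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the term at each row of the (n, q) fraction matrix."""
        X = np.asarray(X, dtype=float)
        if self.kind == "linear":
            (i,) = self.indices
            return X[:, i]
        if self.kind == "quadratic":
            i, j = self.indices
            return X[:, i] * X[:, j]
        if self.kind == "cubic_diff":
            i, j = self.indices
            return X[:, i] * X[:, j] * (X[:, i] - X[:, j])
        i, j, k = self.indices
        return X[:, i] * X[:, j] * X[:, k]

    @property
    def is_linear(self) -> bool:
        return self.kind == "linear"


def term_name(term: TermSpec, aliases: Sequence[str] = "ABCDEFGH") -> str:
    """Conventional name of a term, e.g. ``A``, ``AB``, ``AB(A-B)``, ``ABC``."""
    a = [aliases[i] for i in term.indices]
    if term.kind == "linear":
        return a[0]
    if term.kind == "quadratic":
        return a[0] + a[1]
    if term.kind == "cubic_diff":
        return f"{a[0]}{a[1]}({a[0]}-{a[1]})"
    return "".join(a)


def parse_term(name: str, aliases: Sequence[str] = "ABCDEFGH") -> TermSpec:
    """Parse names like ``"A"``, ``"AB"``, ``"AB(A-B)"``, ``"ABC"``.

    Separators ``*`` and spaces are ignored, so ``"A*B (A-B)"`` also parses.
    """
    s = re.sub(r"[\s*]", "", name)
    lookup = {c: i for i, c in enumerate(aliases)}
    m = re.fullmatch(r"([A-Za-z])([A-Za-z])\((\1)-(\2)\)", s)
    if m:
        return TermSpec("cubic_diff", (lookup[m.group(1)], lookup[m.group(2)]))
    if not s.isalpha():
        raise ValueError(f"cannot parse term {name!r}")
    idx = tuple(lookup[c] for c in s)
    if len(idx) == 1:
        return TermSpec("linear", idx)
    if len(idx) == 2:
        return TermSpec("quadratic", idx)
    if len(idx) == 3:
        return TermSpec("cubic_triple", idx)
    raise ValueError(f"cannot parse term {name!r}")


def scheffe_terms(q: int, degree: str = "quadratic") -> list[TermSpec]:
    """Canonical term sets: ``linear``, ``quadratic``, ``special_cubic``
    (quadratic + triple products), ``reduced_cubic`` (quadratic + all
    cubic difference terms), ``full_cubic`` (reduced cubic + triples)."""
    linear = [TermSpec("linear", (i,)) for i in range(q)]
    pairs = list(itertools.combinations(range(q), 2))
    quad = [TermSpec("quadratic", p) for p in pairs]
    cdiff = [TermSpec("cubic_diff", p) for p in pairs]
    triples = [TermSpec("cubic_triple", t) for t in itertools.combinations(range(q), 3)]
    if degree == "linear":
        return linear
    if degree == "quadratic":
        return linear + quad
    if degree == "special_cubic":
        return linear + quad + triples
    if degree == "reduced_cubic":
        return linear + quad + cdiff
    if degree == "full_cubic":
        return linear + quad + cdiff + triples
    raise ValueError(f"unknown degree {degree!r}")


def model_matrix(X: np.ndarray, terms: Sequence[TermSpec]) -> np.ndarray:
    """(n_runs, n_terms) Scheffe model matrix; no intercept column.

    ``X`` is an (n, q) array of fractions (rows summing to 1).
    """
    terms = list(terms)
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in model")
    if not terms:
        raise ValueError("empty term list")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([t.evaluate(X) for t in terms])


@dataclass(frozen=True)
class ResponseTransform:
    """A strictly monotone response transform with its inverse."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]

    def __call__(self, y):
        return self.forward(np.asarray(y, dtype=float))


def _power_transform(lam: float) -> ResponseTransform:
    if abs(lam) < 1e-12:
        raise ValueError("power(0) is the log transform; use 'ln'")
    return ResponseTransform(
        f"power({lam:g})", lambda y: np.asarray(y, float) ** lam,
        lambda z: np.asarray(z, float) ** (1.0 / lam),
    )


TRANSFORMS: dict[str, ResponseTransform] = {
    "identity": ResponseTransform("identity", lambda y: np.asarray(y, float), lambda z: np.asarray(z, float)),
    "sqrt": ResponseTransform("sqrt", np.sqrt, lambda z: np.asarray(z, float) ** 2),
    "ln": ResponseTransform("ln", np.log, np.exp),
    "inverse": ResponseTransform("inverse", lambda y: 1.0 / np.asarray(y, float), lambda z: 1.0 / np.asarray(z, float)),
    "inverse_sqrt": ResponseTransform(
        "inverse_sqrt", lambda y: 1.0 / np.sqrt(np.asarray(y, float)),
        lambda z: 1.0 / np.asarray(z, float) ** 2,
    ),
}


def get_transform(name: str) -> ResponseTransform:
    """Look up a transform by name; ``power(lam)`` is parsed on the fly."""
    if isinstance(name, ResponseTransform):
        return name
    m = re.fullmatch(r"power\(([-0-9.eE]+)\)", name.strip())
    if m:
        return _power_transform(float(m.group(1)))
    try:
        return TRANSFORMS[name]
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; choose from {sorted(TRANSFORMS)} or power(lam)"
        ) from None


@dataclass
class ModelSpec:
    """A response name, its modeling transform, and a Scheffe term set.

    Scheffe models have no intercept, so all q linear terms must be present.
    """

    response: str
    terms: list[TermSpec]
    transform: ResponseTransform = field(
        default_factory=lambda: TRANSFORMS["identity"]
    )
    units: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.transform, str):
            self.transform = get_transform(self.transform)
        if not self.terms:
            raise ValueError("model has no terms")
        q = self.n_components
        linear = {t.indices[0] for t in self.terms if t.is_linear}
        if linear != set(range(q)):
            raise ValueError(
                "all q linear terms must be present (Scheffe models have no intercept)"
            )

    @property
    def n_components(self) -> int:
        return max(max(t.indices) for t in self.terms) + 1

    @property
    def nonlinear_terms(self) -> list[TermSpec]:
        return [t for t in self.terms if not t.is_linear]

    def term_names(self, aliases: Sequence[str] = "ABCDEFGH") -> list[str]:
        return [term_name(t, aliases) for t in self.terms]
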
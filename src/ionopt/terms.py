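"""Polynomial model terms over coded factors.

Shared between design construction (D-optimality needs the model matrix)
and response-surface fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidValueError, SchemaError

__all__ = ["Term", "quadratic_terms", "linear_terms", "build_matrix"]


@dataclass(frozen=True)
class Term:
    """One model term: intercept, linear, quadratic or two-factor interaction."""

    kind: str  # intercept | linear | quadratic | interaction
    factors: tuple = ()

    def __post_init__(self):
        if self.kind == "intercept" and self.factors:
            raise InvalidValueError("intercept term takes no factors")
        if self.kind in ("linear", "quadratic") and len(self.factors) != 1:
            raise InvalidValueError(f"{self.kind} term needs exactly one factor")
        if self.kind == "interaction":
            if len(self.factors) != 2 or self.factors[0] == self.factors[1]:
                raise InvalidValueError("interaction needs two distinct factors")
        if self.kind not in ("intercept", "linear", "quadratic", "interaction"):
            raise InvalidValueError(f"unknown term kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return "*".join(self.factors)

    @staticmethod
    def parse(name: str) -> "Term":
        name = name.strip()
        if name == "1":
            return Term("intercept")
        if "^2" in name:
            return Term("quadratic", (name.replace("^2", ""),))
        if "*" in name:
            a, b = name.split("*")
            if a == b:
                return Term("quadratic", (a,))
            return Term("interaction", (a, b))
        return Term("linear", (name,))

    def __str__(self) -> str:
        return self.name


def linear_terms(factor_names: Sequence[str], intercept: bool = True) -> list[Term]:
    out = [Term("intercept")] if intercept else []
    out += [Term("linear", (f,)) for f in factor_names]
    return out


def quadratic_terms(
    factor_names: Sequence[str],
    interactions: bool = True,
    quadratics: bool = True,
) -> list[Term]:
    """Full quadratic model term list: 1, linear, interactions, squares."""
    out = linear_terms(factor_names)
    if interactions:
        for i, a in enumerate(factor_names):
            for b in factor_names[i + 1 :]:
                out.append(Term("interaction", (a, b)))
    if quadratics:
        out += [Term("quadratic", (f,)) for f in factor_names]
    return out


def build_matrix(
    coded: np.ndarray, factor_names: Sequence[str], terms: Iterable[Term]
) -> np.ndarray:
    """Evaluate model-term columns at coded design points.

    Parameters
    ----------
    coded : (n, k) array of coded levels.
    factor_names : names matching the columns of ``coded``.
    terms : model terms; factors must all be present in ``factor_names``.
    """
    coded = np.asarray(coded, dtype=float)
    if coded.ndim == 1:
        coded = coded[None, :]
    idx = {name: j for j, name in enumerate(factor_names)}
    cols = []
    for term in terms:
        for f in term.factors:
            if f not in idx:
                raise SchemaError(f"term {term.name!r} references unknown factor {f!r}")
        if term.kind == "intercept":
            cols.append(np.ones(coded.shape[0]))
        elif term.kind == "linear":
            cols.append(coded[:, idx[term.factors[0]]])
        elif term.kind == "quadratic":
            cols.append(coded[:, idx[term.factors[0]]] ** 2)
        else:
            cols.append(coded[:, idx[term.factors[0]]] * coded[:, idx[term.factors[1]]])
    return np.column_stack(cols)
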
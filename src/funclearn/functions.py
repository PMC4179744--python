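"""Polynomial generating functions mapping cue position (mm) to target onset (ms).

The interception task hides a functional relationship between the lateral
position ``x`` of a briefly flashed cue (mm, 0 = display center) and the time
at which the target appears (ms after trial initiation).  All generating
functions used in either experiment are low-degree polynomials; this module
holds the polynomial container plus the canonical function sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P

__all__ = [
    "PolynomialFunction",
    "EXP1_FUNCTIONS",
    "EXP2_FUNCTIONS",
    "eval_function",
]


@dataclass(frozen=True)
class PolynomialFunction:
    """A polynomial ``f(x) = sum_d c_d x^d`` with coefficients ascending by degree.

    Coefficient ``c_d`` carries units ms·mm⁻ᵈ so that ``f(x)`` is in ms when
    ``x`` is in mm.

    Parameters
    ----------
    coefficients : sequence of float
        ``(c_0, c_1, ..., c_degree)``.
    name : str, optional
        Display label (e.g. ``"linear"``).
    """

    coefficients: tuple[float, ...]
    name: str = ""

    def __init__(self, coefficients: Sequence[float], name: str = ""):
        coefficients = tuple(float(c) for c in coefficients)
        if len(coefficients) == 0:
            raise ValueError("need at least one coefficient")
        object.__setattr__(self, "coefficients", coefficients)
        object.__setattr__(self, "name", name)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, x):
        return P.polyval(np.asarray(x, dtype=float), self.coefficients)


def eval_function(f: PolynomialFunction, x) -> float:
    """Evaluate a generating function at lateral position ``x`` (mm)."""
    return f(x)


_A = 1.0 / 1500.0

#: Experiment-1 generating functions (one per session).
EXP1_FUNCTIONS = {
    "linear": PolynomialFunction((1250.0, -5.0), name="linear"),
    "quadratic": PolynomialFunction((1700.0, 0.5, -0.1), name="quadratic"),
    "cubic": PolynomialFunction((1500.0, -3 * _A, _A, _A), name="cubic"),
}

#: Experiment-2 generating functions (constant/linear/quadratic, switched online).
EXP2_FUNCTIONS = {
    "constant": PolynomialFunction((1350.0,), name="constant"),
    "linear": PolynomialFunction((1350.0, 7.0), name="linear"),
    "quadratic": PolynomialFunction((2100.0, 0.1, -0.15), name="quadratic"),
}

#: One-letter complexity labels used for switch transitions (e.g. "CL").
DEGREE_LETTERS = {0: "C", 1: "L", 2: "Q"}
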
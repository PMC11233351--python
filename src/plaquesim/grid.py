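"""Uniform lipid grid with exact pantograph and convolution alignment.

Nodes are a_j = 1 + j/q for j = 0..J with integer ``q`` nodes per unit lipid,
so the spacing h = 1/q divides 1 exactly.  Two structural maps of the model
then land on grid nodes with zero interpolation error:

* proliferation sources cells at ``a`` from parents at ``2a - 1``, and
  2*a_j - 1 = a_{2j};
* the efferocytosis convolution shifts by whole node offsets, since the lower
  cut-off ``a' = 1`` is exactly ``q`` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["LipidGrid"]


@dataclass(frozen=True)
class LipidGrid:
    """Discretisation of a in [1, a_max] with q nodes per unit lipid."""

    q: int
    J: int

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be a positive integer")
        if self.J < 2 * self.q:
            raise ValueError("grid must extend at least to a = 3 (J >= 2q)")
        if self.J % self.q != 0:
            raise ValueError("J must be a multiple of q (integer a_max)")

    @classmethod
    def from_extent(cls, q: int, a_max: float) -> "LipidGrid":
        """Grid on [1, a_max]; ``a_max`` must be an integer >= 3."""
        if a_max != int(a_max):
            raise ValueError("a_max must be an integer so that J is a multiple of q")
        return cls(q=q, J=q * (int(a_max) - 1))

    @property
    def h(self) -> float:
        return 1.0 / self.q

    @property
    def a_max(self) -> float:
        return 1.0 + self.J / self.q

    @property
    def n_nodes(self) -> int:
        return self.J + 1

    @cached_property
    def nodes(self) -> np.ndarray:
        return 1.0 + np.arange(self.J + 1) / self.q

    @cached_property
    def trapezoid_weights(self) -> np.ndarray:
        w = np.full(self.J + 1, self.h)
        w[0] = w[-1] = 0.5 * self.h
        return w

    def integrate(self, f: np.ndarray) -> float:
        """Trapezoidal quadrature of a grid function."""
        return float(self.trapezoid_weights @ f)

    def moment(self, f: np.ndarray, n: int) -> float:
        """Trapezoidal n-th raw moment of a grid function."""
        return float(self.trapezoid_weights @ (self.nodes**n * f))
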
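"""Clamped B-spline bases used as temporal smoothing features.

The decoder projects each neuron's perievent spike train onto a set of
B-spline basis functions, turning a 2000-bin binary vector into a small
number of smooth temporal features. The basis lives on the bin-index
domain [0, M] with uniformly spaced interior knots and clamped
(repeated) boundary knots, so the J = m + d + 1 functions are
non-negative and sum to one everywhere on the domain. The degree-0
intervals follow the half-open convention [eta_j, eta_{j+1}) with the
final interval closed, which is what makes the partition of unity hold
at the knots themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BSplineBasis", "bspline_basis"]


@dataclass
class BSplineBasis:
    """J x (M+1) B-spline basis evaluated on the integer grid 0..M."""

    degree: int
    interior_knots: np.ndarray
    M: int
    knots: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    @property
    def J(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return len(self.interior_knots)

    def to_dict(self) -> dict:
        return {"degree": self.degree, "m": self.m, "M": self.M}

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return bspline_basis(d["m"], d["degree"], d["M"])


def bspline_basis(m: int, d: int, M: int) -> BSplineBasis:
    """Build J = m + d + 1 clamped B-spline functions on [0, M].

    Parameters
    ----------
    m : int >= 0
        Number of uniformly spaced interior knots.
    d : int >= 0
        Polynomial degree.
    M : int > 0
        Right edge of the domain in bin units; the basis is evaluated on
        the integer grid 0..M (M+1 points).
    """
    if m < 0 or d < 0 or M <= 0:
        raise ValueError("require m >= 0, d >= 0, M > 0")
    full = np.linspace(0.0, float(M), m + 2)
    interior = full[1:-1]
    knots = np.concatenate([np.zeros(d + 1), interior, np.full(d + 1, float(M))])
    if np.any(np.diff(knots) < 0):
        raise ValueError("knot sequence must be non-decreasing")
    grid = np.arange(M + 1, dtype=float)
    dm = BSpline.design_matrix(grid, knots, d, extrapolate=False)
    values = np.asarray(dm.todense()).T  # J x (M+1)
    assert values.shape[0] == m + d + 1
    return BSplineBasis(degree=d, interior_knots=interior, M=M, knots=knots, values=values)
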
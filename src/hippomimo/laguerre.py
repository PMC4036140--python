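"""Discrete-time orthonormal Laguerre basis functions.

The Volterra kernels of the spike-transformation model are expanded on
discrete Laguerre functions: exponentially decaying, orthonormal
sequences parameterized by a single pole ``alpha`` in (0, 1). Larger
``alpha`` gives slower decay and therefore longer effective memory; the
order-``j`` function crosses zero ``j`` times.

The functions are generated by the stable state-space recursion

    b_0(t) = sqrt(alpha) * b_0(t-1),              b_0(0) = sqrt(1-alpha)
    b_j(t) = sqrt(alpha) * b_j(t-1) + sqrt(alpha) * b_{j-1}(t) - b_{j-1}(t-1)

which is orthonormal over the infinite horizon; truncation at
``memory_bins`` leaves the Gram matrix within numerical tolerance of the
identity as long as the memory comfortably exceeds the decay length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = ["LaguerreBasis", "laguerre_basis"]


@dataclass
class LaguerreBasis:
    """Orthonormalized discrete Laguerre functions on lags 0..memory_bins.

    ``values[j, tau]`` is the order-j function at lag tau.
    """

    alpha: float
    n_basis: int
    memory_bins: int
    values: np.ndarray = field(repr=False)

    def gram(self) -> np.ndarray:
        return self.values @ self.values.T

    def project(self, kernel: np.ndarray) -> np.ndarray:
        """Least-squares coefficients of a lag-domain kernel on this basis.

        Uses least squares rather than the plain inner product so the
        expand-then-project round trip is exact even when truncation
        leaves the basis slightly non-orthonormal.
        """
        kernel = np.atleast_2d(np.asarray(kernel, float))
        coef, *_ = np.linalg.lstsq(self.values.T, kernel.T, rcond=None)
        return coef.T.squeeze()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_basis": self.n_basis,
            "memory_bins": self.memory_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LaguerreBasis":
        return laguerre_basis(d["alpha"], d["n_basis"], d["memory_bins"])


def laguerre_basis(alpha: float, n_basis: int, memory_bins: int) -> LaguerreBasis:
    """Build ``n_basis`` discrete Laguerre functions with pole ``alpha``.

    Parameters
    ----------
    alpha : float in (0, 1)
        Decay pole; effective decay length is roughly ``-1/ln(alpha)``
        bins for order 0 and grows with order.
    n_basis : int
        Number of functions (orders 0..n_basis-1).
    memory_bins : int
        Truncation lag; functions are evaluated on 0..memory_bins.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_basis < 1 or memory_bins < 1:
        raise ValueError("n_basis and memory_bins must be positive")
    sa = np.sqrt(alpha)
    T = memory_bins + 1
    values = np.empty((n_basis, T))
    impulse = np.zeros(T)
    impulse[0] = 1.0
    values[0] = np.sqrt(1 - alpha) * lfilter([1.0], [1.0, -sa], impulse)
    for j in range(1, n_basis):
        values[j] = lfilter([sa, -1.0], [1.0, -sa], values[j - 1])
    return LaguerreBasis(alpha=alpha, n_basis=n_basis, memory_bins=memory_bins, values=values)
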
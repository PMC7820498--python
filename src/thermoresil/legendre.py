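"""Legendre polynomial basis on a rescaled covariate range.

Random-regression test-day models parameterise curves over an
environmental gradient with Legendre polynomials, after mapping the
covariate ``x`` in ``[x_min, x_max]`` onto ``t in [-1, 1]``.  The
``normalized`` variant scales each polynomial by ``sqrt((2k+1)/2)`` so
the basis is orthonormal under the uniform measure on ``[-1, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["LegendreBasis", "legendre_eval"]

_EPS = 1e-9


@dataclass(frozen=True)
class LegendreBasis:
    """Degree-``degree`` Legendre basis over ``[x_min, x_max]``."""

    x_min: float
    x_max: float
    degree: int = 2
    normalization: str = "normalized"  # or "standard"

    def __post_init__(self):
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be strictly below x_max")
        if self.normalization not in ("normalized", "standard"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.degree < 0:
            raise ValueError("degree must be non-negative")

    @property
    def n_coef(self) -> int:
        return self.degree + 1

    def _scale(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_min - _EPS, self.x_max + _EPS
        if np.any(x < lo) or np.any(x > hi):
            bad = x[(x < lo) | (x > hi)]
            raise ValueError(
                f"covariate value(s) {np.atleast_1d(bad)[:3]} outside basis "
                f"range [{self.x_min}, {self.x_max}]; no extrapolation")
        return 2.0 * (x - self.x_min) / (self.x_max - self.x_min) - 1.0

    def _norms(self) -> np.ndarray:
        if self.normalization == "standard":
            return np.ones(self.n_coef)
        k = np.arange(self.n_coef)
        return np.sqrt((2.0 * k + 1.0) / 2.0)

    def evaluate(self, x) -> np.ndarray:
        """Basis rows ``[phi_0(x) ... phi_degree(x)]``; shape (n, degree+1)."""
        t = self._scale(x)
        return npleg.legvander(np.atleast_1d(t), self.degree) * self._norms()

    def derivative(self, x) -> np.ndarray:
        """d(phi)/dx rows, including the chain-rule factor 2/(x_max - x_min)."""
        t = np.atleast_1d(self._scale(x))
        cols = []
        for k in range(self.n_coef):
            coef = np.zeros(k + 1)
            coef[k] = 1.0
            dcoef = npleg.legder(coef) if k > 0 else np.zeros(1)
            cols.append(npleg.legval(t, dcoef))
        jac = 2.0 / (self.x_max - self.x_min)
        return np.column_stack(cols) * self._norms() * jac


def legendre_eval(x: float, basis: LegendreBasis) -> np.ndarray:
    """Basis vector at a single covariate value (1-D array)."""
    return basis.evaluate(x)[0]
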
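"""Monoexponential signal model and the information-matrix algebra behind
D-optimal design.

The diffusion-weighted signal follows the monoexponential decay

    m(b) = m0 * exp(-b * D)

with ``m0`` the signal at zero diffusion weighting (arbitrary intensity
units) and ``D`` the apparent diffusion coefficient (mm^2/s).  Taking logs
linearises the model,

    ln m_i = ln m0 - b_i * D,

so the unknowns enter through the parameter vector ``x = [ln m0, D]`` and
the N x 2 design matrix ``A`` whose i-th row is ``[1, -b_i]``.  The
information matrix of the log-linear least-squares problem is

    M = A^T A = [[N, -sum(b)], [-sum(b), sum(b^2)]],

and under i.i.d. zero-mean noise of variance sigma^2 on the log-measurements
the estimator covariance is ``sigma^2 * M^{-1}``.  D-optimal design
maximises ``det M = N * sum(b^2) - (sum b)^2``, which depends only on the
b-values — not on (m0, D) — which is the property the whole package is
built around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDesignError

__all__ = [
    "MonoexpParams",
    "AcquisitionDesign",
    "InformationMatrix",
    "signal",
    "design_matrix",
    "information_matrix",
    "det_information",
    "lse_covariance",
]


@dataclass(frozen=True)
class MonoexpParams:
    """Parameters of the monoexponential decay model.

    Attributes
    ----------
    m0 : float
        Non-diffusion-weighted signal amplitude, > 0 (intensity units).
    D : float
        Apparent diffusion coefficient, > 0 (mm^2/s).
    """

    m0: float
    D: float

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValueError(f"m0 must be > 0, got {self.m0}")
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")

    @property
    def x(self) -> np.ndarray:
        """Log-linear parameter vector [ln m0, D] (derived, never stored)."""
        return np.array([math.log(self.m0), self.D])


@dataclass(frozen=True)
class AcquisitionDesign:
    """An ordered multiset of b-values together with its feasibility box.

    Repeated b-values mean repeated acquisitions at the same diffusion
    weighting.  A design with fewer than two *distinct* b-values is
    representable but degenerate: its information matrix is singular and
    every consumer that needs invertibility raises
    :class:`~adcdesign.errors.DegenerateDesignError`.
    """

    b_values: tuple[float, ...]
    b_min: float = 0.0
    b_max: float = math.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        if len(self.b_values) < 2:
            raise ValueError("a design needs at least N = 2 measurements")
        if self.b_min > self.b_max:
            raise ValueError(f"b_min {self.b_min} exceeds b_max {self.b_max}")
        for b in self.b_values:
            if not (self.b_min <= b <= self.b_max):
                raise ValueError(
                    f"b-value {b} outside feasibility bounds "
                    f"[{self.b_min}, {self.b_max}]"
                )

    @property
    def n(self) -> int:
        return len(self.b_values)

    @property
    def is_degenerate(self) -> bool:
        """True when all b-values coincide (singular information matrix)."""
        return len(set(self.b_values)) < 2

    def as_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)


@dataclass(frozen=True, eq=False)
class InformationMatrix:
    """The 2 x 2 information matrix M = A^T A and its closed-form determinant."""

    entries: np.ndarray
    det: float


def signal(params: MonoexpParams, b) -> np.ndarray | float:
    """Evaluate the noise-free signal m0 * exp(-b D) at one or many b-values.

    Raises ``ValueError`` for negative b (diffusion weightings are
    nonnegative by construction of the pulse sequence).
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be nonnegative")
    out = params.m0 * np.exp(-b_arr * params.D)
    return float(out) if np.isscalar(b) or b_arr.ndim == 0 else out


def design_matrix(design: AcquisitionDesign) -> np.ndarray:
    """N x 2 matrix with rows [1, -b_i], in the design's stored order."""
    b = design.as_array()
    return np.column_stack([np.ones_like(b), -b])


def det_information(design: AcquisitionDesign) -> float:
    """det M = N * sum(b_i^2) - (sum b_i)^2, computed in closed form.

    The determinant is invariant under a common shift of all b-values and
    scales as c^2 under b -> c*b; it is zero iff all b-values are equal.
    """
    b = design.as_array()
    n = b.size
    return float(n * np.sum(b * b) - np.sum(b) ** 2)


def information_matrix(design: AcquisitionDesign) -> InformationMatrix:
    """Assemble M = A^T A with its determinant from the closed form."""
    b = design.as_array()
    s1 = float(np.sum(b))
    s2 = float(np.sum(b * b))
    entries = np.array([[design.n, -s1], [-s1, s2]])
    return InformationMatrix(entries=entries, det=det_information(design))


def lse_covariance(design: AcquisitionDesign, sigma: float) -> np.ndarray:
    """Covariance sigma^2 * M^{-1} of the log-linear least-squares estimator.

    ``sigma`` is the standard deviation of the i.i.d. noise on the
    log-measurements y = ln m.  Entry [1, 1] is Var(D_hat).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    det = det_information(design)
    if det <= 0:
        raise DegenerateDesignError(
            "all b-values equal: information matrix is singular"
        )
    b = design.as_array()
    s1 = float(np.sum(b))
    s2 = float(np.sum(b * b))
    # explicit 2x2 inverse of [[N, -s1], [-s1, s2]]
    inv = np.array([[s2, s1], [s1, design.n]]) / det
    return sigma**2 * inv
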
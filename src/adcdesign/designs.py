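"""Generators for acquisition designs: closed-form D-optimal, equidistant,
transcribed Gaussian-CRLB reference designs, a generic numeric CRLB
minimizer, and an exhaustive grid-search oracle.

The closed-form D-optimal rule is a two-point design: put n measurements at
b_min and N - n at b_max, with n = N/2 for even N and n = (N+1)/2 for odd N.
For odd N the mirrored split (majority at b_max) attains the same det(M);
the canonical output puts the majority at b_min because low-b acquisitions
have higher SNR under magnitude (Rician) noise.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from .errors import OptimizationError
from .model import AcquisitionDesign, det_information

__all__ = [
    "d_optimal_design",
    "equidistant_design",
    "gcrlb_reference_design",
    "gaussian_crlb_var_d",
    "numeric_crlb_design",
    "grid_search_d_optimal",
]

# Reference designs transcribed from prior Gaussian-CRLB work; valid for
# D in [0.1, 3] x 10^-3 mm^2/s.  They are *reference* values, not derived here.
_GCRLB_TWO_POINT = (0.0, 820.0)
_GCRLB_TEN_POINT_INTERIOR = 700.0


def _check_box(N: int, b_min: float, b_max: float) -> None:
    if N < 2:
        raise ValueError(f"need N >= 2 measurements, got {N}")
    if not b_min < b_max:
        raise ValueError(f"need b_min < b_max, got [{b_min}, {b_max}]")


def d_optimal_design(
    N: int, b_min: float, b_max: float, majority_high: bool = False
) -> AcquisitionDesign:
    """Closed-form D-optimal design: n copies of b_min then N - n of b_max.

    n = N/2 for even N, (N+1)/2 for odd N.  ``majority_high=True`` returns
    the det-equivalent mirrored design with the extra odd point at b_max.
    """
    _check_box(N, b_min, b_max)
    n = N // 2 if N % 2 == 0 else (N + 1) // 2
    if majority_high:
        n = N - n
    b = (b_min,) * n + (b_max,) * (N - n)
    return AcquisitionDesign(b, b_min=b_min, b_max=b_max)


def equidistant_design(N: int, b_min: float, b_max: float) -> AcquisitionDesign:
    """N b-values uniformly spaced on [b_min, b_max], endpoints included."""
    _check_box(N, b_min, b_max)
    b = tuple(np.linspace(b_min, b_max, N))
    return AcquisitionDesign(b, b_min=b_min, b_max=b_max)


def gcrlb_reference_design(N: int, b_max: float) -> AcquisitionDesign:
    """Transcribed Gaussian-CRLB reference designs for N = 2 or N = 10.

    N=2 -> (0, 820); N=10 -> (0, 0, 700 x 6, b_max, b_max).  These fixed
    values come from prior CRLB-minimisation work for the brain-tissue
    diffusivity range [0.1, 3] x 10^-3 mm^2/s; the interior 700 s/mm^2 value
    is held fixed regardless of b_max.
    """
    if N == 2:
        b = _GCRLB_TWO_POINT
    elif N == 10:
        b = (0.0, 0.0) + (_GCRLB_TEN_POINT_INTERIOR,) * 6 + (b_max, b_max)
    else:
        raise ValueError(
            f"no transcribed GCRLB reference design for N={N}; "
            "use numeric_crlb_design for other N"
        )
    return AcquisitionDesign(b, b_min=0.0, b_max=max(b_max, max(b)))


def gaussian_crlb_var_d(
    b, D: float, m0: float, sigma_G: float
) -> float:
    """Cramer-Rao lower bound on Var(D_hat) for the nonlinear model under
    i.i.d. Gaussian magnitude noise of std ``sigma_G``.

    The Fisher information is built from the signal Jacobian
    d m / d(m0, D) = [exp(-bD), -m0 b exp(-bD)] summed over measurements.
    Returns +inf for designs whose information matrix is singular.
    """
    b = np.asarray(b, dtype=float)
    e = np.exp(-b * D)
    jac = np.column_stack([e, -m0 * b * e])
    fim = jac.T @ jac / sigma_G**2
    det = fim[0, 0] * fim[1, 1] - fim[0, 1] * fim[1, 0]
    if det <= 0 or not np.isfinite(det):
        return math.inf
    return float(fim[0, 0] / det)


def numeric_crlb_design(
    N: int,
    b_min: float,
    b_max: float,
    D: float,
    m0: float,
    sigma_G: float,
    n_starts: int = 16,
    seed: int = 0,
) -> AcquisitionDesign:
    """Numerically minimise the Gaussian-noise CRLB of D_hat over the box.

    Multi-start L-BFGS-B from equidistant, two-point, and random initial
    designs; returns the best local minimiser with b-values sorted
    ascending.  Unlike the closed-form D-optimal rule, the result depends
    on the assumed (D, m0, sigma_G).
    """
    _check_box(N, b_min, b_max)
    if D <= 0 or m0 <= 0 or sigma_G <= 0:
        raise ValueError("D, m0 and sigma_G must all be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    starts = [
        np.linspace(b_min, b_max, N),
        d_optimal_design(N, b_min, b_max).as_array(),
    ]
    starts += [rng.uniform(b_min, b_max, size=N) for _ in range(n_starts - 2)]

    # optimise log(CRLB) over box-normalised coordinates: the raw objective
    # spans many orders of magnitude over b-values of order 1e3, which
    # starves finite-difference gradients
    span = b_max - b_min

    def objective(t: np.ndarray) -> float:
        v = gaussian_crlb_var_d(b_min + t * span, D, m0, sigma_G)
        return math.log(v) if math.isfinite(v) and v > 0 else 100.0

    best_b, best_val, converged = None, math.inf, False
    for x0 in starts:
        res = minimize(
            objective,
            (x0 - b_min) / span,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * N,
        )
        if res.fun < best_val:
            best_b, best_val = b_min + res.x * span, res.fun
            converged = converged or bool(res.success)
    if not converged or best_b is None or not math.isfinite(best_val):
        raise OptimizationError(
            "CRLB minimisation did not converge from any start",
            best_b=best_b,
            best_value=best_val,
        )
    return AcquisitionDesign(tuple(np.sort(best_b)), b_min=b_min, b_max=b_max)


def grid_search_d_optimal(
    N: int, b_min: float, b_max: float, grid_points: int
) -> AcquisitionDesign:
    """Exhaustive-search oracle: best det(M) multiset on a uniform grid.

    Enumerates every multiset of size N drawn from ``grid_points`` equally
    spaced b-values and returns the one maximising det(M); ties go to the
    lexicographically smallest multiset so the result is deterministic.
    Guarded to at most 10^7 enumerated multisets.
    """
    _check_box(N, b_min, b_max)
    if grid_points < 2:
        raise ValueError("need at least 2 grid points")
    n_multisets = math.comb(grid_points + N - 1, N)
    if n_multisets > 10**7:
        raise ValueError(
            f"{n_multisets} multisets exceeds the 1e7 enumeration guard"
        )
    grid = np.linspace(b_min, b_max, grid_points)
    best_b: tuple[float, ...] | None = None
    best_det = -math.inf
    # combinations_with_replacement yields multisets in lexicographic order,
    # so keeping only strict improvements implements the tie-break.
    for combo in itertools.combinations_with_replacement(range(grid_points), N):
        b = grid[list(combo)]
        det = N * float(np.sum(b * b)) - float(np.sum(b)) ** 2
        if det > best_det:
            best_det, best_b = det, tuple(b)
    assert best_b is not None
    return AcquisitionDesign(best_b, b_min=b_min, b_max=b_max)
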
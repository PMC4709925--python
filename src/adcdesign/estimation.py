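"""Log-linear least-squares estimation of (m0, D).

Taking logs of the measurements turns the monoexponential fit into ordinary
least squares: y_i = ln m_i, x = [ln m0, D], and x_hat solves the normal
equations A^T A x = A^T y.  The solver uses a numerically stable
least-squares factorisation (LAPACK gelsd via numpy) rather than forming
(A^T A)^{-1} explicitly; the two agree to machine precision for these tiny
2-column problems.

D_hat is read directly as x_hat[1] thanks to the -b_i sign convention in
the design matrix — no post-hoc sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDesignError, NonPositiveMeasurementError
from .model import AcquisitionDesign, design_matrix

__all__ = ["FitResult", "loglinear_lse", "batch_loglinear_lse"]


@dataclass(frozen=True, eq=False)
class FitResult:
    m0_hat: float
    D_hat: float
    x_hat: np.ndarray       # [ln m0_hat, D_hat]
    residuals: np.ndarray   # log-domain residuals y - A x_hat


def batch_loglinear_lse(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve the log-linear LSE for many trials at once.

    A is the shared N x 2 design matrix, Y an (n_trials, N) array of
    log-measurements.  Returns an (n_trials, 2) array of [ln m0_hat, D_hat].
    """
    X, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    return X.T


def loglinear_lse(
    design: AcquisitionDesign,
    measurements,
    clip_floor: float | None = None,
) -> FitResult:
    """Fit (m0, D) to signal-intensity measurements under a design.

    Measurements must be strictly positive (the log is undefined
    otherwise); a nonpositive value raises
    :class:`~adcdesign.errors.NonPositiveMeasurementError` naming the
    offending index.  ``clip_floor`` is an exploratory escape hatch that
    clips measurements up to the given floor instead — off by default,
    because under the Rician magnitude model nonpositive values cannot
    occur and their presence signals a pipeline bug.
    """
    m = np.asarray(measurements, dtype=float)
    if m.shape != (design.n,):
        raise ValueError(
            f"expected {design.n} measurements to match the design, got {m.shape}"
        )
    if design.is_degenerate:
        raise DegenerateDesignError(
            "design has a single distinct b-value; (m0, D) are not separable"
        )
    if clip_floor is not None:
        if clip_floor <= 0:
            raise ValueError("clip_floor must be positive")
        m = np.maximum(m, clip_floor)
    else:
        bad = np.flatnonzero(m <= 0)
        if bad.size:
            raise NonPositiveMeasurementError(int(bad[0]), float(m[bad[0]]))

    A = design_matrix(design)
    y = np.log(m)
    x_hat = batch_loglinear_lse(A, y[None, :])[0]
    return FitResult(
        m0_hat=float(np.exp(x_hat[0])),
        D_hat=float(x_hat[1]),
        x_hat=x_hat,
        residuals=y - A @ x_hat,
    )
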
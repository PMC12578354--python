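"""Post-inference sensitivity and variability analysis.

Three complementary views of how well the data pin down the inferred
coefficients: two-parameter loss-contour scans around the optimum (broad
valleys mean poorly constrained directions), a local Gaussian (Laplace)
approximation to the parameter posterior built from a finite-difference
Hessian of the misfit, and the carrying-capacity summary of the logistic-type
reaction term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .vsi import ADRModel, COEFF_ALIASES

__all__ = [
    "ContourScan",
    "LaplaceSummary",
    "loss_contours",
    "laplace_covariance",
    "carrying_capacity",
]


def _resolve_index(name_or_index) -> int:
    if isinstance(name_or_index, str):
        return COEFF_ALIASES[name_or_index]
    return int(name_or_index)


@dataclass
class ContourScan:
    """Normalized loss on a 2-parameter grid with the rest of θ held fixed."""

    pair: tuple[int, int]
    axis_a: np.ndarray
    axis_b: np.ndarray
    loss: np.ndarray  # (n_a, n_b), normalized by the grid minimum; NaN = failed
    theta_star: np.ndarray
    n_failed: int = 0

    def min_location(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmin(self.loss), self.loss.shape)
        return float(self.axis_a[i]), float(self.axis_b[j])


def loss_contours(
    loss_fn,
    theta_star,
    pair,
    ranges=None,
    grid_n: int = 41,
) -> ContourScan:
    """Scan the loss over a grid in two coefficients.

    ``loss_fn`` maps a full 8-vector θ to a scalar loss (e.g. the
    PDE-constrained misfit, or the quadratic VSI loss).  The remaining
    parameters are held fixed at ``theta_star``.  ``ranges`` defaults to
    ±50% around the inferred values.  Forward failures at a grid point are
    recorded as missing (NaN), not fatal.  The returned loss matrix is
    normalized by its minimum over the grid, so the minimum is exactly 1.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    ia, ib = (_resolve_index(p) for p in pair)
    if ranges is None:
        ranges = tuple(
            (v - 0.5 * abs(v), v + 0.5 * abs(v)) for v in (theta_star[ia], theta_star[ib])
        )
    axis_a = np.linspace(ranges[0][0], ranges[0][1], grid_n)
    axis_b = np.linspace(ranges[1][0], ranges[1][1], grid_n)
    loss = np.full((grid_n, grid_n), np.nan)
    n_failed = 0
    for i, a in enumerate(axis_a):
        for j, b in enumerate(axis_b):
            th = theta_star.copy()
            th[ia], th[ib] = a, b
            try:
                loss[i, j] = loss_fn(th)
            except (RuntimeError, FloatingPointError):
                n_failed += 1
    if np.all(np.isnan(loss)):
        raise RuntimeError("loss evaluation failed on the entire grid")
    loss = loss / np.nanmin(loss)
    return ContourScan((ia, ib), axis_a, axis_b, loss, theta_star, n_failed)


@dataclass
class LaplaceSummary:
    """Local Gaussian approximation to the parameter posterior.

    With a Gaussian likelihood of noise scale σ², the posterior near the
    optimum is ∝ exp(−ℓ(θ)/(2σ²)); a quadratic expansion ℓ ≈ ℓ* + ½(θ−θ*)ᵀ
    H(θ−θ*) gives covariance 2σ²H⁻¹.  σ² is estimated as the final misfit
    divided by the residual degrees of freedom (documented convention; the
    classical nonlinear-least-squares estimator).
    """

    theta: np.ndarray
    active: tuple[int, ...]
    covariance: np.ndarray  # (n_active, n_active)
    sd: np.ndarray  # per active parameter
    sigma2: float
    hessian: np.ndarray
    positive_definite: bool
    flat_directions: np.ndarray | None = None  # eigenvectors of ~zero curvature


def laplace_covariance(
    theta_star,
    active,
    loss_fn,
    dof: int,
    grad_fn=None,
    rel_step: float = 1e-4,
) -> LaplaceSummary:
    """Hessian-based covariance of the active coefficients at a minimum.

    The Hessian is built by central finite differences of ``grad_fn`` when
    available (one gradient is O(one adjoint solve)), else by second
    differences of ``loss_fn``.  A non-positive-definite Hessian triggers a
    pseudo-inverse with a warning, and the flat directions are reported —
    broad, degenerate valleys in parameter space show up here.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    active = tuple(int(m) for m in active)
    k = len(active)
    base = np.abs(theta_star[list(active)])
    # Step scale for zero components: borrow the largest active magnitude
    # (unit scale as a last resort) — a step of rel_step² at a zero entry
    # would lose the difference to roundoff.
    fallback = base.max() if base.max() > 0 else 1.0
    steps = rel_step * np.where(base > 0, base, fallback)

    H = np.zeros((k, k))
    if grad_fn is not None:
        for i, m in enumerate(active):
            tp, tm = theta_star.copy(), theta_star.copy()
            tp[m] += steps[i]
            tm[m] -= steps[i]
            gp = np.asarray(grad_fn(tp))[list(active)]
            gm = np.asarray(grad_fn(tm))[list(active)]
            H[:, i] = (gp - gm) / (2.0 * steps[i])
        H = 0.5 * (H + H.T)
    else:
        f0 = loss_fn(theta_star)
        for i, m in enumerate(active):
            tp, tm = theta_star.copy(), theta_star.copy()
            tp[m] += steps[i]
            tm[m] -= steps[i]
            H[i, i] = (loss_fn(tp) - 2.0 * f0 + loss_fn(tm)) / steps[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                mi, mj = active[i], active[j]
                t = theta_star.copy()
                t[mi] += steps[i]
                t[mj] += steps[j]
                fpp = loss_fn(t)
                t = theta_star.copy()
                t[mi] += steps[i]
                t[mj] -= steps[j]
                fpm = loss_fn(t)
                t = theta_star.copy()
                t[mi] -= steps[i]
                t[mj] += steps[j]
                fmp = loss_fn(t)
                t = theta_star.copy()
                t[mi] -= steps[i]
                t[mj] -= steps[j]
                fmm = loss_fn(t)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])

    sigma2 = float(loss_fn(theta_star)) / max(dof, 1)
    eigval, eigvec = np.linalg.eigh(H)
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    pd = bool(np.all(eigval > tol))
    flat = None
    if pd:
        cov = 2.0 * sigma2 * np.linalg.inv(H)
    else:
        warnings.warn(
            "misfit Hessian is not positive definite; using pseudo-inverse "
            "(flat directions reported — these indicate parameter degeneracy)",
            stacklevel=2,
        )
        cov = 2.0 * sigma2 * np.linalg.pinv(H, rcond=1e-12)
        flat = eigvec[:, eigval <= tol]
    cov = 0.5 * (cov + cov.T)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return LaplaceSummary(theta_star, active, cov, sd, sigma2, H, pd, flat)


def carrying_capacity(model: ADRModel) -> float:
    """Density at which the logistic-type reaction r(C) = θ6 C + θ7 C²
    vanishes: K = −θ6/θ7 (cells/μm²), from r = θ6 C (1 − C/K).

    Requires growth at low density (θ6 > 0) and saturation (θ7 < 0);
    otherwise no finite positive carrying capacity exists.
    """
    th6, th7 = model.theta[6], model.theta[7]
    if th7 >= 0:
        raise ValueError("no finite carrying capacity: quadratic reaction "
                         "coefficient must be negative")
    if th6 <= 0:
        raise ValueError("no carrying capacity: linear growth rate must be positive")
    return float(-th6 / th7)
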
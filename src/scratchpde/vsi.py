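"""Variational system identification of advection-diffusion-reaction dynamics.

The cell-density evolution is modelled as

    ∂C/∂t = ∇·(D(C)∇C) − ∇·(C v_f(C) v_unit) + r(C)

with the polynomial ansatz

    D(C)   = θ0 + θ1 C + θ2 C²       (diffusivity, μm²/hr per power of C)
    v_f(C) = θ3 + θ4 C + θ5 C²       (advective speed along v_unit, μm/hr)
    r(C)   = θ6 C + θ7 C²            (net proliferation, 1/hr per power of C)

A constant reaction term is omitted by construction: it would create or
destroy cells in regions of zero density.  Testing the weak (variational)
form of the residual against the same P1 basis that interpolates the data
turns inference into a linear regression y = Ξ·θ, where the backward-Euler
time derivative of the data enters the target y and the eight weak-form
operator integrals enter the columns of Ξ.  Greedy backward elimination then
produces a parsimony path, and an elbow criterion picks the model size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import Mesh, NodalFieldSeries, operator_columns, time_derivative

__all__ = [
    "ADRModel",
    "LibrarySystem",
    "VSIResult",
    "ANSATZ_LABELS",
    "COEFF_ALIASES",
    "build_library",
    "stack_systems",
    "solve_ls",
    "stepwise_regression",
    "select_model",
    "select_significant",
    "library_stride",
]

ANSATZ_LABELS = (
    "D:1",
    "D:C",
    "D:C^2",
    "v:1",
    "v:C",
    "v:C^2",
    "r:C",
    "r:C^2",
)

#: Aliases used for the diffusion/reaction coefficients in sensitivity plots.
COEFF_ALIASES = {"D0": 0, "C1": 6, "C2": 7}

_UNITS = (
    "um^2/hr",
    "um^4/(cell*hr)",
    "um^6/(cell^2*hr)",
    "um/hr",
    "um^3/(cell*hr)",
    "um^5/(cell^2*hr)",
    "1/hr",
    "um^2/(cell*hr)",
)


@dataclass
class ADRModel:
    """Parameter vector of the ADR ansatz with its active support.

    Inactive entries of ``theta`` are held at exactly zero; ``v_unit`` is the
    unit vector perpendicular to the wound along which advection may act.
    """

    theta: np.ndarray
    active: tuple[int, ...] = tuple(range(8))
    v_unit: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        th = np.zeros(8)
        t = np.asarray(self.theta, dtype=float).ravel()
        th[: len(t)] = t
        self.active = tuple(sorted(int(m) for m in self.active))
        mask = np.zeros(8, dtype=bool)
        mask[list(self.active)] = True
        th[~mask] = 0.0
        self.theta = th
        v = np.asarray(self.v_unit, dtype=float).ravel()
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("v_unit must be a nonzero direction")
        self.v_unit = v / n

    units = _UNITS
    labels = ANSATZ_LABELS

    def diffusivity(self, C):
        t = self.theta
        return t[0] + t[1] * np.asarray(C) + t[2] * np.asarray(C) ** 2

    def advective_speed(self, C):
        t = self.theta
        return t[3] + t[4] * np.asarray(C) + t[5] * np.asarray(C) ** 2

    def reaction(self, C):
        C = np.asarray(C)
        return self.theta[6] * C + self.theta[7] * C**2

    def with_theta(self, theta, active=None) -> "ADRModel":
        return ADRModel(np.asarray(theta, dtype=float), active or self.active, self.v_unit)


@dataclass
class LibrarySystem:
    """Stacked weak-form regression system y = Ξ·θ.

    Rows are (interior-node weighted residual) × (frame ≥ 1), concatenated
    over frames and replicates; Dirichlet-boundary weighting functions are
    excluded because weighting functions vanish on the Dirichlet boundary
    (the whole boundary, here).  ``blocks`` records the replicate provenance
    of each row range.
    """

    y: np.ndarray
    Xi: np.ndarray
    blocks: list[tuple[int, slice]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Xi = np.atleast_2d(np.asarray(self.Xi, dtype=float))
        if self.Xi.shape != (len(self.y), 8):
            raise ValueError("Xi must be (n_rows, 8) aligned with y")
        if not self.blocks:
            self.blocks = [(0, slice(0, len(self.y)))]

    @property
    def n_rows(self) -> int:
        return len(self.y)


def library_stride(frame_interval: float, temporal_window: float | None) -> int:
    """Default frame stride for library assembly.

    Backward differences taken finer than the temporal smoothing window are
    dominated by the cancellation noise of two almost-identical filtered
    frames; one difference per window length makes consecutive residual rows
    carry independent noise at the largest per-row signal the filter allows.
    Unfiltered data (window at or below the frame spacing) uses every frame.
    """
    if temporal_window is None or frame_interval <= 0:
        return 1
    return max(1, int(round(temporal_window / frame_interval)))


def build_library(
    series: NodalFieldSeries | list[NodalFieldSeries],
    v_unit=(1.0, 0.0),
    stride: int = 1,
) -> LibrarySystem:
    """Assemble the target vector y and operator matrix Ξ from nodal data.

    For each used frame j ≥ 1 (backward Euler needs a predecessor) and
    interior node k, the target row is −∫ (∂C^h/∂t) N_k dΩ with the
    backward-Euler data derivative, and the eight columns hold the weak-form
    operator integrals evaluated on the time-centred field
    (Cʰ_j + Cʰ_{j-1})/2.  The centred evaluation matches the backward
    difference to second order in the frame spacing, and — decisive on
    counting data — makes the observation noise entering the operator
    columns uncorrelated with the differencing noise entering y, removing
    the errors-in-variables covariance that otherwise biases the regression
    (a one-sided evaluation shares the frame-j noise with the target and
    systematically misorients the reaction terms).  ``stride`` subsamples
    the frames (every ``stride``-th, starting at the first) before
    differencing — see :func:`library_stride` for the recommended choice on
    temporally smoothed data.  A list of series (replicates) is aggregated by
    row stacking, which is algebraically identical to minimizing the sum of
    per-replicate losses.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    series_list = series if isinstance(series, (list, tuple)) else [series]
    ys, Xis, blocks = [], [], []
    offset = 0
    for rep, s in enumerate(series_list):
        if stride > 1:
            idx = np.arange(0, s.n_frames, stride)
            if len(idx) < 2:
                raise ValueError("stride leaves fewer than 2 frames")
            s = NodalFieldSeries(s.mesh, s.t[idx], s.d[idx])
        mesh = s.mesh
        interior = mesh.interior_nodes
        M = mesh.mass
        _, dd = time_derivative(s)
        for j in range(1, s.n_frames):
            ys.append(-(M @ dd[j - 1])[interior])
            d_mid = 0.5 * (s.d[j] + s.d[j - 1])
            Xis.append(operator_columns(mesh, d_mid, v_unit)[interior])
        n_rows = (s.n_frames - 1) * len(interior)
        blocks.append((rep, slice(offset, offset + n_rows)))
        offset += n_rows
    return LibrarySystem(np.concatenate(ys), np.vstack(Xis), blocks)


def stack_systems(systems: list[LibrarySystem]) -> LibrarySystem:
    """Row-stack several library systems (replicate aggregation)."""
    blocks = []
    offset = 0
    for rep, s in enumerate(systems):
        blocks.append((rep, slice(offset, offset + s.n_rows)))
        offset += s.n_rows
    return LibrarySystem(
        np.concatenate([s.y for s in systems]),
        np.vstack([s.Xi for s in systems]),
        blocks,
    )


def solve_ls(
    system: LibrarySystem, active: tuple[int, ...] | list[int]
) -> tuple[np.ndarray, float]:
    """Least-squares fit of the active columns: minimize |y − Ξ_active θ|².

    Returns the full 8-vector (inactive entries exactly zero) and the squared
    residual norm.  Rank-deficient active columns give the minimum-norm
    solution with a warning.
    """
    active = sorted(int(m) for m in active)
    theta = np.zeros(8)
    if not active:
        return theta, float(system.y @ system.y)
    A = system.Xi[:, active]
    coef, _, rank, _ = np.linalg.lstsq(A, system.y, rcond=None)
    if rank < len(active):
        warnings.warn(
            "active library columns are linearly dependent; "
            "returning minimum-norm solution",
            stacklevel=2,
        )
    theta[active] = coef
    resid = system.y - A @ coef
    return theta, float(resid @ resid)


@dataclass
class PathStep:
    active: tuple[int, ...]
    theta: np.ndarray
    loss: float


@dataclass
class VSIResult:
    """Backward-elimination path from the full library down to one term.

    ``y_norm2`` (|y|²) records the scale of the regression target; model
    selection uses it as a floating-point noise floor so that losses at
    machine precision — exactly consistent, noise-free data — compare as
    equal rather than by their rounding error.
    """

    path: list[PathStep]
    y_norm2: float = 0.0

    @property
    def losses(self) -> np.ndarray:
        return np.array([s.loss for s in self.path])

    @property
    def n_terms(self) -> np.ndarray:
        return np.array([len(s.active) for s in self.path])

    def step_with(self, n_terms: int) -> PathStep:
        for s in self.path:
            if len(s.active) == n_terms:
                return s
        raise KeyError(f"no path step with {n_terms} terms")


def stepwise_regression(
    system: LibrarySystem, standardize: bool = False, tie_rtol: float | None = None
) -> VSIResult:
    """Greedy backward elimination over the 8-term library.

    Starting from all terms, each step solves the reduced least-squares
    problem for every single-term exclusion and removes the term whose
    exclusion gives the minimal loss growth, until one term remains.  When
    several exclusions tie within ``tie_rtol`` relative, the highest-order
    term among them is dropped, favouring simpler density dependence.  The
    default tie window is the statistical resolution of the loss,
    ``2 / n_rows`` relative: for a fit with n residuals, exchanging one
    noise-level column for another moves the loss by O(loss/n), so smaller
    differences carry no evidence about which term to keep (exact ties at
    machine precision are a special case of this window).

    ``standardize`` rescales columns to unit norm for the *elimination
    decisions only*; reported coefficients are always in physical units.
    Elimination order can differ between the two conventions, so the flag
    defaults to off (coefficients are compared in physical units downstream).
    """
    if tie_rtol is None:
        tie_rtol = 2.0 / system.n_rows
    work = system
    scale = np.ones(8)
    if standardize:
        norms = np.linalg.norm(system.Xi, axis=0)
        scale = np.where(norms > 0, norms, 1.0)
        work = LibrarySystem(system.y, system.Xi / scale, system.blocks)

    def physical(theta_scaled):
        return theta_scaled / scale

    active = list(range(8))
    theta, loss = solve_ls(work, active)
    path = [PathStep(tuple(active), physical(theta), loss)]
    while len(active) > 1:
        losses = {}
        for cand in active:
            reduced = [m for m in active if m != cand]
            _, l = solve_ls(work, reduced)
            losses[cand] = l
        best = min(losses.values())
        tol = abs(best) * tie_rtol + np.finfo(float).tiny
        tied = [m for m in active if losses[m] <= best + tol]
        drop = max(tied)  # tie-break: drop the higher-order term
        active = [m for m in active if m != drop]
        theta, loss = solve_ls(work, active)
        path.append(PathStep(tuple(active), physical(theta), loss))
    return VSIResult(path, float(work.y @ work.y))


def select_model(result: VSIResult, rel_tolerance: float = 0.05) -> PathStep:
    """Elbow-style model selection on the elimination path.

    Returns the path step with the smallest active set whose loss does not
    exceed ``(1 + ρ)`` times the full-library loss — formalizing the visual
    criterion that the loss barely grows until essential terms are removed.
    """
    if rel_tolerance < 0:
        raise ValueError("rel_tolerance must be nonnegative")
    full_loss = result.path[0].loss
    budget = (1.0 + rel_tolerance) * full_loss + 1e-12 * result.y_norm2
    chosen = result.path[0]
    for step in result.path:
        if step.loss <= budget and len(step.active) < len(chosen.active):
            chosen = step
    return chosen


def select_significant(result: VSIResult, n_rows: int, f_crit: float = 3.84) -> PathStep:
    """Backward-elimination stopping by statistical significance (F-to-remove).

    Walk the elimination path from the full library and accept each
    elimination while its loss growth is statistically indistinguishable
    from removing a pure-noise column: stop before the first step with

        (loss_{k-1} − loss_k) / (loss_k / n_rows) > f_crit,

    the classical F-test with ``f_crit`` defaulting to the χ²₁ 95% quantile.
    Unlike the elbow rule of :func:`select_model`, which measures growth
    relative to the full-library loss, this rule stays meaningful when that
    loss is dominated by observation noise (the usual case for weak-form
    regression on counting data, where the explainable signal is a small
    fraction of |y|²).
    """
    chosen = result.path[0]
    for step in result.path[1:]:
        scale = max(step.loss, 1e-12 * result.y_norm2) / max(n_rows, 1)
        if (step.loss - chosen.loss) / scale > f_crit:
            break
        chosen = step
    return chosen
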
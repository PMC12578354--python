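"""Implicit nonlinear forward solver for the advection-diffusion-reaction PDE.

Time stepping is backward Euler on the Galerkin weak form with a consistent
(non-lumped) mass matrix; each step is solved by Newton iteration with an
analytically assembled Jacobian.  Dirichlet values are imposed exactly by
elimination; an empty Dirichlet set leaves the natural (zero-flux Neumann)
boundary condition.  Negative intermediate densities are permitted — they are
reported, not clipped, so that the discrete adjoint of this scheme remains
exactly consistent with the computed trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import (
    Mesh,
    NodalFieldSeries,
    operator_apply,
    operator_jacobian,
    operator_jacobian_dense,
)

#: Meshes up to this many nodes use dense linear algebra in the stepper.
_DENSE_LIMIT = 400
from .vsi import ADRModel

__all__ = [
    "SolverConfig",
    "IBVPSpec",
    "NewtonError",
    "solve_forward",
    "total_mass",
    "rmse",
]


class NewtonError(RuntimeError):
    """Raised when a Newton solve fails to converge; carries diagnostics."""

    def __init__(self, step: int, iterations: int, residual: float):
        self.step = step
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"Newton failed at time step {step} after {iterations} iterations "
            f"(residual norm {residual:.3e})"
        )


@dataclass
class SolverConfig:
    """Newton/stepping controls.

    The default absolute and relative stopping tolerances are 1e-8 and 1e-9;
    ``n_sub`` inserts that many implicit substeps between consecutive output
    frames (Dirichlet data is interpolated linearly in time across them).
    """

    newton_atol: float = 1e-8
    newton_rtol: float = 1e-9
    max_newton_iter: int = 30
    n_sub: int = 1

    def __post_init__(self) -> None:
        if self.newton_atol <= 0 or self.newton_rtol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")


@dataclass
class IBVPSpec:
    """Initial/boundary data for a forward solve.

    ``dirichlet_nodes=None`` means "the whole mesh boundary"; an explicit
    empty array requests pure zero-flux (natural Neumann) boundaries.
    ``dirichlet_values`` holds one row per output frame; values at implicit
    substeps are interpolated linearly in time.
    """

    C0: np.ndarray
    t_frames: np.ndarray
    dirichlet_nodes: np.ndarray | None = None
    dirichlet_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C0 = np.asarray(self.C0, dtype=float).ravel()
        self.t_frames = np.asarray(self.t_frames, dtype=float).ravel()
        if len(self.t_frames) < 2 or np.any(np.diff(self.t_frames) <= 0):
            raise ValueError("t_frames must be strictly increasing with >= 2 frames")

    @classmethod
    def from_series(cls, data: NodalFieldSeries) -> "IBVPSpec":
        """Data-trace IBVP: IC = first frame, Dirichlet = boundary values of
        the (smoothed) data at each frame.  This is the refinement default —
        Dirichlet conditions hold on the whole boundary and the only available
        boundary values are the data's own trace.
        """
        bn = data.mesh.boundary_nodes
        return cls(data.d[0], data.t, bn, data.d[:, bn])

    @classmethod
    def zero_flux(cls, C0, t_frames) -> "IBVPSpec":
        return cls(C0, t_frames, np.empty(0, dtype=np.int64), None)

    def resolve_bc(self, mesh: Mesh) -> tuple[np.ndarray, np.ndarray | None]:
        bn = self.dirichlet_nodes
        if bn is None:
            bn = mesh.boundary_nodes
        bn = np.asarray(bn, dtype=np.int64)
        vals = self.dirichlet_values
        if len(bn) and vals is None:
            # Hold boundary at the initial values if no trace is supplied.
            vals = np.tile(self.C0[bn], (len(self.t_frames), 1))
        if vals is not None:
            vals = np.atleast_2d(np.asarray(vals, dtype=float))
            if vals.shape != (len(self.t_frames), len(bn)):
                raise ValueError("dirichlet_values must be (n_frames, n_dirichlet)")
        return bn, vals


def _newton_step(
    mesh: Mesh,
    theta: np.ndarray,
    v_unit: np.ndarray,
    d_prev: np.ndarray,
    dt: float,
    bc_nodes: np.ndarray,
    bc_vals: np.ndarray | None,
    free: np.ndarray,
    cfg: SolverConfig,
    step_index: int,
    M_dense: np.ndarray | None = None,
) -> np.ndarray:
    M = mesh.mass if M_dense is None else M_dense
    d = d_prev.copy()
    if len(bc_nodes):
        d[bc_nodes] = bc_vals
    nF0 = None
    for it in range(cfg.max_newton_iter):
        F = M @ ((d - d_prev) / dt) + operator_apply(mesh, d, theta, v_unit)
        Fi = F[free]
        nF = float(np.linalg.norm(Fi))
        if nF0 is None:
            nF0 = nF
        if nF <= cfg.newton_atol or nF <= cfg.newton_rtol * max(nF0, 1e-300):
            return d
        if M_dense is not None:
            J = M_dense / dt + operator_jacobian_dense(mesh, d, theta, v_unit)
            delta = np.linalg.solve(J[np.ix_(free, free)], -Fi)
        else:
            J = mesh.mass / dt + operator_jacobian(mesh, d, theta, v_unit)
            delta = spla.spsolve(J[free][:, free].tocsc(), -Fi)
        d[free] += delta
    raise NewtonError(step_index, cfg.max_newton_iter, nF)


def _solve_trajectory(
    model: ADRModel, ibvp: IBVPSpec, mesh: Mesh, cfg: SolverConfig
) -> dict:
    """Run the implicit stepper and keep every substep state (for the adjoint).

    Returns a dict with ``states`` (n_steps+1, n_nodes), per-step ``dts``,
    ``step_times``, the map ``frame_steps`` from output frames to step
    indices, and the index array of non-Dirichlet ("free") nodes.
    """
    if len(ibvp.C0) != mesh.n_nodes:
        raise ValueError("initial condition does not match mesh")
    theta = model.theta
    v_unit = model.v_unit
    bn, bvals = ibvp.resolve_bc(mesh)
    free = np.setdiff1d(np.arange(mesh.n_nodes), bn)
    M_dense = mesh.mass.toarray() if mesh.n_nodes <= _DENSE_LIMIT else None

    t_frames = ibvp.t_frames
    states = [ibvp.C0.copy()]
    dts: list[float] = []
    step_times = [t_frames[0]]
    frame_steps = [0]
    step = 0
    for j in range(len(t_frames) - 1):
        dt = (t_frames[j + 1] - t_frames[j]) / cfg.n_sub
        for s in range(1, cfg.n_sub + 1):
            step += 1
            frac = s / cfg.n_sub
            bc_now = None
            if len(bn):
                bc_now = (1.0 - frac) * bvals[j] + frac * bvals[j + 1]
            d = _newton_step(
                mesh, theta, v_unit, states[-1], dt, bn, bc_now, free, cfg, step,
                M_dense=M_dense,
            )
            states.append(d)
            dts.append(dt)
            step_times.append(t_frames[j] + frac * (t_frames[j + 1] - t_frames[j]))
        frame_steps.append(step)
    states_arr = np.array(states)
    neg_min = float(states_arr.min())
    if neg_min < 0:
        warnings.warn(
            f"forward solution reached negative density (min {neg_min:.3e}); "
            "values are reported unclipped",
            stacklevel=2,
        )
    return {
        "states": states_arr,
        "dts": np.array(dts),
        "step_times": np.array(step_times),
        "frame_steps": np.array(frame_steps),
        "free": free,
        "dirichlet_nodes": bn,
        "negative_min": neg_min,
    }


def solve_forward(
    model: ADRModel, ibvp: IBVPSpec, mesh: Mesh, cfg: SolverConfig | None = None
) -> NodalFieldSeries:
    """Solve the ADR initial/boundary-value problem; returns the nodal field
    sampled at the requested output frames."""
    cfg = cfg or SolverConfig()
    traj = _solve_trajectory(model, ibvp, mesh, cfg)
    d = traj["states"][traj["frame_steps"]]
    return NodalFieldSeries(mesh, ibvp.t_frames, d)


def total_mass(series: NodalFieldSeries, t_index: int) -> float:
    """∫_Ω C^h dV at a stored frame (cells for 2D fields; cells/μm of strip
    depth for 1D profiles)."""
    M = series.mesh.mass
    ones = np.ones(series.mesh.n_nodes)
    return float(ones @ (M @ series.d[t_index]))


def rmse(pred: NodalFieldSeries, data: NodalFieldSeries) -> float:
    """Root mean squared nodal difference over all nodes and frames."""
    if pred.d.shape != data.d.shape:
        raise ValueError("series shapes do not match")
    return float(np.sqrt(np.mean((pred.d - data.d) ** 2)))
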
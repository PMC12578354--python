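"""End-to-end inference: centroid tables -> density fields -> VSI -> refinement.

This module wires the stages together the way the assay workflow runs them:
bin each replicate, smooth, interpolate as nodal fields, assemble the
weak-form library (one backward difference per temporal smoothing window),
eliminate terms stepwise, select the model size at the loss elbow, and
refine the surviving coefficients by PDE-constrained optimization
initialized at the regression estimates.

One structural guard sits between selection and refinement: the final model
must contain a transport (diffusion) term.  A pure-reaction model is
structurally incapable of wound closure — the reaction vanishes at zero
density, so the scratch centre could never repopulate — yet the weak-form
loss is often nearly flat in the diffusion coefficients (random motility is
the least identifiable mechanism in this data, and its regression estimate
is strongly attenuated by observation noise).  When the elbow criterion
drops every diffusion column, the model is expanded with the constant
diffusivity term and the expanded set is re-fit by least squares before
refinement, mirroring the established workflow of expanding the model when
the loss shows low sensitivity to the diffusive coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import NodalFieldSeries, build_mesh_from_field
from .forward import SolverConfig
from .ingest import DensityField, bin_replicates, smooth_field
from .refine import RefineResult, refine_parameters
from .vsi import (
    ADRModel,
    VSIResult,
    build_library,
    library_stride,
    select_model,
    select_significant,
    solve_ls,
    stepwise_regression,
)

__all__ = ["PipelineResult", "ingest_tables", "infer_model"]

DIFFUSION_INDICES = (0, 1, 2)


@dataclass
class PipelineResult:
    """Everything the two-stage inference produced."""

    vsi: VSIResult
    selected_active: tuple[int, ...]
    expanded: bool
    model_vsi: ADRModel
    refine: RefineResult

    @property
    def model(self) -> ADRModel:
        return self.refine.model

    @property
    def theta(self) -> np.ndarray:
        return self.refine.theta


def ingest_tables(
    tables: list[pd.DataFrame],
    bin_size: float,
    domain,
    spatial_window: float = 150.0,
    temporal_window: float = 11.0 / 3.0,
    dims: int = 1,
    strip_width: float | None = None,
    collapse: bool = False,
) -> list[NodalFieldSeries]:
    """Bin and smooth each replicate table, returning nodal field series."""
    from .ingest import collapse_to_1d

    series = []
    for tab in tables:
        fields = bin_replicates(tab, bin_size, domain, dims, strip_width)
        for f in fields.values():
            if collapse:
                f = collapse_to_1d(f)
            f = smooth_field(f, spatial_window, temporal_window)
            _, s = build_mesh_from_field(f)
            series.append(s)
    return series


def infer_model(
    series: list[NodalFieldSeries] | NodalFieldSeries,
    v_unit=None,
    selection: str = "significance",
    rho: float = 0.05,
    stride: int | None = None,
    temporal_window: float | None = 11.0 / 3.0,
    cfg: SolverConfig | None = None,
    ensure_transport: bool = True,
    refine_tol: float = 1e-9,
) -> PipelineResult:
    """Run VSI + stepwise selection + PDE-constrained refinement.

    ``stride`` defaults to one library row-block per temporal smoothing
    window (see :func:`scratchpde.vsi.library_stride`).  ``selection`` picks
    the stopping rule on the elimination path: ``"significance"`` (default;
    F-to-remove, robust when the loss is noise-dominated) or ``"elbow"``
    (loss within (1+rho) of the full library).  With ``ensure_transport``
    the selected model is expanded with the constant diffusivity term when
    selection retained no diffusion column; the expanded set is
    re-estimated by least squares so refinement starts from the regression
    values.
    """
    series_list = series if isinstance(series, (list, tuple)) else [series]
    if v_unit is None:
        v_unit = np.eye(series_list[0].mesh.dim)[0]
    if stride is None:
        dt = float(np.median(np.diff(series_list[0].t)))
        stride = library_stride(dt, temporal_window)

    system = build_library(series_list, v_unit=v_unit, stride=stride)
    path = stepwise_regression(system)
    if selection == "significance":
        step = select_significant(path, system.n_rows)
    elif selection == "elbow":
        step = select_model(path, rho)
    else:
        raise ValueError("selection must be 'significance' or 'elbow'")
    active = step.active
    theta = step.theta
    expanded = False
    if ensure_transport and not set(active) & set(DIFFUSION_INDICES):
        active = tuple(sorted(set(active) | {0}))
        theta, _ = solve_ls(system, active)
        expanded = True
    model = ADRModel(theta, active, v_unit)
    result = refine_parameters(
        model, list(series_list), cfg=cfg or SolverConfig(), tol=refine_tol
    )
    return PipelineResult(path, active, expanded, model, result)
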
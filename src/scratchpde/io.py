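"""Serialization: HDF5 density/nodal containers and JSON model files."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .fem import Mesh, NodalFieldSeries
from .ingest import DensityField
from .vsi import ADRModel, ANSATZ_LABELS, _UNITS

__all__ = [
    "save_field",
    "load_field",
    "save_series",
    "load_series",
    "save_model",
    "load_model",
]


def save_field(path, field: DensityField, series: NodalFieldSeries | None = None) -> None:
    """Write a density field (and optionally its FE interpolant) to HDF5.

    Layout: datasets ``/x1``, ``/x2`` (2D only), ``/t``, ``/C``; attributes
    ``bin_size_um``, ``strip_width_um``, ``smooth_spatial_um``,
    ``smooth_temporal_hr``; optional groups ``/mesh`` and ``/nodal``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("x1", data=field.x1)
        if field.x2 is not None:
            f.create_dataset("x2", data=field.x2)
        f.create_dataset("t", data=field.t)
        f.create_dataset("C", data=field.C)
        for name, val in (
            ("bin_size_um", field.bin_size),
            ("strip_width_um", field.strip_width),
            ("smooth_spatial_um", field.smooth_spatial),
            ("smooth_temporal_hr", field.smooth_temporal),
        ):
            if val is not None:
                f.attrs[name] = val
        if series is not None:
            g = f.create_group("mesh")
            g.create_dataset("nodes", data=series.mesh.nodes)
            g.create_dataset("elements", data=series.mesh.elements)
            g.create_dataset("boundary_nodes", data=series.mesh.boundary_nodes)
            n = f.create_group("nodal")
            n.create_dataset("d", data=series.d)
            n.create_dataset("t", data=series.t)


def load_field(path) -> DensityField:
    with h5py.File(path, "r") as f:
        return DensityField(
            x1=f["x1"][...],
            x2=f["x2"][...] if "x2" in f else None,
            t=f["t"][...],
            C=f["C"][...],
            bin_size=float(f.attrs["bin_size_um"]) if "bin_size_um" in f.attrs else None,
            strip_width=(
                float(f.attrs["strip_width_um"]) if "strip_width_um" in f.attrs else None
            ),
            smooth_spatial=(
                float(f.attrs["smooth_spatial_um"])
                if "smooth_spatial_um" in f.attrs
                else None
            ),
            smooth_temporal=(
                float(f.attrs["smooth_temporal_hr"])
                if "smooth_temporal_hr" in f.attrs
                else None
            ),
        )


def save_series(path, series: NodalFieldSeries) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("mesh")
        g.create_dataset("nodes", data=series.mesh.nodes)
        g.create_dataset("elements", data=series.mesh.elements)
        g.create_dataset("boundary_nodes", data=series.mesh.boundary_nodes)
        n = f.create_group("nodal")
        n.create_dataset("d", data=series.d)
        n.create_dataset("t", data=series.t)


def load_series(path) -> NodalFieldSeries:
    with h5py.File(path, "r") as f:
        mesh = Mesh(
            f["mesh/nodes"][...],
            f["mesh/elements"][...],
            f["mesh/boundary_nodes"][...],
        )
        return NodalFieldSeries(mesh, f["nodal/t"][...], f["nodal/d"][...])


def save_model(path, model: ADRModel, extra: dict | None = None) -> None:
    """Write a model JSON: θ, active set, ansatz labels and units, direction,
    plus any extra blocks (loss path, refined coefficients, covariance...)."""
    doc = {
        "theta": model.theta.tolist(),
        "active_set": list(model.active),
        "v_unit": model.v_unit.tolist(),
        "ansatz": list(ANSATZ_LABELS),
        "units": list(_UNITS),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> tuple[ADRModel, dict]:
    doc = json.loads(Path(path).read_text())
    theta_key = "theta_refined" if "theta_refined" in doc else "theta"
    model = ADRModel(
        np.array(doc[theta_key], dtype=float),
        tuple(doc["active_set"]),
        np.array(doc["v_unit"], dtype=float),
    )
    return model, doc
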
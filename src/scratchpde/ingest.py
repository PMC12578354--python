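"""From cell centroids to smoothed density fields and wound-closure metrics.

The raw observations are tables of nuclear-centroid positions per imaging
frame (produced upstream by fluorescence image processing, which is out of
scope here).  Ingestion bins centroids into areal densities C(x, t) in
cells/μm², smooths them with separable moving averages in space and time
(smoothing tames the noise amplification of numerical differentiation
downstream), optionally reduces 2D fields to 1D profiles by averaging along
the direction parallel to the scratch, and quantifies wound closure from the
distance between automatically detected wound edges.

Conventions: bins are half-open intervals [x, x+Δ) tiling the declared
domain (a point exactly on the upper domain edge is assigned to the last
bin); bin centres become finite-element node coordinates downstream; units
are μm and hr; replicates are kept separate through ingestion — aggregation
happens only in the inference losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

__all__ = [
    "DensityField",
    "WoundEdges",
    "WoundMetrics",
    "CENTROID_COLUMNS",
    "read_centroids",
    "bin_centroids",
    "bin_replicates",
    "smooth_field",
    "collapse_to_1d",
    "detect_wound_edges",
    "wound_closure",
    "closure_metrics",
]

CENTROID_COLUMNS = ("x1_um", "x2_um", "t_hr", "replicate")


@dataclass
class DensityField:
    """Binned (optionally smoothed) cell density on a regular space-time grid.

    ``C`` is indexed (x1[, x2], t) in cells/μm²; ``x1``/``x2`` are bin-centre
    coordinates.  1D fields carry the strip width (the x2 extent the counts
    were divided by) so units stay areal.
    """

    x1: np.ndarray
    t: np.ndarray
    C: np.ndarray
    x2: np.ndarray | None = None
    bin_size: float | None = None
    strip_width: float | None = None
    smooth_spatial: float | None = None
    smooth_temporal: float | None = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float).ravel()
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float)
        if self.x2 is not None:
            self.x2 = np.asarray(self.x2, dtype=float).ravel()
        expected = (
            (len(self.x1), len(self.t))
            if self.x2 is None
            else (len(self.x1), len(self.x2), len(self.t))
        )
        if self.C.shape != expected:
            raise ValueError(f"C shape {self.C.shape} != grid shape {expected}")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("density field must be finite")
        if np.any(self.C < 0):
            raise ValueError("density field must be nonnegative")
        for ax in (self.x1, self.x2, self.t):
            if ax is not None and len(ax) > 2:
                sp = np.diff(ax)
                if not np.allclose(sp, sp[0], rtol=1e-6, atol=1e-9):
                    raise ValueError("grid spacings must be uniform")

    @property
    def ndim_space(self) -> int:
        return 1 if self.x2 is None else 2


def read_centroids(path) -> pd.DataFrame:
    """Read a centroid CSV with the required header x1_um,x2_um,t_hr,replicate."""
    df = pd.read_csv(path)
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"centroid table missing columns {missing}")
    return df


def _axis_edges(lo: float, hi: float, bin_size: float) -> np.ndarray:
    n = (hi - lo) / bin_size
    n_int = int(round(n))
    if n_int < 1 or abs(n - n_int) > 1e-6:
        raise ValueError(
            f"domain extent {hi - lo} μm is not a multiple of bin size {bin_size} μm"
        )
    return lo + bin_size * np.arange(n_int + 1)


def _bin_index(v: np.ndarray, lo: float, bin_size: float, n: int) -> np.ndarray:
    idx = np.floor((v - lo) / bin_size).astype(int)
    # Half-open bins [x, x+Δ); the upper domain edge closes the last bin.
    idx[np.asarray(v) >= lo + n * bin_size - 1e-9] = n - 1
    return idx


def bin_centroids(
    table: pd.DataFrame,
    bin_size: float,
    domain,
    dims: int = 1,
    strip_width: float | None = None,
) -> DensityField:
    """Bin one replicate's centroids into a density field.

    ``domain`` is ``((x1_lo, x1_hi),)`` or ``((x1_lo, x1_hi), (x2_lo, x2_hi))``;
    its extent must tile into whole bins.  For ``dims=1`` the counts per x1
    bin are divided by ``bin_size × strip_width`` (the strip width defaults to
    the declared x2 extent of the domain) so densities remain areal.
    Centroids outside the domain are rejected with their row indices.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    domain = tuple(tuple(map(float, d)) for d in np.atleast_2d(domain))
    if table["replicate"].nunique() > 1:
        raise ValueError(
            "table holds multiple replicates; use bin_replicates to keep them separate"
        )
    t_frames = np.unique(np.asarray(table["t_hr"], dtype=float))
    x1 = np.asarray(table["x1_um"], dtype=float)
    x2 = np.asarray(table["x2_um"], dtype=float)

    (x1_lo, x1_hi) = domain[0]
    edges1 = _axis_edges(x1_lo, x1_hi, bin_size)
    n1 = len(edges1) - 1
    bad = (x1 < x1_lo) | (x1 > x1_hi)
    if len(domain) > 1:
        (x2_lo, x2_hi) = domain[1]
        bad |= (x2 < x2_lo) | (x2 > x2_hi)
    if np.any(bad):
        raise ValueError(
            f"centroids outside declared domain at rows {np.flatnonzero(bad).tolist()}"
        )
    if len(table) == 0:
        warnings.warn("empty centroid table; returning all-zero field", stacklevel=2)
        t_frames = np.array([0.0])

    frame_of = {t: j for j, t in enumerate(t_frames)}
    jt = np.array([frame_of[t] for t in np.asarray(table["t_hr"], dtype=float)], dtype=int)

    if dims == 1:
        if strip_width is None:
            if len(domain) < 2:
                raise ValueError(
                    "1D binning needs strip_width or a declared x2 domain extent"
                )
            strip_width = domain[1][1] - domain[1][0]
        counts = np.zeros((n1, len(t_frames)))
        i1 = _bin_index(x1, x1_lo, bin_size, n1)
        np.add.at(counts, (i1, jt), 1.0)
        C = counts / (bin_size * strip_width)
        centers1 = (edges1[:-1] + edges1[1:]) / 2.0
        return DensityField(
            x1=centers1,
            t=t_frames,
            C=C,
            bin_size=bin_size,
            strip_width=float(strip_width),
        )

    if len(domain) < 2:
        raise ValueError("2D binning needs an x2 domain extent")
    edges2 = _axis_edges(domain[1][0], domain[1][1], bin_size)
    n2 = len(edges2) - 1
    counts = np.zeros((n1, n2, len(t_frames)))
    i1 = _bin_index(x1, x1_lo, bin_size, n1)
    i2 = _bin_index(x2, domain[1][0], bin_size, n2)
    np.add.at(counts, (i1, i2, jt), 1.0)
    C = counts / bin_size**2
    return DensityField(
        x1=(edges1[:-1] + edges1[1:]) / 2.0,
        x2=(edges2[:-1] + edges2[1:]) / 2.0,
        t=t_frames,
        C=C,
        bin_size=bin_size,
    )


def bin_replicates(
    table: pd.DataFrame,
    bin_size: float,
    domain,
    dims: int = 1,
    strip_width: float | None = None,
) -> dict[int, DensityField]:
    """Bin each replicate separately; returns {replicate label: field}."""
    return {
        int(rep): bin_centroids(sub, bin_size, domain, dims, strip_width)
        for rep, sub in table.groupby("replicate")
    }


def _window_bins(window: float, spacing: float, what: str) -> int:
    # A centred window of physical half-width w/2 covers every sample whose
    # centre lies within w/2 of the target: n = 2*floor(w/(2h)) + 1, always
    # odd.  The discrete window never exceeds the physical one — dilating it
    # to the next odd bin count would average in samples the physical window
    # excludes and over-smooth, which distorts the gradients inference needs.
    n = 2 * int(np.floor(window / (2.0 * spacing))) + 1
    if n < 3:
        warnings.warn(
            f"{what} window {window} spans less than three grid spacings "
            f"({spacing} each); smoothing along this axis is the identity",
            stacklevel=3,
        )
        return 1
    return n


def _moving_average(a: np.ndarray, w: int, axis: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the boundaries so only
    observed samples are averaged (no data fabricated outside the domain)."""
    if w <= 1:
        return a
    kern = np.ones(w)
    num = correlate1d(a, kern, axis=axis, mode="constant", cval=0.0)
    den = correlate1d(np.ones(a.shape[axis]), kern, mode="constant", cval=0.0)
    shape = [1] * a.ndim
    shape[axis] = -1
    return num / den.reshape(shape)


def smooth_field(
    field: DensityField, spatial_window: float, temporal_window: float
) -> DensityField:
    """Separable centred moving average: each spatial axis, then time.

    Window lengths are given in physical units and converted to the nearest
    odd number of grid cells.  The application order (space before time) and
    the windows are recorded in the returned field's metadata.
    """
    if spatial_window <= 0 or temporal_window <= 0:
        raise ValueError("smoothing windows must be positive")
    C = field.C.copy()
    dx = field.x1[1] - field.x1[0] if len(field.x1) > 1 else spatial_window
    ws = _window_bins(spatial_window, dx, "spatial")
    C = _moving_average(C, ws, axis=0)
    if field.x2 is not None and len(field.x2) > 1:
        C = _moving_average(C, _window_bins(spatial_window, field.x2[1] - field.x2[0], "spatial"), axis=1)
    if len(field.t) > 1:
        wt = _window_bins(temporal_window, field.t[1] - field.t[0], "temporal")
        C = _moving_average(C, wt, axis=C.ndim - 1)
    C = np.clip(C, 0.0, None)
    return replace(
        field,
        C=C,
        smooth_spatial=float(spatial_window),
        smooth_temporal=float(temporal_window),
    )


def collapse_to_1d(field: DensityField) -> DensityField:
    """Average a 2D field along x2 (the direction parallel to the scratch),
    yielding a 1D profile along x1.  Already-1D fields pass through."""
    if field.x2 is None:
        return field
    strip = float(len(field.x2) * (field.bin_size or (field.x2[1] - field.x2[0])))
    return DensityField(
        x1=field.x1,
        t=field.t,
        C=field.C.mean(axis=1),
        bin_size=field.bin_size,
        strip_width=strip,
        smooth_spatial=field.smooth_spatial,
        smooth_temporal=field.smooth_temporal,
    )


@dataclass
class WoundEdges:
    left: float
    right: float
    closed: bool

    @property
    def width(self) -> float:
        return self.right - self.left


@dataclass
class WoundMetrics:
    """Wound-closure summary: closure = |d_start − d_end| / d_start."""

    d_start: float
    d_end: float
    closure: float


def detect_wound_edges(
    field: DensityField, t: float, threshold_fraction: float = 0.5
) -> WoundEdges:
    """Locate the wound edges on a 1D profile at the frame closest to ``t``.

    The edges are the innermost crossings of C = threshold_fraction × plateau
    (plateau = mean density over the outer 20% of bins), linearly interpolated
    between bin centres.  If the trough never drops below the threshold the
    wound is flagged closed and both edges coincide at the trough centre.
    """
    if field.x2 is not None:
        raise ValueError("wound edges are defined on 1D profiles; collapse first")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    j = int(np.argmin(np.abs(field.t - t)))
    prof = field.C[:, j]
    x = field.x1
    n = len(x)
    n_out = max(1, int(np.ceil(0.1 * n)))
    plateau = float(np.concatenate([prof[:n_out], prof[-n_out:]]).mean())
    thr = threshold_fraction * plateau
    i_tr = int(np.argmin(prof))
    if prof[i_tr] >= thr or plateau <= 0:
        return WoundEdges(float(x[i_tr]), float(x[i_tr]), True)

    def cross(i_hi: int, i_lo: int) -> float:
        # interpolate where the profile crosses thr between bins i_hi, i_lo
        c_hi, c_lo = prof[i_hi], prof[i_lo]
        f = (c_hi - thr) / (c_hi - c_lo)
        return float(x[i_hi] + f * (x[i_lo] - x[i_hi]))

    left = float(x[0])
    for i in range(i_tr, -1, -1):
        if prof[i] >= thr:
            left = cross(i, i + 1)
            break
    right = float(x[-1])
    for i in range(i_tr, n):
        if prof[i] >= thr:
            right = cross(i, i - 1)
            break
    return WoundEdges(left, right, False)


def wound_closure(d_start: float, d_end: float) -> float:
    """Fractional wound closure |d_start − d_end| / d_start."""
    if d_start <= 0:
        raise ValueError("no wound: starting width must be positive")
    return abs(d_start - d_end) / d_start


def closure_metrics(field: DensityField, threshold_fraction: float = 0.5) -> WoundMetrics:
    """Wound closure between the first and last frames of a 1D field."""
    e0 = detect_wound_edges(field, field.t[0], threshold_fraction)
    e1 = detect_wound_edges(field, field.t[-1], threshold_fraction)
    d0, d1 = e0.width, e1.width
    return WoundMetrics(d0, d1, wound_closure(d0, d1))
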
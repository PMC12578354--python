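"""Centroid binning, smoothing, 1D collapse, and wound-closure metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scratchpde.ingest import (
    DensityField,
    bin_centroids,
    bin_replicates,
    closure_metrics,
    collapse_to_1d,
    detect_wound_edges,
    smooth_field,
    wound_closure,
)


def table(x1, x2, t, rep=0):
    return pd.DataFrame(
        {"x1_um": x1, "x2_um": x2, "t_hr": t, "replicate": rep}
    )


class TestBinning:
    def test_four_centroids_in_one_bin(self):
        tab = table([10, 20, 30, 40], [50, 50, 50, 50], 0.0)
        f = bin_centroids(tab, 100.0, ((0, 100), (0, 100)), dims=2)
        assert f.C[0, 0, 0] == pytest.approx(4e-4)

    def test_empty_bins_are_zero(self):
        tab = table([10], [10], 0.0)
        f = bin_centroids(tab, 100.0, ((0, 300), (0, 100)), dims=2)
        assert f.C[0, 0, 0] > 0
        assert f.C[1, 0, 0] == 0 and f.C[2, 0, 0] == 0

    def test_binning_conserves_counts_exactly(self, rng):
        n = 500
        tab = table(
            rng.uniform(0, 1000, n), rng.uniform(0, 400, n),
            rng.choice([0.0, 12.0], n),
        )
        f = bin_centroids(tab, 100.0, ((0, 1000), (0, 400)), dims=2)
        area = 100.0**2
        for j, t in enumerate(f.t):
            assert f.C[:, :, j].sum() * area == (tab["t_hr"] == t).sum()

    def test_1d_density_uses_strip_width(self):
        tab = table([50], [25], 0.0)
        f = bin_centroids(tab, 100.0, ((0, 100), (0, 50)), dims=1)
        assert f.C[0, 0] == pytest.approx(1.0 / (100 * 50))
        assert f.strip_width == 50.0

    def test_poisson_intensity_recovered(self):
        # Monte-Carlo oracle: homogeneous Poisson at 1e-3 /μm² over
        # 1000×1000 μm, 100 μm bins; the binned mean over many seeds must
        # sit within 3 standard errors of the intensity.
        lam, L, h = 1e-3, 1000.0, 100.0
        means = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = r.poisson(lam * L * L)
            tab = table(r.uniform(0, L, n), r.uniform(0, L, n), 0.0)
            f = bin_centroids(tab, h, ((0, L), (0, L)), dims=2)
            means.append(f.C.mean())
        se = lam / np.sqrt(lam * L * L * 50)
        assert abs(np.mean(means) - lam) < 3 * se

    def test_centroid_outside_domain_rejected_with_index(self):
        tab = table([50, 150], [10, 10], 0.0)
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            bin_centroids(tab, 100.0, ((0, 100), (0, 100)), dims=2)

    def test_empty_table_warns_and_zero_field(self):
        tab = table([], [], [])
        with pytest.warns(UserWarning, match="empty"):
            f = bin_centroids(tab, 100.0, ((0, 200), (0, 100)), dims=1)
        assert np.all(f.C == 0)

    def test_replicates_kept_separate(self):
        tab = pd.concat(
            [table([50], [50], 0.0, rep=0), table([50, 60], [50, 50], 0.0, rep=1)]
        )
        with pytest.raises(ValueError, match="replicates"):
            bin_centroids(tab, 100.0, ((0, 100), (0, 100)), dims=1)
        fields = bin_replicates(tab, 100.0, ((0, 100), (0, 100)), dims=1)
        assert fields[0].C.sum() * 100 * 100 == 1
        assert fields[1].C.sum() * 100 * 100 == 2


class TestSmoothing:
    def test_constant_field_unchanged(self):
        f = DensityField(x1=np.arange(10) * 50.0, t=[0.0, 1.0, 2.0],
                         C=np.full((10, 3), 7e-4))
        g = smooth_field(f, 150.0, 2.0)
        assert np.allclose(g.C, 7e-4)
        assert g.smooth_spatial == 150.0 and g.smooth_temporal == 2.0

    def test_interior_spike_spreads_to_window_mean(self):
        f = DensityField(x1=np.arange(11) * 50.0, t=[0.0],
                         C=np.eye(11)[:, [5]] * 1.0)
        g = smooth_field(f, 150.0, 1.0)  # 3-bin window at 50 μm spacing
        assert g.C[5, 0] == pytest.approx(1 / 3)
        assert g.C[4, 0] == pytest.approx(1 / 3)
        assert g.C[3, 0] == pytest.approx(0.0)

    def test_window_below_spacing_is_identity_with_warning(self, rng):
        C = rng.uniform(0, 1, (8, 4))
        f = DensityField(x1=np.arange(8) * 100.0, t=np.arange(4.0), C=C)
        with pytest.warns(UserWarning, match="identity"):
            g = smooth_field(f, 150.0, 0.5)  # 1.5 bins -> truncates to 1
        assert np.allclose(g.C, C)

    def test_noise_variance_reduced_by_window_product(self):
        # i.i.d.-noise field: interior output variance ≈ input / (ws*wt)
        r = np.random.default_rng(7)
        C = 1.0 + 0.3 * r.standard_normal((200, 200))
        f = DensityField(x1=np.arange(200) * 50.0, t=np.arange(200.0), C=np.abs(C))
        g = smooth_field(f, 150.0, 3.0)  # 3 spatial bins × 3 temporal frames
        inner_in = f.C[50:150, 50:150]
        inner_out = g.C[50:150, 50:150]
        ratio = inner_out.var() / inner_in.var()
        assert ratio == pytest.approx(1 / 9, rel=0.25)

    def test_boundary_shrink_preserves_constant_exactly(self):
        f = DensityField(x1=np.arange(6) * 50.0, t=[0.0], C=np.full((6, 1), 2.0))
        g = smooth_field(f, 250.0, 1.0)
        assert np.allclose(g.C, 2.0)  # shrinking window never fabricates data


class TestCollapse:
    def test_constant_in_x2_equals_any_slice(self, rng):
        prof = rng.uniform(0, 1e-3, 6)
        C = np.tile(prof[:, None, None], (1, 4, 2))
        f = DensityField(x1=np.arange(6.0) * 100, x2=np.arange(4.0) * 100,
                         t=[0.0, 1.0], C=C, bin_size=100.0)
        g = collapse_to_1d(f)
        assert np.allclose(g.C[:, 0], prof)

    def test_two_rows_average(self):
        C = np.zeros((3, 2, 1))
        C[:, 0, 0] = [1.0, 2.0, 3.0]
        C[:, 1, 0] = [3.0, 4.0, 5.0]
        f = DensityField(x1=np.arange(3.0), x2=np.arange(2.0), t=[0.0], C=C)
        assert np.allclose(collapse_to_1d(f).C[:, 0], [2.0, 3.0, 4.0])

    def test_random_field_matches_direct_mean(self, rng):
        C = rng.uniform(0, 1, (7, 5, 3))
        f = DensityField(x1=np.arange(7.0), x2=np.arange(5.0), t=np.arange(3.0), C=C)
        assert np.allclose(collapse_to_1d(f).C, C.mean(axis=1))

    def test_collapse_commutes_with_binning(self, rng):
        # x2-average of the 2D binned field equals the 1D binning of the
        # same centroids (exact identity by counting).
        n = 300
        tab = table(rng.uniform(0, 600, n), rng.uniform(0, 300, n), 0.0)
        f2 = bin_centroids(tab, 100.0, ((0, 600), (0, 300)), dims=2)
        f1 = bin_centroids(tab, 100.0, ((0, 600), (0, 300)), dims=1)
        assert np.allclose(collapse_to_1d(f2).C, f1.C, atol=1e-15)

    def test_identity_on_1d(self):
        f = DensityField(x1=np.arange(5.0), t=[0.0], C=np.ones((5, 1)))
        assert collapse_to_1d(f) is f


class TestWoundEdges:
    def _step_profile(self):
        x = np.arange(50, 1000, 100.0)  # centers 50..950
        C = np.where((x >= 300) & (x <= 700), 0.0, 1e-3)
        return DensityField(x1=x, t=[0.0], C=C[:, None])

    def test_step_profile_edges_within_one_bin(self):
        e = detect_wound_edges(self._step_profile(), 0.0, 0.5)
        assert not e.closed
        assert abs(e.left - 300) <= 100
        assert abs(e.right - 700) <= 100

    def test_uniform_profile_flagged_closed(self):
        f = DensityField(x1=np.arange(10) * 100.0, t=[0.0], C=np.full((10, 1), 1e-3))
        e = detect_wound_edges(f, 0.0, 0.5)
        assert e.closed and e.left == e.right

    def test_linear_ramp_crossing_interpolated_to_machine_precision(self):
        # plateau 1, linear ramp down to 0 between x=400 and x=600:
        # the half-max crossing sits exactly at x=500.
        x = np.arange(0, 1001, 50.0)
        C = np.clip(np.abs(x - 500) / 100.0 - 1.0, 0, None)
        C = np.minimum(C, 1.0)
        f = DensityField(x1=x, t=[0.0], C=C[:, None])
        e = detect_wound_edges(f, 0.0, 0.5)
        assert e.left == pytest.approx(350.0, abs=1e-6)
        assert e.right == pytest.approx(650.0, abs=1e-6)


class TestClosure:
    @pytest.mark.parametrize(
        "ds, de, expected", [(400, 0, 1.0), (400, 400, 0.0), (400, 100, 0.75)]
    )
    def test_closure_arithmetic(self, ds, de, expected):
        assert wound_closure(ds, de) == pytest.approx(expected)

    def test_no_wound_rejected(self):
        with pytest.raises(ValueError):
            wound_closure(0.0, 10.0)

    @given(
        ds=st.floats(1.0, 1e4),
        de=st.floats(0.0, 1e4),
        alpha=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, ds, de, alpha):
        assert wound_closure(alpha * ds, alpha * de) == pytest.approx(
            wound_closure(ds, de), rel=1e-9
        )

    def test_metrics_on_closing_scratch(self):
        x = np.arange(50, 2000, 100.0)
        trough0 = np.exp(-((x - 1000) / 220.0) ** 4)
        C0 = 1e-3 * (1 - trough0)
        C1 = 1e-3 * (1 - 0.4 * trough0)
        f = DensityField(x1=x, t=[0.0, 48.0], C=np.stack([C0, C1], axis=1))
        m = closure_metrics(f)
        assert m.d_start > 0
        assert 0 <= m.closure <= 1
        assert m.closure == pytest.approx(
            abs(m.d_start - m.d_end) / m.d_start, rel=1e-12
        )
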
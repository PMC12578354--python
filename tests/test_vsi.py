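"""Weak-form library assembly, least squares, and stepwise elimination."""

import numpy as np
import pytest

from scratchpde.fem import NodalFieldSeries, interval_mesh
from scratchpde.vsi import (
    ADRModel,
    LibrarySystem,
    build_library,
    select_model,
    select_significant,
    solve_ls,
    stack_systems,
    stepwise_regression,
)


class TestBuildLibrary:
    def test_spatially_constant_field_zeroes_diffusion_columns(self):
        mesh = interval_mesh(np.arange(5.0))
        d = np.full((3, 5), 3e-4)
        d *= np.array([1.0, 1.5, 2.0])[:, None]  # varies in time, flat in space
        sys_ = build_library(NodalFieldSeries(mesh, [0, 1, 2], d), v_unit=[1.0])
        assert np.allclose(sys_.Xi[:, 0:3], 0.0, atol=1e-18)

    def test_constant_field_hand_assembled_entries(self):
        # time-constant value c on a uniform mesh with spacing h: for an
        # interior node, Ξ6 = −∫ c N_k = −c·h and Ξ3 = 0 by symmetry.
        c, h = 4e-4, 2.0
        mesh = interval_mesh(np.array([0.0, h, 2 * h]))
        d = np.full((2, 3), c)
        sys_ = build_library(NodalFieldSeries(mesh, [0.0, 1.0], d), v_unit=[1.0])
        assert sys_.n_rows == 1  # one interior node, one usable frame
        assert sys_.Xi[0, 6] == pytest.approx(-c * h, rel=1e-12)
        assert sys_.Xi[0, 3] == pytest.approx(0.0, abs=1e-18)
        assert sys_.Xi[0, 7] == pytest.approx(-(c**2) * h, rel=1e-12)

    def test_time_constant_field_gives_zero_target(self, rng):
        mesh = interval_mesh(np.arange(9.0))
        prof = rng.uniform(0, 1e-3, 9)
        d = np.tile(prof, (4, 1))
        sys_ = build_library(NodalFieldSeries(mesh, np.arange(4.0), d), v_unit=[1.0])
        assert np.allclose(sys_.y, 0.0, atol=1e-18)

    def test_boundary_rows_excluded(self, rng):
        mesh = interval_mesh(np.arange(7.0))
        d = rng.uniform(0, 1e-3, (3, 7))
        sys_ = build_library(NodalFieldSeries(mesh, np.arange(3.0), d))
        assert sys_.n_rows == 5 * 2  # 5 interior nodes × 2 frames

    def test_stride_subsamples_frames(self, rng):
        mesh = interval_mesh(np.arange(7.0))
        d = rng.uniform(0, 1e-3, (9, 7))
        s = NodalFieldSeries(mesh, np.arange(9.0), d)
        assert build_library(s, stride=4).n_rows == 5 * 2  # frames 0,4,8


class TestSolveLS:
    def test_consistent_system_recovered_exactly(self, rng):
        Xi = rng.standard_normal((100, 8))
        theta_true = np.zeros(8)
        theta_true[[0, 6, 7]] = [2.0, -1.0, 0.5]
        sys_ = LibrarySystem(Xi @ theta_true, Xi)
        theta, loss = solve_ls(sys_, (0, 6, 7))
        assert loss < 1e-20 * np.dot(sys_.y, sys_.y)
        assert np.allclose(theta, theta_true, rtol=1e-8)

    def test_orthogonal_target_gives_zero_fit(self):
        Xi = np.zeros((4, 8))
        Xi[:2, 0] = 1.0
        y = np.array([0.0, 0.0, 1.0, -1.0])  # orthogonal to column 0
        theta, loss = solve_ls(LibrarySystem(y, Xi), (0,))
        assert np.allclose(theta, 0.0)
        assert loss == pytest.approx(float(y @ y))

    def test_empty_active_set(self, rng):
        y = rng.standard_normal(20)
        theta, loss = solve_ls(LibrarySystem(y, rng.standard_normal((20, 8))), ())
        assert np.all(theta == 0)
        assert loss == pytest.approx(float(y @ y))

    def test_matches_normal_equations_oracle(self, rng):
        Xi = rng.standard_normal((200, 8))
        y = rng.standard_normal(200)
        theta, loss = solve_ls(LibrarySystem(y, Xi), tuple(range(8)))
        oracle = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert np.allclose(theta, oracle, rtol=1e-8)

    def test_rank_deficiency_warns_minimum_norm(self, rng):
        Xi = rng.standard_normal((50, 8))
        Xi[:, 1] = Xi[:, 0]
        with pytest.warns(UserWarning, match="dependent"):
            theta, _ = solve_ls(LibrarySystem(rng.standard_normal(50), Xi), (0, 1))

    def test_column_scaling_equivariance(self, rng):
        Xi = rng.standard_normal((60, 8))
        y = rng.standard_normal(60)
        t1, l1 = solve_ls(LibrarySystem(y, Xi), (0, 4, 6))
        Xi2 = Xi.copy()
        Xi2[:, 4] *= 10.0
        t2, l2 = solve_ls(LibrarySystem(y, Xi2), (0, 4, 6))
        assert l2 == pytest.approx(l1, rel=1e-10)
        assert t2[4] == pytest.approx(t1[4] / 10.0, rel=1e-8)
        assert t2[0] == pytest.approx(t1[0], rel=1e-8)


def greedy_oracle(system, tie_rtol):
    """Independent brute-force greedy elimination with the documented tie rule."""
    active = list(range(8))
    _, loss = solve_ls(system, active)
    path = [(tuple(active), loss)]
    while len(active) > 1:
        losses = {c: solve_ls(system, [m for m in active if m != c])[1] for c in active}
        best = min(losses.values())
        tied = [c for c in active if losses[c] <= best + abs(best) * tie_rtol + 5e-324]
        active.remove(max(tied))
        _, loss = solve_ls(system, active)
        path.append((tuple(active), loss))
    return path


class TestStepwise:
    def test_path_matches_exhaustive_greedy_oracle(self, rng):
        for _ in range(5):
            Xi = rng.standard_normal((200, 8))
            y = rng.standard_normal(200)
            sys_ = LibrarySystem(y, Xi)
            result = stepwise_regression(sys_)
            oracle = greedy_oracle(sys_, tie_rtol=2.0 / sys_.n_rows)
            for step, (oa, ol) in zip(result.path, oracle):
                assert step.active == oa
                assert step.loss == pytest.approx(ol, rel=1e-10)

    def test_losses_nondecreasing_along_path(self, rng):
        Xi = rng.standard_normal((150, 8))
        theta = np.zeros(8)
        theta[[0, 6]] = [1.0, 2.0]
        y = Xi @ theta + 0.1 * rng.standard_normal(150)
        result = stepwise_regression(LibrarySystem(y, Xi))
        losses = result.losses
        assert np.all(np.diff(losses) >= -1e-12 * losses[:-1])

    def test_nested_elimination_never_decreases_loss(self, rng):
        sys_ = LibrarySystem(rng.standard_normal(80), rng.standard_normal((80, 8)))
        for active in [tuple(range(8)), (0, 2, 5, 6), (1, 7)]:
            _, full = solve_ls(sys_, active)
            for c in active:
                _, red = solve_ls(sys_, tuple(m for m in active if m != c))
                assert red >= full - 1e-12 * abs(full)

    def test_recovers_planted_support(self, rng):
        Xi = rng.standard_normal((400, 8))
        theta = np.zeros(8)
        theta[[0, 6, 7]] = [3.0, -2.0, 1.5]
        y = Xi @ theta + 1e-3 * rng.standard_normal(400)
        result = stepwise_regression(LibrarySystem(y, Xi))
        assert result.step_with(3).active == (0, 6, 7)

    def test_replicate_stacking_equals_summed_losses(self, rng):
        systems = [
            LibrarySystem(rng.standard_normal(60), rng.standard_normal((60, 8)))
            for _ in range(3)
        ]
        stacked = stack_systems(systems)
        theta, loss = solve_ls(stacked, (0, 3, 6))
        per_rep = []
        for s in systems:
            r = s.y - s.Xi[:, [0, 3, 6]] @ theta[[0, 3, 6]]
            per_rep.append(float(r @ r))
        assert loss == pytest.approx(sum(per_rep), rel=1e-12)
        # and the stacked solution minimizes the summed normal equations
        A = sum(s.Xi[:, [0, 3, 6]].T @ s.Xi[:, [0, 3, 6]] for s in systems)
        b = sum(s.Xi[:, [0, 3, 6]].T @ s.y for s in systems)
        assert np.allclose(theta[[0, 3, 6]], np.linalg.solve(A, b), rtol=1e-8)


class TestSelection:
    def _result_with_losses(self, losses):
        from scratchpde.vsi import PathStep, VSIResult

        path = [
            PathStep(tuple(range(8 - k)), np.zeros(8), l) for k, l in enumerate(losses)
        ]
        return VSIResult(path, y_norm2=max(losses))

    def test_constructed_elbow_selects_three_terms(self):
        result = self._result_with_losses([1, 1, 1, 1, 1, 1, 5, 40])
        assert len(select_model(result, 0.1).active) == 3

    def test_infinite_tolerance_selects_single_term(self):
        result = self._result_with_losses([1, 1, 1, 1, 1, 1, 5, 40])
        assert len(select_model(result, np.inf).active) == 1

    def test_selects_true_support_on_planted_fixture(self, rng):
        Xi = rng.standard_normal((400, 8))
        theta = np.zeros(8)
        theta[[0, 6, 7]] = [3.0, -2.0, 1.5]
        y = Xi @ theta + 1e-3 * rng.standard_normal(400)
        result = stepwise_regression(LibrarySystem(y, Xi))
        assert select_model(result, 0.05).active == (0, 6, 7)
        assert select_significant(result, 400).active == (0, 6, 7)

    def test_negative_tolerance_rejected(self):
        result = self._result_with_losses([1, 2, 3, 4, 5, 6, 7, 8])
        with pytest.raises(ValueError):
            select_model(result, -0.1)


class TestADRModel:
    def test_inactive_entries_zeroed_and_v_normalized(self):
        m = ADRModel(np.ones(8), active=(0, 6), v_unit=[3.0, 4.0])
        assert m.theta[1] == 0 and m.theta[7] == 0
        assert np.linalg.norm(m.v_unit) == pytest.approx(1.0)

    def test_ansatz_evaluation(self):
        m = ADRModel([2.0, 0, 0, 0, 0, 0, 0.1, -50.0], active=(0, 6, 7), v_unit=[1.0])
        assert m.diffusivity(0.5) == 2.0
        assert m.reaction(1e-3) == pytest.approx(0.1 * 1e-3 - 50 * 1e-6)
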
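"""Group-sparse EC solver, Pearson FC, Granger causality, vectorisation."""

import numpy as np
import pytest
from scipy import optimize

from ecgcn.connectivity import (
    SolverConfig,
    alpha_max,
    granger_ec,
    group_sparse_ec,
    pearson_fc,
    vectorize_connectivity,
)
from ecgcn.exceptions import ValidationError
from ecgcn.signals import RoiTimeSeries
from ecgcn.synthetic import simulate_regression_fixture


def _series(data, sid="s", tr=2.0):
    return RoiTimeSeries(sid, np.asarray(data, float), tr)


class TestGroupSparseEc:
    def test_alpha_zero_equals_ols(self, rng):
        T, R = 200, 5
        x = rng.standard_normal((T, R))
        ts = _series(x)
        stack = group_sparse_ec(
            [ts], SolverConfig(alpha=0.0, standardize_inputs=False, max_iter=5000,
                               tol=1e-12)
        )
        for r in range(R):
            keep = [j for j in range(R) if j != r]
            w_ols, *_ = np.linalg.lstsq(x[:, keep], x[:, r], rcond=None)
            np.testing.assert_allclose(stack.matrices[0][keep, r], w_ols, atol=1e-6)

    def test_alpha_above_alpha_max_gives_zeros(self, rng):
        series = [
            _series(rng.standard_normal((50, 4)), "a"),
            _series(rng.standard_normal((50, 4)), "b"),
        ]
        for r in range(4):
            am = alpha_max(series, r)
            stack = group_sparse_ec(series, SolverConfig(alpha=1.001 * am))
            assert np.all(stack.matrices[:, :, r] == 0)
        # below alpha_max at least one connection survives for that target
        am0 = alpha_max(series, 0)
        stack = group_sparse_ec(series, SolverConfig(alpha=0.5 * am0))
        assert np.any(stack.matrices[:, :, 0] != 0)

    def test_noiseless_fixture_recovery(self):
        series, coefs = simulate_regression_fixture(
            T=120, R=8, sparsity=3, noise_sd=0.0, n_subjects=2, seed=3
        )
        stack = group_sparse_ec(
            series,
            SolverConfig(alpha=0.05, standardize_inputs=False, max_iter=20_000,
                         tol=1e-14),
        )
        est = stack.matrices[:, :, 0]  # destination ROI 0
        assert set(np.flatnonzero(np.any(est != 0, axis=0))) == set(
            np.flatnonzero(coefs[0])
        )
        np.testing.assert_allclose(est, coefs, atol=1e-3)

    def test_subjects_share_support_with_distinct_weights(self):
        series, coefs = simulate_regression_fixture(
            T=100, R=8, sparsity=3, noise_sd=0.05, n_subjects=3, seed=9
        )
        stack = group_sparse_ec(
            series, SolverConfig(alpha=1.0, standardize_inputs=False)
        )
        est = stack.matrices[:, :, 0]
        nz = est != 0
        # group property: each connection is active for all subjects or none
        assert np.all(np.logical_or(nz.all(axis=0), ~nz.any(axis=0)))
        active = np.flatnonzero(nz.all(axis=0))
        assert active.size > 0
        assert not np.allclose(est[0, active], est[1, active])

    def test_matches_brute_force_minimizer(self, rng):
        # small instances: direct optimisation of the smooth + l2,1 objective
        N, R, T = 2, 4, 25
        data = [rng.standard_normal((T, R)) for _ in range(N)]
        series = [_series(d, f"s{i}") for i, d in enumerate(data)]
        alpha = 2.0
        r = 1
        keep = [j for j in range(R) if j != r]
        Xs = [d[:, keep] for d in data]
        ys = [d[:, r] for d in data]

        def objective(flat):
            W = flat.reshape(R - 1, N)
            smooth = sum(
                0.5 * np.sum((ys[n] - Xs[n] @ W[:, n]) ** 2) for n in range(N)
            )
            return smooth + alpha * np.sum(np.linalg.norm(W, axis=1))

        stack = group_sparse_ec(
            series,
            SolverConfig(alpha=alpha, standardize_inputs=False, tol=1e-14,
                         max_iter=20_000),
        )
        ours = np.column_stack([stack.matrices[n][keep, r] for n in range(N)])
        best = np.inf
        for _ in range(5):
            res = optimize.minimize(
                objective, rng.standard_normal((R - 1) * N) * 0.1,
                method="Powell",
                options={"maxiter": 20_000, "xtol": 1e-10, "ftol": 1e-12},
            )
            best = min(best, res.fun)
        assert objective(ours.ravel()) <= best + 1e-4

    def test_objective_non_increasing(self, rng):
        series = [_series(rng.standard_normal((40, 5)), f"s{i}") for i in range(2)]
        stack = group_sparse_ec(
            series, SolverConfig(alpha=5.0), record_trajectories=True
        )
        for traj in stack.trajectories:
            diffs = np.diff(traj)
            assert np.all(diffs <= 1e-9)

    def test_sparsity_monotone_in_alpha(self, rng):
        series = [_series(rng.standard_normal((60, 6)), f"s{i}") for i in range(2)]
        am = max(alpha_max(series, r) for r in range(6))
        counts = []
        for frac in (0.02, 0.1, 0.3, 0.6, 1.1):
            stack = group_sparse_ec(series, SolverConfig(alpha=frac * am))
            counts.append(int(stack.support_mask.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_mismatched_roi_counts_rejected(self, rng):
        series = [
            _series(rng.standard_normal((30, 4)), "a"),
            _series(rng.standard_normal((30, 5)), "b"),
        ]
        with pytest.raises(ValidationError, match="ROIs"):
            group_sparse_ec(series, SolverConfig(alpha=1.0))


class TestAlphaMax:
    def test_unit_norm_single_predictor(self):
        v = np.zeros(8)
        v[0] = 1.0
        data = np.column_stack([v, v])
        am = alpha_max([_series(data)], r=1, standardize_inputs=False)
        assert am == pytest.approx(1.0, abs=1e-12)

    def test_zero_destination_gives_zero(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 2] = 0.0
        am = alpha_max([_series(x)], r=2, standardize_inputs=False)
        assert am == 0.0

    def test_invalid_index_rejected(self, rng):
        with pytest.raises(IndexError):
            alpha_max([_series(rng.standard_normal((20, 3)))], r=3)


class TestPearsonFc:
    def test_diagonal_and_anticorrelation(self, rng):
        x = rng.standard_normal(50)
        data = np.column_stack([x, -x, rng.standard_normal(50)])
        fc = pearson_fc(_series(data))
        np.testing.assert_allclose(np.diag(fc.matrix), 1.0, atol=1e-12)
        assert fc.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_known_correlation_value(self):
        data = np.column_stack([[1, 2, 3, 4], [1, 2, 3, 5]]).astype(float)
        data = np.column_stack([data, [0.0, 1.0, 0.0, 1.0]])
        fc = pearson_fc(_series(data))
        assert fc.matrix[0, 1] == pytest.approx(0.9827, abs=1e-4)

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((40, 4))
        fc1 = pearson_fc(_series(data))
        data2 = data.copy()
        data2[:, 2] = 3.5 * data2[:, 2] + 11.0
        fc2 = pearson_fc(_series(data2))
        np.testing.assert_allclose(fc1.matrix, fc2.matrix, atol=1e-12)

    def test_constant_column_rejected(self, rng):
        data = rng.standard_normal((30, 3))
        data[:, 1] = 2.0
        with pytest.raises(ValidationError, match="1"):
            pearson_fc(_series(data))


class TestGrangerEc:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2000, 2))
        g = granger_ec(_series(data), order=1)
        assert g[0, 1] < 0.01 and g[1, 0] < 0.01

    def test_lagged_dependence_is_directional(self):
        rng = np.random.default_rng(1)
        T = 500
        x = np.zeros((T, 2))
        x[:, 0] = rng.standard_normal(T)
        for t in range(1, T):
            x[t, 1] = 0.9 * x[t - 1, 0] + 0.1 * rng.standard_normal()
        g = granger_ec(_series(x), order=1)
        assert g[0, 1] > g[1, 0]
        assert g[0, 1] > 0.5

    def test_diagonal_zero_and_nonnegative(self, rng):
        g = granger_ec(_series(rng.standard_normal((100, 4))), order=2)
        assert np.all(np.diag(g) == 0)
        assert np.all(g >= 0)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValidationError, match="too short"):
            granger_ec(_series(rng.standard_normal((4, 2))), order=1)


class TestVectorize:
    def test_fc_length_for_r114(self):
        m = np.eye(114)
        assert vectorize_connectivity(m, "fc").size == 6441

    def test_ec_length_and_structural_zeros(self, rng):
        m = rng.standard_normal((114, 114))
        np.fill_diagonal(m, 0.0)
        v = vectorize_connectivity(m, "ec")
        assert v.size == 114**2
        diag_positions = [r * 114 + r for r in range(114)]
        assert np.all(v[diag_positions] == 0)

    def test_ec_ordering_destination_major(self):
        m = np.zeros((3, 3))
        m[1, 0] = 0.7  # source 2 -> destination 1 (1-based)
        v = vectorize_connectivity(m, "ec")
        assert v[1] == 0.7  # 1-based index 2

    def test_fc_row_major_upper_triangle(self):
        m = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.4], [0.3, 0.4, 1.0]])
        np.testing.assert_allclose(
            vectorize_connectivity(m, "fc"), [0.2, 0.3, 0.4]
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            vectorize_connectivity(np.zeros((3, 4)), "ec")
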
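"""DEA envelopment solver: forced analytic cases, grid-oracle agreement,
and the frontier invariances (units, scale, monotonicity, projection)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flockbench import (
    DEAProblem,
    SolverSettings,
    compute_te,
    maximize_slacks,
    project_to_frontier,
    solve_all,
    solve_theta,
)

from .oracle_grid import brute_force_slacks, grid_theta, random_instance


def _thetas(problem, settings=SolverSettings()):
    return np.array([solve_theta(problem, i, settings)[0] for i in range(problem.n)])


class TestRadialPhase:
    def test_single_dmu_self_envelops(self):
        p = DEAProblem(X=[[3.0]], y=[7.0])
        theta, lam = solve_theta(p, 0)
        assert theta == pytest.approx(1.0, abs=1e-9)
        assert lam[0] == pytest.approx(1.0, abs=1e-7)

    def test_dominated_twin_doubles_output(self):
        # identical inputs, half the output: radial expansion is exactly 2
        p = DEAProblem(X=[[1.0, 1.0]], y=[100.0, 50.0])
        theta, _ = solve_theta(p, 1)
        assert theta == pytest.approx(2.0, abs=1e-9)
        assert compute_te(theta) == pytest.approx(0.5, abs=1e-9)

    def test_convexity_blocks_downscaling(self):
        # B(x=1,y=1) cannot be benchmarked against a scaled-down A(x=2,y=2):
        # intensity weights must sum to 1 under variable returns to scale
        p = DEAProblem(X=[[2.0, 1.0]], y=[2.0, 1.0])
        theta, _ = solve_theta(p, 1)
        assert theta == pytest.approx(1.0, abs=1e-9)

    def test_identical_dmus_all_efficient(self):
        p = DEAProblem(X=np.ones((2, 4)), y=np.full(4, 5.0))
        assert _thetas(p) == pytest.approx(np.ones(4), abs=1e-9)

    def test_max_output_dmu_always_efficient(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n_max=6)
        i = int(np.argmax(y))
        theta, _ = solve_theta(DEAProblem(X=X, y=y), i)
        assert theta == pytest.approx(1.0, abs=1e-9)

    def test_grid_oracle_agreement(self):
        """LP optimum matches the simplex grid search within grid resolution."""
        rng = np.random.default_rng(77)
        step = 0.005
        for _ in range(30):
            X, y = random_instance(rng)
            p = DEAProblem(X=X, y=y)
            i = int(rng.integers(0, p.n))
            theta, _ = solve_theta(p, i)
            theta_grid = grid_theta(X, y, i, step=step)
            assert theta >= theta_grid - 1e-9  # grid never beats the LP
            bound = step * (p.m + 1) * y.max() / y[i]
            assert theta - theta_grid <= bound

    def test_bad_index_raises(self):
        p = DEAProblem(X=[[1.0]], y=[1.0])
        with pytest.raises(IndexError):
            solve_theta(p, 3)


class TestSlackPhase:
    def test_frontier_vertex_has_zero_slacks(self):
        X = np.array([[1.0, 2.0, 3.0]])
        y = np.array([2.0, 3.5, 4.0])  # strictly concave increasing: all vertices
        p = DEAProblem(X=X, y=y)
        for i in range(3):
            theta, _ = solve_theta(p, i)
            s, s_out, _ = maximize_slacks(p, i, theta)
            assert theta == pytest.approx(1.0, abs=1e-9)
            assert np.all(s <= 1e-8) and s_out <= 1e-8

    def test_weakly_efficient_unit_has_input_slack(self):
        # B matches A's output but wastes 4 units of input 2
        p = DEAProblem(X=np.array([[1.0, 1.0], [1.0, 5.0]]), y=np.array([10.0, 10.0]))
        theta, _ = solve_theta(p, 1)
        s, s_out, _ = maximize_slacks(p, 1, theta)
        assert theta == pytest.approx(1.0, abs=1e-9)
        assert s == pytest.approx([0.0, 4.0], abs=1e-8)
        assert s_out == pytest.approx(0.0, abs=1e-8)

    def test_brute_force_oracle_agreement(self):
        """Phase-2 total slack equals exact basic-solution enumeration."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            X, y = random_instance(rng)
            p = DEAProblem(X=X, y=y)
            i = int(rng.integers(0, p.n))
            theta, _ = solve_theta(p, i)
            s, s_out, _ = maximize_slacks(p, i, theta)
            s_ref, s_out_ref = brute_force_slacks(X, y, i, theta)
            assert s.sum() + s_out == pytest.approx(s_ref.sum() + s_out_ref, abs=1e-6)

    def test_input_mean_scaled_objective_runs(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng)
        p = DEAProblem(X=X, y=y)
        cfg = SolverSettings(slack_normalization="input-mean-scaled")
        theta, _ = solve_theta(p, 0, cfg)
        s, s_out, _ = maximize_slacks(p, 0, theta, cfg)
        assert np.all(s >= 0) and s_out >= 0


class TestScalarOps:
    @pytest.mark.parametrize("theta,te", [(1.0, 1.0), (1.25, 0.8), (2.0, 0.5)])
    def test_te_is_reciprocal_theta(self, theta, te):
        assert compute_te(theta) == pytest.approx(te)

    def test_te_rejects_nonpositive_theta(self):
        with pytest.raises(ValueError):
            compute_te(0.0)

    @pytest.mark.parametrize(
        "y,theta,slack,expected",
        [(100.0, 1.372, 0.0, 137.2), (100.0, 1.0, 0.0, 100.0), (50.0, 1.2, 5.0, 65.0)],
    )
    def test_projection_arithmetic(self, y, theta, slack, expected):
        assert project_to_frontier(y, theta, slack) == pytest.approx(expected)

    @given(theta=st.floats(min_value=1.0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_te_always_in_unit_interval(self, theta):
        assert 0.0 < compute_te(theta) <= 1.0


class TestFrontierInvariances:
    N_INSTANCES = 15

    def _instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(self.N_INSTANCES):
            X, y = random_instance(rng, n_max=6, m_max=2)
            yield rng, X, y

    def test_theta_at_least_one_te_in_unit_interval(self):
        for _, X, y in self._instances(101):
            for r in solve_all(DEAProblem(X=X, y=y)):
                assert r.theta >= 1.0 - 1e-9
                assert 0.0 < r.te <= 1.0

    def test_units_invariance_of_input_rows(self):
        for rng, X, y in self._instances(102):
            base = _thetas(DEAProblem(X=X, y=y))
            c = float(rng.uniform(0.1, 50.0))
            k = int(rng.integers(0, X.shape[0]))
            X2 = X.copy()
            X2[k] *= c
            assert _thetas(DEAProblem(X=X2, y=y)) == pytest.approx(base, abs=1e-6)

    def test_output_scale_invariance(self):
        for rng, X, y in self._instances(103):
            base = _thetas(DEAProblem(X=X, y=y))
            c = float(rng.uniform(0.1, 50.0))
            assert _thetas(DEAProblem(X=X, y=y * c)) == pytest.approx(base, abs=1e-6)

    def test_appending_dmu_never_raises_te(self):
        for rng, X, y in self._instances(104):
            base = 1.0 / _thetas(DEAProblem(X=X, y=y))
            xnew = rng.uniform(0.5, 5.0, size=(X.shape[0], 1))
            ynew = rng.uniform(1.0, 10.0)
            grown = DEAProblem(X=np.hstack([X, xnew]), y=np.append(y, ynew))
            te2 = 1.0 / _thetas(grown)[: y.size]
            assert np.all(te2 <= base + 1e-7)

    def test_deleting_inefficient_dmu_changes_nothing(self):
        for _, X, y in self._instances(105):
            p = DEAProblem(X=X, y=y)
            te = 1.0 / _thetas(p)
            ineff = np.flatnonzero(te < 1.0 - 1e-6)
            if ineff.size == 0:
                continue
            drop = int(ineff[0])
            keep = [j for j in range(p.n) if j != drop]
            reduced = DEAProblem(X=X[:, keep], y=y[keep])
            te2 = 1.0 / _thetas(reduced)
            assert te2 == pytest.approx(te[keep], abs=1e-6)

    def test_projected_point_is_efficient(self):
        for _, X, y in self._instances(106):
            p = DEAProblem(X=X, y=y)
            results = solve_all(p)
            r = max(results, key=lambda r: r.theta)  # most inefficient unit
            X2 = np.hstack([X, r.projected_inputs[:, None]])
            y2 = np.append(y, r.projected_output)
            theta_proj, _ = solve_theta(DEAProblem(X=X2, y=y2), p.n)
            assert theta_proj == pytest.approx(1.0, abs=1e-6)


class TestSolveAll:
    def test_known_te_construction_recovered(self):
        # 3 frontier anchors on a concave curve; 3 farms built by scaling
        # anchor outputs down by known factors -> DEA must return exactly those
        anchors_x = np.array([1.0, 2.0, 4.0])
        anchors_y = np.array([5.0, 8.0, 11.0])
        te_true = np.array([1.0, 0.8, 0.5])
        X = np.concatenate([anchors_x, anchors_x])[None, :]
        y = np.concatenate([anchors_y, anchors_y * te_true])
        results = solve_all(DEAProblem(X=X, y=y))
        te_hat = np.array([r.te for r in results])
        assert te_hat == pytest.approx(np.concatenate([np.ones(3), te_true]), abs=1e-6)

    def test_at_least_one_efficient_and_deterministic(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng)
        p = DEAProblem(X=X, y=y)
        r1 = solve_all(p)
        r2 = solve_all(p)
        assert any(r.te >= 1.0 - 1e-9 for r in r1)
        assert [r.theta for r in r1] == [r.theta for r in r2]

    def test_result_contracts(self, solved_population):
        _, records, _, results = solved_population
        cfg = SolverSettings()
        for rec, r in zip(records, results):
            assert r.te == pytest.approx(1.0 / r.theta, abs=1e-7)
            assert r.lambdas.min() >= -1e-9
            assert r.lambdas.sum() == pytest.approx(1.0, abs=1e-6)
            assert r.projected_output == pytest.approx(
                r.theta * rec.gross_revenue + r.output_slack, rel=1e-9
            )
            assert np.all(r.projected_inputs >= 0)
            assert r.projected_output >= rec.gross_revenue - 1e-6

    def test_invalid_problems_rejected(self):
        with pytest.raises(ValueError):
            DEAProblem(X=[[1.0, 1.0]], y=[1.0, -2.0])
        with pytest.raises(ValueError):
            DEAProblem(X=[[1.0, -1.0]], y=[1.0, 2.0])
        with pytest.raises(ValueError):
            DEAProblem(X=[[1.0]], y=[1.0, 2.0])
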
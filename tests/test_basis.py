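"""Basis construction, projection and approximate-value-iteration tests."""

import numpy as np
import pytest

from choicemdp.basis import (
    BasisSpec,
    DimensionBasis,
    approximate_value_iteration,
    design_matrix,
    fit_projection,
)
from choicemdp.core import ConvergenceError, SpecError, TaskSpec, value_iteration
from oracles import bspline_cox_de_boor


def test_constant_only_basis_is_column_of_ones():
    b = BasisSpec(dimensions=[DimensionBasis("piecewise", order=1, knots=())], evaluation_grid=[(0.0, 1.0)])
    phi, labels = design_matrix(np.array([[3.0], [7.0]]), b, check_rank=False)
    assert np.allclose(phi[:, 0], 1.0) and labels[0].endswith("x^0")


def test_cubic_piecewise_row_with_one_knot():
    b = BasisSpec(dimensions=[DimensionBasis("piecewise", order=3, knots=(0.0,))],
                  evaluation_grid=[(-1.0, 0.0, 1.0, 2.0)])
    phi, _ = design_matrix(np.array([[2.0]]), b, check_rank=False)
    assert np.allclose(phi[0], [1.0, 2.0, 4.0, 8.0, 8.0])


def test_bspline_partition_of_unity_and_reference_evaluator():
    dim = DimensionBasis("bspline", order=3, knots=(0.0, 50.0, 150.0))
    xs = np.linspace(0.0, 150.0, 23)
    cols, _ = dim.columns(xs)
    assert np.allclose(cols.sum(axis=1), 1.0, atol=1e-12)
    # against an independent Cox-de Boor recursion
    k = 3
    t = np.concatenate([[0.0] * (k + 1), [50.0], [150.0] * (k + 1)])
    ref = np.array([[bspline_cox_de_boor(float(x), t, j, k) for j in range(len(t) - k - 1)] for x in xs])
    assert np.allclose(cols, ref, atol=1e-12)


def test_knots_must_increase():
    with pytest.raises(SpecError, match="increasing"):
        DimensionBasis("piecewise", order=2, knots=(1.0, 1.0))


class TestProjection:
    rng = np.random.default_rng(7)
    phi = rng.normal(size=(40, 6))

    def test_hat_matrix_idempotent_and_symmetric(self):
        H = fit_projection(self.phi).H
        assert np.allclose(H @ H, H, atol=1e-8)
        assert np.allclose(H, H.T, atol=1e-8)

    def test_in_span_vector_reproduced_exactly(self):
        v = self.phi @ self.rng.normal(size=6)
        assert np.allclose(fit_projection(self.phi).project(v), v, atol=1e-9)

    def test_orthogonal_vector_projects_to_zero(self):
        p = fit_projection(self.phi)
        v = self.rng.normal(size=40)
        v_perp = v - p.project(v)
        assert np.allclose(p.project(v_perp), 0.0, atol=1e-9)

    def test_residual_orthogonal_to_columns(self):
        p = fit_projection(self.phi)
        v = self.rng.normal(size=40)
        resid = v - p.project(v)
        assert np.max(np.abs(self.phi.T @ resid)) < 1e-8

    def test_rank_deficiency_names_offending_columns(self):
        # a knot below the whole evaluation range makes its truncated-power
        # column collinear with the global quadratic
        b = BasisSpec(dimensions=[DimensionBasis("piecewise", order=2, knots=(-1.0,))],
                      evaluation_grid=[(0.0, 1.0, 2.0, 3.0, 4.0)], drop_degenerate=False)
        with pytest.raises(SpecError, match="rank-deficient"):
            design_matrix(b.grid_points(), b)

    def test_degenerate_columns_dropped_when_enabled(self):
        b = BasisSpec(dimensions=[DimensionBasis("piecewise", order=2, knots=(-1.0, 10.0))],
                      evaluation_grid=[(0.0, 1.0, 2.0, 3.0, 4.0)])
        phi, labels = design_matrix(b.grid_points(), b)
        assert "d0:(x--1)+^2" in b.dropped and "d0:(x-10)+^2" in b.dropped
        assert phi.shape[1] == len(labels) == 3


def _complete_basis_mdp():
    """Small discrete MDP whose states double as 1-D coordinates."""
    tr = {
        0: {0: [((1.0,), 1.0)], 1: [((0.0,), 1.0)]},
        1: {0: [((2.0,), 0.5), ((0.0,), 0.5)], 1: [((0.0,), 1.0)]},
        2: {0: [((2.0,), 1.0)], 1: [((0.0,), 1.0)]},
    }
    return TaskSpec(
        actions=lambda s: (0, 1),
        reward=lambda s, a: float(s[0]) * (1.0 if a == 0 else 0.4),
        transitions=lambda s, a: tr[int(s[0])][a],
        discount=0.9,
        states=[(0.0,), (1.0,), (2.0,)],
    )


class TestApproximateValueIteration:
    def test_complete_indicator_basis_recovers_exact_solution(self):
        spec = _complete_basis_mdp()
        basis = BasisSpec(dimensions=[DimensionBasis("indicator", knots=(0.0, 1.0, 2.0))],
                          evaluation_grid=[(0.0, 1.0, 2.0)])
        vf = approximate_value_iteration(spec, basis, tol=1e-10)
        exact = value_iteration(spec, tol=1e-12)
        for s in spec.states:
            assert vf(np.array([s]))[0] == pytest.approx(exact.utility(0, s), abs=1e-6)

    def test_constant_reward_constant_basis_gives_geometric_value(self):
        spec = TaskSpec(
            actions=lambda s: (0,),
            reward=lambda s, a: 3.0,
            transitions=lambda s, a: [((s[0],), 1.0)],
            discount=0.8,
            states=[(0.0,), (1.0,)],
        )
        basis = BasisSpec(dimensions=[DimensionBasis("piecewise", order=1, knots=())],
                          evaluation_grid=[(0.0, 1.0)])
        vf = approximate_value_iteration(spec, basis, tol=1e-10)
        assert np.allclose(vf.fitted, 3.0 / (1.0 - 0.8), atol=1e-6)

    def test_divergence_reports_iteration_trace(self):
        # an explosive "backup": gamma near 1 with a badly extrapolating basis
        spec = TaskSpec(
            actions=lambda s: (0,),
            reward=lambda s, a: 1.0,
            transitions=lambda s, a: [((s[0] * 2.0 + 1.0,), 1.0)],  # walks off the grid
            discount=0.99,
            states=[(0.0,), (1.0,), (2.0,)],
        )
        basis = BasisSpec(dimensions=[DimensionBasis("piecewise", order=2, knots=())],
                          evaluation_grid=[(0.0, 1.0, 2.0)])
        with pytest.raises(ConvergenceError):
            approximate_value_iteration(spec, basis, tol=1e-8, divergence_bound=1e6, max_iter=2000)

    def test_quadratic_interactions_do_not_worsen_residual(self):
        """Nested bases: adding pairwise products cannot increase the
        converged residual variance (novelty task, reduced grid)."""
        from choicemdp.novelty import default_novelty_basis, solve_novelty

        small = dict(n_grid=(1.0, 3.5, 12.0, 45.0, 148.0), p_grid=(0.0, 0.5, 1.0))
        lin = solve_novelty(gamma=0.9, tol=1e-3,
                            basis=default_novelty_basis(**small))
        b2 = default_novelty_basis(**small)
        b1 = default_novelty_basis(**small)
        b1.interaction_order = 1
        m1 = solve_novelty(gamma=0.9, tol=1e-3, basis=b1)
        m2 = solve_novelty(gamma=0.9, tol=1e-3, basis=b2)
        assert m2.value.meta["residual_variance"] <= m1.value.meta["residual_variance"] + 1e-9
        assert lin.value.meta["residual_variance"] == pytest.approx(m2.value.meta["residual_variance"])
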
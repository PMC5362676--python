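"""Laplacian assembly, the unconstrained fit, and the augmented Lagrangian solve."""

import numpy as np
import pytest

from ventjac import (
    BoundSpec,
    DisplacementField,
    FidelityData,
    GridDomain,
    ScalarImage,
    SolverOptions,
    assemble_laplacian,
    augmented_objective_gradient,
    bound_constraint,
    constraint_residual,
    fit_unconstrained,
    forward_jacobian,
    jacobian_determinant,
    solve_constrained,
)
from ventjac.constraints import ConstraintValidityError
from ventjac.solver import IllPosedError
from ventjac.synthetic import make_contraction_case, sample_fidelity


def dense_laplacian_oracle(shape):
    """Loop-built 7-point Neumann stencil matrix, one row per voxel."""
    n = int(np.prod(shape))
    A = np.zeros((n, n))
    for i1 in range(shape[0]):
        for i2 in range(shape[1]):
            for i3 in range(shape[2]):
                row = np.ravel_multi_index((i1, i2, i3), shape)
                for ax, idx in enumerate((i1, i2, i3)):
                    for step in (-1, 1):
                        nb = [i1, i2, i3]
                        nb[ax] += step
                        if 0 <= nb[ax] < shape[ax]:
                            col = np.ravel_multi_index(tuple(nb), shape)
                            A[row, col] += 1.0
                            A[row, row] -= 1.0
                        # replicated ghost: neighbor == itself, zero contribution
    return A


class TestLaplacian:
    def test_constant_null_space(self):
        op = assemble_laplacian(GridDomain((5, 6, 4)))
        np.testing.assert_allclose(op.apply(np.full((5, 6, 4), 2.5)), 0.0, atol=1e-12)

    def test_quadratic_profile_interior(self):
        dom = GridDomain((8, 5, 5))
        op = assemble_laplacian(dom)
        x1 = np.arange(8.0)[:, None, None] * np.ones((8, 5, 5))
        out = op.apply(x1**2)
        np.testing.assert_allclose(out[1:-1], 2.0, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        dom = GridDomain((5, 5, 5))
        op = assemble_laplacian(dom)
        A = dense_laplacian_oracle(dom.shape)
        v = rng.standard_normal(125)
        np.testing.assert_allclose(op.matrix @ v, A @ v, atol=1e-12)

    def test_symmetric_rows_sum_zero(self):
        op = assemble_laplacian(GridDomain((4, 4, 4)))
        M = op.matrix
        assert abs(M - M.T).max() == 0
        np.testing.assert_allclose(np.asarray(M.sum(axis=1)).ravel(), 0.0, atol=1e-12)


class TestFitUnconstrained:
    def test_interpolation_limit(self, rng):
        dom = GridDomain((4, 4, 4))
        idx = np.stack(np.meshgrid(*[np.arange(4)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = rng.standard_normal((64, 3))
        fld = fit_unconstrained(FidelityData(idx, vals), 0.0, dom)
        np.testing.assert_allclose(fld.data.reshape(3, -1).T, vals, atol=1e-10)

    def test_large_alpha_tends_to_mean(self, rng):
        dom = GridDomain((6, 6, 6))
        idx = rng.choice(216, size=30, replace=False)
        indices = np.stack(np.unravel_index(idx, dom.shape), axis=1)
        vals = rng.standard_normal((30, 3))
        fld = fit_unconstrained(FidelityData(indices, vals), 1e8, dom)
        for c in range(3):
            np.testing.assert_allclose(fld.data[c], vals[:, c].mean(), atol=1e-4)

    def test_matches_dense_normal_equations(self, rng):
        dom = GridDomain((6, 6, 6))
        flat = np.sort(rng.choice(216, size=20, replace=False))
        indices = np.stack(np.unravel_index(flat, dom.shape), axis=1)
        vals = rng.standard_normal((20, 3))
        fld = fit_unconstrained(FidelityData(indices, vals), 1.0, dom)
        A = dense_laplacian_oracle(dom.shape)
        P = np.zeros((216, 216))
        P[flat, flat] = 1.0
        M = P + A.T @ A
        for c in range(3):
            rhs = np.zeros(216)
            rhs[flat] = vals[:, c]
            want = np.linalg.solve(M, rhs)
            np.testing.assert_allclose(fld.data[c].ravel(), want, atol=1e-8)

    def test_alpha_zero_partial_data_ill_posed(self):
        dom = GridDomain((4, 4, 4))
        with pytest.raises(IllPosedError):
            fit_unconstrained(FidelityData([[0, 0, 0]], [[1.0, 0, 0]]), 0.0, dom)


class TestConstraintResidual:
    def test_zero_field_unit_target(self, domain8):
        z = DisplacementField.zeros(domain8)
        f = ScalarImage(domain8, np.ones((8, 8, 8)))
        res = constraint_residual(z, f)
        inter = domain8.interior()
        np.testing.assert_allclose(res.values[inter], 0.0, atol=1e-14)
        assert np.isnan(res.values[~inter]).all()

    def test_feasible_field_zero_residual(self, smooth_field8):
        det = jacobian_determinant(forward_jacobian(smooth_field8)).values
        res = constraint_residual(smooth_field8, ScalarImage(smooth_field8.domain, det))
        inter = smooth_field8.domain.interior()
        np.testing.assert_allclose(res.values[inter], 0.0, atol=1e-14)

    def test_matches_per_voxel_recompute(self, smooth_field8, rng):
        f = ScalarImage(smooth_field8.domain, rng.uniform(0.5, 1.5, size=(8, 8, 8)))
        res = constraint_residual(smooth_field8, f)
        det = jacobian_determinant(forward_jacobian(smooth_field8)).values
        inter = smooth_field8.domain.interior()
        np.testing.assert_allclose(res.values[inter], (det - f.values)[inter], atol=1e-14)


@pytest.fixture
def small_instance(rng):
    dom = GridDomain((4, 4, 4))
    fld, jac = make_contraction_case(dom, seed=5)
    fid = sample_fidelity(fld, 0.3, 0.05, seed=6)
    lam = np.where(dom.interior(), rng.standard_normal(dom.shape), 0.0)
    return dom, fld, jac, fid, lam


class TestAugmentedObjectiveGradient:
    def test_reduces_to_quadratic_when_unpenalized(self, small_instance):
        dom, fld, jac, fid, _ = small_instance
        lam0 = np.zeros(dom.shape)
        val, grad, terms = augmented_objective_gradient(fld, fid, 0.5, jac, lam0, 0.0)
        assert terms["constraint"] == 0.0
        # gradient equals that of the pure quadratic (fidelity + regularizer)
        op = assemble_laplacian(dom)
        want = np.zeros_like(fld.data)
        flat = fid.flat_indices(dom)
        for c in range(3):
            g = np.zeros(dom.n_voxels)
            g[flat] = 2.0 * (fld.data[c].ravel()[flat] - fid.values[:, c])
            g += 2.0 * 0.5 * (op.matrix.T @ (op.matrix @ fld.data[c].ravel()))
            want[c] = g.reshape(dom.shape)
        np.testing.assert_allclose(grad, want, atol=1e-10)

    def test_constraint_terms_vanish_at_feasible_point(self, small_instance):
        dom, fld, jac, fid, _ = small_instance
        lam0 = np.zeros(dom.shape)
        _, _, terms = augmented_objective_gradient(fld, fid, 0.5, jac, lam0, 100.0)
        assert terms["constraint"] == pytest.approx(0.0, abs=1e-20)
        assert terms["max_violation"] == pytest.approx(0.0, abs=1e-14)

    def test_gradient_matches_central_differences(self, small_instance, rng):
        dom, fld, jac, fid, lam = small_instance
        f = ScalarImage(dom, jac.values * 0.95)
        x0 = fld.data + 0.01 * rng.standard_normal(fld.data.shape)

        def fun(x):
            cand = DisplacementField(dom, x.reshape(fld.data.shape))
            v, g, _ = augmented_objective_gradient(cand, fid, 0.5, f, lam, 7.0)
            return v, g.ravel()

        v0, g0 = fun(x0.ravel())
        eps = 1e-6
        for k in range(5):
            u = rng.standard_normal(x0.size)
            u /= np.linalg.norm(u)
            vp, _ = fun(x0.ravel() + eps * u)
            vm, _ = fun(x0.ravel() - eps * u)
            fd = (vp - vm) / (2 * eps)
            assert fd == pytest.approx(float(g0 @ u), rel=1e-6, abs=1e-9)


class TestSolveConstrained:
    def test_trivially_feasible_zero_field(self):
        dom = GridDomain((6, 6, 6))
        idx = np.argwhere(np.ones(dom.shape, dtype=bool))[::7]
        fid = FidelityData(idx, np.zeros((len(idx), 3)))
        f = ScalarImage(dom, np.ones(dom.shape))
        fld, state = solve_constrained(fid, f, SolverOptions(alpha=0.5))
        assert state.converged
        assert state.violation_history[-1] <= 1e-3
        np.testing.assert_allclose(fld.data, 0.0, atol=1e-6)

    def test_recovers_target_jacobian(self):
        dom = GridDomain((8, 8, 8))
        truth, jac = make_contraction_case(dom, seed=2)
        fid = sample_fidelity(truth, 0.2, 0.1, seed=3)
        fld, state = solve_constrained(fid, jac, SolverOptions(alpha=0.1))
        assert state.converged
        inter = dom.interior()
        det = jacobian_determinant(forward_jacobian(fld)).values
        assert np.max(np.abs(det[inter] - jac.values[inter])) <= 1e-3

    def test_deterministic_trajectory(self):
        dom = GridDomain((6, 6, 6))
        truth, jac = make_contraction_case(dom, seed=4)
        fid = sample_fidelity(truth, 0.25, 0.05, seed=5)
        opts = SolverOptions(alpha=0.1)
        f1, s1 = solve_constrained(fid, jac, opts)
        f2, s2 = solve_constrained(fid, jac, opts)
        np.testing.assert_array_equal(f1.data, f2.data)
        assert s1.violation_history == s2.violation_history
        assert s1.objective_history == s2.objective_history

    def test_rejects_nonpositive_target(self):
        dom = GridDomain((6, 6, 6))
        truth, jac = make_contraction_case(dom, seed=4)
        fid = sample_fidelity(truth, 0.25, 0.05, seed=5)
        bad = ScalarImage(dom, jac.values - jac.values.max())
        with pytest.raises(ConstraintValidityError):
            solve_constrained(fid, bad, SolverOptions(alpha=0.1))

    def test_tighter_constraints_move_solution_from_fidelity(self):
        # fidelity misfit is non-decreasing along {unconstrained, UB=1.0, UB=0.75}
        dom = GridDomain((8, 8, 8))
        truth, _ = make_contraction_case(dom, seed=7)
        fid = sample_fidelity(truth, 0.2, 0.1, seed=8)
        alpha = 0.1
        unc = fit_unconstrained(fid, alpha, dom)
        unc_det = ScalarImage(dom, jacobian_determinant(forward_jacobian(unc)).values)

        def fidelity_term(fld):
            flat = fid.flat_indices(dom)
            r = fld.data.reshape(3, -1)[:, flat].T - fid.values
            return float(np.sum(r * r))

        misfits = [fidelity_term(unc)]
        for ub in (1.0, 0.75):
            f = bound_constraint(unc_det, BoundSpec(0.5, ub, 1.0))
            sol, state = solve_constrained(fid, f, SolverOptions(alpha=alpha), initial=unc)
            assert state.converged
            misfits.append(fidelity_term(sol))
        assert misfits[0] <= misfits[1] + 1e-9
        assert misfits[1] <= misfits[2] + 1e-9

    def test_nonconvergence_is_flagged(self):
        dom = GridDomain((6, 6, 6))
        truth, jac = make_contraction_case(dom, seed=4)
        fid = sample_fidelity(truth, 0.25, 0.05, seed=5)
        opts = SolverOptions(alpha=0.1, max_outer=1, inner_maxiter=2)
        _, state = solve_constrained(fid, jac, opts)
        assert not state.converged
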
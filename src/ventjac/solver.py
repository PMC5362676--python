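"""Jacobian-constrained displacement-field optimization.

The method fits a smooth displacement field to a priori fidelity data
(displacement estimates y_i from an upstream registration at voxels i in I)
while forcing the forward-difference Jacobian determinant to equal a
user-defined target image f:

    min_d  sum_{i in I} ||d(x_i) - y_i||^2  +  alpha sum_j ||A d~_j||^2
    s.t.   det(J~(x_k; d)) = f(x_k)   for every constrained voxel x_k,

where A is the 7-point centered-difference Laplacian with zero-normal
(Neumann) boundary conditions and d~_j collects component j lexicographically.
Constraints are enforced only at voxels whose three forward neighbors lie
inside Omega (the Jacobian stencil is undefined beyond the grid).

Without the constraints the problem is a strictly convex sparse linear
least-squares fit with a unique solution (``fit_unconstrained``).  With them
it is nonconvex; it is solved by the classical augmented Lagrangian method:
an outer loop maintains multiplier estimates lambda_k and a penalty mu, the
inner smooth subproblem is minimized with L-BFGS using analytic gradients
(the determinant's gradient with respect to the matrix entries is the
cofactor matrix, scattered onto the <= 12 displacement unknowns each
constraint touches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .grid import (
    DisplacementField,
    GridDomain,
    InvalidInputError,
    ScalarImage,
    cofactor3,
    det3,
    forward_jacobian,
)
from .constraints import ConstraintValidityError, validate_constraint

__all__ = [
    "FidelityData",
    "LaplacianOperator",
    "SolverOptions",
    "SolverState",
    "IllPosedError",
    "assemble_laplacian",
    "fit_unconstrained",
    "constraint_residual",
    "augmented_objective_gradient",
    "solve_constrained",
]

logger = logging.getLogger("ventjac.solver")


class IllPosedError(ValueError):
    """The unconstrained fit has no unique solution (alpha = 0 with partial data)."""


@dataclass(frozen=True)
class FidelityData:
    """A priori displacement estimates y_i ~= d(x_i) at voxels i in I.

    ``indices`` is an (M, 3) integer array of voxel indices, ``values`` the
    matching (M, 3) displacement estimates in voxel units.
    """

    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.intp).reshape(-1, 3)
        val = np.asarray(self.values, dtype=float).reshape(-1, 3)
        if idx.shape[0] != val.shape[0]:
            raise InvalidInputError("fidelity indices and values must have equal length")
        if idx.shape[0] < 1:
            raise InvalidInputError("fidelity data must contain at least one sample")
        if not np.all(np.isfinite(val)):
            raise InvalidInputError("fidelity values must be finite")
        uniq = {tuple(r) for r in idx}
        if len(uniq) != idx.shape[0]:
            raise InvalidInputError("fidelity indices must be unique")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)

    @property
    def m(self) -> int:
        return int(self.indices.shape[0])

    def check_in_grid(self, domain: GridDomain) -> None:
        n = np.asarray(domain.shape)
        if np.any(self.indices < 0) or np.any(self.indices >= n):
            raise InvalidInputError("fidelity indices fall outside the grid")

    def flat_indices(self, domain: GridDomain) -> np.ndarray:
        return np.ravel_multi_index(tuple(self.indices.T), domain.shape)


@dataclass(frozen=True)
class LaplacianOperator:
    """Sparse 7-point Neumann Laplacian on lexicographically ordered volumes."""

    matrix: sp.csr_matrix
    shape: Tuple[int, int, int]
    boundary: str = "zero-normal-derivative"

    def apply(self, volume: np.ndarray) -> np.ndarray:
        return (self.matrix @ volume.ravel()).reshape(self.shape)


@dataclass(frozen=True)
class SolverOptions:
    """Augmented Lagrangian controls.

    alpha
        Laplacian regularization weight (>= 0); sets the smoothness of the
        solution field.
    constraint_tol
        Convergence threshold on max_k |det - f| (voxel-volume units).
    mu0, mu_growth, violation_shrink
        Initial penalty, its growth factor, and the per-outer-iteration
        violation shrink factor below which the penalty is left unchanged.
    max_outer
        Outer (multiplier-update) iteration cap.
    inner_gtol0, inner_gtol_shrink, inner_gtol_min, inner_maxiter
        Projected-gradient tolerance schedule and iteration cap for the inner
        L-BFGS solves; the tolerance tightens geometrically per outer
        iteration.
    """

    alpha: float = 1.0
    constraint_tol: float = 1e-3
    mu0: float = 10.0
    mu_growth: float = 10.0
    violation_shrink: float = 0.25
    max_outer: int = 20
    inner_gtol0: float = 1e-4
    inner_gtol_shrink: float = 0.2
    inner_gtol_min: float = 1e-10
    inner_maxiter: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.constraint_tol <= 0 or self.mu0 <= 0:
            raise ValueError("tolerances and penalties must be > 0")
        if self.mu_growth <= 1:
            raise ValueError("penalty growth factor must be > 1")


@dataclass
class SolverState:
    """Convergence diagnostics of one constrained solve."""

    multipliers: np.ndarray
    mu: float
    converged: bool
    n_outer: int
    objective_history: List[float] = dc_field(default_factory=list)
    fidelity_history: List[float] = dc_field(default_factory=list)
    violation_history: List[float] = dc_field(default_factory=list)
    inner_status: List[str] = dc_field(default_factory=list)
    min_det: float = float("nan")

    def report(self) -> dict:
        return {
            "converged": self.converged,
            "n_outer": self.n_outer,
            "final_mu": self.mu,
            "max_violation": self.violation_history[-1] if self.violation_history else None,
            "objective_history": self.objective_history,
            "fidelity_history": self.fidelity_history,
            "violation_history": self.violation_history,
            "inner_status": self.inner_status,
            "min_det": self.min_det,
        }


# ---------------------------------------------------------------------------
# Laplacian and the unconstrained fit
# ---------------------------------------------------------------------------

def _laplacian_1d(n: int) -> sp.csr_matrix:
    # centered second difference with replicated ghost values (Neumann):
    # row 0 -> (-1, 1), interior -> (1, -2, 1), row n-1 -> (1, -1)
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def assemble_laplacian(domain: GridDomain) -> LaplacianOperator:
    """7-point Neumann Laplacian matching C-order (axis-3 fastest) flattening."""
    n1, n2, n3 = domain.shape
    L1, L2, L3 = (_laplacian_1d(n) for n in (n1, n2, n3))
    I1, I2, I3 = (sp.identity(n, format="csr") for n in (n1, n2, n3))
    A = (
        sp.kron(L1, sp.kron(I2, I3))
        + sp.kron(I1, sp.kron(L2, I3))
        + sp.kron(I1, sp.kron(I2, L3))
    )
    return LaplacianOperator(A.tocsr(), domain.shape)


def fit_unconstrained(
    fidelity: FidelityData, alpha: float, domain: GridDomain
) -> DisplacementField:
    """Unique minimizer of the Laplacian-regularized least-squares fit.

    Solves (S^T S + alpha A^T A) d~_j = S^T y_j independently per component,
    where S selects the fidelity voxels.  With alpha = 0 the fidelity set
    must cover every voxel (pure interpolation), otherwise the normal matrix
    is singular.
    """
    fidelity.check_in_grid(domain)
    n = domain.n_voxels
    flat = fidelity.flat_indices(domain)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0 and fidelity.m < n:
        raise IllPosedError(
            "alpha = 0 requires fidelity data at every voxel; the fit is singular otherwise"
        )
    sel = np.zeros(n)
    sel[flat] = 1.0
    P = sp.diags(sel, format="csc")
    if alpha > 0:
        A = assemble_laplacian(domain).matrix
        M = (P + alpha * (A.T @ A)).tocsc()
    else:
        M = P.tocsc()
    lu = spla.splu(M)
    out = np.empty((3, n))
    for c in range(3):
        rhs = np.zeros(n)
        rhs[flat] = fidelity.values[:, c]
        out[c] = lu.solve(rhs)
    return DisplacementField(domain, out.reshape(3, *domain.shape))


# ---------------------------------------------------------------------------
# Constraints and the augmented Lagrangian
# ---------------------------------------------------------------------------

def constraint_residual(
    fld: DisplacementField,
    f: ScalarImage,
    constrained_set: Optional[np.ndarray] = None,
) -> ScalarImage:
    """c_k = det(J~(x_k; d)) - f(x_k) on the constrained voxel set (NaN elsewhere)."""
    if constrained_set is None:
        constrained_set = fld.domain.interior()
    det = det3(forward_jacobian(fld).entries)
    res = np.where(constrained_set, det - f.values, np.nan)
    img = ScalarImage.__new__(ScalarImage)
    object.__setattr__(img, "domain", fld.domain)
    object.__setattr__(img, "values", res)
    return img


def _shift_forward(vol: np.ndarray, axis: int) -> np.ndarray:
    """Move the value at index k to index k+1 along ``axis`` (zero-fill at 0)."""
    out = np.zeros_like(vol)
    dst = [slice(None)] * 3
    src = [slice(None)] * 3
    dst[axis] = slice(1, None)
    src[axis] = slice(0, -1)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def augmented_objective_gradient(
    fld: DisplacementField,
    fidelity: FidelityData,
    alpha: float,
    f: ScalarImage,
    lam: np.ndarray,
    mu: float,
    laplacian: Optional[LaplacianOperator] = None,
    constrained_set: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray, dict]:
    """Value and analytic gradient of the augmented Lagrangian.

    L(d) = sum_i ||d(x_i) - y_i||^2 + alpha sum_j ||A d~_j||^2
           + sum_k lambda_k c_k + (mu / 2) sum_k c_k^2

    ``lam`` is a grid-shaped multiplier volume (zero off the constrained
    set).  The gradient of each c_k distributes the cofactor entries of
    J~(x_k) onto d^(i)(x_k + e_j) with weight +1 and onto d^(i)(x_k) with
    weight -1.  Returns (value, gradient array shaped like the field data,
    term breakdown).
    """
    domain = fld.domain
    if laplacian is None and alpha > 0:
        laplacian = assemble_laplacian(domain)
    if constrained_set is None:
        constrained_set = domain.interior()

    grad = np.zeros_like(fld.data)

    # fidelity term
    flat = fidelity.flat_indices(domain)
    fid_val = 0.0
    for c in range(3):
        comp = fld.data[c].ravel()
        r = comp[flat] - fidelity.values[:, c]
        fid_val += float(r @ r)
        g = np.zeros(domain.n_voxels)
        g[flat] = 2.0 * r
        grad[c] += g.reshape(domain.shape)

    # Laplacian regularizer
    reg_val = 0.0
    if alpha > 0:
        A = laplacian.matrix
        for c in range(3):
            Ad = A @ fld.data[c].ravel()
            reg_val += alpha * float(Ad @ Ad)
            grad[c] += (2.0 * alpha * (A.T @ Ad)).reshape(domain.shape)

    # constraint terms
    jac = forward_jacobian(fld)
    det = det3(jac.entries)
    c_vol = np.where(constrained_set, det - f.values, 0.0)
    lam_vol = np.where(constrained_set, lam, 0.0)
    con_val = float(np.sum(lam_vol * c_vol) + 0.5 * mu * np.sum(c_vol * c_vol))
    w = lam_vol + mu * c_vol  # dL/dc_k
    if np.any(w):
        cof = cofactor3(jac.entries)
        for i in range(3):
            acc = np.zeros(domain.shape)
            for j in range(3):
                Wij = w * cof[i, j]
                grad[i] += _shift_forward(Wij, j)
                acc += Wij
            grad[i] -= acc

    value = fid_val + reg_val + con_val
    terms = {
        "fidelity": fid_val,
        "regularizer": reg_val,
        "constraint": con_val,
        "max_violation": float(np.max(np.abs(c_vol))) if c_vol.size else 0.0,
    }
    return value, grad, terms


def solve_constrained(
    fidelity: FidelityData,
    f: ScalarImage,
    opts: SolverOptions,
    domain: Optional[GridDomain] = None,
    initial: Optional[DisplacementField] = None,
) -> Tuple[DisplacementField, SolverState]:
    """Augmented Lagrangian solve of the Jacobian-constrained fit.

    Starts from the unconstrained fit (or ``initial``), then alternates inner
    L-BFGS minimizations of the augmented Lagrangian with first-order
    multiplier updates lambda_k <- lambda_k + mu c_k; the penalty grows when
    the maximum violation fails to shrink by ``opts.violation_shrink``.
    Deterministic given inputs and options.  On non-convergence the best
    iterate is returned with ``state.converged = False`` — never a silent
    success.
    """
    domain = domain or f.domain
    constrained = domain.interior()
    rep = validate_constraint(f, mask=constrained)
    if not rep["passed"]:
        raise ConstraintValidityError(
            f"target Jacobian not strictly positive on the constrained set "
            f"({rep['n_violations']} violations)"
        )

    lap = assemble_laplacian(domain) if opts.alpha > 0 else None
    if initial is None:
        fld = fit_unconstrained(fidelity, opts.alpha, domain)
    else:
        fld = initial.copy()

    lam = np.zeros(domain.shape)
    mu = opts.mu0
    gtol = opts.inner_gtol0
    shape = (3, *domain.shape)

    state = SolverState(multipliers=lam, mu=mu, converged=False, n_outer=0)
    best_x = fld.data.copy()
    best_viol = np.inf
    prev_viol = np.inf

    def fun(x: np.ndarray):
        cand = DisplacementField.__new__(DisplacementField)
        object.__setattr__(cand, "domain", domain)
        object.__setattr__(cand, "data", x.reshape(shape))
        val, grad, _ = augmented_objective_gradient(
            cand, fidelity, opts.alpha, f, lam, mu, lap, constrained
        )
        return val, grad.ravel()

    x = fld.data.ravel().copy()
    for outer in range(1, opts.max_outer + 1):
        res = minimize(
            fun,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts.inner_maxiter, "gtol": gtol, "ftol": 1e-16},
        )
        x = res.x
        cand = DisplacementField(domain, x.reshape(shape))
        val, _, terms = augmented_objective_gradient(
            cand, fidelity, opts.alpha, f, lam, mu, lap, constrained
        )
        viol = terms["max_violation"]
        state.objective_history.append(terms["fidelity"] + terms["regularizer"])
        state.fidelity_history.append(terms["fidelity"])
        state.violation_history.append(viol)
        state.inner_status.append(str(res.message))
        state.n_outer = outer
        logger.info(
            "outer %2d: fidelity+reg=%.6e  max|det-f|=%.3e  mu=%.1e",
            outer, terms["fidelity"] + terms["regularizer"], viol, mu,
        )

        if viol < best_viol:
            best_viol = viol
            best_x = x.copy()
        if viol <= opts.constraint_tol:
            state.converged = True
            break

        # first-order multiplier update, then penalty growth if stagnating
        c_vol = np.where(
            constrained, det3(forward_jacobian(cand).entries) - f.values, 0.0
        )
        lam = lam + mu * c_vol
        if viol > opts.violation_shrink * prev_viol:
            mu *= opts.mu_growth
        prev_viol = viol
        gtol = max(gtol * opts.inner_gtol_shrink, opts.inner_gtol_min)

    if not state.converged:
        x = best_x
        logger.warning(
            "constrained solve did not reach tol %.1e in %d outer iterations "
            "(best max violation %.3e); returning best iterate",
            opts.constraint_tol, opts.max_outer, best_viol,
        )
    out = DisplacementField(domain, x.reshape(shape))
    det_final = det3(forward_jacobian(out).entries)
    state.multipliers = lam
    state.mu = mu
    state.min_det = float(np.min(det_final[constrained])) if constrained.any() else float("nan")
    return out, state
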
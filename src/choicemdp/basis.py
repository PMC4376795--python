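"""Least-squares basis approximation of value functions.

Continuous (or too-large discrete) belief spaces are handled by writing
the utility as a linear combination of fixed basis functions,
``v_hat(s) = sum_i a_i phi_i(s)``, fitting the coefficients by least
squares on an evaluation grid, and alternating Bellman backups with
projection onto the basis span until the fitted values stop changing.

Per-dimension families:

* ``piecewise`` — global polynomials x^0..x^K plus truncated power terms
  (x - t_j)_+^K at each knot t_j;
* ``bspline`` — the B-spline basis of order (degree) K on the given
  breakpoints, clamped at the ends;
* ``indicator`` — one indicator column per knot value (exact tabular
  representation of a small discrete dimension; used to check the
  approximate solver against the exact one).

Multi-dimensional bases take one intercept (carried by the first
dimension's block), the remaining dimensions' blocks with their
constant-equivalent column dropped, and — for ``interaction_order >= 2``
— pairwise products of main-effect columns across distinct dimensions.
Richer tensor products are deliberately not built: quadratic
interactions were where the approximation stopped improving on these
tasks, and over-rich bases make the iteration diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

from .core import ConvergenceError, SpecError, TaskSpec, _Compiled

__all__ = [
    "DimensionBasis",
    "BasisSpec",
    "ProjectionOperator",
    "design_matrix",
    "fit_projection",
    "approximate_value_iteration",
    "ApproxValueFunction",
]

#: condition-number threshold for declaring the design matrix rank-deficient
COND_THRESHOLD = 1e10


@dataclass(frozen=True)
class DimensionBasis:
    """Basis family for one state-space dimension."""

    family: str  # piecewise | bspline | indicator
    order: int = 3
    knots: tuple[float, ...] = ()

    def __post_init__(self):
        if self.family not in ("piecewise", "bspline", "indicator"):
            raise SpecError(f"unknown basis family {self.family!r}")
        if self.order < 1 and self.family != "indicator":
            raise SpecError("basis order must be >= 1")
        if list(self.knots) != sorted(set(self.knots)):
            raise SpecError("knots must be strictly increasing")
        if self.family == "bspline" and len(self.knots) < 2:
            raise SpecError("bspline needs at least 2 breakpoints")

    def columns(self, x: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Evaluate this dimension's full column block at points ``x``."""
        x = np.asarray(x, dtype=float)
        if self.family == "piecewise":
            cols = [x**i for i in range(self.order + 1)]
            labels = [f"x^{i}" for i in range(self.order + 1)]
            for t in self.knots:
                cols.append(np.clip(x - t, 0.0, None) ** self.order)
                labels.append(f"(x-{t:g})+^{self.order}")
            return np.column_stack(cols), labels
        if self.family == "indicator":
            cols = [(x == t).astype(float) for t in self.knots]
            return np.column_stack(cols), [f"1[x={t:g}]" for t in self.knots]
        # bspline: clamped knot vector over the breakpoints; extrapolation
        # beyond the outer breakpoints continues the end polynomial pieces
        k = self.order
        t = np.concatenate([[self.knots[0]] * (k + 1), list(self.knots[1:-1]), [self.knots[-1]] * (k + 1)])
        nb = len(t) - k - 1
        dm = BSpline.design_matrix(x, t, k, extrapolate=True).toarray()
        return dm, [f"B{j}" for j in range(nb)]

    @property
    def n_columns(self) -> int:
        if self.family == "piecewise":
            return self.order + 1 + len(self.knots)
        if self.family == "indicator":
            return len(self.knots)
        return len(self.knots) + self.order - 1


@dataclass
class BasisSpec:
    """Multi-dimensional basis: per-dimension families plus interactions.

    ``interaction_order`` 1 is additive; 2 adds pairwise products of
    main-effect columns from distinct dimensions.  ``evaluation_grid``
    lists the sample points per dimension; its cartesian product is the
    grid on which values are fitted.  ``drop_degenerate`` silently drops
    columns that are identically zero on the grid (e.g. a truncated-power
    term whose knot lies beyond the last grid point) and records them.
    """

    dimensions: Sequence[DimensionBasis]
    interaction_order: int = 1
    evaluation_grid: Sequence[Sequence[float]] = ()
    drop_degenerate: bool = True
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.interaction_order < 1:
            raise SpecError("interaction_order must be >= 1")
        if self.interaction_order > 2:
            raise SpecError("interaction terms beyond pairwise are not supported")
        if self.evaluation_grid and len(self.evaluation_grid) != len(self.dimensions):
            raise SpecError("evaluation_grid must list sample points for every dimension")

    def grid_points(self) -> np.ndarray:
        """Cartesian product of the per-dimension evaluation grids."""
        if not self.evaluation_grid:
            raise SpecError("no evaluation grid configured")
        mesh = np.meshgrid(*[np.asarray(g, dtype=float) for g in self.evaluation_grid], indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])


def design_matrix(points: np.ndarray, basis: BasisSpec, check_rank: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix Phi (rows = states, cols = basis functions) with labels.

    Column order: dimension-0 full block, then each further dimension's
    block with its constant-equivalent column dropped, then (if
    ``interaction_order == 2``) products of main-effect columns across
    distinct dimension pairs.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != len(basis.dimensions):
        raise SpecError(f"points have {pts.shape[1]} coordinates; basis has {len(basis.dimensions)} dimensions")
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    main: list[tuple[np.ndarray, list[str]]] = []  # non-constant columns per dim
    for d, dim in enumerate(basis.dimensions):
        cols, labs = dim.columns(pts[:, d])
        labs = [f"d{d}:{l}" for l in labs]
        if dim.family == "piecewise":
            nc, nl = cols[:, 1:], labs[1:]
        elif dim.family == "bspline":
            # B-spline columns sum to 1; drop the last to remove the constant
            nc, nl = cols[:, :-1], labs[:-1]
        else:
            nc, nl = cols[:, 1:], labs[1:]
        main.append((nc, nl))
        if d == 0:
            blocks.append(cols)
            labels.extend(labs)
        else:
            blocks.append(nc)
            labels.extend(nl)
    if basis.interaction_order >= 2:
        for d1 in range(len(basis.dimensions)):
            for d2 in range(d1 + 1, len(basis.dimensions)):
                c1, l1 = main[d1]
                c2, l2 = main[d2]
                prod = c1[:, :, None] * c2[:, None, :]
                blocks.append(prod.reshape(len(pts), -1))
                labels.extend(f"{a}*{b}" for a in l1 for b in l2)
    phi = np.hstack(blocks)
    if basis.drop_degenerate and phi.shape[0] >= 2:
        keep = _independent_columns(phi)
        if len(keep) < phi.shape[1]:
            kept = set(keep)
            basis.dropped = [l for i, l in enumerate(labels) if i not in kept]
            labels = [labels[i] for i in keep]
            phi = phi[:, keep]
    if check_rank and phi.shape[0] >= phi.shape[1]:
        sv = np.linalg.svd(phi, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > COND_THRESHOLD:
            # name the columns involved in the near-null space
            _, _, vt = np.linalg.svd(phi)
            weights = np.abs(vt[-1])
            worst = [labels[i] for i in np.argsort(weights)[::-1][:4]]
            raise SpecError(
                "design matrix is rank-deficient on the evaluation grid "
                f"(condition number {sv[0] / max(sv[-1], 1e-300):.2e}); "
                f"columns implicated: {worst} — adjust knots or grid"
            )
    return phi, labels


def _independent_columns(phi: np.ndarray, rel_tol: float = 1e-9) -> list[int]:
    """Indices of a maximal independent column set, keeping earliest columns.

    Incremental orthogonalization: a column whose residual against the
    kept span is below ``rel_tol`` times its norm (or identically zero)
    is degenerate on these points — e.g. a truncated-power term whose
    knot lies outside the evaluation range.
    """
    q: list[np.ndarray] = []
    keep: list[int] = []
    for i in range(phi.shape[1]):
        col = phi[:, i].astype(float)
        nrm = np.linalg.norm(col)
        if nrm == 0.0:
            continue
        resid = col.copy()
        for qi in q:
            resid -= (qi @ resid) * qi
        # re-orthogonalize once for numerical safety
        for qi in q:
            resid -= (qi @ resid) * qi
        rn = np.linalg.norm(resid)
        if rn <= rel_tol * nrm:
            continue
        q.append(resid / rn)
        keep.append(i)
    return keep


@dataclass
class ProjectionOperator:
    """Least-squares projection onto the span of a design matrix."""

    phi: np.ndarray
    labels: list[str]

    def __post_init__(self):
        sv = np.linalg.svd(self.phi, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > COND_THRESHOLD:
            raise SpecError(
                "Phi'Phi is numerically singular; change the knot configuration or evaluation grid"
            )
        self._pinv = np.linalg.pinv(self.phi)

    @property
    def H(self) -> np.ndarray:
        """The projection (hat) matrix Phi (Phi'Phi)^-1 Phi'."""
        return self.phi @ self._pinv

    def coefficients(self, v: np.ndarray) -> np.ndarray:
        return self._pinv @ np.asarray(v, dtype=float)

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.phi @ self.coefficients(v)


def fit_projection(phi: np.ndarray, labels: list[str] | None = None) -> ProjectionOperator:
    """Build the projection operator for design matrix ``phi``."""
    phi = np.asarray(phi, dtype=float)
    if labels is None:
        labels = [f"c{i}" for i in range(phi.shape[1])]
    return ProjectionOperator(phi, labels)


@dataclass
class ApproxValueFunction:
    """Fitted value function: evaluate v_hat at arbitrary state coordinates."""

    basis: BasisSpec
    coefficients: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    meta: dict

    def _eval_matrix(self, points: np.ndarray) -> np.ndarray:
        """Design rows aligned to the fitted coefficient vector.

        Columns dropped as degenerate at fit time are dropped here by
        label, so evaluation stays consistent off the fitting grid.
        """
        full = BasisSpec(
            dimensions=self.basis.dimensions,
            interaction_order=self.basis.interaction_order,
            drop_degenerate=False,
        )
        phi, labs = design_matrix(np.atleast_2d(points), full, check_rank=False)
        keep = [i for i, l in enumerate(labs) if l in set(self.meta["labels"])]
        return phi[:, keep]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self._eval_matrix(points) @ self.coefficients


def approximate_value_iteration(
    spec: TaskSpec,
    basis: BasisSpec,
    tol: float = 1e-4,
    max_iter: int = 100_000,
    divergence_bound: float = 1e12,
    successor_phi: np.ndarray | None = None,
    verbose: bool = False,
) -> ApproxValueFunction:
    """Approximate value iteration: Bellman backup + least-squares projection.

    ``spec.states`` must be the evaluation-grid states, each a coordinate
    tuple; successors returned by ``spec.transitions`` may lie anywhere in
    the coordinate space (they are valued through the fitted basis).
    Stops when the fitted grid values change by less than ``tol`` in max
    norm; raises :class:`~choicemdp.core.ConvergenceError` with the
    iteration trace if the values grow past ``divergence_bound`` (the
    classic failure mode of an over-rich basis).
    """
    if spec.discount >= 1.0:
        raise SpecError("approximate value iteration requires gamma < 1")
    if spec.states is None:
        raise SpecError("spec.states must list the evaluation-grid states")
    grid = np.asarray([tuple(s) for s in spec.states], dtype=float)
    phi_grid, labels = design_matrix(grid, basis)
    proj = fit_projection(phi_grid, labels)

    # flatten (state, action, successor) once; successor coordinates are
    # fixed, so their design rows can be precomputed
    comp = _Compiled_successors(spec)
    stub = ApproxValueFunction(basis, np.zeros(phi_grid.shape[1]), grid, np.zeros(len(grid)), {"labels": labels})
    if successor_phi is None:
        succ_phi = stub._eval_matrix(comp.succ_coords)
    else:
        succ_phi = successor_phi

    coef = np.zeros(phi_grid.shape[1])
    v_hat = phi_grid @ coef
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        v_succ = succ_phi @ coef
        contrib = comp.tr_prob * v_succ
        fev = np.add.reduceat(contrib, comp.tr_off[:-1])
        q = comp.row_iev + spec.discount * fev
        v_new = np.maximum.reduceat(q, comp.sa_off[:-1])
        coef = proj.coefficients(v_new)
        v_hat_new = phi_grid @ coef
        change = float(np.max(np.abs(v_hat_new - v_hat)))
        trace.append(change)
        if not np.isfinite(change) or np.max(np.abs(v_hat_new)) > divergence_bound:
            raise ConvergenceError(
                f"approximate value iteration diverged at iteration {it} "
                f"(basis too rich for the backup); trace of last changes: {trace[-10:]}"
            )
        v_hat = v_hat_new
        if verbose and it % 50 == 0:
            print(f"  iter {it}: max change {change:.3e}")
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"approximate value iteration did not converge in {max_iter} iterations "
            f"(last change {trace[-1]:.3e})"
        )
    resid = v_new - v_hat
    meta = {
        "iterations": it,
        "final_change": change,
        "residual_variance": float(np.var(resid)),
        # self-consistency check: regress fitted values after the last
        # backup on the previous fit (slope near 1 = converged)
        "consistency_slope": _slope(v_hat, phi_grid @ proj.coefficients(v_new)),
        "n_basis": phi_grid.shape[1],
        "labels": labels,
    }
    return ApproxValueFunction(basis=basis, coefficients=coef, grid=grid, fitted=v_hat, meta=meta)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    vx = float(np.var(x))
    if vx == 0.0:
        return 1.0
    return float(np.cov(x, y)[0, 1] / vx)


class _Compiled_successors:
    """Like core._Compiled but keeps successor *coordinates* (off-grid OK)."""

    def __init__(self, spec: TaskSpec):
        sa_off = [0]
        row_iev: list[float] = []
        tr_off = [0]
        tr_prob: list[float] = []
        succ_coords: list[tuple] = []
        for s in spec.states:
            acts = spec.actions(s)
            if not acts:
                raise SpecError(f"empty action set for state {s!r}")
            for a in acts:
                row_iev.append(spec.reward(s, a) + spec.cost(s, a))
                for j, p in spec.checked_transitions(s, a):
                    succ_coords.append(tuple(j))
                    tr_prob.append(p)
                tr_off.append(len(tr_prob))
            sa_off.append(len(row_iev))
        self.sa_off = np.asarray(sa_off, dtype=np.int64)
        self.row_iev = np.asarray(row_iev, dtype=float)
        self.tr_off = np.asarray(tr_off, dtype=np.int64)
        self.tr_prob = np.asarray(tr_prob, dtype=float)
        self.succ_coords = np.asarray(succ_coords, dtype=float)
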
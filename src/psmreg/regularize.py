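"""Score regularization: minimize smoothing + fitting inconsistency.

Given initial scores X and the affinity graph, the new scores Y minimize

    Q(Y) = (1 - lam) * L(Y) + lam * F(Y)

where L(Y) = sum_{i<j} w_ij (y_i/sqrt(d_ii) - y_j/sqrt(d_jj))^2 is the
normalized-Laplacian smoothing cost (identically Y^T (I - S) Y) and
F(Y) = ||Y - X||^2 keeps the new scores near the search engine's.  The
stationarity condition gives the closed form

    Y* = lam * (I - (1 - lam) S)^(-1) X,

always solvable for lam in (0, 1) because the eigenvalues of S lie in
[-1, 1].  For large graphs the same fixed point is reached by the
diffusion iteration Y(t+1) = lam*X + (1 - lam)*S Y(t), a contraction
with factor at most (1 - lam).

Dummy nodes carry initial score 0 and their regularized values are
discarded; they exist only to keep the degree matrix invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, ContractError, ConvergenceError
from .graph import AffinityGraph, build_graph
from .io import PSMRecord

#: Rule-of-thumb default for the regularization parameter.
DEFAULT_LAMBDA = 0.5
#: Above this node count the auto solver switches to the iteration.
AUTO_SOLVER_CUTOFF = 5000


@dataclass(frozen=True)
class RegularizationResult:
    """Regularized scores over the real (non-dummy) nodes plus diagnostics.

    ``Y_full`` keeps the dummy-node entries too, so the stationarity
    condition (I - (1-lam)S) Y_full = lam X_full can be re-checked
    against the full system.
    """

    Y: np.ndarray
    lambda_: float
    method: str  # "closed_form" | "iterative"
    iterations: int
    final_residual: float
    Y_full: np.ndarray | None = None

    @property
    def alpha(self) -> float:
        """Weight on the neighbor term, alpha = 1 - lambda."""
        return 1.0 - self.lambda_


def _check_lambda(lambda_: float) -> None:
    if not 0.0 < lambda_ < 1.0:
        raise ConfigError(
            f"lambda must lie strictly inside (0, 1), got {lambda_}"
        )


def _extend(X: np.ndarray, graph: AffinityGraph) -> np.ndarray:
    """Pad X with zeros for the dummy nodes."""
    X = np.asarray(X, dtype=float)
    if X.shape != (graph.n_real,):
        raise ContractError(
            f"score vector has shape {X.shape}, expected ({graph.n_real},)"
        )
    return np.concatenate([X, np.zeros(graph.n_dummy)])


def smoothing_cost(Y: Sequence[float] | np.ndarray, graph: AffinityGraph) -> float:
    """Inter-peptide inconsistency L(Y), summed once per unordered pair.

    Computed pairwise over the edges; equals Y^T (I - S) Y exactly.
    ``Y`` must cover all n_total nodes (dummies included).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (graph.n_total,):
        raise ContractError(
            f"score vector has shape {Y.shape}, expected ({graph.n_total},)"
        )
    d = graph.degrees
    coo = sp.triu(graph.W, k=1).tocoo()
    diffs = Y[coo.row] / np.sqrt(d[coo.row]) - Y[coo.col] / np.sqrt(d[coo.col])
    return float(np.sum(coo.data * diffs**2))


def fitting_cost(Y: Sequence[float] | np.ndarray, X: Sequence[float] | np.ndarray) -> float:
    """Deviation from the initial scores, F(Y) = ||Y - X||^2."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape != X.shape:
        raise ContractError(f"shape mismatch: {Y.shape} vs {X.shape}")
    return float(np.sum((Y - X) ** 2))


def objective(
    Y: Sequence[float] | np.ndarray,
    X: Sequence[float] | np.ndarray,
    graph: AffinityGraph,
    lambda_: float,
) -> float:
    """Regularized objective Q(Y) = (1-lam) L(Y) + lam F(Y).

    ``Y`` and ``X`` cover all n_total nodes.
    """
    _check_lambda(lambda_)
    return (1.0 - lambda_) * smoothing_cost(Y, graph) + lambda_ * fitting_cost(Y, X)


def _stationarity_residual(
    Y_full: np.ndarray, X_full: np.ndarray, graph: AffinityGraph, lambda_: float
) -> float:
    """Max-norm of (I - (1-lam)S) Y - lam X — zero at the minimizer."""
    r = Y_full - (1.0 - lambda_) * (graph.S @ Y_full) - lambda_ * X_full
    return float(np.max(np.abs(r))) if r.size else 0.0


def solve_closed_form(
    X: Sequence[float] | np.ndarray, graph: AffinityGraph, lambda_: float = DEFAULT_LAMBDA
) -> RegularizationResult:
    """Solve (I - (1-lam)S) Y = lam X by sparse direct factorization.

    ``X`` covers the real nodes only; dummies are padded with zeros and
    dropped from the returned Y.
    """
    _check_lambda(lambda_)
    X_full = _extend(np.asarray(X, dtype=float), graph)
    A = (sp.eye(graph.n_total) - (1.0 - lambda_) * graph.S).tocsc()
    Y_full = spla.spsolve(A, lambda_ * X_full)
    Y_full = np.atleast_1d(Y_full)
    return RegularizationResult(
        Y=Y_full[: graph.n_real],
        lambda_=lambda_,
        method="closed_form",
        iterations=0,
        final_residual=_stationarity_residual(Y_full, X_full, graph, lambda_),
        Y_full=Y_full,
    )


def solve_iterative(
    X: Sequence[float] | np.ndarray,
    graph: AffinityGraph,
    lambda_: float = DEFAULT_LAMBDA,
    tol: float = 1e-9,
    max_iter: int = 10000,
    warm_start: bool = True,
) -> RegularizationResult:
    """Reach the same fixed point by diffusion: Y <- lam X + (1-lam) S Y.

    Starts from Y(0) = X (warm start; the fixed point is unique, so the
    start only affects the iteration count).  Stops when the max-norm
    update falls below ``tol``.  Convergence is guaranteed since the
    spectral radius of (1-lam)S is below 1, but a ``max_iter`` safety
    net raises ConvergenceError with the last residual.
    """
    _check_lambda(lambda_)
    X_full = _extend(np.asarray(X, dtype=float), graph)
    Y = X_full.copy() if warm_start else np.zeros_like(X_full)
    lam_X = lambda_ * X_full
    one_minus = 1.0 - lambda_
    residual = np.inf
    for t in range(1, max_iter + 1):
        Y_next = lam_X + one_minus * (graph.S @ Y)
        residual = float(np.max(np.abs(Y_next - Y))) if Y.size else 0.0
        Y = Y_next
        if residual < tol:
            return RegularizationResult(
                Y=Y[: graph.n_real],
                lambda_=lambda_,
                method="iterative",
                iterations=t,
                final_residual=residual,
                Y_full=Y,
            )
    raise ConvergenceError(
        f"diffusion did not converge in {max_iter} iterations "
        f"(last max-norm update {residual:.3e})",
        residual=residual,
        iterations=max_iter,
    )


def rerank(
    records: Sequence[PSMRecord],
    lambda_: float = DEFAULT_LAMBDA,
    solver: str = "auto",
    tol: float = 1e-9,
    max_iter: int = 10000,
    dummy_weight: float = 1e-8,
    kernel: str = "jaccard",
) -> tuple[AffinityGraph, RegularizationResult]:
    """End-to-end re-ranking: graph, score vector, solve, new scores.

    ``solver`` is one of ``auto`` (closed form up to 5000 nodes, then
    iterative), ``closed_form`` or ``iterative``.  ``result.Y[i]`` is
    the regularized score of ``records[i]``.
    """
    _check_lambda(lambda_)
    graph = build_graph(records, dummy_weight=dummy_weight, kernel=kernel)
    X = np.array([r.initial_score for r in records], dtype=float)
    if solver == "auto":
        solver = "closed_form" if graph.n_total <= AUTO_SOLVER_CUTOFF else "iterative"
    if solver == "closed_form":
        result = solve_closed_form(X, graph, lambda_)
    elif solver == "iterative":
        result = solve_iterative(X, graph, lambda_, tol=tol, max_iter=max_iter)
    else:
        raise ConfigError(
            f"unknown solver {solver!r}; choose auto, closed_form or iterative"
        )
    return graph, result
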
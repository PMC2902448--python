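"""NIPALS power iteration and its penalized (sparse) modification.

Ordinary PCA of a column-centered matrix ``X`` (rows = samples) can be
computed one component at a time by the NIPALS algorithm: starting from a
score vector ``z`` (the first column of ``X``), alternate

1. ``v <- X.T @ z / (z.T @ z)``   (regress every column of X on z)
2. ``v <- v / ||v||``
3. ``z <- X @ v``

until ``v`` stabilizes; this is the power method for the leading right
singular vector.  Sparsity is obtained by replacing step 1 with a penalized
regression solved by iterative weighted least squares (IWLS):

    ``v_j = X_j.T @ z / (z.T @ z + W_j)``,   ``W_j = p'(|v~_j|) / |v~_j|``,

with the weights refreshed from the current ``v`` until the inner loop
converges.  Subsequent components are extracted after deflating
``X <- X - z v.T``.  Optionally the loading estimation operates on a
condition-number-shrunken reconstruction ``X*`` of the current matrix (the
super-sparse variant) while scores and deflation always use the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .penalties import PenaltyFamily, PenaltySpec, iwls_weight_diagonal

__all__ = [
    "CenteredMatrix",
    "SparsePCAFit",
    "center_columns",
    "nipals_first_component",
    "sparse_loading_step",
    "fit",
]


@dataclass(frozen=True)
class CenteredMatrix:
    """A samples x variables matrix with column means removed."""

    values: NDArray[np.float64]
    column_means: NDArray[np.float64]
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class SparsePCAFit:
    """Per-component results of an (sparse) NIPALS fit.

    ``loadings`` columns are unit-norm; ``scores[:, k] = X_k @ loadings[:, k]``
    where ``X_k`` is the k-th deflated data matrix; ``singular_values[k]`` is
    the norm of that score.  ``nonzero_counts`` applies the reporting
    threshold of the penalty spec.  Adjusted variances (percent of total
    variance, QR-based) account for correlation between sparse scores.
    """

    loadings: NDArray[np.float64]
    scores: NDArray[np.float64]
    singular_values: NDArray[np.float64]
    nonzero_counts: NDArray[np.int64]
    penalty: PenaltySpec
    converged_flags: NDArray[np.bool_]
    iteration_counts: NDArray[np.int64]
    adjusted_variance: NDArray[np.float64]
    cumulative_adjusted_variance: NDArray[np.float64]
    lambdas: NDArray[np.float64]
    thetas: NDArray[np.float64]
    kappa_max: Optional[float] = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _values(X) -> NDArray[np.float64]:
    return np.asarray(X.values if isinstance(X, CenteredMatrix) else X, dtype=float)


def center_columns(
    raw: ArrayLike,
    row_labels: Optional[Sequence[str]] = None,
    col_labels: Optional[Sequence[str]] = None,
) -> CenteredMatrix:
    """Remove column means from a raw samples x variables matrix."""
    A = np.array(raw, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        bad = np.argwhere(~np.isfinite(A))[0]
        raise ValueError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 rows to center")
    means = A.mean(axis=0)
    return CenteredMatrix(
        values=A - means,
        column_means=means,
        row_labels=list(row_labels) if row_labels is not None else [str(i) for i in range(n)],
        col_labels=list(col_labels) if col_labels is not None else [f"V{j}" for j in range(p)],
    )


def _initial_score(A: NDArray[np.float64]) -> NDArray[np.float64]:
    """First column of A, or the largest-norm column if that one is zero."""
    z = A[:, 0]
    if np.linalg.norm(z) > 0:
        return z.copy()
    norms = np.linalg.norm(A, axis=0)
    j = int(np.argmax(norms))
    if norms[j] == 0:
        raise ValueError("matrix is identically zero")
    return A[:, j].copy()


def _canonical_sign(v: NDArray[np.float64]) -> NDArray[np.float64]:
    """Flip sign so the largest-magnitude entry is positive (determinism)."""
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def nipals_first_component(
    X, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[NDArray[np.float64], NDArray[np.float64], float]:
    """Leading principal component by NIPALS power iteration.

    Returns ``(v, z, d)``: the unit-norm leading right singular vector (sign
    canonicalized), the score ``z = X @ v`` and ``d = ||z||``.  Convergence is
    declared when the max-norm change in ``v`` falls below ``tol``; if
    ``max_iter`` is reached the best iterate is returned.
    """
    v, z, d, _, _ = _nipals_loop(_values(X), PenaltySpec(family=PenaltyFamily.NONE, lam=0.0), tol, max_iter)
    return v, z, d


def sparse_loading_step(
    X,
    z: NDArray[np.float64],
    spec: PenaltySpec,
    v_init: Optional[NDArray[np.float64]] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> NDArray[np.float64]:
    """Penalized regression of every column of ``X`` on the score ``z``.

    Solves, coordinate-wise, the penalized least squares problem whose
    stationarity condition is ``v_j = X_j.T z / (z.T z + W_j)`` with the
    diagonal IWLS weight ``W_j`` refreshed from the current ``v`` until the
    inner loop converges.  With ``family=NONE`` (or ``lam=0``) this is the
    ordinary least squares step ``X.T z / (z.T z)`` of plain NIPALS.
    """
    A = _values(X)
    z = np.asarray(z, dtype=float)
    ztz = float(z @ z)
    if ztz == 0:
        raise ValueError("score vector z must be nonzero")
    xtz = A.T @ z
    if spec.family is PenaltyFamily.NONE or spec.lam == 0:
        return xtz / ztz
    v = np.asarray(v_init, dtype=float).copy() if v_init is not None else xtz / ztz
    for _ in range(max_iter):
        W = iwls_weight_diagonal(spec, v)
        v_new = xtz / (ztz + W)
        if np.max(np.abs(v_new - v)) < tol * max(1.0, np.max(np.abs(v_new))):
            return v_new
        v = v_new
    return v


def _nipals_loop(
    A: NDArray[np.float64],
    spec: PenaltySpec,
    tol: float,
    max_iter: int,
    inner_tol: float = 1e-6,
    inner_max_iter: int = 100,
) -> tuple[NDArray[np.float64], NDArray[np.float64], float, bool, int]:
    """One (possibly penalized) NIPALS extraction on the matrix ``A``.

    The unit-norm constraint is applied inside the iteration: each IWLS
    solution is normalized before refreshing the score.
    """
    z = _initial_score(A)
    v_old: Optional[NDArray[np.float64]] = None
    v = np.zeros(A.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = sparse_loading_step(A, z, spec, v_init=v_old, tol=inner_tol, max_iter=inner_max_iter)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            # penalty strong enough to annihilate every coordinate
            v = np.zeros(A.shape[1])
            break
        v = v / nv
        if v_old is not None:
            # power iterations may flip sign between steps
            diff = min(np.max(np.abs(v - v_old)), np.max(np.abs(v + v_old)))
            if diff < tol:
                converged = True
                break
        v_old = v
        z = A @ v
    v = _canonical_sign(v)
    z = A @ v
    return v, z, float(np.linalg.norm(z)), converged, it


def fit(
    X: CenteredMatrix,
    k: int = 1,
    spec: Optional[PenaltySpec] = None,
    *,
    use_condition_shrinkage: bool = False,
    tuning=None,
    kappa_max: Optional[float] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SparsePCAFit:
    """Extract ``k`` (sparse) principal components by modified NIPALS.

    Parameters
    ----------
    X : CenteredMatrix
        Column-centered data, rows = samples.
    k : int
        Number of components, ``1 <= k <= min(n, p)``.
    spec : PenaltySpec, optional
        Penalty; ``None`` means ordinary PCA.  If ``tuning`` is given, its
        ``lam``/``theta`` are re-estimated per component and the remaining
        fields (family, w, delta, ...) are kept.
    use_condition_shrinkage : bool
        If true, loading estimation for each component runs on the
        condition-number-shrunken reconstruction ``X*`` of the current
        (deflated) matrix; scores and deflation always use the data itself.
    tuning : sspca.tuning.TuningConfig, optional
        Cross-validation configuration for ``theta``/``lambda`` selection.
    kappa_max : float, optional
        Fixed condition-number bound; when omitted and shrinkage is on, it is
        selected once by K-fold cross-validation on the input matrix.
    """
    from . import components as _components  # local import avoids a cycle
    from . import shrinkage as _shrinkage
    from . import tuning as _tuning

    A0 = _values(X)
    n, p = A0.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must be in [1, {min(n, p)}], got {k}")
    if np.linalg.matrix_rank(A0) < k:
        raise ValueError(f"k={k} exceeds the rank of the matrix")
    if spec is None:
        spec = PenaltySpec(family=PenaltyFamily.NONE, lam=0.0)

    kappa = kappa_max
    if use_condition_shrinkage and kappa is None:
        cv_folds = tuning.K if tuning is not None else 5
        cv_seed = tuning.seed if tuning is not None else 0
        kappa = _shrinkage.select_kappa_cv(A0, folds=cv_folds, seed=cv_seed)

    A = A0.copy()
    loadings = np.zeros((p, k))
    scores = np.zeros((n, k))
    dvals = np.zeros(k)
    nnz = np.zeros(k, dtype=np.int64)
    conv = np.zeros(k, dtype=bool)
    iters = np.zeros(k, dtype=np.int64)
    lambdas = np.full(k, spec.lam, dtype=float)
    thetas = np.full(k, spec.theta, dtype=float)

    for c in range(k):
        work = A
        if use_condition_shrinkage:
            work = _shrinkage.shrink_matrix(A, kappa).X_star
        spec_c = spec
        # unpenalized power iterations are cheap; run them to a tolerance
        # tight enough that the loading matches a dense SVD even when the
        # trailing spectral gap is small (wide random matrices)
        tol_c = tol if spec.family is not PenaltyFamily.NONE else min(tol, 1e-9)
        if tuning is not None and spec.family is not PenaltyFamily.NONE:
            theta_c = (
                tuning.theta_override
                if tuning.theta_override is not None
                else _tuning.estimate_theta(work)
            )
            spec_c = spec.with_(theta=theta_c, lam=1.0)
            lam_c = _tuning.select_lambda_cv(work, spec_c, tuning)
            spec_c = spec_c.with_(lam=lam_c)
        v, _, _, cflag, nit = _nipals_loop(work, spec_c, tol_c, max_iter)
        if np.linalg.norm(v) == 0:
            raise RuntimeError(
                f"component {c + 1}: penalty annihilated every loading; reduce lambda"
            )
        z = A @ v
        loadings[:, c] = v
        scores[:, c] = z
        dvals[c] = np.linalg.norm(z)
        nnz[c] = int(np.sum(np.abs(v) >= spec_c.zero_threshold))
        conv[c] = cflag
        iters[c] = nit
        lambdas[c] = spec_c.lam
        thetas[c] = spec_c.theta
        A = A - np.outer(z, v)

    adj, cum = _components.adjusted_variance(A0, loadings)
    return SparsePCAFit(
        loadings=loadings,
        scores=scores,
        singular_values=dvals,
        nonzero_counts=nnz,
        penalty=spec,
        converged_flags=conv,
        iteration_counts=iters,
        adjusted_variance=adj,
        cumulative_adjusted_variance=cum,
        lambdas=lambdas,
        thetas=thetas,
        kappa_max=kappa,
    )
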
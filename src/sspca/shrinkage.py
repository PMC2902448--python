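"""Condition-number-constrained shrinkage of the sample spectrum.

Sample covariance eigenvalues are systematically more dispersed than the
population ones: the largest is biased up, the smallest down, and for p > n
the sample covariance is outright singular.  Constraining the condition
number of the covariance estimate to ``kappa_max`` repairs this: among
matrices sharing the sample eigenvectors, the constrained Gaussian maximum
likelihood estimate truncates the *inverse* spectrum to an interval,

    1 / l*_i = clamp(1 / l_i, t*, kappa_max * t*),

with the interval endpoint ``t*`` chosen to maximize the constrained
likelihood ``sum_i [log(1/l*_i) - l_i / l*_i]``.  We locate ``t*`` by a 1-D
numerical maximization (dense log-grid plus local refinement), recording the
indices ``alpha`` (number of large eigenvalues clamped at ``1/t*``) and
``beta`` (first small eigenvalue clamped at the floor) for inspection.

Given the truncated spectrum, the data matrix is reconstructed with the same
singular vectors but shrunken singular values ``d*_i = sqrt(n * l*_i)``; this
``X*`` feeds the super-sparse PCA loading estimation.  For p > n only the
(at most n) positive eigenvalues exist and are truncated; zero singular
values stay zero, which is exactly what operating on the transpose and
mapping back yields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import optimize
from sklearn.model_selection import KFold

__all__ = ["ShrinkageResult", "truncate_spectrum", "shrink_matrix", "select_kappa_cv"]

_RANK_RTOL = 1e-12


@dataclass(frozen=True)
class ShrinkageResult:
    """Truncated spectrum and the reconstructed matrix ``X*``."""

    eigenvalues_raw: NDArray[np.float64]
    eigenvalues_shrunk: NDArray[np.float64]
    t_star: float
    kappa_max: float
    alpha_idx: int  # number of leading eigenvalues clamped at the ceiling 1/t*
    beta_idx: int  # 0-based index of the first eigenvalue clamped at the floor (= r if none)
    X_star: NDArray[np.float64]


def _values(X) -> NDArray[np.float64]:
    return np.asarray(getattr(X, "values", X), dtype=float)


def _constrained_loglik(t: float, l: NDArray[np.float64], kappa: float) -> float:
    """Gaussian log-likelihood (up to constants) of the truncated spectrum."""
    u = np.clip(1.0 / l, t, kappa * t)
    return float(np.sum(np.log(u) - l * u))


def truncate_spectrum(
    l: NDArray[np.float64], kappa_max: float
) -> tuple[NDArray[np.float64], float, int, int]:
    """Truncate a positive spectrum so its condition number is <= kappa_max.

    Parameters
    ----------
    l : array
        Positive eigenvalues in non-increasing order (zero eigenvalues of a
        rank-deficient covariance are handled upstream and never passed here).
    kappa_max : float
        Condition-number bound, >= 1.

    Returns
    -------
    (l_star, t_star, alpha_idx, beta_idx)
        Truncated eigenvalues, the interval endpoint, the count of leading
        eigenvalues clamped at the ceiling ``1/t*`` and the 0-based index of
        the first trailing eigenvalue clamped at the floor ``1/(kappa t*)``
        (equal to ``len(l)`` when none is).
    """
    l = np.asarray(l, dtype=float)
    if kappa_max < 1:
        raise ValueError(f"kappa_max must be >= 1, got {kappa_max}")
    if l.ndim != 1 or l.size == 0 or l[0] <= 0:
        raise ValueError("l must be a nonempty positive spectrum")
    if np.any(np.diff(l) > 1e-12 * l[0]):
        raise ValueError("l must be non-increasing")
    if np.any(l <= 0):
        raise ValueError("l must be strictly positive (drop the zero tail upstream)")

    cond = l[0] / l[-1]
    if kappa_max >= cond:
        # constraint slack: any t in [1/(kappa l_r), 1/l_1] leaves l unchanged
        return l.copy(), 1.0 / l[0], 0, l.size

    # unimodal in practice: dense log-grid bracket, then local refinement
    t_lo = 1.0 / (kappa_max * l[0])
    t_hi = 1.0 / l[-1]
    grid = np.geomspace(t_lo, t_hi, 512)
    vals = np.array([_constrained_loglik(t, l, kappa_max) for t in grid])
    j = int(np.argmax(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            lambda t: -_constrained_loglik(t, l, kappa_max),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12 * hi},
        )
        t_star = float(res.x)
        if _constrained_loglik(t_star, l, kappa_max) < vals[j]:
            t_star = float(grid[j])
    else:  # pragma: no cover - degenerate bracket
        t_star = float(grid[j])

    # polish to machine precision: given the clamp pattern at the numeric
    # optimum, stationarity gives t in closed form ((a+b)/t = sum of clamped
    # eigenvalues); a flat optimum limits the 1-D search to ~sqrt(eps)
    inv_all = 1.0 / l
    ceil_mask = inv_all < t_star
    floor_mask = inv_all > kappa_max * t_star
    a, b = int(np.sum(ceil_mask)), int(np.sum(floor_mask))
    if a + b > 0:
        denom = float(np.sum(l[ceil_mask]) + kappa_max * np.sum(l[floor_mask]))
        t_polished = (a + b) / denom
        if _constrained_loglik(t_polished, l, kappa_max) >= _constrained_loglik(
            t_star, l, kappa_max
        ):
            t_star = t_polished

    inv = 1.0 / l
    l_star = 1.0 / np.clip(inv, t_star, kappa_max * t_star)
    alpha_idx = int(np.sum(inv < t_star))
    floored = np.nonzero(inv > kappa_max * t_star)[0]
    beta_idx = int(floored[0]) if floored.size else l.size
    return l_star, t_star, alpha_idx, beta_idx


def shrink_matrix(X, kappa_max: float) -> ShrinkageResult:
    """Reconstruct ``X*`` with the same singular vectors, shrunken values.

    Eigenvalues of the sample covariance are ``l_i = d_i**2 / n``; only the
    positive spectrum (at most ``min(n, p)`` values, fewer after centering)
    is truncated, and ``X* = U diag(sqrt(n l*_i)) V.T``.  Because the
    truncation is scale-equivariant this is identical to running the
    procedure on ``X.T`` and transposing back, which is the efficient route
    when p > n.
    """
    A = _values(X)
    n = A.shape[0]
    U, d, Vt = np.linalg.svd(A, full_matrices=False)
    if d[0] == 0:
        raise ValueError("cannot shrink an all-zero matrix")
    r = int(np.sum(d > d[0] * _RANK_RTOL))
    l = d[:r] ** 2 / n
    l_star, t_star, alpha_idx, beta_idx = truncate_spectrum(l, kappa_max)
    d_star = np.sqrt(n * l_star)
    X_star = (U[:, :r] * d_star) @ Vt[:r]
    return ShrinkageResult(
        eigenvalues_raw=l,
        eigenvalues_shrunk=l_star,
        t_star=t_star,
        kappa_max=float(kappa_max),
        alpha_idx=alpha_idx,
        beta_idx=beta_idx,
        X_star=X_star,
    )


def _fold_loglik(
    train: NDArray[np.float64], valid: NDArray[np.float64], kappa: float
) -> float:
    """Held-out Gaussian log-likelihood of the constrained covariance.

    The covariance estimate is fit on the training rows (centered by the
    training means, which also center the validation rows -- no leakage).
    In the p > n case the estimate is completed to full rank by placing the
    constraint floor ``1/(kappa t*)`` on the null space, so the density is
    proper.
    """
    mu = train.mean(axis=0)
    Tr = train - mu
    Va = valid - mu
    n_tr, p = Tr.shape
    _, d, Vt = np.linalg.svd(Tr, full_matrices=False)
    r = int(np.sum(d > max(d[0], 1e-300) * _RANK_RTOL))
    if r == 0:
        return -np.inf
    l = d[:r] ** 2 / n_tr
    l_star, t_star, _, _ = truncate_spectrum(l, kappa)
    floor = 1.0 / (kappa * t_star)
    logdet = float(np.sum(np.log(l_star))) + (p - r) * np.log(floor)
    proj = Va @ Vt[:r].T  # coordinates in the retained eigenbasis
    quad = np.sum(proj * proj / l_star, axis=1)
    resid = np.sum(Va * Va, axis=1) - np.sum(proj * proj, axis=1)
    quad = quad + np.maximum(resid, 0.0) / floor
    m = Va.shape[0]
    return float(-0.5 * (np.sum(quad) + m * logdet + m * p * np.log(2 * np.pi)))


def select_kappa_cv(
    X,
    folds: int = 5,
    grid: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> float:
    """Select ``kappa_max`` by K-fold held-out Gaussian likelihood.

    The default grid is 10 log-spaced values between 1 and the sample
    condition number of the positive spectrum.  Ties break toward the
    smaller (more strongly regularizing) value.

    When the matrix has more columns than rows (p > n) the whole procedure
    runs on the transpose: folds then split variables and the validated
    covariance is the full-rank n x n dual, which keeps the likelihood
    well-posed.  The condition-number bound is scale-free, so the selected
    value applies unchanged to the primal spectrum.
    """
    A = _values(X)
    if A.shape[1] > A.shape[0]:
        A = A.T
    n = A.shape[0]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    if grid is None:
        d = np.linalg.svd(A - A.mean(axis=0), compute_uv=False)
        r = int(np.sum(d > d[0] * _RANK_RTOL))
        cond = (d[0] / d[r - 1]) ** 2
        grid = np.geomspace(1.0, max(cond, 1.0 + 1e-6), 10)
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("kappa grid must be nonempty")
    if grid.size == 1:
        return float(grid[0])

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = [(tr, va) for tr, va in kf.split(A)]
    for tr, _ in splits:
        if tr.size < 2:
            raise ValueError("degenerate fold with fewer than 2 training rows")
    scores = np.zeros(grid.size)
    for gi, kappa in enumerate(grid):
        scores[gi] = sum(_fold_loglik(A[tr], A[va], kappa) for tr, va in splits)
    return float(grid[int(np.argmax(scores))])  # argmax takes the first (smallest) max
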
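"""Selection of the penalty tuning parameters theta and lambda.

``theta`` (the marginal variance of a loading coefficient in the
random-effect model) is estimated by a moment estimator: the mean squared
entry of the ordinary-PCA first loading.  Because that loading is unit-norm
the raw second moment equals ``1/p`` exactly; we nevertheless compute it from
the fitted loading so overrides and non-standard inputs behave sensibly.

``lambda`` is chosen by K-fold cross-validation (default K = 5): for each
candidate, the first sparse loading is fit on the training rows and scored by
the variance it captures on the held-out rows, ``v_hat' S_valid v_hat``; the
candidate maximizing the summed held-out variance wins, ties going to the
larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.typing import NDArray
from sklearn.model_selection import KFold

from .penalties import PenaltySpec

__all__ = ["TuningConfig", "estimate_theta", "default_lambda_grid", "select_lambda_cv"]


@dataclass(frozen=True)
class TuningConfig:
    """Cross-validation settings for penalty tuning.

    ``lambda_grid=None`` requests the automatic grid of
    :func:`default_lambda_grid` (20 log-spaced points spanning six decades
    around the data-driven coefficient scale).
    """

    K: int = 5
    lambda_grid: Optional[tuple[float, ...]] = None
    seed: int = 0
    theta_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.lambda_grid is not None:
            g = tuple(float(x) for x in self.lambda_grid)
            if len(g) == 0:
                raise ValueError("lambda_grid must be nonempty")
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError("lambda_grid must be strictly increasing")
            if g[0] <= 0:
                raise ValueError("lambda_grid must be positive")
            object.__setattr__(self, "lambda_grid", g)
        if self.theta_override is not None and self.theta_override <= 0:
            raise ValueError("theta_override must be positive")


def _values(X) -> NDArray[np.float64]:
    return np.asarray(getattr(X, "values", X), dtype=float)


def estimate_theta(X) -> float:
    """Moment estimate of the loading dispersion theta.

    Fits the ordinary-PCA first loading ``v1`` and returns the mean squared
    deviation of its entries from their sample mean,
    ``(1/p) * sum_j (v1_j - mean(v1))**2``.  Because ``||v1|| = 1`` this is
    ``1/p - mean(v1)**2``, so it is at most ``1/p`` and sign-invariant up to
    the (canonicalized) loading sign.
    """
    from .nipals import nipals_first_component

    A = _values(X)
    if not np.any(A):
        raise ValueError("cannot estimate theta from a zero matrix")
    v1, _, _ = nipals_first_component(A)
    theta = float(np.mean((v1 - np.mean(v1)) ** 2))
    if theta <= 0:  # constant loading (e.g. p == 1): fall back to the raw moment
        theta = float(np.mean(v1 * v1))
    return theta


def default_lambda_grid(X, num: int = 20) -> NDArray[np.float64]:
    """Data-driven lambda grid: ``logspace(-4, 2, num) * scale``.

    The scale is ``median_j |X_j' z|``, the typical gradient magnitude of the
    regression of a column on the leading score ``z``.  The IWLS update is
    ``v_j = X_j'z / (z'z + W_j)``, so penalties of this order are where the
    weight starts to rival the coefficient signal; six decades around it
    bracket both effectively-unpenalized and fully-annihilating strengths.
    """
    from .nipals import nipals_first_component

    A = _values(X)
    _, z, _ = nipals_first_component(A)
    scale = float(np.median(np.abs(A.T @ z)))
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    return np.geomspace(1e-4, 1e2, num) * scale


def select_lambda_cv(X, spec_template: PenaltySpec, cfg: TuningConfig) -> float:
    """Pick lambda maximizing the K-fold held-out score variance.

    Each training fold is centered by its own column means; the held-out
    covariance uses the same means (no leakage).  A fold where the fit
    collapses (all-zero loading) contributes ``-inf`` for that lambda.
    """
    from .nipals import _nipals_loop

    A = _values(X)
    n = A.shape[0]
    if n < cfg.K:
        raise ValueError(f"need at least K={cfg.K} rows")
    grid = (
        np.asarray(cfg.lambda_grid, dtype=float)
        if cfg.lambda_grid is not None
        else default_lambda_grid(A)
    )
    if grid.size == 1:
        return float(grid[0])

    kf = KFold(n_splits=cfg.K, shuffle=True, random_state=cfg.seed)
    splits = list(kf.split(A))
    objective = np.zeros(grid.size)
    for tr, va in splits:
        mu = A[tr].mean(axis=0)
        Tr = A[tr] - mu
        Va = A[va] - mu
        S_va = Va.T @ Va / Va.shape[0]
        for gi, lam in enumerate(grid):
            try:
                v, _, _, _, _ = _nipals_loop(Tr, spec_template.with_(lam=float(lam)), 1e-6, 500)
                if np.linalg.norm(v) == 0:
                    raise FloatingPointError("loading collapsed to zero")
                objective[gi] += float(v @ S_va @ v)
            except (FloatingPointError, RuntimeError, np.linalg.LinAlgError):
                objective[gi] = -np.inf
    best = np.max(objective)
    if not np.isfinite(best):
        raise RuntimeError("every lambda failed cross-validation")
    # ties toward the larger (sparser) lambda
    return float(grid[np.nonzero(objective >= best - 1e-12 * abs(best))[0][-1]])
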
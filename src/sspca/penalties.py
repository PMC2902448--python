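"""Penalty families for sparse loading estimation.

The central penalty comes from a hierarchical random-effect model on a single
loading coefficient ``v``: conditionally ``v | u ~ N(0, u * theta)`` with a
gamma-distributed scale ``u`` of mean 1 and variance ``w``.  Profiling the
scale out of the hierarchical (h-)likelihood yields a penalty whose shape is
controlled by ``w``: quadratic (ridge) at ``w = 0``, a LASSO-like cusp at
``w = 2``, and *unbounded at the origin* for ``w > 2`` -- the regime that
forces extreme sparsity.  We refer to this family as the HL penalty, with
``w = 30`` as the default super-sparse choice.

LASSO, SCAD, elastic-net and ridge are exposed through the same two hooks the
penalized NIPALS loop consumes:

* :func:`penalty_derivative` -- the derivative ``p'(|v|)`` of the penalty with
  respect to the magnitude of the coefficient, and
* :func:`iwls_weight_diagonal` -- the diagonal weight ``p'(|v~|)/|v~|`` of the
  iterative weighted least squares (IWLS) update, evaluated at the perturbed
  magnitude ``v~ = sqrt(v**2 + delta)`` so it is always finite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "PenaltyFamily",
    "PenaltySpec",
    "solve_hl_scale",
    "penalty_derivative",
    "iwls_weight_diagonal",
]


class PenaltyFamily(str, enum.Enum):
    """Supported penalty families."""

    HL = "hl"
    LASSO = "lasso"
    SCAD = "scad"
    EN = "en"
    RIDGE = "ridge"
    NONE = "none"


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family plus its parameters.

    Parameters
    ----------
    family : PenaltyFamily
        Which penalty to apply.  ``NONE`` disables penalization (ordinary
        least squares step, i.e. ordinary PCA).
    lam : float
        Overall penalty strength ``lambda``.  For the HL family this is the
        ratio ``phi / theta`` of the residual to the loading dispersion; the
        two are never needed separately, only their ratio.
    theta : float
        Dispersion of the loading coefficients in the random-effect model
        (marginal variance of a loading entry).  Estimated from data by
        :func:`sspca.tuning.estimate_theta`.
    w : float
        Variance of the gamma scale mixture.  ``0`` recovers ridge, ``2`` the
        LASSO cusp, ``> 2`` an unbounded penalty at the origin (default 30).
    delta : float
        Magnitude perturbation used inside the IWLS weights so they remain
        finite at exact zeros (default ``1e-8``).
    scad_a : float
        SCAD shape parameter ``a > 2`` (default 3.7, the standard choice).
    en_lambda2 : float
        Ridge part of the elastic-net penalty.
    zero_threshold : float
        Reporting threshold: loading entries with magnitude below it are
        declared zero (default ``5e-5``).  This is a reporting rule only;
        stored loadings are never truncated.
    """

    family: PenaltyFamily = PenaltyFamily.HL
    lam: float = 1.0
    theta: float = 1.0
    w: float = 30.0
    delta: float = 1e-8
    scad_a: float = 3.7
    en_lambda2: float = 0.0
    zero_threshold: float = 5e-5

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", PenaltyFamily(self.family))
        if self.lam < 0:
            raise ValueError(f"lambda must be nonnegative, got {self.lam}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.w < 0:
            raise ValueError(f"w must be nonnegative, got {self.w}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.scad_a <= 2:
            raise ValueError(f"SCAD a must exceed 2, got {self.scad_a}")
        if self.en_lambda2 < 0:
            raise ValueError("en_lambda2 must be nonnegative")
        if self.zero_threshold <= 0:
            raise ValueError("zero_threshold must be positive")

    def with_(self, **kwargs) -> "PenaltySpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def solve_hl_scale(v: ArrayLike, theta: float, w: float) -> NDArray[np.float64] | float:
    """Profile estimate of the gamma scale ``u`` given a coefficient ``v``.

    Under ``v | u ~ N(0, u*theta)`` and ``u ~ Gamma(mean 1, variance w)`` the
    stationarity condition ``dh/du = 0`` of the h-likelihood reduces to the
    quadratic ``u**2 + u*(w/2 - 1) - w*v**2/(2*theta) = 0``; this returns its
    nonnegative root

        u_hat = [(1 - w/2) + sqrt((w/2 - 1)**2 + 2*w*v**2/theta)] / 2 .

    At ``w = 0`` the root is identically 1 (ridge); at ``w = 2`` it equals
    ``|v|/sqrt(theta)`` (LASSO-proportional); for ``w > 2`` it vanishes
    quadratically as ``v -> 0``, producing an IWLS weight that diverges at the
    origin.  Accepts scalars or arrays (vectorized over ``v``).
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    if np.any(w < 0):
        raise ValueError("w must be nonnegative")
    v = np.asarray(v, dtype=float)
    b = w / 2.0 - 1.0
    u = 0.5 * (-b + np.sqrt(b * b + 2.0 * w * v * v / theta))
    # at w == 0 the formula reduces exactly to the ridge fixed point u == 1
    u = np.where(w == 0, 1.0, u)
    return u if u.ndim else float(u)


def penalty_derivative(spec: PenaltySpec, v: ArrayLike) -> NDArray[np.float64] | float:
    """Derivative ``p'(|v|)`` of the penalty with respect to the magnitude.

    Conventions (documented because only the ratio ``p'(|v|)/|v|`` matters to
    the IWLS step): ridge is ``p(|v|) = lam * v**2`` so ``p' = 2*lam*|v|``;
    elastic net is ``lam*|v| + en_lambda2*v**2`` so ``p' = lam +
    2*en_lambda2*|v|``.  The HL derivative is ``lam*|v|/u_hat(|v|)``; for
    ``w > 2`` it diverges as ``v -> 0`` (the unbounded-at-origin penalty) and
    ``inf`` is returned at an exact zero.
    """
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    fam = spec.family
    if fam is PenaltyFamily.NONE:
        out = np.zeros_like(a)
    elif fam is PenaltyFamily.LASSO:
        out = np.full_like(a, spec.lam)
    elif fam is PenaltyFamily.RIDGE:
        out = 2.0 * spec.lam * a
    elif fam is PenaltyFamily.EN:
        out = spec.lam + 2.0 * spec.en_lambda2 * a
    elif fam is PenaltyFamily.SCAD:
        lam, sa = spec.lam, spec.scad_a
        if lam == 0:
            out = np.zeros_like(a)
        else:
            inner = a <= lam
            out = np.where(
                inner, lam, np.maximum(sa * lam - a, 0.0) / (sa - 1.0)
            )
    elif fam is PenaltyFamily.HL:
        u = np.asarray(solve_hl_scale(a, spec.theta, spec.w))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = spec.lam * a / u
        # limits at a == 0: u_hat -> 1 - w/2 for w < 2 (derivative 0), the
        # cusp value lam*sqrt(theta) at w == 2, +inf for w > 2
        at_zero = a == 0
        if np.any(at_zero):
            if spec.w < 2:
                val = 0.0
            elif spec.w == 2:
                val = spec.lam * np.sqrt(spec.theta)
            else:
                val = np.inf
            out = np.where(at_zero, val, out)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown family {fam}")
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def iwls_weight_diagonal(spec: PenaltySpec, v_current: ArrayLike) -> NDArray[np.float64]:
    """Diagonal of the IWLS weight matrix ``W`` at the current loadings.

    Entry ``j`` is ``p'(|v~_j|) / |v~_j|`` evaluated at the perturbed
    magnitude ``v~_j = sqrt(v_j**2 + delta)``, so every entry is finite and
    positive even at exact zeros (for the HL family this is
    ``lam / u_hat(v~_j)``).  The perturbation changes estimates negligibly for
    small ``delta`` but makes the weight defined everywhere.
    """
    v = np.atleast_1d(np.asarray(v_current, dtype=float))
    if not np.all(np.isfinite(v)):
        raise ValueError("v_current must be finite")
    vt = np.sqrt(v * v + spec.delta)
    if spec.family is PenaltyFamily.HL:
        u = np.asarray(solve_hl_scale(vt, spec.theta, spec.w))
        return spec.lam / u
    return np.asarray(penalty_derivative(spec, vt), dtype=float) / vt
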
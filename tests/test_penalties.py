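"""Penalty families: closed forms against independent numerical oracles."""

import numpy as np
import pytest
from scipy import optimize

from sspca import PenaltySpec, iwls_weight_diagonal, penalty_derivative, solve_hl_scale


def h_loglik(u, v, theta, w):
    """Joint log density of (v, log u) under the gamma scale mixture.

    v | u ~ N(0, u*theta); u ~ Gamma(shape 1/w, scale w) with the Jacobian of
    the log-u parametrization.  Constants in (v, u) are dropped.  Independent
    of the production closed form: evaluated directly from the densities.
    """
    return (
        -(v**2) / (2 * u * theta)
        - 0.5 * np.log(u * theta)
        + (1.0 / w) * np.log(u)
        - u / w
    )


def h_prime(u, v, theta, w):
    return v**2 / (2 * u**2 * theta) - 1 / (2 * u) + 1 / (w * u) - 1 / w


class TestHLScale:
    @pytest.mark.parametrize(
        "v,theta,w,expected",
        [
            (1.7, 1.0, 0.0, 1.0),  # w=0 quadratic is u^2 - u = 0: ridge
            (1.0, 1.0, 2.0, 1.0),  # at w=2, u_hat = |v|/sqrt(theta)
            (0.0, 1.0, 30.0, 0.0),  # unbounded penalty: u_hat vanishes at 0
            (-2.0, 4.0, 2.0, 1.0),  # sign-invariant; |v|/sqrt(theta)
        ],
    )
    def test_closed_form_special_cases(self, v, theta, w, expected):
        assert solve_hl_scale(v, theta, w) == pytest.approx(expected, abs=1e-12)

    def test_stationarity_residual_on_random_triples(self, rng):
        """h'(u_hat) = 0 within 1e-8 over 1000 random (v, theta, w) triples."""
        v = rng.uniform(0.01, 5.0, 1000) * rng.choice([-1, 1], 1000)
        theta = rng.uniform(0.1, 10.0, 1000)
        w = rng.uniform(0.05, 50.0, 1000)
        u = solve_hl_scale(v, theta, w)
        assert np.all(u > 0)
        resid = h_prime(u, v, theta, w)
        # residual measured relative to the size of the competing terms of
        # h' (they can individually be huge when u_hat is tiny)
        scale = np.maximum(1.0, v**2 / (2 * u**2 * theta) + 1 / (w * u))
        assert np.max(np.abs(resid) / scale) < 1e-8

    def test_matches_brute_force_h_maximizer(self, rng):
        """Closed-form root agrees with direct 1-D maximization of h."""
        for _ in range(60):
            v = rng.uniform(0.05, 4.0)
            theta = rng.uniform(0.2, 5.0)
            w = rng.uniform(0.1, 40.0)
            res = optimize.minimize_scalar(
                lambda s: -h_loglik(np.exp(s), v, theta, w),
                bounds=(-30, 10),
                method="bounded",
                options={"xatol": 1e-14},
            )
            u_brute = float(np.exp(res.x))
            u_closed = solve_hl_scale(v, theta, w)
            assert u_closed == pytest.approx(u_brute, rel=1e-5)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            solve_hl_scale(1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            solve_hl_scale(1.0, 1.0, -0.5)


def scad_penalty(v, lam, a):
    """SCAD penalty value (independent closed form, for differentiation)."""
    v = abs(v)
    if v <= lam:
        return lam * v
    if v <= a * lam:
        return (2 * a * lam * v - v**2 - lam**2) / (2 * (a - 1))
    return lam**2 * (a + 1) / 2


class TestPenaltyDerivative:
    @pytest.mark.parametrize(
        "spec,v,expected",
        [
            (PenaltySpec(family="lasso", lam=0.3), 5.0, 0.3),
            (PenaltySpec(family="scad", lam=1.0), 0.5, 1.0),  # inner branch
            (PenaltySpec(family="scad", lam=1.0), 10.0, 0.0),  # beyond a*lam
            (PenaltySpec(family="ridge", lam=2.0), 3.0, 12.0),  # 2*lam*|v|
            (PenaltySpec(family="en", lam=1.0, en_lambda2=0.5), 2.0, 3.0),
            (PenaltySpec(family="none", lam=0.0), 7.0, 0.0),
        ],
    )
    def test_closed_forms(self, spec, v, expected):
        assert penalty_derivative(spec, v) == pytest.approx(expected, abs=1e-12)

    def test_scad_matches_numerical_differentiation(self):
        spec = PenaltySpec(family="scad", lam=1.3, scad_a=3.7)
        eps = 1e-6
        for v in [0.2, 1.0, 1.5, 3.0, 4.7, 6.0]:
            num = (scad_penalty(v + eps, 1.3, 3.7) - scad_penalty(v - eps, 1.3, 3.7)) / (2 * eps)
            assert penalty_derivative(spec, v) == pytest.approx(num, abs=1e-5)

    def test_hl_unbounded_at_origin_for_w_above_2(self):
        spec = PenaltySpec(family="hl", lam=1.0, theta=1.0, w=30.0)
        assert penalty_derivative(spec, 0.0) == np.inf
        # but finite and decaying in the tail (bell-shaped family)
        assert penalty_derivative(spec, 100.0) < penalty_derivative(spec, 1.0)


class TestIWLSWeights:
    def test_lasso_weight_at_zero_is_large_but_finite(self):
        spec = PenaltySpec(family="lasso", lam=1.0, delta=1e-8)
        w = iwls_weight_diagonal(spec, [0.0])
        assert w[0] == pytest.approx(1e4, rel=1e-10)

    def test_hl_w0_is_ridge_constant_weight(self):
        spec = PenaltySpec(family="hl", lam=1.0, theta=1.0, w=0.0)
        vals = iwls_weight_diagonal(spec, np.linspace(-5, 5, 41))
        assert np.ptp(vals) / vals.mean() < 1e-10
        assert vals[0] == pytest.approx(1.0, rel=1e-8)

    def test_tail_behavior_by_family(self):
        big = np.array([1e4])
        hl = iwls_weight_diagonal(PenaltySpec(family="hl", lam=1.0, w=30.0), big)
        scad = iwls_weight_diagonal(PenaltySpec(family="scad", lam=1.0), big)
        lasso = iwls_weight_diagonal(PenaltySpec(family="lasso", lam=1.0), big)
        assert hl[0] < 1e-3 and scad[0] < 1e-3  # clipped / bell-shaped
        assert lasso[0] == pytest.approx(1e-4, rel=1e-6)  # lam / |v|

    def test_lasso_proportionality_at_w2_cusp(self):
        """HL at w=2 has a weight proportional to the LASSO weight in v."""
        v = np.geomspace(0.01, 10, 50)
        hl = iwls_weight_diagonal(PenaltySpec(family="hl", lam=1.0, theta=2.0, w=2.0), v)
        lasso = iwls_weight_diagonal(PenaltySpec(family="lasso", lam=1.0), v)
        ratio = hl / lasso
        assert np.ptp(ratio) / ratio.mean() < 1e-6

    def test_hl_weight_strictly_decreasing_for_w_above_2(self):
        spec = PenaltySpec(family="hl", lam=1.0, theta=0.5, w=30.0)
        v = np.linspace(0.0, 8.0, 200)
        wts = iwls_weight_diagonal(spec, v)
        assert np.all(np.diff(wts) < 0)

    def test_weights_always_finite(self, rng):
        """Perturbed weights are finite everywhere; strictly positive except
        for SCAD, whose derivative is exactly zero beyond a*lambda."""
        for fam in ["hl", "lasso", "scad", "en", "ridge"]:
            spec = PenaltySpec(family=fam, lam=0.7, theta=0.3, w=30.0, en_lambda2=0.2)
            wts = iwls_weight_diagonal(spec, rng.normal(size=100))
            assert np.all(np.isfinite(wts))
            assert np.all(wts >= 0)
            if fam != "scad":
                assert np.all(wts > 0)


class TestPenaltySpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -1.0},
            {"theta": 0.0},
            {"delta": 0.0},
            {"w": -3.0},
            {"scad_a": 2.0},
            {"zero_threshold": 0.0},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            PenaltySpec(family="hl", **kwargs)
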
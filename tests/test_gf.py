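"""Generating-function coefficients and the likelihood recurrence."""

import math

import numpy as np
import pytest

from popbp import (
    LikelihoodCache,
    ModelParams,
    Schedule,
    build_coefficients,
    likelihood_derivative_recursive,
    likelihood_recursive,
)
from popbp.simulate import (
    BruteForceConfig,
    derivative_bruteforce,
    likelihood_bruteforce,
)


def _all_vectors(n, max_degree):
    if n == 0:
        yield ()
        return
    for first in range(max_degree + 1):
        for rest in _all_vectors(n - 1, max_degree - first):
            yield (first,) + rest


class TestCoefficients:
    def test_single_observation_hand_expansion(self):
        # Q_1 = (p u_1 + q)((1 - ups) + ups u_0) with ups_{1,2} = 1
        lam = math.log(2)
        params = ModelParams(lam, 0.3)
        co = build_coefficients(params, Schedule((1.0,)))
        p, q, u = 0.3, 0.7, 0.5
        assert co.q_coeff((0, 0)) == pytest.approx(q * (1 - u))
        assert co.q_coeff((1, 0)) == pytest.approx(q * u)
        assert co.q_coeff((0, 1)) == pytest.approx(p * (1 - u))
        assert co.q_coeff((1, 1)) == pytest.approx(p * u)
        assert co.normalizer == pytest.approx(1 - q * (1 - u))

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_all_coefficients_positive_and_counted(self, n):
        params = ModelParams(0.9, 0.35)
        times = tuple((i + 1) / n for i in range(n))
        co = build_coefficients(params, Schedule(times))
        assert co.q.size == 2 ** (n + 1)
        assert np.all(co.q > 0)          # exactly 2^(n+1) nonzero terms
        assert 0 < co.normalizer <= 1

    def test_degenerate_p_legal(self):
        for p in (0.0, 1.0):
            co = build_coefficients(ModelParams(1.0, p), Schedule((0.5, 1.0)))
            assert np.all(co.q >= 0)

    def test_numerator_coefficients(self):
        params = ModelParams(1.0, 0.6)
        sch = Schedule((0.4, 1.0))
        co = build_coefficients(params, sch)
        theta = math.exp(-1.0)
        assert co.numer_coeff((0, 0)) == pytest.approx(theta * 0.4**2)
        assert co.numer_coeff((1, 0)) == pytest.approx(theta * 0.6 * 0.4)
        assert co.numer_coeff((1, 1)) == pytest.approx(theta * 0.36)
        assert co.numer_coeff((2, 0)) == 0.0  # numerator is multilinear
        assert co.dnumer_coeff((1, 1)) == pytest.approx(-1.0 * theta * 0.36)

    def test_matches_generic_polynomial_expansion(self, rng):
        # independent oracle: dict-based multivariate polynomial arithmetic
        n = 3
        lam = 0.5 + rng.uniform(0, 1)
        p = rng.uniform(0.1, 0.9)
        times = np.sort(rng.uniform(0.1, 0.9, size=n - 1))
        sch = Schedule(tuple(times) + (1.0,))
        params = ModelParams(lam, p)
        co = build_coefficients(params, sch)

        def poly_mul(a, b):
            out = {}
            for ka, va in a.items():
                for kb, vb in b.items():
                    k = tuple(x + y for x, y in zip(ka, kb))
                    out[k] = out.get(k, 0.0) + va * vb
            return out

        zero = (0,) * (n + 1)

        def unit(i):
            k = list(zero)
            k[i] = 1
            return tuple(k)

        ups = sch.decay(lam)
        Q = {zero: 1 - ups[0], unit(0): ups[0]}
        for i in range(1, n + 1):
            u = ups[i] if i < n else 1.0
            aff = {zero: 1 - p, unit(i): p}
            Q = poly_mul(aff, Q)
            Q = {k: u * v for k, v in Q.items()}
            Q[zero] = Q.get(zero, 0.0) + (1 - u)
        for k, v in Q.items():
            assert co.q_coeff(k) == pytest.approx(v, abs=1e-12)

    def test_derivative_coefficients_by_finite_differences(self):
        n, p = 2, 0.4
        times = (0.3, 1.0)
        h = 1e-6
        co = build_coefficients(ModelParams(1.0, p), Schedule(times))
        co_hi = build_coefficients(ModelParams(1.0 + h, p), Schedule(times))
        co_lo = build_coefficients(ModelParams(1.0 - h, p), Schedule(times))
        fd = (co_hi.q - co_lo.q) / (2 * h)
        assert np.allclose(co.dq, fd, atol=1e-8)

    def test_serialisation_roundtrip(self, two_obs_coeffs):
        import json

        data = json.loads(two_obs_coeffs.to_json())
        assert data["order"] == 2
        assert len(data["q"]) == 8
        assert data["q"]["000"] == pytest.approx(float(two_obs_coeffs.q[0]))


class TestRecursion:
    def test_geometric_gatekeeper(self):
        # n=1, p=1: the recursion must reproduce ups*(1-ups)**(y-1) exactly.
        # This discriminates the u0-constant-coefficient specialisation from
        # the (incorrect) substitution u0 = 1.
        lam = math.log(2)
        co = build_coefficients(ModelParams(lam, 1.0), Schedule((1.0,)))
        cache = LikelihoodCache()
        ups = 0.5
        for y in range(1, 21):
            expected = ups * (1 - ups) ** (y - 1)
            assert likelihood_recursive((y,), co, cache) == pytest.approx(
                expected, abs=1e-14
            )
        assert likelihood_recursive((0,), co, cache) == 0.0

    def test_thinned_geometric_zero_count(self):
        # closed form L(0) = q*ups / (1 - q*(1-ups))
        lam = math.log(2)
        co = build_coefficients(ModelParams(lam, 0.5), Schedule((1.0,)))
        assert likelihood_recursive((0,), co) == pytest.approx(0.25 / 0.75, abs=1e-14)

    def test_matches_bruteforce_two_obs(self, two_obs_model, two_obs_coeffs, two_obs_bf_cfg):
        params, sch = two_obs_model
        cache = LikelihoodCache()
        for y in _all_vectors(2, 6):
            L_rec = likelihood_recursive(y, two_obs_coeffs, cache)
            L_bf = likelihood_bruteforce(y, params, sch, two_obs_bf_cfg)
            assert L_rec == pytest.approx(L_bf, abs=1e-10)

    def test_matches_bruteforce_three_obs(self):
        params = ModelParams(0.8, 0.5)
        sch = Schedule((0.3, 0.6, 1.0))
        co = build_coefficients(params, sch)
        cfg = BruteForceConfig.for_model(params, sch, tail_bound=1e-13)
        cache = LikelihoodCache()
        for y in _all_vectors(3, 4):
            L_rec = likelihood_recursive(y, co, cache)
            L_bf = likelihood_bruteforce(y, params, sch, cfg)
            assert L_rec == pytest.approx(L_bf, abs=1e-10)

    @pytest.mark.parametrize("x0", [2, 3])
    def test_general_initial_size_vs_bruteforce(self, x0):
        params = ModelParams(1.0, 0.6, init_size=x0)
        sch = Schedule((0.4, 1.0))
        co = build_coefficients(params, sch)
        cfg = BruteForceConfig.for_model(params, sch, tail_bound=1e-13)
        cache = LikelihoodCache()
        for y in _all_vectors(2, 5):
            L_rec = likelihood_recursive(y, co, cache, x0=x0)
            L_bf = likelihood_bruteforce(y, params, sch, cfg)
            assert L_rec == pytest.approx(L_bf, abs=1e-10)

    def test_recurrence_coefficients_nonnegative(self, two_obs_coeffs):
        # no cancellation in the forward recursion
        assert np.all(two_obs_coeffs.q >= 0)
        assert two_obs_coeffs.normalizer > 0


class TestDerivative:
    def test_single_full_observation_derivative(self):
        # n=1, p=1, t1=1: L(1) = exp(-lam), dL = -exp(-lam)
        lam = 1.0
        co = build_coefficients(ModelParams(lam, 1.0), Schedule((1.0,)))
        cache = LikelihoodCache()
        assert likelihood_recursive((1,), co, cache) == pytest.approx(math.exp(-1))
        assert likelihood_derivative_recursive((1,), co, cache) == pytest.approx(
            -math.exp(-1), abs=1e-14
        )

    def test_matches_central_finite_differences(self, two_obs_model):
        params, sch = two_obs_model
        h = 1e-6
        co = build_coefficients(params, sch)
        co_hi = build_coefficients(ModelParams(1.0 + h, 0.6), sch)
        co_lo = build_coefficients(ModelParams(1.0 - h, 0.6), sch)
        cache, chi, clo = LikelihoodCache(), LikelihoodCache(), LikelihoodCache()
        for y in _all_vectors(2, 6):
            d = likelihood_derivative_recursive(y, co, cache)
            fd = (
                likelihood_recursive(y, co_hi, chi)
                - likelihood_recursive(y, co_lo, clo)
            ) / (2 * h)
            assert d == pytest.approx(fd, rel=1e-6, abs=1e-12)

    def test_matches_bruteforce_derivative(self, two_obs_model, two_obs_coeffs, two_obs_bf_cfg):
        params, sch = two_obs_model
        cache = LikelihoodCache()
        for y in _all_vectors(2, 6):
            d_rec = likelihood_derivative_recursive(y, two_obs_coeffs, cache)
            d_bf = derivative_bruteforce(y, params, sch, two_obs_bf_cfg)
            assert d_rec == pytest.approx(d_bf, abs=1e-8)


class TestContracts:
    def test_wrong_length_rejected(self, two_obs_coeffs):
        with pytest.raises(ValueError):
            likelihood_recursive((1,), two_obs_coeffs)

    def test_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            Schedule(())
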
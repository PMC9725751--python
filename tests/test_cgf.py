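import math

import numpy as np
import pytest

from lineagestat import (
    cgf,
    cgf_derivatives,
    cumulants,
    fitness_landscape,
    fitness_variance,
    kprime_curve,
    mean_fitness,
    measure_difference,
    perturbed_growth,
    response_slope,
    selection_strengths,
    trait_distribution_pair,
)
from lineagestat.fixtures import build_skewed_regrowth
from lineagestat import LineageEnsemble, LineageRecord

from _oracles import central_moment_cumulants, moments_to_cumulants, raw_moments

LN2 = math.log(2.0)


@pytest.fixture
def t1_pair(t1):
    return trait_distribution_pair(t1)


@pytest.fixture
def uniform_pair(uniform_tree):
    return trait_distribution_pair(uniform_tree)


class TestCGF:
    def test_zero_at_origin(self, t1_pair, uniform_pair):
        assert cgf(t1_pair, 0.0) == pytest.approx(0.0, abs=1e-14)
        assert cgf(uniform_pair, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_unit_argument_gives_log_fold_growth(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            assert cgf(pair, 1.0) == pytest.approx(pair.tau_lambda, abs=1e-10)

    def test_t1_midpoint(self, t1_pair):
        expected = math.log(0.5 * 2 ** 0.5 + 0.5 * 4 ** 0.5)
        assert cgf(t1_pair, 0.5) == pytest.approx(expected, abs=1e-12)
        assert cgf(t1_pair, 0.5) == pytest.approx(0.5348, abs=1e-4)


class TestDerivatives:
    def test_t1_endpoints(self, t1_pair):
        kp0, kpp0 = cgf_derivatives(t1_pair, 0.0)
        assert kp0 == pytest.approx(1.5 * LN2, abs=1e-12)
        assert kpp0 == pytest.approx(0.25 * LN2 ** 2, abs=1e-12)
        kp1, _ = cgf_derivatives(t1_pair, 1.0)
        assert kp1 == pytest.approx((5 / 3) * LN2, abs=1e-12)

    def test_endpoint_identities_on_fuzzed_ensembles(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            m_cl, m_rs = mean_fitness(pair)
            v_cl, v_rs = fitness_variance(pair)
            kp, kpp = cgf_derivatives(pair, np.array([0.0, 1.0]))
            assert kp[0] == pytest.approx(m_cl, abs=1e-10)
            assert kp[1] == pytest.approx(m_rs, abs=1e-10)
            assert kpp[0] == pytest.approx(v_cl, abs=1e-10)
            assert kpp[1] == pytest.approx(v_rs, abs=1e-10)

    def test_uniform_pair_degenerate(self, uniform_pair):
        xi = np.linspace(0, 1, 11)
        kp, kpp = cgf_derivatives(uniform_pair, xi)
        assert np.allclose(kp, uniform_pair.tau_lambda, atol=1e-12)
        assert np.allclose(kpp, 0.0, atol=1e-12)

    def test_convexity(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            _, kpp = cgf_derivatives(pair, np.linspace(0, 1, 21))
            assert np.all(kpp >= -1e-12)


class TestCumulants:
    def test_t1_low_orders(self, t1_pair):
        ser = cumulants(t1_pair)
        assert ser.kappa[0] == pytest.approx(1.0397, abs=1e-4)
        assert ser.kappa[1] == pytest.approx(0.12011, abs=1e-5)
        assert ser.kappa[2] == pytest.approx(0.0, abs=1e-12)  # symmetric two-point
        assert ser.w[0] == pytest.approx(0.946, abs=1e-3)
        assert ser.skewness == pytest.approx(0.0, abs=1e-10)

    def test_uniform_pair_trivial_series(self, uniform_pair):
        ser = cumulants(uniform_pair)
        assert ser.kappa[0] == pytest.approx(uniform_pair.tau_lambda, abs=1e-12)
        assert np.allclose(ser.kappa[1:], 0.0, atol=1e-10)
        assert np.allclose(ser.w, 1.0, atol=1e-10)
        assert ser.converged

    def test_power_series_route_matches_moment_recursion(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            h = fitness_landscape(pair)
            ser = cumulants(pair, n_max=8)
            oracle = moments_to_cumulants(raw_moments(h, pair.q_cl, 8))
            assert np.allclose(ser.kappa, oracle, atol=1e-9)

    def test_low_orders_match_central_moment_formulas(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            h = fitness_landscape(pair)
            ser = cumulants(pair, n_max=6)
            oracle = central_moment_cumulants(h, pair.q_cl)
            assert np.allclose(ser.kappa[:4], oracle, atol=1e-9)

    def test_series_consistency_when_converged(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            ser = cumulants(pair, n_max=25)
            if ser.converged:
                total = np.sum(ser.kappa / np.array([math.factorial(n) for n in range(1, 26)]))
                assert abs(total - pair.tau_lambda) < 1e-6 * abs(pair.tau_lambda)

    def test_zero_growth_rejected(self):
        # one founder, one lineage, no divisions: tau*Lambda = 0
        ens = LineageEnsemble("tree", [LineageRecord("a", 0)], 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="undefined"):
            cumulants(trait_distribution_pair(ens))


class TestMeasureDifference:
    def test_symmetric_pair_near_zero(self, t1_pair):
        md = measure_difference(t1_pair)
        # two-point support: kappa3 = 0 but higher even cumulants contribute
        assert abs(md.exact) < 0.01
        assert md.truncation_gap < 1e-8

    def test_right_skew_inflates_retrospective_variance(self):
        ens, _ = build_skewed_regrowth(p0=0.9, dmax=6, n=200)
        pair = trait_distribution_pair(ens)
        md = measure_difference(pair, n_max=30)
        _, s_kl1, s_kl2 = selection_strengths(pair)
        assert s_kl2 > s_kl1
        assert md.exact > 0
        assert md.variance_effect == "increase"

    def test_left_skew_mirror(self):
        # mostly prolific lineages with a rare dormant tail
        counts = [6] * 180 + [0, 1, 2, 3, 4] * 4
        recs = [LineageRecord(f"s{i}", c) for i, c in enumerate(counts)]
        ens = LineageEnsemble("chronological", recs, float(len(recs)), 0.0, 1.0)
        pair = trait_distribution_pair(ens)
        _, s_kl1, s_kl2 = selection_strengths(pair)
        md = measure_difference(pair, n_max=30)
        assert s_kl1 > s_kl2
        assert md.exact < 0
        assert md.variance_effect == "decrease"


class TestKprimeCurve:
    def test_uniform_flat_line(self, uniform_pair):
        curve = kprime_curve(uniform_pair)
        assert np.allclose(curve.kprime, uniform_pair.tau_lambda, atol=1e-12)

    def test_t1_endpoints_and_monotonicity(self, t1_pair):
        curve = kprime_curve(t1_pair)
        assert curve.kprime[0] == pytest.approx(1.5 * LN2, abs=1e-12)
        assert curve.kprime[-1] == pytest.approx((5 / 3) * LN2, abs=1e-12)
        assert np.all(np.diff(curve.kprime) >= -1e-12)

    def test_area_under_kprime_equals_growth(self, t1_pair):
        curve = kprime_curve(t1_pair, step=0.01)
        assert curve.area_kprime() == pytest.approx(t1_pair.tau_lambda, abs=1e-4)


class TestPerturbationResponse:
    def test_limits(self, t1_pair):
        assert perturbed_growth(t1_pair, 0.0) == pytest.approx(t1_pair.tau_lambda, abs=1e-12)
        assert perturbed_growth(t1_pair, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_t1_half_strength(self, t1_pair):
        assert perturbed_growth(t1_pair, 0.5) == pytest.approx(0.5348, abs=1e-4)

    def test_uniform_relative_slope_is_minus_one(self, uniform_pair):
        slope, relative = response_slope(uniform_pair)
        assert relative == pytest.approx(-1.0, abs=1e-12)
        assert slope == pytest.approx(-uniform_pair.tau_lambda / uniform_pair.tau, abs=1e-12)

    def test_t1_slope_values(self, t1_pair):
        slope, relative = response_slope(t1_pair)
        assert slope == pytest.approx(-(5 / 3) * LN2, abs=1e-12)
        assert relative == pytest.approx(-1.0515, abs=1e-3)

    def test_finite_difference_oracle(self, random_ensembles):
        eps = 1e-4
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            slope, _ = response_slope(pair)
            fd = (perturbed_growth(pair, eps) - perturbed_growth(pair, 0.0)) / eps
            assert fd == pytest.approx(slope, rel=1e-3)

    def test_non_division_trait_guarded(self, t1):
        from lineagestat import BinningSpec

        ens = t1.with_traits("x", [1.0, 2.0, 3.0])
        pair = trait_distribution_pair(ens, "x", BinningSpec("explicit", width=1.0, origin=1.0))
        with pytest.raises(ValueError, match="division"):
            perturbed_growth(pair, 0.1)
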
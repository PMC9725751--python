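import math

import numpy as np
import pytest

from lineagestat import (
    BinningSpec,
    LineageEnsemble,
    LineageRecord,
    decompose_growth,
    fitness_landscape,
    mean_fitness,
    population_growth,
    randomization_null,
    relative_selection_strength,
    selection_strengths,
    selection_summary,
    trait_distribution_pair,
)
from lineagestat.fixtures import random_tree_ensemble

from _oracles import division_stats

LN2 = math.log(2.0)


class TestPopulationGrowth:
    def test_t1(self, t1):
        lam, tau_lambda = population_growth(t1)
        assert tau_lambda == pytest.approx(math.log(3.0))
        assert lam == pytest.approx(math.log(3.0))  # tau = 1

    def test_uniform_tree(self, uniform_tree):
        _, tau_lambda = population_growth(uniform_tree)
        assert tau_lambda == pytest.approx(3 * LN2)

    def test_microcolony_counts_glucose_37C(self):
        # 163 founders growing to 3989 cells over a 5 h window
        ens = LineageEnsemble(
            "tree", [LineageRecord(str(i), 0) for i in range(3989)],
            163.0, 0.0, 5.0,
        )
        lam, tau_lambda = population_growth(ens)
        assert lam == pytest.approx(0.6395, abs=2e-4)
        assert tau_lambda == pytest.approx(math.log(3989 / 163))

    def test_chronological_growth_estimator(self, chrono_pair_01):
        _, tau_lambda = population_growth(chrono_pair_01)
        assert tau_lambda == pytest.approx(math.log((1 + 2) / 2))


class TestFitnessLandscape:
    def test_t1_values(self, t1):
        pair = trait_distribution_pair(t1)
        h = fitness_landscape(pair)
        assert h == pytest.approx([LN2, 2 * LN2])

    def test_division_landscape_is_d_ln2_on_complete_trees(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            h = fitness_landscape(pair)
            assert np.allclose(h, pair.bin_centers * LN2, atol=1e-10)

    def test_uniform_landscape_equals_tau_lambda(self, uniform_tree):
        pair = trait_distribution_pair(uniform_tree)
        h = fitness_landscape(pair)
        assert h == pytest.approx([pair.tau_lambda])


class TestSelectionStrengths:
    def test_t1_values(self, t1):
        pair = trait_distribution_pair(t1)
        s_jf, s_kl1, s_kl2 = selection_strengths(pair)
        assert s_kl1 == pytest.approx(math.log(3) - 1.5 * LN2, abs=1e-12)
        assert s_kl2 == pytest.approx((5 / 3) * LN2 - math.log(3), abs=1e-12)
        assert s_jf == pytest.approx(s_kl1 + s_kl2, abs=1e-12)

    def test_uniform_tree_zero(self, uniform_tree):
        assert selection_strengths(trait_distribution_pair(uniform_tree)) == \
            pytest.approx((0.0, 0.0, 0.0), abs=1e-14)

    def test_two_root(self, two_root):
        _, s_kl1, _ = selection_strengths(trait_distribution_pair(two_root))
        assert s_kl1 == pytest.approx(math.log(1.5) - 0.5 * LN2, abs=1e-12)

    def test_matches_bruteforce_oracle(self, random_ensembles):
        for ens in random_ensembles:
            oracle = division_stats(ens.divisions, ens.n0)
            s_jf, s_kl1, s_kl2 = selection_strengths(trait_distribution_pair(ens))
            assert s_kl1 == pytest.approx(oracle["s_kl1"], abs=1e-10)
            assert s_kl2 == pytest.approx(oracle["s_kl2"], abs=1e-10)
            assert s_jf == pytest.approx(oracle["s_kl1"] + oracle["s_kl2"], abs=1e-10)

    def test_exact_identities(self, random_ensembles):
        for ens in random_ensembles:
            pair = trait_distribution_pair(ens)
            s_jf, s_kl1, s_kl2 = selection_strengths(pair)
            m_cl, m_rs = mean_fitness(pair)
            tl = pair.tau_lambda
            assert s_jf == pytest.approx(s_kl1 + s_kl2, abs=1e-10)
            assert tl == pytest.approx(m_cl + s_kl1, abs=1e-10)
            assert tl == pytest.approx(m_rs - s_kl2, abs=1e-10)
            assert m_rs >= m_cl - 1e-12  # Jeffreys non-negativity


class TestDecomposition:
    def test_t1(self, t1):
        dec = decompose_growth(trait_distribution_pair(t1))
        assert dec.mean_fitness_cl == pytest.approx(1.5 * LN2, abs=1e-12)
        assert dec.s_kl1 == pytest.approx(0.058892, abs=1e-5)
        assert dec.gain_fraction == pytest.approx(0.0536, abs=1e-4)

    def test_uniform_gain_zero(self, uniform_tree):
        assert decompose_growth(trait_distribution_pair(uniform_tree)).gain_fraction == \
            pytest.approx(0.0, abs=1e-14)

    def test_deterministic_heterogeneous_tree_against_enumeration(self):
        # one founder yields 2 lineages of D=1, another 8 lineages of D=3
        recs = [LineageRecord(f"a{i}", 1) for i in range(2)] + \
               [LineageRecord(f"b{i}", 3) for i in range(8)]
        ens = LineageEnsemble("tree", recs, 2.0, 0.0, 1.0)
        dec = decompose_growth(trait_distribution_pair(ens))
        oracle = division_stats(ens.divisions, 2.0)
        assert dec.tau_lambda == pytest.approx(oracle["tau_lambda"], abs=1e-12)
        assert dec.mean_fitness_cl == pytest.approx(oracle["mean_cl"], abs=1e-12)
        assert dec.s_kl1 == pytest.approx(oracle["s_kl1"], abs=1e-12)
        assert dec.tau_lambda == pytest.approx(dec.mean_fitness_cl + dec.s_kl1, abs=1e-10)

    def test_non_division_trait_guarded(self, t1):
        ens = t1.with_traits("x", [1.0, 2.0, 3.0])
        pair = trait_distribution_pair(ens, "x", BinningSpec("explicit", width=1.0, origin=1.0))
        with pytest.raises(ValueError, match="division"):
            decompose_growth(pair)
        decompose_growth(pair, allow_generic=True)  # identity still holds


class TestRelativeSelectionStrength:
    def test_trait_equal_to_divisions(self, t1):
        summ = selection_summary(t1.with_traits("x", [1.0, 2.0, 2.0]), "x",
                                 BinningSpec("explicit", width=1.0, origin=1.0))
        assert summ.s_rel == pytest.approx(1.0, abs=1e-12)

    def test_bijection_of_divisions(self, t1):
        # any relabeling of D states leaves the divergences invariant
        summ = selection_summary(t1.with_traits("x", [10.0, -3.0, -3.0]), "x",
                                 BinningSpec("explicit", width=1.0, origin=-3.0))
        assert summ.s_rel == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait(self, t1):
        summ = selection_summary(t1.with_traits("x", [5.0, 5.0, 5.0]), "x",
                                 BinningSpec("explicit", width=1.0, origin=5.0))
        assert summ.s_rel == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_cases(self):
        assert relative_selection_strength(0.0, 0.0) is None
        with pytest.raises(ValueError):
            relative_selection_strength(0.5, 0.0)
        with pytest.raises(ValueError):
            relative_selection_strength(1.0, 0.5)

    def test_maximum_bound_under_fuzzed_traits_and_binnings(self, rng):
        """Data-processing inequality: no trait/binning beats the division
        count's selection strength."""
        for _ in range(40):
            ens = random_tree_ensemble(rng, max_lineages=60)
            _, s_d, _ = selection_strengths(trait_distribution_pair(ens))
            vals = ens.divisions + rng.normal(0, rng.uniform(0.1, 2.0), ens.n_lineages)
            ens2 = ens.with_traits("x", vals)
            width = rng.uniform(0.3, 3.0)
            pair = trait_distribution_pair(ens2, "x", BinningSpec("fixed_width", width=width))
            s_jf_x, s_kl1_x, s_kl2_x = selection_strengths(pair)
            pair_d = trait_distribution_pair(ens2)
            s_jf_d, s_kl1_d, s_kl2_d = selection_strengths(pair_d)
            assert s_kl1_x <= s_kl1_d + 1e-9
            # the same sufficiency argument applies to the other measures
            assert s_kl2_x <= s_kl2_d + 1e-9
            assert s_jf_x <= s_jf_d + 1e-9


class TestRandomizationNull:
    def test_trait_identical_to_divisions_tops_the_null(self, rng):
        ens = random_tree_ensemble(rng, max_lineages=60)
        ens = ens.with_traits("x", ens.divisions.astype(float))
        null = randomization_null(ens, "x", BinningSpec("explicit", width=1.0, origin=0.0),
                                  n_perm=100, seed=1)
        assert null.observed == pytest.approx(1.0, abs=1e-9)
        assert null.percentile >= 0.95

    def test_deterministic_under_seed(self, rng):
        ens = random_tree_ensemble(rng, max_lineages=40, n_traits=1)
        a = randomization_null(ens, "x0", n_perm=20, seed=7)
        b = randomization_null(ens, "x0", n_perm=20, seed=7)
        assert np.array_equal(a.null_samples, b.null_samples)
        assert a.percentile == b.percentile

    def test_independent_trait_calibration(self, rng):
        """A trait independent of D should rarely look significant."""
        inside = 0
        reps = 20
        for _ in range(reps):
            ens = random_tree_ensemble(rng, max_lineages=50)
            vals = rng.normal(0.0, 1.0, ens.n_lineages)  # independent of D
            ens2 = ens.with_traits("x", vals)
            null = randomization_null(ens2, "x", n_perm=79, seed=int(rng.integers(2**31)))
            lo, hi = np.quantile(null.null_samples, [0.025, 0.975])
            if null.observed is None or lo <= null.observed <= hi:
                inside += 1
        assert inside >= reps * 0.7
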
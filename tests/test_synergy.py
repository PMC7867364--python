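import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from synscreen.simulate import simulate_combination
from synscreen.synergy import (
    CombinationExperiment,
    additive_expectation,
    bliss_expectation,
    permutation_pvalue,
    read_combination,
    score_combination,
    write_combination,
)

fractions = st.floats(0.0, 1.0)


class TestExpectations:
    def test_additive_is_capped_sum(self):
        assert additive_expectation(0.04, 0.06) == pytest.approx(0.10)
        assert additive_expectation(0.7, 0.8) == 1.0
        assert additive_expectation(0.0, 0.3) == 0.3

    def test_bliss_values(self):
        assert bliss_expectation(0.2, 0.3) == pytest.approx(0.44)
        assert bliss_expectation(0.5, 0.0) == 0.5
        assert bliss_expectation(1.0, 0.25) == 1.0

    @pytest.mark.parametrize("fn", [additive_expectation, bliss_expectation])
    @pytest.mark.parametrize("a,b", [(-0.1, 0.5), (0.5, 1.2), (math.nan, 0.5)])
    def test_out_of_range_rejected(self, fn, a, b):
        with pytest.raises(ValueError):
            fn(a, b)

    @given(fractions, fractions)
    def test_symmetry(self, a, b):
        assert additive_expectation(a, b) == additive_expectation(b, a)
        assert bliss_expectation(a, b) == bliss_expectation(b, a)

    @given(fractions, fractions)
    def test_bounds_ordering(self, a, b):
        bliss = bliss_expectation(a, b)
        additive = additive_expectation(a, b)
        assert max(a, b) <= bliss + 1e-12
        assert bliss <= additive + 1e-12
        assert additive <= 1.0

    def test_bounds_on_grid(self):
        grid = np.linspace(0, 1, 21)
        for a, b in itertools.product(grid, grid):
            assert max(a, b) - 1e-12 <= bliss_expectation(a, b) \
                <= additive_expectation(a, b) <= 1.0


def brute_force_exact_p(group, reference):
    """Enumerate every relabeling of the pooled values (independent oracle)."""
    pooled = list(group) + list(reference)
    k = len(group)
    observed = np.mean(group) - np.mean(reference)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), k):
        g = [pooled[i] for i in idx]
        r = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if np.mean(g) - np.mean(r) >= observed - 1e-12:
            count += 1
    return count / total


class TestPermutationTest:
    def test_exact_matches_brute_force_enumeration_3_plus_3(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0.4, 0.05, 3)
            y = rng.normal(0.3, 0.05, 3)
            p, exact = permutation_pvalue(x, y)
            assert exact
            assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.1, 4)
        y = rng.normal(0.3, 0.1, 5)

        def statistic(a, b, axis=-1):
            return np.mean(a, axis=axis) - np.mean(b, axis=axis)

        ref = stats.permutation_test(
            (x, y), statistic, permutation_type="independent",
            alternative="greater", n_resamples=np.inf,
        )
        p, exact = permutation_pvalue(x, y)
        assert exact
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identity_labeling_bounds_p_away_from_zero(self):
        x = [1.0, 1.1, 1.2]
        y = [0.0, 0.1, 0.2]
        p, _ = permutation_pvalue(x, y)
        assert p == pytest.approx(1 / 20)  # C(6,3) = 20 arrangements

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.45, 0.05, 9)
        y = rng.normal(0.40, 0.05, 9)  # C(18,9) = 48620 > max_exact
        p_mc, exact = permutation_pvalue(x, y, n_permutations=40_000, seed=1)
        assert not exact
        p_ref, ref_exact = permutation_pvalue(x, y, max_exact=100_000)
        assert ref_exact
        assert p_mc == pytest.approx(p_ref, abs=0.02)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match=">= 2"):
            permutation_pvalue([1.0], [0.0, 0.1])

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0.5, 0.1, 10), rng.normal(0.4, 0.1, 10)
        p1, _ = permutation_pvalue(x, y, seed=5)
        p2, _ = permutation_pvalue(x, y, seed=5)
        assert p1 == p2


class TestScoreCombination:
    def test_worked_headline_arithmetic(self):
        """Combination killing 37% against single agents summing to 10%:
        excess over the cumulative expectation is 27 points."""
        a, b = 0.04, 0.06
        excess = 0.37 - bliss_expectation(a, b)
        exp = simulate_combination(a, b, interaction_excess=excess,
                                   n_replicates=3, noise_sd=0.0, seed=0)
        res = score_combination(exp, seed=0)
        assert res.effect_combo == pytest.approx(0.37, abs=1e-12)
        assert res.expected_additive == pytest.approx(0.10, abs=1e-12)
        assert res.excess_additive == pytest.approx(0.27, abs=1e-12)

    def test_combo_equal_to_additive_expectation_gives_zero_excess(self):
        exp = CombinationExperiment(values={
            "vehicle": np.array([0.05, 0.05]),
            "drug_a": np.array([0.15, 0.15]),
            "drug_b": np.array([0.25, 0.25]),
            "combination": np.array([0.35, 0.35]),
        })
        res = score_combination(exp, seed=0)
        assert res.excess_additive == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_bliss_independent_has_zero_bliss_excess(self):
        exp = simulate_combination(0.2, 0.3, interaction_excess=0.0,
                                   n_replicates=3, noise_sd=0.0, seed=0)
        res = score_combination(exp, seed=0)
        assert res.excess_bliss == pytest.approx(0.0, abs=1e-12)
        assert res.effect_a == pytest.approx(0.2, abs=1e-12)
        assert res.effect_b == pytest.approx(0.3, abs=1e-12)

    def test_vehicle_subtraction(self):
        exp = CombinationExperiment(values={
            "vehicle": np.array([0.10, 0.10]),
            "drug_a": np.array([0.30, 0.30]),
            "drug_b": np.array([0.20, 0.20]),
            "combination": np.array([0.60, 0.60]),
        })
        res = score_combination(exp, seed=0)
        assert res.effect_a == pytest.approx(0.20)
        assert res.effect_b == pytest.approx(0.10)
        assert res.effect_combo == pytest.approx(0.50)

    def test_single_replicate_arm_rejected(self):
        exp = CombinationExperiment(values={
            "vehicle": np.array([0.1]),
            "drug_a": np.array([0.2, 0.2]),
            "drug_b": np.array([0.2, 0.2]),
            "combination": np.array([0.5, 0.5]),
        })
        with pytest.raises(ValueError, match="replicate"):
            score_combination(exp)

    def test_bias_of_excess_bliss_over_many_experiments(self):
        """Monte-Carlo: the excess-Bliss estimator is unbiased at the
        generator's noise scale."""
        noise_sd, n_rep = 0.03, 4
        vals = []
        for seed in range(500):
            exp = simulate_combination(0.15, 0.2, 0.0, n_replicates=n_rep,
                                       noise_sd=noise_sd, seed=seed)
            vals.append(score_combination(exp, seed=seed).excess_bliss)
        assert abs(np.mean(vals)) < 3 * noise_sd / np.sqrt(n_rep)


class TestCombinationIO:
    def test_roundtrip_fraction_units(self, tmp_path):
        exp = simulate_combination(0.1, 0.2, 0.05, n_replicates=3,
                                   noise_sd=0.02, seed=4)
        path = tmp_path / "combo.tsv"
        write_combination(exp, path)
        back = read_combination(path)
        for cond in exp.values:
            assert np.allclose(back.values[cond], exp.values[cond])

    def test_percent_units_are_converted(self, tmp_path):
        path = tmp_path / "combo_percent.tsv"
        path.write_text(
            "# units: percent\n"
            "condition\treplicate_id\tvalue\n"
            + "".join(f"vehicle\t{i}\t5.0\n" for i in (1, 2))
            + "".join(f"drug_a\t{i}\t9.0\n" for i in (1, 2))
            + "".join(f"drug_b\t{i}\t11.0\n" for i in (1, 2))
            + "".join(f"combination\t{i}\t42.0\n" for i in (1, 2))
        )
        exp = read_combination(path)
        assert np.allclose(exp.values["combination"], 0.42)
        res = score_combination(exp, seed=0)
        assert res.effect_combo == pytest.approx(0.37)
        assert res.excess_additive == pytest.approx(0.27)

    def test_out_of_range_fractions_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CombinationExperiment(values={
                "vehicle": np.array([0.1, 0.1]),
                "drug_a": np.array([1.2, 0.2]),
                "drug_b": np.array([0.2, 0.2]),
                "combination": np.array([0.5, 0.5]),
            })
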
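"""Match-outcome statistics: rates, overlaps, encounter curves, power laws."""
import numpy as np
import pytest
from scipy import stats as sps

from sitematch.errors import ParameterError
from sitematch.fixtures import make_match_matrix
from sitematch.match_stats import (
    MatchMatrix,
    encounter_curve,
    enrichment_ratios,
    fit_power_law,
    overlap_test,
    resample_subsets,
    success_rate_by,
)


def planted_matrix(rows, order=None):
    fast = np.array(rows, dtype=np.int8)
    return MatchMatrix(
        sites=[f"s{i}" for i in range(fast.shape[0])],
        scaffolds=[f"f{j}" for j in range(fast.shape[1])],
        fast=fast,
        order=order or list(range(fast.shape[1])),
    )


class TestEnrichment:
    def test_equal_frequencies_give_unity(self):
        f = {"A": 0.5, "W": 0.5}
        assert enrichment_ratios(f, f) == {"A": 1.0, "W": 1.0}

    def test_division(self):
        assert enrichment_ratios({"W": 0.10}, {"W": 0.02})["W"] == pytest.approx(5.0)

    def test_inverse_scaling_with_background(self):
        site = {"W": 0.10}
        r1 = enrichment_ratios(site, {"W": 0.04})["W"]
        r2 = enrichment_ratios(site, {"W": 0.02})["W"]
        assert r2 == pytest.approx(2 * r1)

    def test_zero_background_names_offender(self):
        with pytest.raises(ParameterError) as err:
            enrichment_ratios({"W": 0.1}, {"W": 0.0})
        assert "W" in str(err.value)


class TestSuccessRates:
    def test_hand_computed_fractions(self):
        matrix = planted_matrix([[1, 0], [0, 0], [1, 1], [0, 1]])
        sizes = {"s0": 2, "s1": 2, "s2": 3, "s3": 3}
        rates = success_rate_by(matrix, sizes.__getitem__)
        assert rates[2].count == 2 and rates[2].rate == pytest.approx(0.5)
        assert rates[3].count == 2 and rates[3].rate == pytest.approx(1.0)
        assert list(rates) == [2, 3]  # ascending keys, no empty keys


class TestOverlap:
    def test_identical_vectors_closed_form(self):
        n = 40
        v = np.array([True] * 20 + [False] * 20)
        result = overlap_test(v, v)
        assert result.expected == pytest.approx(n / 4)
        assert result.observed == n // 2
        assert result.chi2 == pytest.approx(n)

    def test_degenerate_margin(self):
        a = np.ones(10, dtype=bool)
        b = np.array([True] * 4 + [False] * 6)
        result = overlap_test(a, b)
        assert result.observed == 4
        assert result.expected == pytest.approx(4.0)

    def test_agrees_with_scipy_contingency(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.random(200) < 0.4
            b = rng.random(200) < 0.3
            if not (a.any() and b.any() and (~a).any() and (~b).any()):
                continue
            mine = overlap_test(a, b)
            table = [[(a & b).sum(), (a & ~b).sum()],
                     [(~a & b).sum(), (~a & ~b).sum()]]
            ref = sps.chi2_contingency(table, correction=False)
            assert mine.chi2 == pytest.approx(ref.statistic, rel=1e-9)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_simulation_consistent(self):
        rng = np.random.default_rng(5)
        n = 10_000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.3
        result = overlap_test(a, b)
        sigma = np.sqrt(n * 0.3 * 0.3 * (1 - 0.3 * 0.3))
        assert abs(result.observed - result.expected) < 3 * sigma
        assert result.p > 1e-4  # no spurious dependence under the null

    def test_product_rule_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            a = rng.random(n) < rng.random()
            b = rng.random(n) < rng.random()
            result = overlap_test(a, b)
            assert result.expected == pytest.approx(a.sum() * b.sum() / n)


class TestEncounterCurve:
    def test_planted_encounters(self):
        matrix = planted_matrix([[1, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 0]])
        assert matrix.encounter == [1, 1, 3, None]
        assert encounter_curve(matrix, 2) == 2
        assert encounter_curve(matrix, 3) == 3  # endpoint = total matched

    def test_monotone_nondecreasing(self):
        matrix = make_match_matrix(30, 12, 0.2, seed=3)
        curve = [encounter_curve(matrix, n) for n in range(1, 13)]
        assert all(b >= a for a, b in zip(curve, curve[1:]))
        assert curve[-1] == int(matrix.matched_any().sum())

    def test_out_of_range_rejected(self):
        matrix = planted_matrix([[1, 0]])
        with pytest.raises(ParameterError):
            encounter_curve(matrix, 0)
        with pytest.raises(ParameterError):
            encounter_curve(matrix, 3)


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        n = np.arange(1, 21)
        fit = fit_power_law(list(zip(n, 100.0 * n**0.25)))
        assert fit.exponent == pytest.approx(0.25, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.extrapolate(10_000) == pytest.approx(100.0 * 10_000**0.25,
                                                        rel=1e-9)

    def test_constant_counts_give_zero_exponent(self):
        fit = fit_power_law([(n, 7.0) for n in range(1, 10)])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(17)
        n = np.arange(1, 51)
        slopes = []
        for _ in range(50):
            noise = rng.lognormal(mean=0.0, sigma=0.05, size=n.size)
            fit = fit_power_law(list(zip(n, 50.0 * n**0.3 * noise)))
            slopes.append(fit.exponent)
        assert abs(np.mean(slopes) - 0.3) < 0.01

    def test_scale_equivariance(self):
        pts = [(n, 5.0 * n**0.4) for n in range(1, 15)]
        base = fit_power_law(pts)
        scaled = fit_power_law([(n, 10.0 * c) for n, c in pts])
        assert scaled.exponent == pytest.approx(base.exponent, abs=1e-12)
        assert scaled.intercept == pytest.approx(base.intercept + 1.0,
                                                 abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ParameterError):
            fit_power_law([(1, 0.0), (2, 5.0)])


class TestResample:
    def test_full_subset_equals_total(self):
        matrix = make_match_matrix(25, 10, 0.3, seed=2)
        total = int(matrix.matched_any().sum())
        result = resample_subsets(matrix, 10, reps=20, seed=1)
        assert result.mean_matches == total
        assert set(result.counts) == {total}

    def test_deterministic_for_fixed_seed(self):
        matrix = make_match_matrix(25, 10, 0.3, seed=2)
        r1 = resample_subsets(matrix, 4, 50, seed=11)
        r2 = resample_subsets(matrix, 4, 50, seed=11)
        assert np.array_equal(r1.counts, r2.counts)

    def test_hypergeometric_expectation(self):
        # Each site matches exactly one distinct scaffold: a rep drawing k of
        # m scaffolds matches S*k/m sites in expectation.
        s = m = 30
        fast = np.eye(s, dtype=np.int8)
        matrix = MatchMatrix(sites=[f"s{i}" for i in range(s)],
                             scaffolds=[f"f{j}" for j in range(m)], fast=fast)
        k, reps = 10, 400
        result = resample_subsets(matrix, k, reps, seed=5)
        expected = s * k / m
        var_single = s * (k / m) * (1 - k / m) * (m - k) / (m - 1) / 1
        sigma_mean = np.sqrt(var_single / reps)
        assert abs(result.mean_matches - expected) < 3 * max(sigma_mean, 0.2)

    def test_untested_cells_rejected(self):
        matrix = planted_matrix([[1, -1], [0, 1]])
        with pytest.raises(ParameterError):
            resample_subsets(matrix, 1, 10, seed=0)


class TestMatrixInvariants:
    def test_confirmed_requires_fast(self):
        with pytest.raises(ParameterError):
            MatchMatrix(sites=["s0"], scaffolds=["f0", "f1"],
                        fast=np.array([[1, 0]]),
                        confirmed=np.array([[1, 1]]))

    def test_confirmed_subset_accepted(self):
        matrix = MatchMatrix(sites=["s0"], scaffolds=["f0", "f1"],
                             fast=np.array([[1, 1]]),
                             confirmed=np.array([[1, 0]]))
        assert int(matrix.matched_any(confirmed=True).sum()) == 1

    def test_encounter_respects_recorded_order(self):
        matrix = planted_matrix([[0, 1, 0]], order=[2, 1, 0])
        assert matrix.encounter == [2]
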
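"""Normalized-slope fits, the Monte-Carlo expected slope distribution, group trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from proteome_allocation import (
    NoiseSpec,
    SlopeFit,
    expected_slope_distribution,
    fit_normalized_slope,
    group_trend,
    normalize_to_mean,
    simulate_half_coordinated,
)
from proteome_allocation.slopes import fit_all_slopes


def brute_force_ols(x, y):
    """Oracle: slope and intercept from the normal equations, assembled by hand."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestFitNormalizedSlope:
    def test_exact_line_recovered(self):
        g = np.linspace(0.1, 0.7, 12)
        fit = fit_normalized_slope(1.0 * g + 0.5, g)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-12)

    def test_two_points_interpolate(self):
        fit = fit_normalized_slope([0.7, 1.3], [0.2, 0.6])
        assert fit.slope == pytest.approx(1.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.residual_se == 0.0
        assert fit.n_obs == 2

    def test_singular_design_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_normalized_slope([1.0, 2.0, 3.0], [0.4, 0.4, 0.4])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 100_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        x = rng.uniform(0.1, 0.7, n)
        if np.ptp(x) == 0:
            x[0] += 0.1
        y = rng.normal(1.0, 0.3, n)
        fit = fit_normalized_slope(y, x)
        slope, intercept = brute_force_ols(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        resid = y - (slope * x + intercept)
        assert fit.residual_se == pytest.approx(
            np.sqrt((resid**2).sum() / (n - 2)), abs=1e-10
        )

    def test_invalid_slopefit_rejected(self):
        with pytest.raises(ValueError):
            SlopeFit(1.0, 0.5, 1.0, 0.1, n_obs=1)
        with pytest.raises(ValueError):
            SlopeFit(1.0, 0.5, 1.0, -0.1, n_obs=5)


class TestExpectedSlopeDistribution:
    def test_zero_residuals_give_point_mass(self):
        fits = [SlopeFit(1.0, 0.5, 1.0, 0.0, 10) for _ in range(3)]
        g = np.linspace(0.1, 0.7, 10)
        sample = expected_slope_distribution(fits, 1.2, 0.4, g, reps=50, seed=0)
        assert np.allclose(sample, 1.2)

    def test_slope_sd_matches_closed_form(self):
        """sd of simulated slopes = residual_se / sqrt(sum (g - mean g)^2)."""
        g = np.linspace(0.12, 0.66, 20)
        se = 0.25
        fits = [SlopeFit(1.0, 0.5, 0.9, se, 20)]
        sample = expected_slope_distribution(fits, 1.0, 0.5, g, reps=20_000, seed=1)
        expected_sd = se / np.sqrt(((g - g.mean()) ** 2).sum())
        assert sample.std() == pytest.approx(expected_sd, rel=0.03)
        assert sample.mean() == pytest.approx(1.0, abs=3 * expected_sd / np.sqrt(20_000))

    def test_noise_scales_linearly(self):
        g = np.linspace(0.1, 0.7, 15)
        base = [SlopeFit(1.0, 0.5, 0.9, 0.2, 15) for _ in range(5)]
        doubled = [SlopeFit(1.0, 0.5, 0.9, 0.4, 15) for _ in range(5)]
        s1 = expected_slope_distribution(base, 1.0, 0.5, g, reps=4000, seed=2)
        s2 = expected_slope_distribution(doubled, 1.0, 0.5, g, reps=4000, seed=2)
        assert s2.std() == pytest.approx(2 * s1.std(), rel=0.05)

    def test_deterministic_under_seed(self):
        fits = [SlopeFit(1.0, 0.5, 0.9, 0.3, 10)]
        g = np.linspace(0.1, 0.7, 10)
        a = expected_slope_distribution(fits, 1.0, 0.5, g, reps=100, seed=7)
        b = expected_slope_distribution(fits, 1.0, 0.5, g, reps=100, seed=7)
        assert np.array_equal(a, b)


class TestGroupTrend:
    def test_single_protein_equals_own_fit(self, half_coordinated_noisy):
        norm = normalize_to_mean(half_coordinated_noisy)
        pid = norm.protein_ids[0]
        single = group_trend(norm, [pid])
        own = fit_normalized_slope(norm.fractions.loc[pid].values, norm.growth_rates.values)
        assert single.slope == pytest.approx(own.slope)
        assert single.intercept == pytest.approx(own.intercept)

    def test_empty_subset_rejected(self, half_coordinated_noisy):
        with pytest.raises(ValueError):
            group_trend(normalize_to_mean(half_coordinated_noisy), [])

    def test_noise_averages_out_with_group_size(self):
        """Group slope converges to the shared normalized slope as the group grows."""
        data = simulate_half_coordinated(
            n_proteins=800, coordinated_share=1.0, noise=NoiseSpec(cv=0.25, seed=5)
        )
        norm = normalize_to_mean(data)
        g = norm.growth_rates.values
        # the generating line, rescaled by its own mean (normalization contract)
        line = 1.0 * g + 0.5
        target = 1.0 / line.mean()
        err_small = abs(group_trend(norm, norm.protein_ids[:5]).slope - target)
        err_large = abs(group_trend(norm, norm.protein_ids).slope - target)
        assert err_large < err_small
        assert err_large < 0.05 * target


class TestCoordinationRecovery:
    def test_group_slope_and_ks_compatibility(self, half_coordinated_noisy):
        """The benchmark recovery: group slope near the generating normalized slope,
        and the observed per-protein slope histogram statistically compatible with
        the shared-slope Monte-Carlo expectation."""
        data = half_coordinated_noisy
        norm = normalize_to_mean(data)
        truth = data.protein_meta["true_class"]
        coord = list(truth.index[truth == "coordinated"])
        g = norm.growth_rates.values
        generating = 1.0 / (1.0 * g + 0.5).mean()  # slope 1, intercept 0.5 rescaled

        shared = group_trend(norm, coord)
        assert shared.slope == pytest.approx(generating, abs=0.1)

        fits = fit_all_slopes(norm, coord)
        expected = expected_slope_distribution(
            fits, shared.slope, shared.intercept, g, reps=20, seed=13
        )
        stat = ks_2samp(fits["slope"].values, expected)
        assert stat.pvalue > 0.01

    def test_mean_per_protein_slope_unbiased(self):
        """Mean fitted slope over many coordinated proteins ≈ generating slope."""
        data = simulate_half_coordinated(
            n_proteins=2000, coordinated_share=1.0, noise=NoiseSpec(cv=0.25, seed=29)
        )
        norm = normalize_to_mean(data)
        g = norm.growth_rates.values
        generating = 1.0 / (1.0 * g + 0.5).mean()
        fits = fit_all_slopes(norm)
        se = fits["slope"].std() / np.sqrt(len(fits))
        assert fits["slope"].mean() == pytest.approx(generating, abs=4 * se + 0.02)
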
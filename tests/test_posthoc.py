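"""Post-survey density estimation and bootstrap uncertainty."""

import numpy as np
import pytest
from scipy import stats

from lqastools import (
    BetaPrior,
    beta_fit_interval_prob,
    bootstrap_se,
    density_curves,
    generate_survey,
    histogram_interval_prob,
    kde_bandwidth,
    kde_interval_prob,
    observed_proportions,
    prior_interval_mass,
)


class TestObservedProportions:
    def test_jan2000_values(self, jan2000):
        assert np.array_equal(
            observed_proportions(jan2000), np.array([7, 9, 14, 13, 17, 19, 12]) / 19
        )

    def test_baseline_mean_coverage(self, jan1999):
        """June 1999 mean coverage is 70/133 = 52.6%."""
        assert round(100 * observed_proportions(jan1999).mean(), 1) == 52.6

    def test_zero_retained(self):
        from lqastools import SurveyTable

        table = SurveyTable.from_counts([0, 5], 19)
        assert observed_proportions(table)[0] == 0.0


class TestHistogram:
    def test_grey_region_fraction(self, jan2000):
        """Three of seven areas have point estimates inside (0.35, 0.65)."""
        assert histogram_interval_prob(jan2000, 0.35, 0.65) == 3 / 7

    def test_full_interval(self, jan2000):
        assert histogram_interval_prob(jan2000, 0.0, 1.0) == 1.0

    def test_closed_final_bin(self, jan2000):
        """The 19/19 area sits at exactly 1.0 and belongs to the last bin."""
        assert histogram_interval_prob(jan2000, 0.9, 1.0) == 1 / 7

    def test_partition_sums_to_one_exactly(self, jan2000):
        edges = [0.0, 0.35, 0.65, 1.0]
        total = sum(
            histogram_interval_prob(jan2000, lo, hi)
            for lo, hi in zip(edges[:-1], edges[1:])
        )
        assert total == 1.0  # counts/m are exact binary rationals here

    def test_bad_interval(self, jan2000):
        with pytest.raises(ValueError):
            histogram_interval_prob(jan2000, 0.65, 0.35)


class TestBandwidth:
    def test_jan2000_value(self, jan2000):
        """Hand computation: s = 0.2212, IQR = 0.2632, so the Silverman
        bandwidth 0.1198 shrinks to 0.0668 after the extra m^(-0.3)."""
        props = observed_proportions(jan2000)
        assert props.std(ddof=1) == pytest.approx(0.22122, abs=5e-6)
        assert np.subtract(*np.percentile(props, [75, 25])) == pytest.approx(
            0.26316, abs=5e-6
        )
        assert kde_bandwidth(props) == pytest.approx(0.066804, abs=5e-7)

    def test_extreme_points(self):
        assert 0 < kde_bandwidth([0.0, 1.0]) < np.inf

    def test_scale_equivariance(self, jan2000):
        """Shrinking the spread about the mean by c shrinks the bandwidth by c."""
        props = observed_proportions(jan2000)
        shrunk = props.mean() + 0.5 * (props - props.mean())
        assert kde_bandwidth(shrunk) == pytest.approx(
            0.5 * kde_bandwidth(props), rel=1e-12
        )

    def test_degenerate_spread(self):
        with pytest.raises(ValueError):
            kde_bandwidth([0.4, 0.4, 0.4])
        with pytest.raises(ValueError):
            kde_bandwidth([0.4])


class TestKernelEstimate:
    def test_grey_region_value(self, jan2000):
        """The kernel grey-region estimate is 36.9% under the narrow bandwidth."""
        assert kde_interval_prob(jan2000, 0.35, 0.65) == pytest.approx(
            0.3689, abs=5e-4
        )

    def test_total_mass(self, jan2000):
        assert kde_interval_prob(jan2000, -10.0, 11.0) == pytest.approx(1.0, abs=1e-12)

    def test_additive_over_adjacent_intervals(self, jan2000):
        whole = kde_interval_prob(jan2000, 0.2, 0.8)
        parts = kde_interval_prob(jan2000, 0.2, 0.5) + kde_interval_prob(
            jan2000, 0.5, 0.8
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_small_bandwidth_limit_is_histogram(self, jan2000):
        """As the kernels collapse to point masses the estimate matches the
        crude histogram (no observation sits on an interval edge here)."""
        collapsed = kde_interval_prob(jan2000, 0.35, 0.65, bandwidth=1e-9)
        assert collapsed == pytest.approx(
            histogram_interval_prob(jan2000, 0.35, 0.65), abs=1e-12
        )


class TestBetaEstimate:
    def test_full_interval(self, jan1999):
        assert beta_fit_interval_prob(jan1999, 0.0, 1.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_recovers_generating_mass(self):
        truth = BetaPrior(5, 5)
        survey = generate_survey(truth, m=500, n=100, seed=9)
        estimate = beta_fit_interval_prob(survey, 0.35, 0.65)
        assert estimate == pytest.approx(
            prior_interval_mass(truth, 0.35, 0.65), abs=0.03
        )

    def test_jan2000_count_moment_fit_grey_mass(self, jan2000):
        """The beta-binomial moment fit puts 34.2% of the coverage
        distribution in the grey region on the follow-up data."""
        value = beta_fit_interval_prob(jan2000, 0.35, 0.65)
        assert round(100 * value, 1) == 34.2

    def test_jan2000_proportions_mle_dominated_by_boundary(self, jan2000):
        """The clipped Beta likelihood is dragged toward 1 by the 19/19
        area, giving a J-shaped fit with less grey mass than the
        count-level fits (which absorb the boundary point as sampling
        noise)."""
        clipped = beta_fit_interval_prob(jan2000, 0.35, 0.65, method="proportions_mle")
        count_level = beta_fit_interval_prob(jan2000, 0.35, 0.65)
        assert 0.05 < clipped < count_level


class TestBootstrap:
    def test_deterministic_under_seed(self, jan2000):
        one = bootstrap_se(jan2000, "histogram", 0.35, 0.65, B=100, seed=7)
        two = bootstrap_se(jan2000, "histogram", 0.35, 0.65, B=100, seed=7)
        assert one == two

    def test_histogram_se_matches_binomial_closed_form(self, jan2000):
        """The bootstrap sd of a sample fraction converges on
        sqrt(p(1-p)/m); tolerance is three Monte-Carlo sds."""
        summary = bootstrap_se(jan2000, "histogram", 0.35, 0.65, B=5000, seed=11)
        p_hat = 3 / 7
        closed_form = np.sqrt(p_hat * (1 - p_hat) / 7)
        mc_sd = closed_form / np.sqrt(2 * (5000 - 1))
        assert summary.estimate == p_hat
        assert summary.se == pytest.approx(closed_form, abs=3 * mc_sd + 0.004)

    def test_kernel_se_near_paper_scale(self, jan2000):
        summary = bootstrap_se(jan2000, "kernel", 0.35, 0.65, B=2000, seed=5)
        assert summary.se == pytest.approx(0.140, abs=0.015)
        assert summary.n_failed < 50  # degenerate resamples are rare

    def test_beta_refits_and_counts_failures(self, jan2000):
        summary = bootstrap_se(jan2000, "beta", 0.35, 0.65, B=50, seed=3)
        assert summary.replicates == 50
        assert 0 <= summary.n_failed < 50
        assert summary.se >= 0

    def test_parameter_validation(self, jan2000):
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_se(jan2000, "histogram", 0.35, 0.65, B=1, seed=1)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_se(jan2000, "histogram", 0.35, 0.65, B=10)
        with pytest.raises(ValueError, match="unknown estimator"):
            bootstrap_se(jan2000, "spline", 0.35, 0.65, B=10, seed=1)


class TestDensityCurves:
    def test_curves_are_proper_densities(self, jan2000):
        frame = density_curves(jan2000, grid_size=2001)
        assert set(frame["method"]) == {"histogram", "kernel", "beta"}
        hist = frame[frame.method == "histogram"]
        assert np.trapezoid(hist["density"], hist["p"]) == pytest.approx(1.0, abs=0.02)
        # the kernel spills mass outside [0, 1] by design; account for it
        kern = frame[frame.method == "kernel"]
        inside = np.trapezoid(kern["density"], kern["p"])
        assert inside == pytest.approx(
            kde_interval_prob(jan2000, 0.0, 1.0), abs=1e-3
        )

    def test_beta_curve_matches_closed_form(self, jan1999):
        from lqastools import fit_beta

        frame = density_curves(jan1999, grid_size=101)
        beta_part = frame[frame.method == "beta"]
        prior = fit_beta(jan1999)
        assert np.allclose(
            beta_part["density"], stats.beta.pdf(beta_part["p"], prior.a, prior.b)
        )

    def test_bad_grid(self, jan2000):
        with pytest.raises(ValueError):
            density_curves(jan2000, grid_size=1)
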
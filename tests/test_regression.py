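import numpy as np
import pytest

from colonykit.branching import ColonySizeDistribution
from colonykit.errors import (
    DomainError,
    IncomparableFitsError,
    InsufficientDataError,
)
from colonykit.regression import (
    RegressionFit,
    aic_compare,
    confidence_band,
    fit_size_distribution,
)


def make_dist(freqs, f1_estimated=False, dose="0"):
    return ColonySizeDistribution(
        dose, {n: f for n, f in enumerate(freqs, start=1)},
        f1_estimated=f1_estimated)


def power_law_dist(a=-1.28, b=1.02, n_max=15):
    n = np.arange(1, n_max + 1)
    return make_dist(10.0 ** (b + a * np.log10(n)))


class TestFit:
    def test_exact_power_law_recovery(self):
        fit = fit_size_distribution(power_law_dist(), "log_log")
        assert fit.a == pytest.approx(-1.28, abs=1e-12)
        assert fit.b == pytest.approx(1.02, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_exponential_recovery(self):
        n = np.arange(1, 16)
        dist = make_dist(10.0 ** (0.70 - 0.089 * n))
        fit = fit_size_distribution(dist, "log_linear")
        assert fit.a == pytest.approx(-0.089, abs=1e-12)
        assert fit.b == pytest.approx(0.70, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_data_r2_zero_convention(self):
        fit = fit_size_distribution(make_dist([5.0] * 8), "log_linear")
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(np.log10(5.0))
        assert fit.r2 == 0.0

    def test_r2_invariant_under_rescaling(self):
        n = np.arange(1, 13)
        freqs = 10.0 ** (1.0 - 1.3 * np.log10(n)) * (1 + 0.05 * np.sin(n))
        f1 = fit_size_distribution(make_dist(freqs), "log_log")
        f2 = fit_size_distribution(make_dist(freqs * 3.7), "log_log")
        assert f2.a == pytest.approx(f1.a)
        assert f2.r2 == pytest.approx(f1.r2)
        assert f2.b - f1.b == pytest.approx(np.log10(3.7))

    def test_aic_decreases_with_residual_sum(self):
        n = np.arange(1, 13)
        clean = 10.0 ** (1.0 - 0.1 * n)
        noisy = clean * 10.0 ** (0.05 * np.sin(n))
        aic_clean = fit_size_distribution(make_dist(clean), "log_linear").aic
        aic_noisy = fit_size_distribution(make_dist(noisy), "log_linear").aic
        assert aic_clean < aic_noisy

    def test_estimated_f1_in_fit_but_not_in_aic(self):
        dist = power_law_dist()
        dist.f1_estimated = True
        fit = fit_size_distribution(dist, "log_log", include_f1=True)
        assert fit.n_points == 15
        assert 1 not in fit.aic_sizes and len(fit.aic_sizes) == 14

    def test_exclude_f1_drops_the_point(self):
        fit = fit_size_distribution(power_law_dist(), "log_log",
                                    include_f1=False)
        assert fit.n_points == 14 and 1 not in fit.sizes

    def test_errors(self):
        with pytest.raises(DomainError):
            fit_size_distribution(make_dist([1.0, 0.0, 2.0]), "log_log")
        with pytest.raises(InsufficientDataError):
            fit_size_distribution(make_dist([1.0, 2.0]), "log_log")
        with pytest.raises(DomainError):
            fit_size_distribution(power_law_dist(), "loglog")


class TestConfidenceBand:
    def test_zero_width_for_perfect_fit(self):
        fit = fit_size_distribution(power_law_dist(), "log_log")
        lo, hi = confidence_band(fit, [1, 5, 15])
        assert hi - lo == pytest.approx(np.zeros(3), abs=1e-8)

    def test_narrowest_at_design_centroid_and_monotone_in_level(self, rng):
        n = np.arange(1, 16)
        freqs = 10.0 ** (1.0 - 1.2 * np.log10(n) + rng.normal(0, 0.05, 15))
        fit = fit_size_distribution(make_dist(freqs), "log_log")
        centroid = 10.0 ** np.mean(np.log10(n))  # centroid on the log axis
        grid = np.array([1.0, centroid, 15.0])
        lo, hi = confidence_band(fit, grid)
        width = np.log10(hi) - np.log10(lo)
        assert width[1] < width[0] and width[1] < width[2]
        lo99, hi99 = confidence_band(fit, grid, level=0.99)
        assert np.all(np.log10(hi99) - np.log10(lo99) > width)

    def test_band_undefined_without_data(self):
        fit = RegressionFit.from_params("log_log", -1.0, 1.0)
        with pytest.raises(InsufficientDataError):
            confidence_band(fit, 3)


class TestAicCompare:
    @staticmethod
    def fake(family, aic, sizes=(2, 3, 4)):
        return RegressionFit(family=family, a=-1, b=1, r2=0.9, aic=aic,
                             n_points=len(sizes), aic_sizes=tuple(sizes))

    def test_selects_minimum(self):
        # AIC pairs seen in practice for high-dose distributions favor the
        # power-law family...
        sel = aic_compare([self.fake("log_linear", -21.108),
                           self.fake("log_log", -44.430)])
        assert sel.selected.family == "log_log" and not sel.tie
        # ...while shallow unirradiated distributions can favor exponential
        sel = aic_compare([self.fake("log_linear", -18.410),
                           self.fake("log_log", -16.509)])
        assert sel.selected.family == "log_linear"

    def test_tie_flagged_first_family_wins(self):
        sel = aic_compare([self.fake("log_linear", -5.0),
                           self.fake("log_log", -5.0)],
                          order=("log_linear", "log_log"))
        assert sel.tie and sel.selected.family == "log_linear"

    def test_incomparable_point_sets_rejected(self):
        with pytest.raises(IncomparableFitsError):
            aic_compare([self.fake("log_linear", -5.0, sizes=(2, 3, 4)),
                         self.fake("log_log", -6.0, sizes=(2, 3, 5))])
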
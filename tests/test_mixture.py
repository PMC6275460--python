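import numpy as np
import pytest

from covroi import CoverageTrack
from covroi.detrend import DetrendConfig, normalize, running_median
from covroi.mixture import (
    DegenerateDataError,
    InsufficientDataError,
    MixtureFit,
    ThresholdSpec,
    adaptive_thresholds,
    centralness,
    expected_chance_outliers,
    fit_em,
    tolerance_interval,
    zscores,
)


def draw_mixture(rng, n, pi0, mu0, s0, mu1, s1):
    k = rng.random(n) < pi0
    x = np.where(k, rng.normal(mu0, s0, n), rng.normal(mu1, s1, n))
    return np.abs(x)  # coverage ratios are non-negative


class TestToleranceInterval:
    def test_printed_values(self):
        """Central normal mass for n = 3, 4, 5 matches the erfc-based values."""
        # printed values are truncated at the shown precision
        assert abs(tolerance_interval(3) * 100 - 99.73) < 0.01
        assert abs(tolerance_interval(4) * 100 - 99.993) < 0.001
        assert tolerance_interval(5) == pytest.approx(0.99999942, abs=1.5e-8)

    def test_agrees_with_monte_carlo_mass(self, rng):
        draws = rng.standard_normal(1_000_000)
        for n in (1, 2, 3):
            p = tolerance_interval(n)
            emp = np.mean(np.abs(draws) < n)
            se = np.sqrt(p * (1 - p) / draws.size)
            assert abs(emp - p) < 3 * se + 1e-9

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            tolerance_interval(0)


class TestChanceOutliers:
    def test_megabase_counts(self):
        assert expected_chance_outliers(10**6, 3) == pytest.approx(2700, abs=1)
        # the coarse printed "about 70" corresponds to an exact 63.3
        assert expected_chance_outliers(10**6, 4) == pytest.approx(63.3, abs=0.1)
        assert expected_chance_outliers(0, 3) == 0


class TestFitEM:
    def test_recovers_generating_parameters(self, rng):
        x = draw_mixture(rng, 100_000, 0.95, 1.0, 0.05, 2.0, 0.1)
        fit = fit_em(x)
        assert fit.mu0 == pytest.approx(1.0, abs=0.01)
        assert fit.sigma0 == pytest.approx(0.05, rel=0.10)
        assert fit.pi0 == pytest.approx(0.95, abs=0.02)
        assert fit.mu1 == pytest.approx(2.0, abs=0.1)
        assert not fit.single_population

    def test_single_population_limit(self, rng):
        x = rng.normal(1.0, 0.05, 100_000)
        fit = fit_em(x)
        assert fit.mu0 == pytest.approx(1.0, abs=0.01)
        assert fit.sigma0 == pytest.approx(0.05, rel=0.1)

    def test_loglik_never_decreases(self, rng):
        x = draw_mixture(rng, 20_000, 0.9, 1.0, 0.1, 1.8, 0.2)
        fit = fit_em(x)
        assert np.all(np.diff(fit.loglik_path) >= -1e-9)

    def test_pi_sums_to_one_and_sigma_floored(self, rng):
        x = draw_mixture(rng, 10_000, 0.95, 1.0, 0.05, 2.0, 0.1)
        fit = fit_em(x)
        assert fit.pi0 + fit.pi1 == pytest.approx(1.0, abs=1e-9)
        assert fit.sigma0 >= 1e-6 and fit.sigma1 >= 1e-6

    def test_masked_and_zero_values_are_ignored(self, rng):
        x = draw_mixture(rng, 50_000, 0.95, 1.0, 0.05, 2.0, 0.1)
        with_zeros = np.concatenate([x, np.zeros(5_000)])
        fit_a = fit_em(x)
        fit_b = fit_em(with_zeros)
        assert fit_b.mu0 == pytest.approx(fit_a.mu0, abs=1e-6)
        mask = np.zeros(with_zeros.size, bool)
        mask[: x.size] = True  # mask out the real values, keep zeros -> too few
        with pytest.raises(InsufficientDataError):
            fit_em(with_zeros, mask)

    def test_insufficient_and_degenerate_data(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_em(np.full(50, 1.0))
        with pytest.raises(DegenerateDataError):
            fit_em(np.full(500, 1.0))

    def test_agrees_with_reference_em(self, rng):
        """Well-separated mixture: our EM matches scikit-learn's."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = draw_mixture(rng, 50_000, 0.93, 1.0, 0.06, 2.2, 0.15)
        fit = fit_em(x)
        gm = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(x.reshape(-1, 1))
        i = int(np.argmax(gm.weights_))
        assert fit.mu0 == pytest.approx(float(gm.means_[i, 0]), abs=0.005)
        assert fit.sigma0 == pytest.approx(
            float(np.sqrt(gm.covariances_[i].ravel()[0])), rel=0.05)
        assert fit.pi0 == pytest.approx(float(gm.weights_[i]), abs=0.01)

    def test_stability_in_window_choice(self, rng):
        """mu0/sigma0 of a trend-free 1 Mb Poisson track barely depend on W."""
        track = CoverageTrack("c", rng.poisson(100, 1_000_000), circular=True)
        fits = []
        for W in (5_001, 20_001, 100_001):
            det = normalize(track, running_median(track, DetrendConfig(W, circular=True)))
            fits.append(fit_em(det.normalized, det.undefined_mask))
        mu = [f.mu0 for f in fits]
        sd = [f.sigma0 for f in fits]
        assert max(mu) / min(mu) - 1 < 0.005
        assert max(sd) / min(sd) - 1 < 0.10


class TestZScores:
    def fit(self, mu0=1.0, s0=0.1):
        return MixtureFit(mu0=mu0, sigma0=s0, pi0=0.97, mu1=0.3, sigma1=0.2,
                          pi1=0.03, n_iter=5, loglik=0.0, converged=True)

    def test_direct_substitution(self):
        track = CoverageTrack("c", np.array([120, 100]))
        det = normalize(track, np.array([100.0, 100.0]))
        z = zscores(det, self.fit())
        assert z[0] == pytest.approx(2.0)
        assert z[1] == pytest.approx(0.0)

    def test_masked_bases_get_low_side_sentinel(self):
        track = CoverageTrack("c", np.array([0, 100]))
        det = normalize(track, np.array([0.0, 100.0]))
        z = zscores(det, self.fit())
        assert z[0] == -np.inf

    def test_reconstruction_identity(self, rng, poisson_track):
        """Coverage is exactly (mu0 + z sigma0) * RM on unmasked bases."""
        cfg = DetrendConfig(W=2001)
        det = normalize(poisson_track, running_median(poisson_track, cfg))
        fit = fit_em(det.normalized, det.undefined_mask)
        z = zscores(det, fit)
        keep = ~det.undefined_mask
        recon = (fit.mu0 + z[keep] * fit.sigma0) * det.rm[keep]
        np.testing.assert_allclose(recon, poisson_track.coverage[keep], rtol=1e-9)


class TestAdaptiveThresholds:
    def test_direct_substitution(self):
        fit = TestZScores().fit()
        lower, upper = adaptive_thresholds(
            np.array([500.0]), fit, ThresholdSpec(n_high=4, n_low=-4))
        assert upper[0] == pytest.approx(700.0)
        assert lower[0] == pytest.approx(300.0)

    def test_linear_in_rm_and_degenerate_sigma(self):
        fit = TestZScores().fit()
        lower, upper = adaptive_thresholds(np.array([400.0, 500.0]), fit, ThresholdSpec())
        np.testing.assert_allclose(upper, [560.0, 700.0])
        tight = TestZScores().fit(s0=1e-6)
        lo, up = adaptive_thresholds(np.array([500.0]), tight, ThresholdSpec())
        assert lo[0] == pytest.approx(500.0, abs=0.01)
        assert up[0] == pytest.approx(500.0, abs=0.01)

    def test_lower_threshold_clipped_at_zero(self):
        fit = TestZScores().fit(s0=0.5)
        lower, _ = adaptive_thresholds(np.array([100.0]), fit, ThresholdSpec())
        assert lower[0] == 0.0


class TestCentralness:
    def test_no_outliers_gives_unity(self):
        assert centralness(np.zeros(100), 4) == 1.0

    def test_direct_count(self):
        z = np.zeros(1000)
        z[:25] = 5.0
        assert centralness(z, 4) == pytest.approx(0.975)

    def test_warns_below_half(self):
        z = np.full(100, 9.0)
        with pytest.warns(UserWarning, match="below 0.5"):
            assert centralness(z, 4) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            centralness(np.array([]), 4)


class TestThresholdSpec:
    def test_double_thresholds_derived(self):
        spec = ThresholdSpec(n_high=4, n_low=-4, alpha=0.5)
        assert spec.m_high == 2.0 and spec.m_low == -2.0

    @pytest.mark.parametrize("kw", [
        {"n_high": -1}, {"n_low": 1}, {"alpha": 0.0}, {"alpha": 1.5},
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            ThresholdSpec(**kw)
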
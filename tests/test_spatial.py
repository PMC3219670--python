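"""Spatially regularized EM: neighbourhood average, noise-adaptive beta,
blended E/M steps, and the reduction to the plain mixture at beta = 0."""

import numpy as np
import pytest

from emseg import (MixtureParams, NoiseSpec, SpatialConfig, add_rician_noise,
                   e_step, estimate_noise_variance, extract_background,
                   fit_em1, fit_gmm, generate_phantom, log_likelihood,
                   m_step, neighborhood_average, resolve_beta, spatial_e_step,
                   spatial_log_likelihood, spatial_m_step)

from conftest import (naive_e_step, naive_log_likelihood, naive_m_step,
                      random_mixture)


def _sliding_mean(data, window, include_center, pad_mode):
    """Oracle: neighbourhood mean by explicit padding and window loops."""
    k = window // 2
    if pad_mode == "reflect":
        padded = np.pad(data, k, mode="symmetric")
    else:
        padded = np.pad(data, k, mode="constant")
    out = np.zeros_like(data, dtype=float)
    for idx in np.ndindex(data.shape):
        sl = tuple(slice(i, i + window) for i in idx)
        block = padded[sl]
        total = block.sum()
        n = block.size
        if not include_center:
            total -= data[idx]
            n -= 1
        out[idx] = total / n
    return out


class TestNeighborhoodAverage:
    def test_constant_image_is_fixed_point(self):
        img = np.full((10, 10), 3.7)
        for w in (3, 5):
            out = neighborhood_average(img, SpatialConfig(window=w))
            np.testing.assert_allclose(out, img, atol=1e-12)

    def test_center_exclusion_on_impulse(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        excl = neighborhood_average(img, SpatialConfig(window=3))
        incl = neighborhood_average(img, SpatialConfig(window=3,
                                                       include_center=True))
        assert excl[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert incl[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_reflect_padding_on_tiny_image(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = neighborhood_average(img, SpatialConfig(window=3))
        # corner (0,0): symmetric padding -> window values {1,1,2,1,1,2,3,3,4}
        assert out[0, 0] == pytest.approx((1 + 1 + 2 + 1 + 2 + 3 + 3 + 4) / 8)
        np.testing.assert_allclose(out, _sliding_mean(img, 3, False, "reflect"),
                                   atol=1e-12)

    @pytest.mark.parametrize("padding", ["reflect", "constant_zero"])
    @pytest.mark.parametrize("include_center", [False, True])
    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_sliding_window_oracle(self, rng, padding, include_center,
                                           window):
        img = rng.uniform(0, 1, size=(9, 11))
        cfg = SpatialConfig(window=window, include_center=include_center,
                            padding=padding)
        pad = "reflect" if padding == "reflect" else "constant"
        np.testing.assert_allclose(
            neighborhood_average(img, cfg),
            _sliding_mean(img, window, include_center, pad), atol=1e-12)

    def test_three_d_default_is_slicewise(self, rng):
        vol = rng.uniform(0, 1, size=(4, 8, 8))
        out = neighborhood_average(vol, SpatialConfig(window=3))
        for z in range(4):
            np.testing.assert_allclose(
                out[z], neighborhood_average(vol[z], SpatialConfig(window=3)),
                atol=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_average(np.zeros((2, 2)), SpatialConfig(window=5))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            SpatialConfig(window=4)


class TestBackgroundAndNoise:
    def test_explicit_mask_passthrough_order(self, rng):
        img = rng.uniform(0, 1, size=(5, 5))
        mask = np.zeros((5, 5), bool)
        mask[0, 3] = mask[2, 1] = mask[4, 4] = True
        vals = extract_background(img, mask=mask)
        np.testing.assert_array_equal(vals, img[mask])

    def test_threshold_separates_black_pixels(self):
        img = np.array([0.0] * 10 + [0.8] * 10).reshape(4, 5)
        vals = extract_background(img)
        assert vals.size == 10 and np.all(vals == 0.0)

    def test_threshold_recovers_background_count(self):
        """With the threshold between noise ceiling and tissue floor the
        selected pixel count equals the true background size."""
        ph = generate_phantom((40, 40), 2, class_means=(0.0, 1.0),
                              class_stddevs=(0.0, 0.0), seed=0)
        noisy = add_rician_noise(ph.image, NoiseSpec(2.0, seed=0))
        vals = extract_background(noisy, threshold=0.2)
        assert vals.size == int((ph.truth == 0).sum())

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            extract_background(np.array([[-1.0, 0.0]]))

    def test_constant_observations(self):
        est = estimate_noise_variance([0.4] * 20)
        assert est.sigma2 == pytest.approx(0.4 ** 2 / 2, abs=1e-15)
        assert est.n_background == 20

    def test_two_observations_closed_form(self):
        assert estimate_noise_variance([1.0, 2.0]).sigma2 == pytest.approx(1.25)

    def test_rayleigh_mle_consistency(self):
        sigma = 0.3
        rng = np.random.default_rng(0)
        samples = sigma * np.sqrt(rng.standard_normal(100_000) ** 2
                                  + rng.standard_normal(100_000) ** 2)
        est = estimate_noise_variance(samples)
        assert abs(est.sigma2 - sigma ** 2) / sigma ** 2 < 0.02

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_variance([])


class TestResolveBeta:
    def test_explicit_beta_passthrough(self, rng):
        img = rng.uniform(0, 1, size=(8, 8))
        assert resolve_beta(img, SpatialConfig(beta=0.25)) == 0.25

    def test_noise_free_background_gives_zero(self):
        ph = generate_phantom((32, 32), 2, class_means=(0.0, 1.0),
                              class_stddevs=(0.0, 0.0), seed=0)
        assert resolve_beta(ph.image, SpatialConfig()) == 0.0

    def test_consistent_with_noise_estimator(self):
        ph = generate_phantom((64, 64), 4, seed=3)
        noisy = ph.noisy(9.0, seed=3)
        noisy = noisy / noisy.max()
        mask = ph.truth == 0
        est = estimate_noise_variance(noisy[mask])
        beta = resolve_beta(noisy, SpatialConfig(beta_mode="variance"), mask=mask)
        assert beta == pytest.approx(est.sigma2, rel=1e-12)
        beta_std = resolve_beta(noisy, SpatialConfig(beta_mode="std"), mask=mask)
        assert beta_std == pytest.approx(np.sqrt(est.sigma2), rel=1e-12)

    def test_fallback_on_empty_background(self):
        img = np.full((8, 8), 1.0)  # nothing at or below 5% of max
        assert resolve_beta(img, SpatialConfig()) == pytest.approx(0.1)

    def test_clamped_to_beta_max(self):
        img = np.zeros((8, 8))
        img[0, 0] = 1.0
        img[img == 0] = 0.04  # background at 4% of max, sigma2 small
        beta = resolve_beta(img, SpatialConfig(beta_max=1e-4))
        assert beta == pytest.approx(1e-4)


class TestSpatialOperations:
    def test_beta_zero_is_bitwise_reduction(self, rng):
        xs = rng.uniform(0, 1, size=8)
        xb = rng.uniform(0, 1, size=8)
        w, m, v = random_mixture(rng, 3)
        p = MixtureParams.from_scalars(w, m, v)
        assert spatial_log_likelihood(xs, xb, p, 0.0) == log_likelihood(xs, p)
        assert np.array_equal(spatial_e_step(xs, xb, p, 0.0), e_step(xs, p))
        resp = rng.dirichlet(np.ones(3), size=8)
        p0 = spatial_m_step(xs, xb, resp, 0.0)
        p1 = m_step(xs, resp)
        assert np.array_equal(p0.means, p1.means)
        assert np.array_equal(p0.covariances, p1.covariances)
        assert np.array_equal(p0.weights, p1.weights)

    def test_constant_image_degeneracy(self, rng):
        """xbar = x implies the blended densities coincide for any beta."""
        xs = np.full(6, 0.4)
        w, m, v = random_mixture(rng, 2)
        p = MixtureParams.from_scalars(w, m, v)
        for beta in (0.0, 0.3, 0.9):
            assert spatial_log_likelihood(xs, xs, p, beta) == pytest.approx(
                log_likelihood(xs, p), abs=1e-12)
            np.testing.assert_allclose(spatial_e_step(xs, xs, p, beta),
                                       e_step(xs, p), atol=1e-12)

    def test_log_likelihood_matches_naive_oracle(self, rng):
        xs = rng.uniform(0, 1, size=4)
        xb = rng.uniform(0, 1, size=4)
        w, m, v = random_mixture(rng, 2)
        p = MixtureParams.from_scalars(w, m, v)
        assert spatial_log_likelihood(xs, xb, p, 0.3) == pytest.approx(
            naive_log_likelihood(xs, w, m, v, xb, 0.3), abs=1e-12)

    def test_e_step_matches_naive_oracle(self, rng):
        xs = rng.uniform(0, 1, size=5)
        xb = rng.uniform(0, 1, size=5)
        w, m, v = random_mixture(rng, 2)
        p = MixtureParams.from_scalars(w, m, v)
        r = spatial_e_step(xs, xb, p, 0.4)
        np.testing.assert_allclose(r, naive_e_step(xs, w, m, v, xb, 0.4),
                                   atol=1e-12)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)

    def test_m_step_matches_naive_oracle(self, rng):
        xs = rng.uniform(0, 1, size=6)
        xb = rng.uniform(0, 1, size=6)
        resp = rng.dirichlet(np.ones(2), size=6)
        p = spatial_m_step(xs, xb, resp, 0.5)
        w, m, v = naive_m_step(xs, resp, xb, 0.5)
        np.testing.assert_allclose(p.weights, w, atol=1e-12)
        np.testing.assert_allclose(p.means.ravel(), m, atol=1e-12)
        np.testing.assert_allclose(p.covariances.ravel(), v, atol=1e-12)

    def test_covariance_normalization_flag(self, rng):
        xs = rng.uniform(0, 1, size=6)
        xb = rng.uniform(0, 1, size=6)
        resp = rng.dirichlet(np.ones(2), size=6)
        raw = spatial_m_step(xs, xb, resp, 0.5)
        norm = spatial_m_step(xs, xb, resp, 0.5, normalize_covariance=True)
        np.testing.assert_allclose(norm.covariances, raw.covariances / 1.5,
                                   atol=1e-12)

    def test_invalid_beta_rejected(self, rng):
        p = MixtureParams.from_scalars([1.0], [0.0], [1.0])
        with pytest.raises(ValueError):
            spatial_e_step(np.zeros(3), np.zeros(3), p, 1.5)


class TestFitEm1:
    def test_beta_zero_reduces_to_fit_gmm(self, brain_phantom):
        img = brain_phantom.noisy(7.0, seed=0)
        a = fit_gmm(img, 4, seed=5)
        b = fit_em1(img, 4, config=SpatialConfig(beta=0.0), seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.log_likelihood_trace == b.log_likelihood_trace

    def test_noise_free_phantom_segments_perfectly(self, clean_binary_phantom):
        from emseg import evaluate

        ph = clean_binary_phantom
        res = fit_em1(ph.image, 2, seed=0)
        report = evaluate(res.labels, ph.truth, exclude_background=False,
                          image=ph.image)
        assert report.averages["rho"] == 1.0

    def test_parameter_recovery_with_spatial_term(self):
        ph = generate_phantom((64, 64), 2, class_means=(0.3, 0.7),
                              class_stddevs=(0.05, 0.05), seed=2)
        res = fit_em1(ph.image, 2, seed=2)
        np.testing.assert_allclose(np.sort(res.params.means.ravel()),
                                   [0.3, 0.7], atol=0.02)

    def test_auto_beta_recorded_in_result(self, brain_phantom):
        img = brain_phantom.noisy(9.0, seed=1)
        res = fit_em1(img, 4, seed=1, background_mask=brain_phantom.truth == 0)
        assert 0.0 < res.beta <= 0.5

    def test_improves_on_plain_em_under_heavy_noise(self, brain_phantom):
        from emseg import evaluate

        img = brain_phantom.noisy(9.0, seed=3)
        mask = brain_phantom.truth == 0
        r0 = fit_gmm(img, 4, seed=3)
        r1 = fit_em1(img, 4, seed=3, background_mask=mask)
        rho0 = evaluate(r0.labels, brain_phantom.truth, image=img).averages["rho"]
        rho1 = evaluate(r1.labels, brain_phantom.truth, image=img).averages["rho"]
        assert rho1 > rho0 - 0.01  # never substantially worse on one seed
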
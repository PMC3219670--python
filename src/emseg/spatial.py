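"""Spatially regularized EM segmentation (the EM-1 algorithm).

A neighbourhood-average image xbar is computed once, before any EM
iteration, and its component density is blended into the likelihood and
into every EM update with weight beta:

    log L(theta | X) = sum_i log sum_j alpha_j [(1-beta) p_j(x_i) + beta p_j(xbar_i)]

The E-step normalizes alpha_j * [(1-beta) p_j(x_i) + beta p_j(xbar_i)] over
components; the mean update averages (1-beta) x_i + beta xbar_i; the
covariance update adds beta times the squared deviation of xbar_i on top
of the pixel term (deliberately not a convex combination; an optional
flag divides by (1+beta) for a variance-consistent variant).

beta is tied to the image noise: magnitude-MRI background contains no
signal, so its Rician noise reduces to a Rayleigh law whose scale is
estimated by maximum likelihood from background pixels,
sigma_hat^2 = (1/2n) sum O_i^2.  By default beta is set to sigma_hat — the
noise level on the [0,1]-normalized intensity scale — clamped to [0, 0.5]
so the pixel's own evidence always dominates; smoothing therefore grows
with noise and vanishes on clean images.  (``beta_mode="variance"`` uses
sigma_hat^2 instead; on unit-normalized intensities that weight is so
small that the spatial term is effectively inert.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import uniform_filter

from . import gmm
from .gmm import FitResult, MixtureParams
from .io import ImageVolume, normalize_intensity

logger = logging.getLogger(__name__)


@dataclass
class SpatialConfig:
    """Knobs of the spatial regularization.

    beta:
        Spatial weight in [0, 1], or ``None`` (auto) to estimate it from the
        image background before fitting.
    window:
        Odd window extent per axis (int, applied to every spatial axis).
    include_center:
        Whether the center pixel enters its own neighbourhood average
        (default False: the average is over the *neighbours*).
    padding:
        ``"reflect"`` (edge-including reflection) or ``"constant_zero"``.
    beta_mode:
        ``"std"`` (default) sets beta to the Rayleigh MLE sigma_hat, the
        noise standard deviation on the normalized intensity scale;
        ``"variance"`` uses sigma_hat^2 instead.
    volumetric:
        For 3-D inputs, apply the window in 3-D; default is slice-wise 2-D
        (axis 0 is the slice axis).
    """

    beta: Optional[float] = None
    window: int = 3
    include_center: bool = False
    padding: str = "reflect"
    beta_mode: str = "std"
    beta_max: float = 0.5
    beta_fallback: float = 0.1
    background_threshold: float = 0.05
    normalize_covariance: bool = False
    volumetric: bool = False

    def __post_init__(self) -> None:
        if self.beta is not None and not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.padding not in ("reflect", "constant_zero"):
            raise ValueError(f"unknown padding {self.padding!r}")
        if self.beta_mode not in ("variance", "std"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")


@dataclass
class NoiseEstimate:
    """Rayleigh-MLE noise variance: sigma2 = (1/2n) sum O_i^2."""

    sigma2: float
    n_background: int


def _window_size(shape: tuple, config: SpatialConfig) -> tuple:
    if len(shape) == 3 and not config.volumetric:
        return (1, config.window, config.window)
    return (config.window,) * len(shape)


def neighborhood_average(image, config: Optional[SpatialConfig] = None) -> np.ndarray:
    """Windowed mean around each pixel, computed once before EM.

    With ``include_center=False`` the center pixel is removed from the
    window sum.  3-D volumes use a slice-wise 2-D window unless
    ``config.volumetric`` is set.
    """
    config = config or SpatialConfig()
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image, float)
    size = _window_size(data.shape, config)
    # the padding half-width must stay below the image extent so a single
    # border reflection defines every window unambiguously
    if any(s // 2 >= d for s, d in zip(size, data.shape)):
        raise ValueError(f"window {size} too large for image {data.shape}")
    mode = "reflect" if config.padding == "reflect" else "constant"
    mean_inc = uniform_filter(data, size=size, mode=mode, cval=0.0)
    if config.include_center:
        return mean_inc
    n = int(np.prod(size))
    if n < 2:
        raise ValueError("window of size 1 has no neighbours to average")
    return (mean_inc * n - data) / (n - 1)


def extract_background(image, mask: Optional[np.ndarray] = None,
                       threshold: float = 0.05) -> np.ndarray:
    """Background pixel values used as Rayleigh observations.

    With an explicit boolean ``mask``, returns exactly the masked pixels in
    row-major order.  Otherwise returns pixels that are "black" up to noise:
    intensity <= threshold * max(image).
    """
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image, float)
    if data.min() < 0:
        raise ValueError("image must be nonnegative")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape does not match image")
        return data[mask]
    return data[data <= threshold * data.max()]


def estimate_noise_variance(observations) -> NoiseEstimate:
    """Maximum-likelihood Rayleigh scale^2 from background observations.

    For i.i.d. Rayleigh samples O_i the MLE of sigma^2 is (1/2n) sum O_i^2,
    which is exactly the noise variance of the underlying complex Gaussian
    channels of magnitude-MRI noise.
    """
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("empty observation list")
    return NoiseEstimate(sigma2=float(np.sum(obs ** 2) / (2.0 * obs.size)),
                         n_background=int(obs.size))


def resolve_beta(image, config: Optional[SpatialConfig] = None,
                 mask: Optional[np.ndarray] = None) -> float:
    """Spatial weight: explicit value, or the background-noise estimate.

    Auto mode expects intensities on the [0, 1] scale (the fitters
    normalize before calling).  The estimate is clamped to
    ``[0, config.beta_max]``; with no background pixels at all the
    configured fallback is used.
    """
    config = config or SpatialConfig()
    if config.beta is not None:
        return float(config.beta)
    bg = extract_background(image, mask=mask, threshold=config.background_threshold)
    if bg.size == 0:
        logger.warning("no background pixels found; falling back to beta=%g",
                       config.beta_fallback)
        return float(config.beta_fallback)
    est = estimate_noise_variance(bg)
    value = est.sigma2 if config.beta_mode == "variance" else float(np.sqrt(est.sigma2))
    beta = float(np.clip(value, 0.0, config.beta_max))
    if value > config.beta_max:
        logger.info("beta estimate %.4g clamped to %.4g", value, config.beta_max)
    logger.info("resolved beta=%.6g (mode=%s, sigma2=%.6g from %d background pixels)",
                beta, config.beta_mode, est.sigma2, est.n_background)
    return beta


# ---------------------------------------------------------------------------
# spatial E / M / likelihood — thin views on the shared engine
# ---------------------------------------------------------------------------


def spatial_log_likelihood(data, avg, params: MixtureParams, beta: float) -> float:
    """Neighbourhood-augmented log-likelihood; beta = 0 is the plain value."""
    _check_beta(beta)
    X, _ = gmm._as_features(data)
    Xb, _ = gmm._as_features(avg)
    return gmm._loglik(X, params, Xb, beta)


def spatial_e_step(data, avg, params: MixtureParams, beta: float) -> np.ndarray:
    """Posterior probabilities with blended densities; rows sum to one."""
    _check_beta(beta)
    X, _ = gmm._as_features(data)
    Xb, _ = gmm._as_features(avg)
    return gmm._e_step(X, params, Xb, beta)


def spatial_m_step(data, avg, responsibilities, beta: float,
                   variance_floor: float = gmm.VARIANCE_FLOOR,
                   normalize_covariance: bool = False) -> MixtureParams:
    """Weight/mean/covariance updates with the neighbourhood terms."""
    _check_beta(beta)
    X, _ = gmm._as_features(data)
    Xb, _ = gmm._as_features(avg)
    return gmm._m_step(X, np.asarray(responsibilities, float), Xb, beta,
                       variance_floor, normalize_covariance)


def _check_beta(beta: float) -> None:
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")


def fit_em1(image, M: int, config: Optional[SpatialConfig] = None,
            init="kmeans", seed: int = 0, tol: float = 1e-6,
            max_iter: int = 200, background_mask: Optional[np.ndarray] = None,
            variance_floor: float = gmm.VARIANCE_FLOOR) -> FitResult:
    """Fit the spatially regularized mixture (EM-1) to an image.

    Pipeline: min-max normalize to [0, 1]; compute the neighbourhood-average
    image once; resolve beta (explicit or from the background noise
    estimate, optionally guided by ``background_mask``); then alternate the
    spatial E- and M-steps monitoring the augmented log-likelihood.  With
    beta = 0 the run is bit-identical to :func:`emseg.gmm.fit_gmm` at the
    same ``init``/``seed``.
    """
    config = config or SpatialConfig()
    X, shape = gmm._as_features(image)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    n_distinct = np.unique(X[:, 0]).shape[0]
    if M < 1 or M > n_distinct:
        raise ValueError(f"M={M} exceeds the number of distinct values ({n_distinct})")
    arr = image.data if isinstance(image, ImageVolume) else np.asarray(image, float)
    arr_n, (vmin, vmax) = normalize_intensity(arr)
    avg = neighborhood_average(arr_n, config)
    beta = resolve_beta(arr_n, config, mask=background_mask)
    Xn = arr_n.reshape(-1, 1)
    Xb = avg.reshape(-1, 1)
    if isinstance(init, MixtureParams):
        scale = vmax - vmin if vmax > vmin else 1.0
        init = init.scaled(1.0 / scale, -vmin / scale)
    out = gmm._fit(Xn, M, init, seed, tol, max_iter, Xb=Xb, beta=beta,
                   variance_floor=variance_floor,
                   normalize_covariance=config.normalize_covariance)
    labels = np.argmax(out["responsibilities"], axis=1).reshape(shape)
    scale = vmax - vmin if vmax > vmin else 1.0
    logger.info("EM-1: beta=%.6g window=%d iterations=%d objective=%.6g",
                beta, config.window, out["n_iterations"],
                out["trace"][-1] if out["trace"] else float("nan"))
    return FitResult(
        params=out["params"].scaled(scale, vmin),
        responsibilities=out["responsibilities"],
        labels=labels,
        log_likelihood_trace=out["trace"],
        n_iterations=out["n_iterations"],
        converged=out["converged"],
        beta=beta,
        value_range=(vmin, vmax),
        stop_reason=out["stop_reason"],
    )
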
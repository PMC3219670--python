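"""Synthetic multi-class phantoms with ground truth and Rician noise.

Phantoms are piecewise-constant "tissue" maps (nested disks, Voronoi blobs
or stripes) whose pixel intensities are drawn from per-class Gaussians;
class 0 plays the role of image background (mean 0 in the standard brain
configuration).  Acquisition noise follows the magnitude-MRI (Rician)
model: the noise-free value m becomes sqrt((m+g1)^2 + g2^2) with g1, g2
independent zero-mean Gaussians.  The noise "level" is the Gaussian sigma
expressed as a percentage of the maximum noise-free intensity, the
convention of the common simulated-MRI repositories.  In signal-free
background this produces exactly Rayleigh-distributed values, which is
what the noise-variance estimator in :mod:`emseg.spatial` relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The standard three-tissue configuration used throughout the test-bench:
#: background plus three tissue classes at evenly spaced mean intensities,
#: mimicking CSF / grey matter / white matter contrast in T1-weighted MRI.
DEFAULT_CLASS_MEANS = (0.0, 0.3, 0.6, 0.9)
DEFAULT_CLASS_STDDEVS = (0.0, 0.02, 0.02, 0.02)

GEOMETRIES = ("nested_disks", "voronoi_blobs", "stripes")


@dataclass
class NoiseSpec:
    """Rician noise at sigma = level_percent/100 * max(noise-free image)."""

    level_percent: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level_percent < 0:
            raise ValueError("noise level must be nonnegative")


@dataclass
class Phantom:
    """A noise-free synthetic image with its ground-truth label map."""

    image: np.ndarray
    truth: np.ndarray
    class_means: tuple
    class_stddevs: tuple

    @property
    def shape(self) -> tuple:
        return self.image.shape

    def noisy(self, level_percent: float, seed: int = 0) -> np.ndarray:
        """Convenience: the image after Rician noise at the given level."""
        return add_rician_noise(self.image, NoiseSpec(level_percent, seed))


def _radial_labels(shape: tuple, n_classes: int) -> np.ndarray:
    """Concentric annuli: class 0 outside, classes 1..n-1 from rim to core."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    r2 = sum(((g - c) ** 2) for g, c in zip(grids, center))
    r = np.sqrt(r2)
    rmax = 0.95 * min(shape) / 2.0
    labels = np.zeros(shape, dtype=np.int32)
    n_fg = n_classes - 1
    if n_fg == 0:
        return labels
    # equal-area annuli keep every class above the 1% occupancy floor
    edges = rmax * np.sqrt(1.0 - np.arange(1, n_fg + 1) / n_fg)
    for k in range(1, n_fg + 1):
        inner = edges[k - 1]
        outer = rmax if k == 1 else edges[k - 2]
        labels[(r >= inner) & (r < outer)] = k
    return labels


def _voronoi_labels(shape: tuple, n_classes: int,
                    rng: np.random.Generator) -> np.ndarray:
    n_seeds = 4 * n_classes
    pts = np.column_stack([rng.uniform(0, s, size=n_seeds) for s in shape])
    seed_class = np.arange(n_seeds) % n_classes
    grids = np.indices(shape).reshape(len(shape), -1).T
    d2 = ((grids[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return seed_class[np.argmin(d2, axis=1)].reshape(shape).astype(np.int32)


def _stripe_labels(shape: tuple, n_classes: int, width: int = 3) -> np.ndarray:
    """Fine stripes along the last axis cycling through all classes."""
    idx = np.arange(shape[-1]) // width % n_classes
    labels = np.broadcast_to(idx, shape).astype(np.int32)
    return np.ascontiguousarray(labels)


def generate_phantom(shape, n_classes: int,
                     class_means: Optional[Sequence[float]] = None,
                     class_stddevs: Optional[Sequence[float]] = None,
                     geometry: str = "nested_disks", seed: int = 0,
                     stripe_width: int = 3) -> Phantom:
    """Generate a deterministic multi-class phantom with ground truth.

    Class means must be strictly increasing; class 0 is the outermost /
    background class.  Every class occupies at least 1% of the pixels.
    Intensities are clipped to be nonnegative.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3):
        raise ValueError("shape must be 2-D or 3-D")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if class_means is None:
        class_means = np.linspace(0.0, 0.9, n_classes)
    if class_stddevs is None:
        class_stddevs = [0.0] + [0.02] * (n_classes - 1)
    class_means = tuple(float(m) for m in class_means)
    class_stddevs = tuple(float(s) for s in class_stddevs)
    if len(class_means) != n_classes or len(class_stddevs) != n_classes:
        raise ValueError("class_means/class_stddevs length must equal n_classes")
    if any(b <= a for a, b in zip(class_means, class_means[1:])):
        raise ValueError("class means must be strictly increasing")
    if any(s < 0 for s in class_stddevs):
        raise ValueError("class stddevs must be nonnegative")
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}")

    rng = np.random.default_rng(seed)
    if geometry == "nested_disks":
        truth = _radial_labels(shape, n_classes)
    elif geometry == "stripes":
        truth = _stripe_labels(shape, n_classes, stripe_width)
    else:
        for _ in range(20):
            truth = _voronoi_labels(shape, n_classes, rng)
            counts = np.bincount(truth.ravel(), minlength=n_classes)
            if counts.min() >= 0.01 * truth.size:
                break
        else:
            raise RuntimeError("could not place Voronoi blobs with >=1% per class")
    counts = np.bincount(truth.ravel(), minlength=n_classes)
    if counts.min() < 0.01 * truth.size:
        raise RuntimeError(f"class occupancy below 1%: {counts / truth.size}")

    means = np.asarray(class_means)[truth]
    stds = np.asarray(class_stddevs)[truth]
    image = means + stds * rng.standard_normal(shape)
    image = np.clip(image, 0.0, None)
    return Phantom(image=image, truth=truth, class_means=class_means,
                   class_stddevs=class_stddevs)


def add_rician_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt a nonnegative image with Rician noise.

    out = sqrt((image + g1)^2 + g2^2), g1 and g2 i.i.d. N(0, sigma^2) with
    sigma = (level_percent/100) * max(image).  A zero level returns the
    image unchanged.  Identical in law to sampling a Rice distribution and
    exactly Rayleigh where the image is zero.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0:
        raise ValueError("image must be nonnegative")
    if spec.level_percent < 0:
        raise ValueError("noise level must be nonnegative")
    if spec.level_percent == 0:
        return image.copy()
    sigma = spec.level_percent / 100.0 * image.max()
    rng = np.random.default_rng(spec.seed)
    g1 = rng.normal(0.0, sigma, size=image.shape)
    g2 = rng.normal(0.0, sigma, size=image.shape)
    return np.sqrt((image + g1) ** 2 + g2 ** 2)
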
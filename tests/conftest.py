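"""Shared fixtures and naive reference implementations.

The naive_* functions evaluate the mixture formulas by direct double loops
over pixels and components, independently of the package's vectorized
log-space code paths; they are the oracle for the equivalence tests.
"""

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# naive oracles (scalar intensities)
# ---------------------------------------------------------------------------


def naive_pdf(x, mean, var):
    return math.exp(-(x - mean) ** 2 / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def naive_blend(x, xb, w, m, v, beta, j):
    return (1.0 - beta) * naive_pdf(x, m[j], v[j]) + beta * naive_pdf(xb, m[j], v[j])


def naive_log_likelihood(xs, weights, means, variances, xbars=None, beta=0.0):
    total = 0.0
    for i, x in enumerate(xs):
        s = 0.0
        for j in range(len(weights)):
            if beta == 0.0:
                s += weights[j] * naive_pdf(x, means[j], variances[j])
            else:
                s += weights[j] * naive_blend(x, xbars[i], weights, means,
                                              variances, beta, j)
        total += math.log(s)
    return total


def naive_e_step(xs, weights, means, variances, xbars=None, beta=0.0):
    M = len(weights)
    out = np.zeros((len(xs), M))
    for i, x in enumerate(xs):
        num = []
        for j in range(M):
            if beta == 0.0:
                a = naive_pdf(x, means[j], variances[j])
            else:
                a = naive_blend(x, xbars[i], weights, means, variances, beta, j)
            num.append(weights[j] * a)
        z = sum(num)
        out[i] = [n / z for n in num]
    return out


def naive_m_step(xs, resp, xbars=None, beta=0.0):
    xs = np.asarray(xs, float)
    resp = np.asarray(resp, float)
    N, M = resp.shape
    weights = np.zeros(M)
    means = np.zeros(M)
    variances = np.zeros(M)
    for j in range(M):
        nj = sum(resp[i, j] for i in range(N))
        weights[j] = nj / N
        if beta == 0.0:
            means[j] = sum(resp[i, j] * xs[i] for i in range(N)) / nj
            variances[j] = sum(resp[i, j] * (xs[i] - means[j]) ** 2
                               for i in range(N)) / nj
        else:
            means[j] = sum(resp[i, j] * ((1 - beta) * xs[i] + beta * xbars[i])
                           for i in range(N)) / nj
            variances[j] = sum(
                resp[i, j] * ((xs[i] - means[j]) ** 2
                              + beta * (xbars[i] - means[j]) ** 2)
                for i in range(N)) / nj
    return weights, means, variances


def random_mixture(rng, M):
    """A valid random scalar mixture: weights on the simplex, spread means."""
    w = rng.dirichlet(np.ones(M) * 2.0)
    m = np.sort(rng.uniform(0.0, 1.0, size=M))
    v = rng.uniform(0.01, 0.2, size=M)
    return w, m, v


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def brain_phantom():
    """Standard 4-label (background + 3 tissues) 64x64 phantom."""
    from emseg import generate_phantom

    return generate_phantom((64, 64), 4, seed=7)


@pytest.fixture
def clean_binary_phantom():
    """Zero-noise, zero-spread binary phantom: segments perfectly."""
    from emseg import generate_phantom

    return generate_phantom((16, 16), 2, class_means=(0.0, 1.0),
                            class_stddevs=(0.0, 0.0), seed=0)
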
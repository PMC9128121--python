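"""Step-length and turn-angle distributions and moment-matching helpers.

The movement model describes 4-day step lengths with a Weibull distribution
and turning behaviour with a wrapped Cauchy distribution whose concentration
parameter is the "directional persistence" (0 = uniform turning, near 1 =
straight-line travel).  Individual-level parameters are tied to
population-level (class) parameters through Gamma and Beta hyper-distributions
parameterized by the method of moments, so the class mean and the
inter-individual standard deviation appear directly as model parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln
from scipy.special import gamma as _gamma_fn

TWO_PI = 2.0 * np.pi

__all__ = [
    "wrap_angle",
    "mom_gamma_params",
    "mom_beta_params",
    "gamma_logpdf",
    "beta_logpdf",
    "weibull_logpdf",
    "wrapped_cauchy_logpdf",
    "sample_wrapped_cauchy",
    "mean_step_length",
]


def wrap_angle(a):
    """Wrap angles (radians) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a, TWO_PI)
    w = np.where(w > np.pi, w - TWO_PI, w)
    return w if w.ndim else float(w)


def mom_gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape and rate of the Gamma distribution with the given mean and SD.

    shape = mean^2 / sd^2, rate = mean / sd^2, so that shape/rate = mean and
    shape/rate^2 = sd^2.
    """
    if not (mean > 0):
        raise ValueError(f"mean must be positive, got {mean}")
    if not (sd > 0):
        raise ValueError(f"sd must be positive, got {sd}")
    var = sd * sd
    return mean * mean / var, mean / var


def mom_beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the Beta distribution with given mean and SD.

    Requires sd^2 < mean * (1 - mean); outside that bound no Beta distribution
    has the requested moments and a ``ValueError`` naming the bound is raised.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if not (sd > 0):
        raise ValueError(f"sd must be positive, got {sd}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(
            f"infeasible Beta moments: sd^2 = {var:g} must be < "
            f"mean*(1-mean) = {bound:g}"
        )
    a = (mean**2 - mean**3 - mean * var) / var
    b = (mean - 2 * mean**2 + mean**3 - var + mean * var) / var
    return a, b


def gamma_logpdf(x, shape, rate):
    """Log density of Gamma(shape, rate) at x (vectorized)."""
    x = np.asarray(x, dtype=float)
    out = shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    return np.where(x > 0, out, -np.inf)


def beta_logpdf(x, a, b):
    """Log density of Beta(a, b) at x (vectorized)."""
    x = np.asarray(x, dtype=float)
    inside = (x > 0) & (x < 1)
    xs = np.where(inside, x, 0.5)
    out = (a - 1.0) * np.log(xs) + (b - 1.0) * np.log1p(-xs) - betaln(a, b)
    return np.where(inside, out, -np.inf)


def weibull_logpdf(l, k, g):
    """Log density of the Weibull(shape k, scale g) step-length distribution.

    log[(k/g) (l/g)^(k-1) exp(-(l/g)^k)].  At l = 0 the density is 0 for
    k > 1 (log-density -inf), 1/g for k = 1, and diverges for k < 1.
    """
    l = np.asarray(l, dtype=float)
    k = np.asarray(k, dtype=float)
    g = np.asarray(g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.log(l) - np.log(g)
        out = np.log(k) - np.log(g) + (k - 1.0) * d - np.exp(k * d)
    at_zero = np.where(k > 1.0, -np.inf, np.where(k == 1.0, -np.log(g), np.inf))
    out = np.where(l == 0.0, at_zero, out)
    out = np.where(l < 0.0, -np.inf, out)
    return out if out.ndim else float(out)


def wrapped_cauchy_logpdf(theta, mu, r):
    """Log density of the wrapped Cauchy distribution with centre mu.

    log[(1 - r^2) / (2 pi (1 + r^2 - 2 r cos(theta - mu)))]; the angular
    difference is taken on the circle so any real-valued inputs are accepted.
    r = 0 gives the circular uniform density 1/(2 pi).
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    d = theta - np.asarray(mu, dtype=float)
    out = np.log1p(-r * r) - np.log(TWO_PI) - np.log1p(r * r - 2.0 * r * np.cos(d))
    out = np.where((r < 0) | (r >= 1), -np.inf, out)
    return out if out.ndim else float(out)


def sample_wrapped_cauchy(mu, r, size, rng: np.random.Generator):
    """Draw wrapped Cauchy variates by wrapping a linear Cauchy.

    A Cauchy with scale s wrapped onto the circle has concentration
    r = exp(-s), so s = -log(r).  r = 0 falls back to circular uniform.
    """
    if r <= 0.0:
        return rng.uniform(-np.pi, np.pi, size=size)
    if r >= 1.0:
        return wrap_angle(np.broadcast_to(np.asarray(mu, float), size or ()).copy())
    s = -np.log(r)
    u = rng.uniform(0.0, 1.0, size=size)
    return wrap_angle(np.asarray(mu, float) + s * np.tan(np.pi * (u - 0.5)))


def mean_step_length(k, g):
    """Mean of the Weibull(k, g) step length: g * Gamma(1 + 1/k)."""
    k = np.asarray(k, dtype=float)
    g = np.asarray(g, dtype=float)
    out = g * _gamma_fn(1.0 + 1.0 / k)
    return out if out.ndim else float(out)
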
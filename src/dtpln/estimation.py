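"""Point estimation for the DTPLN model.

The zero proportion ``delta`` and, given the threshold, the log-scale
location and variance have closed-form maximum-likelihood estimates.
The threshold ``a`` itself is estimated by the Cohen-Whitten modified
method of moments: the sample mean and sample variance of the positives
are matched to their shifted-lognormal counterparts, and the third
equation replaces the (unstable) third moment with a condition on the
smallest order statistic.  Two classical variants of that third
condition are provided:

``log-order-stat`` (default)
    ``ln(x_(1) - a) = mu + sigma * E[Z_(1:n1)]`` where ``Z_(1:n1)`` is
    the smallest of ``n1`` standard normal variates.
``raw-order-stat``
    ``x_(1) = E[X_(1)]`` with the expectation of the smallest order
    statistic of the fitted shifted lognormal taken on the raw scale.

With ``mu`` and ``sigma^2`` profiled out of the first two moment
equations, either variant reduces to a one-dimensional root search for
``a`` in ``[0, x_(1))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .model import DTPLNParams, SampleData

__all__ = [
    "Estimates",
    "ThresholdConvergenceError",
    "estimate_delta",
    "estimate_threshold",
    "threshold_score",
    "estimate_location_scale",
    "threshold_variance",
    "log_likelihood",
    "fit",
    "expected_min_normal",
]

#: hard upper bound for the threshold, as a fraction of the smallest positive
_A_UPPER_FRAC = 1.0 - 1e-9


class ThresholdConvergenceError(RuntimeError):
    """Raised when the modified-moment equations have no root in [0, x_(1))."""


@dataclass(frozen=True)
class Estimates:
    """Point estimates for a DTPLN sample.

    ``s2_unbiased`` uses divisor ``n1 - 1`` and is the variance estimate
    consumed by every interval method; ``s2_mle`` (divisor ``n1``) is
    retained for likelihood identities.  ``var_a_hat`` is the asymptotic
    variance of the threshold estimate.
    """

    delta_hat: float
    a_hat: float
    mu_hat: float
    s2_unbiased: float
    s2_mle: float
    var_a_hat: float
    n0: int
    n1: int
    mean_pos: float
    threshold_fallback: bool = False

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    @property
    def theta_hat(self) -> float:
        """Plug-in estimate of the log-mean (uses the unbiased variance)."""
        return float(np.log1p(-self.delta_hat)
                     + np.log(self.a_hat + np.exp(self.mu_hat + self.s2_unbiased / 2.0)))


def estimate_delta(n0: int, n: int) -> float:
    """MLE of the zero proportion: n0 / n."""
    if not 0 <= n0 <= n or n < 1:
        raise ValueError("require 0 <= n0 <= n and n >= 1")
    return n0 / n


@lru_cache(maxsize=None)
def _min_order_quadrature(n: int, npts: int = 400):
    """Quadrature nodes/weights for E[g(Z_(1:n))], Z_(1:n) = min of n N(0,1)."""
    z, w = np.polynomial.legendre.leggauss(npts)
    lo, hi = -12.0, 12.0
    z = 0.5 * (hi - lo) * z + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * w
    # density of the minimum: n * phi(z) * (1 - Phi(z))^(n-1), via logs
    logpdf = (np.log(n) + stats.norm.logpdf(z)
              + (n - 1) * stats.norm.logsf(z))
    return z, w * np.exp(logpdf)


def expected_min_normal(n: int) -> float:
    """E[Z_(1:n)], the expected smallest of n standard normal variates."""
    z, w = _min_order_quadrature(n)
    return float(np.sum(w * z))


def _profiled_moments(a: float, mean: float, var: float):
    """(mu, sigma2) matching the positive-part mean/variance at threshold a."""
    m = mean - a
    sigma2 = np.log1p(var / (m * m))
    mu = np.log(m) - sigma2 / 2.0
    return mu, sigma2


def _moment_residual(a, positives, variant, ddof, n1, x1, mean, var, ez1):
    mu, sigma2 = _profiled_moments(a, mean, var)
    if variant == "log-order-stat":
        return np.log(x1 - a) - (mu + np.sqrt(sigma2) * ez1)
    # raw scale: x_(1) - E[a + exp(mu + sigma * Z_(1:n1))]
    z, w = _min_order_quadrature(n1)
    emin = a + np.sum(w * np.exp(mu + np.sqrt(sigma2) * z))
    return x1 - emin


def estimate_threshold(positives, variant: str = "log-order-stat",
                       ddof: int = 1, fallback: bool = True) -> float:
    """Cohen-Whitten modified-moment estimate of the threshold ``a``.

    Parameters
    ----------
    positives : array_like
        The strictly positive observations (n1 >= 3).
    variant : {"log-order-stat", "raw-order-stat"}
        Form of the first-order-statistic matching condition.
    ddof : int
        Divisor convention for the matched sample variance
        (1 = ``n1 - 1``, the default; 0 = ``n1``).
    fallback : bool
        When the moment residual has no sign change on ``[0, x_(1))`` —
        a small-sample pathology — return 0.0 with a warning instead of
        raising :class:`ThresholdConvergenceError`.
    """
    if variant not in ("log-order-stat", "raw-order-stat"):
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(positives, dtype=float).ravel()
    n1 = x.size
    if n1 < 3:
        raise ValueError("threshold estimation requires n1 >= 3")
    if np.any(x <= 0):
        raise ValueError("positives must be strictly positive")
    x1 = float(x.min())
    mean = float(x.mean())
    var = float(x.var(ddof=ddof))
    if var == 0.0:
        raise ValueError("positives are all equal; threshold not identifiable")
    ez1 = expected_min_normal(n1)
    args = (x, variant, ddof, n1, x1, mean, var, ez1)
    hi = x1 * _A_UPPER_FRAC
    f_lo = _moment_residual(0.0, *args)
    f_hi = _moment_residual(hi, *args)
    if f_lo == 0.0:
        return 0.0
    if np.sign(f_lo) == np.sign(f_hi):
        msg = (f"modified-moment residual has no sign change on [0, {x1:g}): "
               f"f(0)={f_lo:.4g}, f({hi:g})={f_hi:.4g}")
        if fallback:
            warnings.warn(msg + "; falling back to a=0", RuntimeWarning,
                          stacklevel=2)
            return 0.0
        raise ThresholdConvergenceError(msg)
    root = optimize.brentq(_moment_residual, 0.0, hi, args=args,
                           xtol=1e-10, rtol=8.9e-16)
    assert 0.0 <= root < x1
    return float(root)


def threshold_score(a: float, positives, mu_y: float | None = None,
                    sigma2_y: float | None = None) -> float:
    """Score (partial derivative of the log-likelihood) in the threshold.

    Evaluates ``d/da ln L = sum 1/(x_i - a) +
    (1/sigma^2) * sum [ln(x_i - a) - mu] / (x_i - a)``.  When ``mu_y``
    and ``sigma2_y`` are omitted they are replaced by their MLEs at the
    candidate ``a`` (divisor n1), giving the profile-likelihood score.
    A consistent root lies near the threshold MLE; this is a diagnostic
    cross-check, not the default estimator.
    """
    x = np.asarray(positives, dtype=float).ravel()
    if a >= x.min():
        raise ValueError("threshold_score requires a < min(positives)")
    y = np.log(x - a)
    if mu_y is None:
        mu_y = float(y.mean())
    if sigma2_y is None:
        sigma2_y = float(y.var(ddof=0))
    inv = 1.0 / (x - a)
    return float(np.sum(inv) + np.sum((y - mu_y) * inv) / sigma2_y)


def estimate_location_scale(positives, a: float, ddof: int = 1):
    """MLEs of the log-scale location and variance given the threshold.

    Returns ``(mu_hat, s2)`` with ``mu_hat`` the mean of ``ln(x - a)``
    and ``s2`` its variance with divisor ``n1 - ddof``.
    """
    x = np.asarray(positives, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two positive observations")
    if np.any(x <= a):
        raise ValueError("all positives must exceed the threshold a")
    y = np.log(x - a)
    return float(y.mean()), float(y.var(ddof=ddof))


def threshold_variance(mu_hat: float, s2: float, n1: int) -> float:
    """Asymptotic variance of the modified-moment threshold estimate.

    ``sigma2 * exp(2*mu - sigma2) / (n1 * [exp(sigma2)(1 + sigma2)
    - 2*sigma2 - 1])`` evaluated at the plug-in estimates.
    """
    if s2 <= 0 or n1 < 3:
        raise ValueError("require s2 > 0 and n1 >= 3")
    denom = np.exp(s2) * (1.0 + s2) - 2.0 * s2 - 1.0
    # expm1-type positivity: exp(s)(1+s) - 2s - 1 > 0 for all s > 0
    assert denom > 0.0, "degenerate variance denominator"
    return float(s2 * np.exp(2.0 * mu_hat - s2) / (n1 * denom))


def log_likelihood(params: DTPLNParams, sample: SampleData) -> float:
    """DTPLN log-likelihood up to the additive binomial-coefficient constant.

    The constant ``ln C(n, n0)`` from the zero/positive split is
    excluded; differences of log-likelihoods are unaffected.  Returns
    ``-inf`` (rather than raising) when ``a >= x_(1)``.
    """
    n0, n1 = sample.n0, sample.n1
    pos = sample.positives
    if n1 > 0 and params.a >= pos.min():
        return -np.inf
    if params.delta == 0.0 and n0 > 0:
        return -np.inf
    ll = 0.0
    if n0 > 0:
        ll += n0 * np.log(params.delta)
    ll += n1 * np.log1p(-params.delta)
    if n1 > 0:
        y = np.log(pos - params.a)
        ll -= 0.5 * n1 * np.log(params.sigma2_y)
        ll -= np.sum((y - params.mu_y) ** 2) / (2.0 * params.sigma2_y)
        ll -= np.sum(y)
    return float(ll)


def fit(sample: SampleData, variant: str = "log-order-stat",
        ddof: int = 1, fallback: bool = True) -> Estimates:
    """Full point-estimation pass; the entry point for every interval method."""
    if sample.n1 < 3:
        raise ValueError("fit requires at least 3 positive observations")
    pos = sample.positives
    delta_hat = estimate_delta(sample.n0, sample.n)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", RuntimeWarning)
        a_hat = estimate_threshold(pos, variant=variant, ddof=ddof,
                                   fallback=fallback)
        fell_back = any(issubclass(w.category, RuntimeWarning) for w in caught)
    for w in caught:  # re-emit for the caller's logging
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    mu_hat, s2_unbiased = estimate_location_scale(pos, a_hat, ddof=1)
    _, s2_mle = estimate_location_scale(pos, a_hat, ddof=0)
    var_a_hat = threshold_variance(mu_hat, s2_unbiased, sample.n1)
    return Estimates(delta_hat=delta_hat, a_hat=a_hat, mu_hat=mu_hat,
                     s2_unbiased=s2_unbiased, s2_mle=s2_mle,
                     var_a_hat=var_a_hat, n0=sample.n0, n1=sample.n1,
                     mean_pos=float(pos.mean()), threshold_fallback=fell_back)
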
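"""Generalized confidence interval (GCI) for the log-mean via
generalized pivotal quantities (GPQs).

A GPQ is a function of the data and of pivot variates whose
distribution is free of unknown parameters and whose observed value
depends only on the parameter of interest.  The component GPQs are

    R_a      = a_hat - T * sqrt(var_a_hat),        T ~ t_{n1-2}
    R_delta  = sin^2( arcsin sqrt(delta_hat) - K / (2 sqrt(n1)) ),
                                                   K ~ N(0, 1)
    R_sigma2 = (n1 - 1) s2 / U,                    U ~ chi2_{n1-1}
    R_mu     = mu_hat - W * sqrt(R_sigma2 / n1),   W ~ N(0, 1)

and the log-mean GPQ is
``R_theta = ln(1 - R_delta) + ln(R_a + exp(R_mu + R_sigma2 / 2))``.
The GCI is the pair of empirical (alpha/2, 1 - alpha/2) quantiles of
``R_theta``.

Because ``T`` is heavy-tailed, ``R_a`` can occasionally be so negative
that the second logarithm has a nonpositive argument; such draws are
rejected and redrawn (with the count recorded), and an error is raised
if more than 5% of draws are rejected.

The arcsine standardization divides by ``sqrt(n1)`` (the positive-part
count) as printed in the source derivation; ``k_standardization="n"``
uses the full sample size instead, matching the original
variance-stabilizing construction for a binomial proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Interval, as_rng
from .estimation import Estimates

__all__ = ["GPQDraws", "draw_gpq", "gci_interval"]


@dataclass(frozen=True)
class GPQDraws:
    """Vectors of component GPQ draws and the induced log-mean draws."""

    r_a: np.ndarray = field(repr=False)
    r_delta: np.ndarray = field(repr=False)
    r_mu: np.ndarray = field(repr=False)
    r_sigma2: np.ndarray = field(repr=False)
    r_theta: np.ndarray = field(repr=False)
    n_rejected: int = 0

    @property
    def m(self) -> int:
        return int(self.r_theta.size)


def _gpq_from_variates(est: Estimates, n0: int, n1: int, t, k, w, u,
                       k_standardization: str = "n1"):
    """Map driving variates (T, K, W, U) to component GPQs.

    Exposed separately so that the zero-noise identity (T=K=W=0,
    U=n1-1 implies R_theta = theta_hat) can be checked exactly.
    """
    t = np.asarray(t, dtype=float)
    denom_n = n1 if k_standardization == "n1" else n0 + n1
    r_a = est.a_hat - t * np.sqrt(est.var_a_hat)
    r_delta = np.sin(np.arcsin(np.sqrt(est.delta_hat))
                     - np.asarray(k, dtype=float) / (2.0 * np.sqrt(denom_n))) ** 2
    r_sigma2 = (n1 - 1) * est.s2_unbiased / np.asarray(u, dtype=float)
    r_mu = est.mu_hat - np.asarray(w, dtype=float) * np.sqrt(r_sigma2 / n1)
    return r_a, r_delta, r_mu, r_sigma2


def draw_gpq(est: Estimates, n0: int, n1: int, m: int = 5000, seed=None,
             k_standardization: str = "n1",
             max_reject_frac: float = 0.05) -> GPQDraws:
    """Simulate ``m`` GPQ draws of the log-mean."""
    if n1 < 3:
        raise ValueError("need n1 >= 3")
    if k_standardization not in ("n1", "n"):
        raise ValueError(f"unknown k_standardization {k_standardization!r}")
    rng = as_rng(seed)

    def batch(size):
        t = rng.standard_t(n1 - 2, size=size)
        k = rng.standard_normal(size)
        w = rng.standard_normal(size)
        u = rng.chisquare(n1 - 1, size=size)
        return _gpq_from_variates(est, n0, n1, t, k, w, u, k_standardization)

    r_a, r_delta, r_mu, r_sigma2 = batch(m)
    arg = r_a + np.exp(r_mu + r_sigma2 / 2.0)
    n_rejected = 0
    bad = arg <= 0.0
    while np.any(bad):
        n_rejected += int(bad.sum())
        if n_rejected > max_reject_frac * m:
            raise RuntimeError(
                f"excessive GPQ rejection: {n_rejected} redraws exceed "
                f"{max_reject_frac:.0%} of m={m}")
        nb = int(bad.sum())
        ra2, rd2, rm2, rs2 = batch(nb)
        r_a[bad], r_delta[bad], r_mu[bad], r_sigma2[bad] = ra2, rd2, rm2, rs2
        arg[bad] = ra2 + np.exp(rm2 + rs2 / 2.0)
        bad = arg <= 0.0
    r_theta = np.log1p(-r_delta) + np.log(arg)
    return GPQDraws(r_a, r_delta, r_mu, r_sigma2, r_theta, n_rejected)


def gci_interval(gpq: GPQDraws, level: float = 0.95) -> Interval:
    """GCI: empirical (alpha/2, 1 - alpha/2) quantiles of the theta GPQ."""
    draws = np.asarray(gpq.r_theta, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return Interval(float(lo), float(hi), level)
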
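"""Closed-form MOVER interval for the log-mean.

MOVER (method of variance estimates recovery) builds an interval for a
sum of parameters from separate component intervals: for
``lambda_1 + lambda_2`` with point estimates ``l1_hat, l2_hat`` and
component intervals ``[l_i, u_i]``,

    lower = (l1_hat + l2_hat) - sqrt((l1_hat - l_1)^2 + (l2_hat - l_2)^2)
    upper = (l1_hat + l2_hat) + sqrt((u_1 - l1_hat)^2 + (u_2 - l2_hat)^2).

Here ``theta = ln theta_1 + ln theta_2`` with ``theta_1 = 1 - delta``
(positive-observation probability) and
``theta_2 = a + exp(mu_y + sigma2_y / 2)`` (mean of the positive part):

* ``ln theta_1`` gets a Wilson score interval on the log scale;
* ``ln theta_2`` is itself assembled by MOVER from a Student-t interval
  for ``a`` and an interval for ``mu_y + sigma2_y / 2`` (normal-mean
  part plus a chi-square correction for the variance half).

The inner combination mixes a threshold-scale distance with the
``mu + sigma^2/2`` interval.  By default (``component2_scale =
"original"``) the second component's distances are measured between
``exp(mu_hat + s2/2)`` and the exponentiated bounds, which is
dimensionally consistent with ``a + exp(.)``; ``"log"`` uses the
log-scale bounds literally as in the source presentation.  The whole
construction is deterministic — no random draws.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model import Interval
from .estimation import Estimates

__all__ = [
    "wilson_log_interval",
    "threshold_interval",
    "meanlog_interval",
    "mover_theta_interval",
]


def wilson_log_interval(n0: int, n1: int, level: float = 0.95) -> Interval:
    """Wilson score interval for ``ln(1 - delta)`` = log positive proportion.

    Bounds are the log of
    ``(n1 + k^2/2 -/+ k sqrt(n0 n1 / n + k^2/4)) / (n + k^2)`` with
    ``k`` the upper alpha/2 standard-normal quantile; both are <= 0.
    """
    if n1 < 1 or n0 < 0:
        raise ValueError("require n1 >= 1 and n0 >= 0")
    n = n0 + n1
    k = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    k2 = k * k
    half = k * np.sqrt(n0 * n1 / n + k2 / 4.0)
    lo = np.log((n1 + k2 / 2.0 - half) / (n + k2))
    hi = np.log((n1 + k2 / 2.0 + half) / (n + k2))
    return Interval(float(lo), float(min(hi, 0.0)), level)


def threshold_interval(a_hat: float, var_a_hat: float, n1: int,
                       level: float = 0.95) -> Interval:
    """Student-t interval for the threshold: ``a_hat -/+ t_{alpha/2, n1-2} sd``.

    Symmetric about ``a_hat``; may extend below zero — it is only used
    as a component distance inside the MOVER combination.
    """
    if var_a_hat < 0 or n1 < 3:
        raise ValueError("require var_a_hat >= 0 and n1 >= 3")
    t = stats.t.ppf(1.0 - (1.0 - level) / 2.0, n1 - 2)
    half = t * np.sqrt(var_a_hat)
    return Interval(float(a_hat - half), float(a_hat + half), level)


def meanlog_interval(mu_hat: float, s2: float, n1: int,
                     level: float = 0.95) -> Interval:
    """Interval for ``mu_y + sigma2_y / 2`` (log of the shifted-part mean).

    Combines the normal-mean half-width ``w_{alpha/2} sqrt(s2/n1)`` with
    a chi-square-based half-width for the ``sigma^2/2`` term; the upper
    half-width always exceeds the lower one for ``s2 > 0``.
    """
    if s2 <= 0 or n1 < 2:
        raise ValueError("require s2 > 0 and n1 >= 2")
    alpha = 1.0 - level
    w2 = stats.norm.ppf(1.0 - alpha / 2.0) ** 2
    point = mu_hat + s2 / 2.0
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, n1 - 1)
    chi_lo = stats.chi2.ppf(alpha / 2.0, n1 - 1)
    lo = point - np.sqrt(w2 * s2 / n1
                         + s2 * s2 / 2.0 * (1.0 - (n1 - 1) / chi_hi) ** 2)
    hi = point + np.sqrt(w2 * s2 / n1
                         + s2 * s2 / 2.0 * (1.0 - (n1 - 1) / chi_lo) ** 2)
    return Interval(float(lo), float(hi), level)


def mover_theta_interval(est: Estimates, level: float = 0.95,
                         component2_scale: str = "original") -> Interval:
    """MOVER interval for the log-mean ``theta``.

    Builds the ``ln theta_2`` interval by MOVER-combining the threshold
    interval with the ``mu + sigma^2/2`` interval inside
    ``theta_2_hat = a_hat + exp(mu_hat + s2/2)``, then combines it with
    the Wilson ``ln theta_1`` interval.  Deterministic.

    Raises ``ValueError`` if the inner lower distance reaches
    ``theta_2_hat`` (the log would be nonpositive); this is reported,
    not clamped.
    """
    if component2_scale not in ("original", "log"):
        raise ValueError(f"unknown component2_scale {component2_scale!r}")
    if est.n1 < 3:
        raise ValueError("need n1 >= 3")
    e_hat = np.exp(est.mu_hat + est.s2_unbiased / 2.0)
    theta2_hat = est.a_hat + e_hat

    ia = threshold_interval(est.a_hat, est.var_a_hat, est.n1, level)
    im = meanlog_interval(est.mu_hat, est.s2_unbiased, est.n1, level)
    if component2_scale == "original":
        d_lo = np.hypot(est.a_hat - ia.lower, e_hat - np.exp(im.lower))
        d_hi = np.hypot(ia.upper - est.a_hat, np.exp(im.upper) - e_hat)
    else:
        point = est.mu_hat + est.s2_unbiased / 2.0
        d_lo = np.hypot(est.a_hat - ia.lower, point - im.lower)
        d_hi = np.hypot(ia.upper - est.a_hat, im.upper - point)
    if theta2_hat - d_lo <= 0.0:
        raise ValueError(
            "MOVER inner lower distance reaches theta_2 estimate "
            f"({d_lo:.4g} >= {theta2_hat:.4g}); log undefined")
    ln_t2 = np.log(theta2_hat)
    l2, u2 = np.log(theta2_hat - d_lo), np.log(theta2_hat + d_hi)

    iw = wilson_log_interval(est.n0, est.n1, level)
    ln_t1 = np.log1p(-est.delta_hat)
    theta_hat = ln_t1 + ln_t2
    lower = theta_hat - np.hypot(ln_t1 - iw.lower, ln_t2 - l2)
    upper = theta_hat + np.hypot(iw.upper - ln_t1, u2 - ln_t2)
    return Interval(float(lower), float(upper), level)
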
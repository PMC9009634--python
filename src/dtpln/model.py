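"""Delta-three-parameter lognormal (DTPLN) model.

The DTPLN distribution describes nonnegative data with a point mass at
zero: an observation is exactly zero with probability ``delta`` and
otherwise follows a three-parameter (threshold-shifted) lognormal law,
``X = a + exp(Y)`` with ``Y ~ N(mu_y, sigma2_y)``.  It is the natural
model for, e.g., weekly rainfall records where a fraction of stations
report no rain at all and the positive amounts are strongly right-skewed
with a physical lower bound ``a`` on the positive part.

The quantity of inferential interest throughout this package is the
log-transformed mean

    theta = ln(1 - delta) + ln(a + exp(mu_y + sigma2_y / 2)),

so that ``exp(theta)`` is the distribution mean
``(1 - delta) * (a + exp(mu_y + sigma2_y / 2))``.

All randomness is driven by an explicit :class:`numpy.random.Generator`
(or an integer seed); no global RNG state is touched anywhere in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DTPLNParams",
    "SampleData",
    "Interval",
    "theta_of",
    "dtpln_cdf",
    "tpln_pdf",
    "rdtpln",
    "as_rng",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DTPLNParams:
    """Parameters of the delta-three-parameter lognormal distribution.

    Attributes
    ----------
    delta : float
        Probability of a zero observation, ``0 <= delta < 1``
        (``delta = 0`` gives the pure three-parameter lognormal).
    mu_y : float
        Location of ``ln(X - a)`` for the positive part (log units).
    sigma2_y : float
        Variance of ``ln(X - a)``, strictly positive.
    a : float
        Threshold (lower bound) of the positive part, ``a >= 0``,
        in the units of the observations.
    """

    delta: float
    mu_y: float
    sigma2_y: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0, 1); got {self.delta}")
        if self.sigma2_y <= 0.0:
            raise ValueError(f"sigma2_y must be > 0; got {self.sigma2_y}")
        if self.a < 0.0:
            raise ValueError(f"a must be >= 0; got {self.a}")

    @property
    def theta(self) -> float:
        """Log-transformed mean of the distribution."""
        return theta_of(self)

    @property
    def mean(self) -> float:
        """Mean of the distribution on the original scale, ``exp(theta)``."""
        return float(np.exp(self.theta))


@dataclass(frozen=True)
class SampleData:
    """A sample of nonnegative observations with its zero/positive split.

    Zeros are detected by exact equality with 0.  Values in ``(0, a]``
    are legal under the distribution function but rejected by the
    estimation routines (they indicate a misspecified threshold).
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size == 0:
            raise ValueError("sample must contain at least one value")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("sample values must be finite and nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def n0(self) -> int:
        return int(np.count_nonzero(self.values == 0.0))

    @property
    def n1(self) -> int:
        return self.n - self.n0

    @property
    def positives(self) -> np.ndarray:
        return self.values[self.values > 0.0]

    @property
    def min_pos(self) -> float:
        """Smallest positive value x_(1); undefined when n1 = 0."""
        if self.n1 == 0:
            raise ValueError("min_pos undefined: sample has no positive values")
        return float(self.positives.min())


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence/credible interval.

    ``scale`` records whether the bounds live on the log-mean (theta)
    scale or on the original data scale.
    """

    lower: float
    upper: float
    level: float = 0.95
    scale: str = "log-mean"

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def exp(self) -> "Interval":
        """Map a log-mean-scale interval to the original scale."""
        if self.scale != "log-mean":
            raise ValueError("exp() only applies to log-mean-scale intervals")
        return Interval(float(np.exp(self.lower)), float(np.exp(self.upper)),
                        self.level, scale="original")


def theta_of(params: DTPLNParams) -> float:
    """Log-transformed mean: ``ln(1-delta) + ln(a + exp(mu_y + sigma2_y/2))``."""
    if params.delta >= 1.0:
        raise ValueError("theta undefined for delta >= 1")
    return float(np.log1p(-params.delta)
                 + np.log(params.a + np.exp(params.mu_y + params.sigma2_y / 2.0)))


def dtpln_cdf(x, params: DTPLNParams):
    """Distribution function of the DTPLN law.

    Equals ``delta`` on ``[0, a]`` (the point mass at zero plus the empty
    interval ``(0, a]``) and ``delta + (1-delta) * H(x)`` for ``x > a``,
    where ``H`` is the CDF of the shifted lognormal positive part.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("dtpln_cdf requires x >= 0")
    sigma = np.sqrt(params.sigma2_y)
    out = np.full(x.shape, params.delta, dtype=float)
    pos = x > params.a
    if np.any(pos):
        h = stats.norm.cdf((np.log(x[pos] - params.a) - params.mu_y) / sigma)
        out[pos] = params.delta + (1.0 - params.delta) * h
    return out if out.ndim else float(out)


def tpln_pdf(x, params: DTPLNParams):
    """Density of the three-parameter lognormal positive part, for x > a."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= params.a):
        raise ValueError("tpln_pdf requires x > a")
    z = np.log(x - params.a) - params.mu_y
    out = (np.exp(-z * z / (2.0 * params.sigma2_y))
           / ((x - params.a) * np.sqrt(2.0 * np.pi * params.sigma2_y)))
    return out if out.ndim else float(out)


def rdtpln(params: DTPLNParams, n: int, seed=None) -> SampleData:
    """Draw ``n`` observations from the DTPLN distribution.

    Each observation is 0 with probability ``delta`` and otherwise
    ``a + exp(y)`` with ``y ~ N(mu_y, sigma2_y)``; positives are
    therefore strictly greater than ``a``.  Reproducible for a fixed
    seed/generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    zero = rng.random(n) < params.delta
    y = rng.normal(params.mu_y, np.sqrt(params.sigma2_y), size=n)
    values = np.where(zero, 0.0, params.a + np.exp(y))
    return SampleData(values)
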
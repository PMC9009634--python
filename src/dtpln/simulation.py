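"""Monte Carlo benchmark engine: coverage probability (CP) and expected
length (EL) of the six interval methods over a parameter grid.

For each replicate a sample is drawn from the DTPLN law, the point
estimates are computed, every requested interval is built, and the
interval is scored against the true log-mean ``theta`` (recomputed from
the generating parameters, never estimated).  CP is the fraction of
intervals containing the true ``theta``; EL is the mean width on the
log-mean scale.

Replicates are driven by per-replicate seeds spawned deterministically
from the scenario seed, so results are reproducible and independent of
any scheduling.  Degenerate replicates (fewer than 3 positives, or all
positives equal) are redrawn and the redraw count reported.  Method
failures within a replicate are logged, counted, and excluded from that
method's aggregates; a scenario aborts if more than 2% of replicates
fail for any method.

The study grid of the accompanying benchmark uses ``a in {1, 5, 15}``,
``n in {30, 50, 100}``, ``delta in {0.1, 0.3, 0.5}``, ``mu_y = 2`` and
``sigma2_y in {0.3, 0.5, 0.8, 1.0, 2.0}`` with 5000 replicates and 5000
posterior/GPQ draws per replicate; :func:`benchmark_grid` builds it (at
configurable replicate counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DTPLNParams, rdtpln, theta_of
from .estimation import fit
from . import bayes, gci, mover

__all__ = [
    "METHODS",
    "ScenarioConfig",
    "MethodPerformance",
    "ScenarioResult",
    "run_scenario",
    "run_grid",
    "benchmark_grid",
]

logger = logging.getLogger("dtpln.simulation")

METHODS = ("HPD-NI1", "ET-NI1", "HPD-NI2", "ET-NI2", "GCI", "MOVER")

#: grid of the reference benchmark study
GRID_A = (1.0, 5.0, 15.0)
GRID_N = (30, 50, 100)
GRID_DELTA = (0.1, 0.3, 0.5)
GRID_SIGMA2 = (0.3, 0.5, 0.8, 1.0, 2.0)
GRID_MU = 2.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (parameter set + engine settings)."""

    a: float
    delta: float
    mu_y: float
    sigma2_y: float
    n: int
    reps: int = 5000
    m: int = 5000
    level: float = 0.95
    seed: int | None = None
    methods: tuple = METHODS

    def __post_init__(self) -> None:
        if self.reps < 1 or self.m < 100:
            raise ValueError("require reps >= 1 and m >= 100")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        DTPLNParams(self.delta, self.mu_y, self.sigma2_y, self.a)  # validate

    @property
    def params(self) -> DTPLNParams:
        return DTPLNParams(self.delta, self.mu_y, self.sigma2_y, self.a)


@dataclass(frozen=True)
class MethodPerformance:
    cp: float
    el: float
    failures: int


@dataclass(frozen=True)
class ScenarioResult:
    config: ScenarioConfig
    performance: dict = field(repr=False)
    theta_true: float = float("nan")
    redraws: int = 0
    threshold_fallbacks: int = 0

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        rows = [
            {"a": cfg.a, "n": cfg.n, "delta": cfg.delta,
             "sigma2": cfg.sigma2_y, "method": meth, "cp": perf.cp,
             "el": perf.el, "reps": cfg.reps, "m": cfg.m,
             "failures": perf.failures}
            for meth, perf in self.performance.items()
        ]
        return pd.DataFrame(rows)


def _draw_valid_sample(params, n, rng):
    """Sample from the DTPLN law, redrawing degenerate replicates."""
    redraws = 0
    while True:
        sample = rdtpln(params, n, seed=rng)
        if sample.n1 >= 3 and np.ptp(sample.positives) > 0:
            return sample, redraws
        redraws += 1


def run_scenario(cfg: ScenarioConfig, extra_methods: dict | None = None) -> ScenarioResult:
    """Run one scenario and aggregate CP/EL for every requested method.

    ``extra_methods`` maps extra method names to callables
    ``f(sample, est, cfg, rng) -> Interval`` scored alongside the
    built-in ones (used for oracle checks).
    """
    params = cfg.params
    theta_true = theta_of(params)
    extra_methods = extra_methods or {}
    names = list(cfg.methods) + list(extra_methods)
    covers = {meth: 0 for meth in names}
    widths = {meth: 0.0 for meth in names}
    fails = {meth: 0 for meth in names}
    need_ni1 = any(m in cfg.methods for m in ("HPD-NI1", "ET-NI1"))
    need_ni2 = any(m in cfg.methods for m in ("HPD-NI2", "ET-NI2"))
    ni2_cfg = bayes.NI2Config(alpha_level=1.0 - cfg.level)

    root = np.random.SeedSequence(cfg.seed)
    redraws = 0
    fallbacks = 0
    for rep_seq in root.spawn(cfg.reps):
        s_sample, s_ni1, s_ni2, s_gci, s_extra = rep_seq.spawn(5)
        rng = np.random.default_rng(s_sample)
        sample, rd = _draw_valid_sample(params, cfg.n, rng)
        redraws += rd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = fit(sample)
        fallbacks += est.threshold_fallback

        intervals = {}
        if need_ni1:
            try:
                post = bayes.draw_posterior_ni1(sample, est, m=cfg.m, seed=s_ni1)
                if "ET-NI1" in cfg.methods:
                    intervals["ET-NI1"] = bayes.equal_tailed(post.theta_draws, cfg.level)
                if "HPD-NI1" in cfg.methods:
                    intervals["HPD-NI1"] = bayes.hpd(post.theta_draws, cfg.level)
            except Exception as exc:
                logger.debug("NI1 failure: %s", exc)
                for meth in ("ET-NI1", "HPD-NI1"):
                    if meth in cfg.methods:
                        fails[meth] += 1
        if need_ni2:
            try:
                post = bayes.draw_posterior_ni2(sample, est, ni2_cfg, m=cfg.m, seed=s_ni2)
                if "ET-NI2" in cfg.methods:
                    intervals["ET-NI2"] = bayes.equal_tailed(post.theta_draws, cfg.level)
                if "HPD-NI2" in cfg.methods:
                    intervals["HPD-NI2"] = bayes.hpd(post.theta_draws, cfg.level)
            except Exception as exc:
                logger.debug("NI2 failure: %s", exc)
                for meth in ("ET-NI2", "HPD-NI2"):
                    if meth in cfg.methods:
                        fails[meth] += 1
        if "GCI" in cfg.methods:
            try:
                draws = gci.draw_gpq(est, sample.n0, sample.n1, m=cfg.m, seed=s_gci)
                intervals["GCI"] = gci.gci_interval(draws, cfg.level)
            except Exception as exc:
                logger.debug("GCI failure: %s", exc)
                fails["GCI"] += 1
        if "MOVER" in cfg.methods:
            try:
                intervals["MOVER"] = mover.mover_theta_interval(est, cfg.level)
            except Exception as exc:
                logger.debug("MOVER failure: %s", exc)
                fails["MOVER"] += 1
        if extra_methods:
            rng_extra = np.random.default_rng(s_extra)
            for meth, fn in extra_methods.items():
                try:
                    intervals[meth] = fn(sample, est, cfg, rng_extra)
                except Exception as exc:
                    logger.debug("%s failure: %s", meth, exc)
                    fails[meth] += 1

        for meth, iv in intervals.items():
            covers[meth] += iv.contains(theta_true)
            widths[meth] += iv.width

    performance = {}
    for meth in names:
        ok = cfg.reps - fails[meth]
        if fails[meth] > 0.02 * cfg.reps:
            raise RuntimeError(
                f"scenario aborted: method {meth} failed in {fails[meth]} of "
                f"{cfg.reps} replicates (> 2%)")
        performance[meth] = MethodPerformance(
            cp=covers[meth] / ok if ok else float("nan"),
            el=widths[meth] / ok if ok else float("nan"),
            failures=fails[meth])
    logger.info("scenario a=%g n=%d delta=%g sigma2=%g done (redraws=%d, "
                "threshold fallbacks=%d)", cfg.a, cfg.n, cfg.delta,
                cfg.sigma2_y, redraws, fallbacks)
    return ScenarioResult(cfg, performance, theta_true, redraws, fallbacks)


def run_grid(grid, extra_methods: dict | None = None) -> pd.DataFrame:
    """Run a list of scenarios; one tidy row per (scenario, method)."""
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    frames = []
    for i, cfg in enumerate(grid):
        logger.info("scenario %d/%d", i + 1, len(grid))
        frames.append(run_scenario(cfg, extra_methods).to_frame())
    return pd.concat(frames, ignore_index=True)


def benchmark_grid(reps: int = 5000, m: int = 5000, level: float = 0.95,
               seed: int | None = None, methods: tuple = METHODS):
    """The full 135-scenario benchmark grid (3 a x 3 n x 3 delta x 5 sigma2).

    Per-scenario seeds are derived deterministically from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    configs = []
    children = iter(root.spawn(len(GRID_A) * len(GRID_N) * len(GRID_DELTA)
                               * len(GRID_SIGMA2)))
    for a in GRID_A:
        for n in GRID_N:
            for delta in GRID_DELTA:
                for s2 in GRID_SIGMA2:
                    child = next(children)
                    configs.append(ScenarioConfig(
                        a=a, delta=delta, mu_y=GRID_MU, sigma2_y=s2, n=n,
                        reps=reps, m=m, level=level,
                        seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                        methods=methods))
    return configs
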
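"""Moment-matched marginal distributions for cohort simulation.

Clinical variables are reported as mean +/- SD on bounded or half-bounded
scales, so a marginal is only faithful if its *realised* moments -- after
truncation, discretisation or binning -- match the reported values.  Every
marginal here is a monotone map ``z -> x`` from a standard-normal latent,
which is what lets a Gaussian copula carry rank correlations through it
unchanged (for continuous margins) or with a quantifiable attenuation (for
discretised ones).

Fitting helpers solve small moment-matching problems:

* :func:`fit_truncnorm` -- truncated normal whose truncated mean/SD equal the
  targets (used for age, OSDI scales, pain).
* :func:`fit_lognorm_moments` -- closed-form lognormal moment match (HLA-DR,
  Schirmer, TBUT, where the printed coefficient of variation is near or
  above 1 and a nonnegative truncated normal cannot reach it).
* :func:`fit_lognorm_quantile` -- lognormal pinned by one tail probability
  (nerve density, tortuosity, reflectivity latents, where only a grading
  flag rate is specified).
* :func:`fit_ordinal` -- discretised normal on an integer grid (Oxford 0-5).
* :func:`fit_binned_lognorm` -- lognormal whose *binned* score mean/SD match
  (inflammatory-cell density behind the 4-level ICsc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class MarginalError(ValueError):
    """A marginal could not be fitted to the requested moments."""


@dataclass(frozen=True)
class TruncNormMarginal:
    """Truncated normal on [lo, hi]; ``loc``/``scale`` are the latent params."""

    loc: float
    scale: float
    lo: float = -np.inf
    hi: float = np.inf
    discrete: bool = False

    def from_z(self, z: np.ndarray) -> np.ndarray:
        a = (self.lo - self.loc) / self.scale
        b = (self.hi - self.loc) / self.scale
        u = stats.norm.cdf(z)
        return stats.truncnorm.ppf(u, a, b, loc=self.loc, scale=self.scale)


@dataclass(frozen=True)
class LogNormMarginal:
    """``x = shift + exp(mu + sigma * z)``."""

    mu: float
    sigma: float
    shift: float = 0.0
    discrete: bool = False

    def from_z(self, z: np.ndarray) -> np.ndarray:
        return self.shift + np.exp(self.mu + self.sigma * np.asarray(z))


@dataclass(frozen=True)
class OrdinalMarginal:
    """Integer grid obtained by cutting the latent normal at fixed cutpoints."""

    loc: float
    scale: float
    values: tuple[float, ...]
    cutpoints: tuple[float, ...]
    discrete: bool = True

    def from_z(self, z: np.ndarray) -> np.ndarray:
        zcuts = (np.asarray(self.cutpoints) - self.loc) / self.scale
        idx = np.searchsorted(zcuts, np.asarray(z))
        return np.asarray(self.values, dtype=float)[idx]

    def category_probs(self) -> np.ndarray:
        zcuts = (np.asarray(self.cutpoints) - self.loc) / self.scale
        cdf = np.concatenate([[0.0], stats.norm.cdf(zcuts), [1.0]])
        return np.diff(cdf)


def fit_truncnorm(
    mean: float, sd: float, lo: float = -np.inf, hi: float = np.inf
) -> TruncNormMarginal:
    """Truncated normal whose realised mean/SD match ``mean``/``sd``."""
    if sd <= 0:
        raise MarginalError(f"sd must be positive, got {sd}")
    if not (lo < mean < hi):
        raise MarginalError(f"mean {mean} outside truncation bounds [{lo}, {hi}]")

    def resid(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        dist = stats.truncnorm(a, b, loc=loc, scale=scale)
        return [dist.mean() - mean, dist.std() - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise MarginalError(
            f"no truncated normal on [{lo}, {hi}] has mean {mean}, sd {sd}"
        )
    loc, log_scale = sol.x
    return TruncNormMarginal(loc=float(loc), scale=float(np.exp(log_scale)), lo=lo, hi=hi)


def fit_lognorm_moments(mean: float, sd: float, shift: float = 0.0) -> LogNormMarginal:
    m = mean - shift
    if m <= 0 or sd <= 0:
        raise MarginalError(f"need mean > shift and sd > 0 (mean={mean}, sd={sd})")
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return LogNormMarginal(mu=float(mu), sigma=float(np.sqrt(sigma2)), shift=shift)


def fit_lognorm_quantile(
    threshold: float, p_below: float, sigma: float, shift: float = 0.0
) -> LogNormMarginal:
    """Lognormal with ``P(X <= threshold) = p_below`` at a chosen shape ``sigma``."""
    if not 0 < p_below < 1:
        raise MarginalError(f"p_below must be in (0,1), got {p_below}")
    if threshold <= shift:
        raise MarginalError("threshold must exceed shift")
    mu = np.log(threshold - shift) - sigma * stats.norm.ppf(p_below)
    return LogNormMarginal(mu=float(mu), sigma=float(sigma), shift=shift)


def _discrete_moments(probs: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    m = float(probs @ values)
    v = float(probs @ values**2) - m * m
    return m, float(np.sqrt(max(v, 0.0)))


def fit_ordinal(
    mean: float,
    sd: float,
    values: tuple[float, ...],
    cutpoints: tuple[float, ...] | None = None,
) -> OrdinalMarginal:
    """Discretised normal whose category mean/SD match (e.g. Oxford 0..5)."""
    vals = np.asarray(values, dtype=float)
    if cutpoints is None:
        cutpoints = tuple((vals[:-1] + vals[1:]) / 2.0)
    cuts = np.asarray(cutpoints, dtype=float)

    def resid(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        cdf = np.concatenate([[0.0], stats.norm.cdf((cuts - loc) / scale), [1.0]])
        m, s = _discrete_moments(np.diff(cdf), vals)
        return [m - mean, s - sd]

    sol = optimize.root(resid, x0=[mean, np.log(max(sd, 1e-3))], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise MarginalError(
            f"no discretised normal on {values} has mean {mean}, sd {sd}"
        )
    loc, log_scale = sol.x
    return OrdinalMarginal(
        loc=float(loc),
        scale=float(np.exp(log_scale)),
        values=tuple(vals),
        cutpoints=tuple(cuts),
    )


def fit_binned_lognorm(
    score_mean: float,
    score_sd: float,
    bin_edges: tuple[float, ...] = (10.0, 50.0, 100.0),
) -> LogNormMarginal:
    """Lognormal density whose binned 0..k score has the target mean/SD.

    The score is ``digitize(x, bin_edges)``; probabilities are evaluated
    exactly through the normal CDF in log space, so the fitted marginal is
    unbiased for the score moments (no Monte Carlo involved).
    """
    edges = np.log(np.asarray(bin_edges, dtype=float))
    vals = np.arange(len(bin_edges) + 1, dtype=float)

    def resid(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        cdf = np.concatenate([[0.0], stats.norm.cdf((edges - mu) / sigma), [1.0]])
        m, s = _discrete_moments(np.diff(cdf), vals)
        return [m - score_mean, s - score_sd]

    sol = optimize.root(resid, x0=[np.log(50.0), 0.0], method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise MarginalError(
            f"no lognormal yields binned score mean {score_mean}, sd {score_sd}"
        )
    mu, log_sigma = sol.x
    return LogNormMarginal(mu=float(mu), sigma=float(np.exp(log_sigma)))
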
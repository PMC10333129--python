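"""Posterior-summary helpers shared across the modelling modules.

Conventions used throughout the package: point estimates are posterior
modes from a Gaussian kernel density (Silverman bandwidth), intervals are
95% highest-posterior-density intervals, and significance is reported as
pMCMC = twice the smaller tail proportion of draws relative to zero with a
finite-sample correction, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["posterior_mode", "hpd_interval", "pmcmc", "ParamSummary", "summarize_draws"]


def posterior_mode(draws: np.ndarray) -> float:
    """Mode of a 1-d posterior sample via Gaussian KDE (Silverman)."""
    draws = np.asarray(draws, dtype=float)
    if draws.std() == 0:
        return float(draws[0])
    kde = gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = max(int(np.ceil(prob * n)), 2)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def pmcmc(draws: np.ndarray, test_value: float = 0.0) -> float:
    """Approximate two-sided MCMC p-value against ``test_value``."""
    d = np.asarray(draws, dtype=float) - test_value
    n = len(d)
    lo = np.sum(d <= 0) + 1
    hi = np.sum(d >= 0) + 1
    return float(min(2.0 * min(lo, hi) / (n + 1), 1.0))


@dataclass
class ParamSummary:
    name: str
    mode: float
    mean: float
    ci_low: float
    ci_high: float
    pmcmc: float
    n_draws: int

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pmcmc": self.pmcmc,
            "n_draws": self.n_draws,
        }


def summarize_draws(draws: np.ndarray, name: str = "", prob: float = 0.95,
                    interval: str = "hpd") -> ParamSummary:
    draws = np.asarray(draws, dtype=float)
    if interval == "hpd":
        lo, hi = hpd_interval(draws, prob)
    else:
        lo, hi = np.quantile(draws, [(1 - prob) / 2, 1 - (1 - prob) / 2])
    return ParamSummary(
        name=name,
        mode=posterior_mode(draws),
        mean=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        pmcmc=pmcmc(draws),
        n_draws=len(draws),
    )
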
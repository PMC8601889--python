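"""Seasonal-climatology surrogates: the seasonality-only null model.

A surrogate keeps a series' repeating seasonal cycle but destroys any
dynamics in the anomalies: (i) compute the 12 calendar-month climatological
means, (ii) subtract them to get residuals, (iii) shuffle the residuals
across all observed months, (iv) add them back onto the tiled climatology.
Forecast skill on surrogates estimates how much of the real skill is
attributable to seasonality alone.

Choices worth stating: residuals are permuted without replacement (a true
shuffle, conserving the residual multiset) and across *all* observed
positions, not within calendar months — within-month shuffling would preserve
exactly the seasonal variance structure the null is meant to destroy.
Missing months stay missing, so real series and surrogates are forecast on
identical support.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edm import EmbeddingConfig, select_embedding
from .errors import (
    SeriesUnusableError,
    UndefinedClimatologyError,
    UndefinedCorrelationError,
)
from .timeseries import MonthlyTimeSeries

__all__ = [
    "Climatology",
    "SurrogateSkill",
    "seasonal_climatology",
    "make_surrogate",
    "surrogate_skill",
]


@dataclass
class Climatology:
    """Calendar-month means and observation counts, indexed Jan..Dec (0..11)."""

    monthly_means: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.monthly_means = np.asarray(self.monthly_means, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.monthly_means.shape != (12,) or self.counts.shape != (12,):
            raise ValueError("climatology needs exactly 12 calendar months")

    def tiled(self, series: MonthlyTimeSeries) -> np.ndarray:
        """The climatology repeated along a series' grid."""
        return self.monthly_means[series.calendar_months() - 1]


def seasonal_climatology(series: MonthlyTimeSeries) -> Climatology:
    """Average all observations of each calendar month.

    Raises
    ------
    UndefinedClimatologyError
        If some calendar month has no non-missing observation.
    """
    months = series.calendar_months()
    means = np.full(12, np.nan)
    counts = np.zeros(12, dtype=int)
    for m in range(1, 13):
        vals = series.values[(months == m) & series.observed_mask]
        counts[m - 1] = vals.size
        if vals.size:
            means[m - 1] = vals.mean()
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise UndefinedClimatologyError(
            f"undefined climatology month(s): {[int(m) + 1 for m in empty]}"
        )
    return Climatology(means, counts)


def make_surrogate(
    series: MonthlyTimeSeries,
    climatology: Climatology,
    rng_seed: int | np.random.SeedSequence,
) -> MonthlyTimeSeries:
    """Climatology plus uniformly shuffled residuals; missing months preserved."""
    rng = np.random.default_rng(rng_seed)
    cycle = climatology.tiled(series)
    values = series.values
    obs = series.observed_mask
    residuals = values[obs] - cycle[obs]
    shuffled = rng.permutation(residuals)
    out = np.full_like(values, np.nan)
    out[obs] = cycle[obs] + shuffled
    # a large negative anomaly relocated onto a low-climatology month can
    # undershoot zero; the null keeps it (clipping would break the residual
    # multiset conservation the test relies on)
    return series.copy_with(out, allow_negative=True)


@dataclass
class SurrogateSkill:
    """Skill of an ensemble of surrogates for one series.

    ``rhos`` holds one entry per surrogate (NaN where the forecast failed);
    ``mean_rho`` averages the successful ones.  Surrogate ``i`` is regenerable
    from ``SeedSequence((master_seed, i))``.
    """

    rhos: np.ndarray
    mean_rho: float
    n_failed: int
    master_seed: int


def surrogate_skill(
    series: MonthlyTimeSeries,
    n_surrogates: int,
    config: EmbeddingConfig | None = None,
    rng_seed: int = 0,
) -> SurrogateSkill:
    """Forecast skill of ``n_surrogates`` seasonal surrogates of a series.

    Each surrogate gets an independent sub-seed derived from
    ``(rng_seed, index)``; a surrogate whose forecast is degenerate (for
    example a constant aggregate) is recorded as failed and excluded from the
    mean.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    clim = seasonal_climatology(series)
    rhos = np.full(n_surrogates, np.nan)
    for i in range(n_surrogates):
        surrogate = make_surrogate(
            series, clim, np.random.SeedSequence((rng_seed, i))
        )
        try:
            rhos[i] = select_embedding(surrogate, config).rho
        except (SeriesUnusableError, UndefinedCorrelationError):
            continue
    ok = ~np.isnan(rhos)
    mean = float(rhos[ok].mean()) if ok.any() else float("nan")
    return SurrogateSkill(
        rhos=rhos, mean_rho=mean, n_failed=int((~ok).sum()), master_seed=rng_seed
    )
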
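"""Univariate state-space reconstruction and simplex-projection forecasting.

The method: embed a single monthly series in E dimensions with unit lag
(Takens delay embedding), then forecast each point one month ahead from the
E+1 nearest neighbors of its delay vector, weighting each neighbor's observed
continuation by ``exp(-d/d_min)`` where ``d_min`` is the distance to the
closest neighbor.  Skill is the Pearson correlation between observations and
these leave-one-out predictions; the embedding dimension is chosen by scanning
E over a range and keeping the E with the highest skill.

Conventions adopted here (documented, since the classic method leaves them
open):

* Leave-one-out excludes only the target's own delay vector from the library;
  there is no temporal exclusion radius.
* Skill is the raw Pearson coefficient and may be negative.  Values below zero
  mean "worse than the mean forecast"; they are reported unclamped so that
  averaging over Monte-Carlo trials is unbiased.
* Series are embedded raw, without normalisation: Pearson correlation is
  scale-invariant, and the aggregation experiments compare raw cell-density
  sums.
* Missing months propagate: any delay vector or forecast target touching a
  missing month is dropped, never interpolated.
* Exact duplicates of the target pattern (zero distance) all enter the
  neighbor set with weight 1, even if that exceeds E+1 neighbors; the
  remaining selected neighbors are weighted ``exp(-d/d~)`` with ``d~`` the
  smallest nonzero selected distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    InsufficientLengthError,
    InsufficientPredictionsError,
    InvalidDimensionError,
    SeriesUnusableError,
    UndefinedCorrelationError,
)
from .timeseries import MonthlyTimeSeries

__all__ = [
    "EmbeddingConfig",
    "PredictionResult",
    "lagged_embedding",
    "simplex_forecast",
    "select_embedding",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding-scan settings.

    E_min..E_max is the scanned range of embedding dimensions, tau the lag in
    months, tp the forecast horizon in months.  The neighbor count follows the
    classic E+1 rule.  ``tie_tol`` is the skill margin below which two E are
    considered tied (ties resolve to the smaller, more parsimonious E).
    """

    E_min: int = 1
    E_max: int = 10
    tau: int = 1
    tp: int = 1
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 1 <= self.E_min <= self.E_max:
            raise ValueError("require 1 <= E_min <= E_max")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.tp < 1:
            raise ValueError("tp must be >= 1")


@dataclass
class PredictionResult:
    """Outcome of a simplex forecast.

    ``rho`` is the raw Pearson correlation of the (observed, predicted) pairs
    and may be negative.  ``times`` holds the grid index of each forecast
    target ``t + tp``.
    """

    E_opt: int
    rho: float
    n_pairs: int
    times: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)

    @property
    def pairs(self) -> list[tuple[int, float, float]]:
        return [
            (int(t), float(o), float(p))
            for t, o, p in zip(self.times, self.observed, self.predicted)
        ]

    def as_record(self, series_id: str = "") -> dict:
        """Flat record for tidy output."""
        return {
            "series_id": series_id,
            "E_opt": self.E_opt,
            "rho": self.rho,
            "n_pairs": self.n_pairs,
        }


def lagged_embedding(
    series: MonthlyTimeSeries, E: int, tau: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embed a series in E dimensions.

    Returns ``(times, points)``: ``points[i]`` is the vector
    ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})`` for ``t = times[i]``.  Vectors
    touching a missing month are omitted.

    Raises
    ------
    InvalidDimensionError
        If ``E < 1``.
    InsufficientLengthError
        If the series is shorter than ``E*tau + 1``.
    """
    if E < 1:
        raise InvalidDimensionError(f"invalid dimension E={E}")
    x = series.values
    n = x.size
    if n < E * tau + 1:
        raise InsufficientLengthError(
            f"insufficient length: need >= {E * tau + 1} months, have {n}"
        )
    t0 = (E - 1) * tau
    times = np.arange(t0, n)
    # column j holds x_{t - j*tau}
    cols = [x[t0 - j * tau : n - j * tau] for j in range(E)]
    points = np.stack(cols, axis=1)
    ok = ~np.isnan(points).any(axis=1)
    return times[ok], points[ok]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError(
            "undefined correlation: constant values across pairs"
        )
    return float(np.corrcoef(a, b)[0, 1])


def simplex_forecast(
    series: MonthlyTimeSeries, E: int, config: EmbeddingConfig | None = None
) -> PredictionResult:
    """One-step simplex projection with leave-one-out cross-validation.

    For every delay vector whose forecast target ``x_{t+tp}`` is observed, the
    library is every *other* delay vector with an observed target; the
    prediction is the ``exp(-d/d_min)``-weighted mean of the E+1 nearest
    library vectors' targets.  When fewer than E+1 library points exist, all
    available ones are used.

    Raises
    ------
    InsufficientPredictionsError
        Fewer than 3 valid (observed, predicted) pairs.
    UndefinedCorrelationError
        Observations (or predictions) constant across the pairs.
    """
    cfg = config or EmbeddingConfig()
    tau, tp = cfg.tau, cfg.tp
    times, points = lagged_embedding(series, E, tau)
    x = series.values
    n = x.size

    # keep only points with an observed forecast target; these form both the
    # prediction set and the library (minus self)
    tgt_idx = times + tp
    has_target = np.zeros(times.size, dtype=bool)
    in_range = tgt_idx < n
    has_target[in_range] = ~np.isnan(x[tgt_idx[in_range]])
    times = times[has_target]
    points = points[has_target]
    m = times.size
    if m < 3:
        raise InsufficientPredictionsError(
            f"insufficient predictions: only {m} valid pairs"
        )
    targets = x[times + tp]

    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    k = min(E + 1, m - 1)

    # stable argsort: ties resolve to the earlier library time
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    rows = np.arange(m)[:, None]
    d_sel = D[rows, order]
    d_min = d_sel[:, 0]

    predicted = np.empty(m)
    regular = d_min > 0
    if regular.any():
        w = np.exp(-d_sel[regular] / d_min[regular, None])
        y = targets[order[regular]]
        predicted[regular] = (w * y).sum(axis=1) / w.sum(axis=1)
    for i in np.flatnonzero(~regular):
        # duplicate target pattern in the library: every zero-distance point
        # joins with weight 1; nonzero selected neighbors keep the exponential
        # kernel scaled by the smallest nonzero selected distance
        row = D[i]
        zero_idx = np.flatnonzero(row == 0)
        nz_sel = order[i][d_sel[i] > 0]
        idx = np.concatenate([zero_idx, nz_sel])
        weights = np.ones(idx.size)
        if nz_sel.size:
            d_nz = row[nz_sel]
            weights[zero_idx.size :] = np.exp(-d_nz / d_nz.min())
        predicted[i] = float(np.dot(weights, targets[idx]) / weights.sum())

    rho = _pearson(targets, predicted)
    return PredictionResult(
        E_opt=E,
        rho=rho,
        n_pairs=m,
        times=times + tp,
        observed=targets.copy(),
        predicted=predicted,
    )


def select_embedding(
    series: MonthlyTimeSeries, config: EmbeddingConfig | None = None
) -> PredictionResult:
    """Scan E over ``config.E_min..E_max`` and return the best forecast.

    Dimensions that fail (series too short, too few pairs, degenerate
    correlation) are skipped; skill ties within ``config.tie_tol`` resolve to
    the smallest E.

    Raises
    ------
    SeriesUnusableError
        If no E in the range admits a forecast.
    """
    cfg = config or EmbeddingConfig()
    best: PredictionResult | None = None
    for E in range(cfg.E_min, cfg.E_max + 1):
        try:
            result = simplex_forecast(series, E, cfg)
        except (
            InsufficientLengthError,
            InsufficientPredictionsError,
            UndefinedCorrelationError,
            InvalidDimensionError,
        ):
            continue
        if best is None or result.rho > best.rho + cfg.tie_tol:
            best = result
    if best is None:
        raise SeriesUnusableError(
            f"series unusable: no feasible E in {cfg.E_min}..{cfg.E_max}"
        )
    return best
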